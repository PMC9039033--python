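import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevostab import parallel_evolution as pe
from coevostab import synthetic_data as sd
from coevostab.io_formats import GeneCatalog, MUTATION_COLUMNS


def _table(rows):
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


class TestFilterMutations:
    def test_frequency_floor_is_inclusive(self):
        t = _table([("C1", "coculture", "LP", "geneA", 1, "A", "G", "nonsynonymous", 0.05)])
        assert len(pe.filter_mutations(t)) == 1

    def test_below_floor_removed_per_species(self):
        t = _table(
            [
                ("C1", "coculture", "LP", "geneA", 1, "A", "G", "nonsynonymous", 0.04),
                ("C1", "coculture", "SC", "geneB", 2, "A", "G", "nonsynonymous", 0.29),
                ("C2", "coculture", "SC", "geneB", 3, "A", "G", "nonsynonymous", 0.30),
            ]
        )
        out = pe.filter_mutations(t)
        assert list(out["population_id"]) == ["C2"]

    def test_intergenic_removed_even_at_high_frequency(self):
        t = _table([("C1", "coculture", "LP", "INTERGENIC", 1, "A", "G", "intergenic", 0.9)])
        assert len(pe.filter_mutations(t)) == 0

    def test_empty_table_passes_through(self):
        t = _table([])
        assert len(pe.filter_mutations(t)) == 0

    def test_missing_species_threshold_errors(self):
        t = _table([("C1", "coculture", "XX", "geneA", 1, "A", "G", "nonsynonymous", 0.5)])
        with pytest.raises(ValueError, match="XX"):
            pe.filter_mutations(t)

    def test_class_restriction(self):
        t = _table(
            [
                ("C1", "coculture", "LP", "geneA", 1, "A", "G", "synonymous", 0.5),
                ("C1", "coculture", "LP", "geneB", 2, "A", "G", "nonsense", 0.5),
            ]
        )
        out = pe.filter_mutations(t, classes=pe.AMINO_ACID_CHANGING)
        assert list(out["gene_id"]) == ["geneB"]


class TestCollapseToHits:
    def test_shared_identical_mutation_counts_once(self):
        # the standing-variation case: one SNP present in all ten populations
        rows = [
            (f"C{i}", "coculture", "LP", "copZ", 602, "G", "T", "nonsynonymous", 0.95)
            for i in range(1, 11)
        ]
        hits = pe.collapse_to_hits(_table(rows))
        assert hits.hits_per_gene["copZ"] == 1
        assert hits.n_draws_observed == 1
        assert hits.matrix.loc["copZ", "C1"]  # lexicographically first population
        assert not hits.matrix.loc["copZ", "C10"]

    def test_multiple_mutations_one_gene_one_population_single_hit(self):
        rows = [
            ("C1", "coculture", "LP", "geneA", p, "A", "G", "nonsynonymous", 0.5)
            for p in (10, 20, 30)
        ]
        hits = pe.collapse_to_hits(_table(rows))
        assert hits.hits_per_gene["geneA"] == 1
        assert hits.n_draws_observed == 3  # records survive rule 1, collapse is per gene

    def test_distinct_mutations_in_two_populations_two_hits(self):
        rows = [
            ("C1", "coculture", "LP", "geneA", 10, "A", "G", "nonsynonymous", 0.5),
            ("C2", "coculture", "LP", "geneA", 20, "C", "T", "nonsynonymous", 0.5),
        ]
        hits = pe.collapse_to_hits(_table(rows))
        assert hits.hits_per_gene["geneA"] == 2

    def test_explicit_population_order_controls_first_instance(self):
        rows = [
            ("C1", "coculture", "LP", "geneA", 10, "A", "G", "nonsynonymous", 0.5),
            ("C2", "coculture", "LP", "geneA", 10, "A", "G", "nonsynonymous", 0.5),
        ]
        hits = pe.collapse_to_hits(_table(rows), population_order=["C2", "C1"])
        assert hits.matrix.loc["geneA", "C2"]
        assert not hits.matrix.loc["geneA", "C1"]

    def test_empty_table(self):
        hits = pe.collapse_to_hits(_table([]))
        assert hits.n_draws_observed == 0
        assert hits.hits_per_gene.empty

    def test_intergenic_rows_rejected(self):
        t = _table([("C1", "coculture", "LP", "INTERGENIC", 1, "A", "G", "intergenic", 0.9)])
        with pytest.raises(ValueError, match="intergenic"):
            pe.collapse_to_hits(t)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_invariants_on_generated_tables(self, seed):
        """Hit counts bounded by populations; draws bound total hits."""
        cat = sd.synthetic_gene_catalog(n_genes=40, seed=99)
        cfg = sd.SyntheticMutationConfig(
            gene_catalog=cat, n_populations=5, mean_mutations=8, sd_mutations=3,
            shared_mutations=1, seed=seed,
        )
        table = pe.filter_mutations(sd.generate_mutation_table(cfg))
        hits = pe.collapse_to_hits(table)
        assert (hits.hits_per_gene <= hits.n_populations).all()
        assert hits.hits_per_gene.sum() <= hits.n_draws_observed
        assert (hits.hits_per_gene == hits.matrix.sum(axis=1)).all()


class TestSimulateNull:
    def test_single_gene_gets_every_draw(self):
        cat = GeneCatalog(pd.Series({"only": 500}))
        res = pe.simulate_null(pe.NullModelConfig(cat, n_draws=7, n_reps=50, seed=0))
        assert res.per_gene_max_hits["only"] == 7
        assert res.tail_counts[0, 7] == 50  # every replicate reaches 7

    def test_mean_hits_match_length_weights(self, tiny_catalog):
        # lengths (100, 200, 700), M = 10 -> expected hits (1, 2, 7)
        res = pe.simulate_null(pe.NullModelConfig(tiny_catalog, n_draws=10, n_reps=10_000, seed=3))
        mean_hits = res.tail_counts[:, 1:].sum(axis=1) / res.n_reps
        p = tiny_catalog.weights()
        expected = 10 * p
        se = np.sqrt(10 * p * (1 - p) / res.n_reps)
        assert np.all(np.abs(mean_hits - expected) < 3 * se)

    def test_draw_conservation(self, tiny_catalog):
        res = pe.simulate_null(pe.NullModelConfig(tiny_catalog, n_draws=10, n_reps=500, seed=1))
        # sum_k tail[g, k>=1] counts each draw exactly once per replicate
        assert res.tail_counts[:, 1:].sum() == 10 * 500

    def test_determinism_bit_identical(self, tiny_catalog):
        cfg = pe.NullModelConfig(tiny_catalog, n_draws=10, n_reps=2_000, seed=42)
        a, b = pe.simulate_null(cfg), pe.simulate_null(cfg)
        assert (a.per_gene_max_hits == b.per_gene_max_hits).all()
        assert (a.tail_counts == b.tail_counts).all()

    def test_zero_draws(self, tiny_catalog):
        res = pe.simulate_null(pe.NullModelConfig(tiny_catalog, n_draws=0, n_reps=10, seed=0))
        assert (res.per_gene_max_hits == 0).all()

    def test_empty_catalog_with_draws_rejected(self):
        cat = GeneCatalog(pd.Series(dtype=np.int64))
        with pytest.raises(ValueError, match="empty"):
            pe.NullModelConfig(cat, n_draws=3, n_reps=10, seed=0)

    def test_tail_probabilities_match_enumeration(self):
        """Monte-Carlo tails vs exhaustive enumeration on a 3-gene, M=4 case."""
        cat = GeneCatalog(pd.Series({"a": 150, "b": 350, "c": 500}))
        M, n_reps = 4, 10_000
        exact = _enumerate_tails(cat.weights(), M)
        res = pe.simulate_null(pe.NullModelConfig(cat, n_draws=M, n_reps=n_reps, seed=5))
        for g in range(3):
            for k in range(1, M + 1):
                q = exact[g][k]
                mc = res.tail_counts[g, k] / n_reps if k < res.tail_counts.shape[1] else 0.0
                se = np.sqrt(q * (1 - q) / n_reps)
                assert abs(mc - q) <= 3 * se + 1e-12


def _enumerate_tails(weights, n_draws):
    """Exact P(gene g receives >= k of n_draws weighted draws), by brute force."""
    n_genes = len(weights)
    tails = [np.zeros(n_draws + 1) for _ in range(n_genes)]
    for outcome in itertools.product(range(n_genes), repeat=n_draws):
        prob = np.prod([weights[g] for g in outcome])
        counts = np.bincount(outcome, minlength=n_genes)
        for g in range(n_genes):
            for k in range(1, counts[g] + 1):
                tails[g][k] += prob
    return tails


class TestCallMultihit:
    def _null(self, max_hits, n_reps=10_000):
        """Build a NullModelResult with prescribed per-gene maxima."""
        genes = pd.Index(sorted(max_hits))
        mx = pd.Series({g: max_hits[g] for g in genes})
        kmax = int(mx.max())
        tail = np.zeros((len(genes), kmax + 2), dtype=np.int64)
        tail[:, 0] = n_reps
        for i, g in enumerate(genes):
            for k in range(1, mx[g] + 1):
                tail[i, k] = max(1, n_reps // 10 ** k)
        return pe.NullModelResult(genes, mx, tail, n_reps, 10, 0)

    def _hits(self, counts):
        n_pop = max(counts.values()) if counts else 1
        mat = pd.DataFrame(
            {f"P{j}": [j < c for g, c in counts.items()] for j in range(n_pop)},
            index=list(counts),
        )
        return pe.HitTable(matrix=mat, n_draws_observed=sum(counts.values()))

    def test_observed_above_null_max_significant(self):
        calls = pe.call_multihit(self._hits({"g": 4}), self._null({"g": 3}))
        assert calls.loc[0, "significant"]

    def test_tie_with_null_max_not_significant(self):
        calls = pe.call_multihit(self._hits({"g": 3}), self._null({"g": 3}))
        assert not calls.loc[0, "significant"]

    def test_single_population_hit_never_significant(self):
        calls = pe.call_multihit(self._hits({"g": 1}), self._null({"g": 0}))
        assert not calls.loc[0, "significant"]

    def test_missing_gene_errors(self):
        with pytest.raises(KeyError):
            pe.call_multihit(self._hits({"absent": 2}), self._null({"other": 1}))

    def test_pvalue_uses_pseudocount(self):
        null = self._null({"g": 3}, n_reps=10_000)
        calls = pe.call_multihit(self._hits({"g": 5}), null).set_index("gene_id")
        # no replicate reached 5 hits -> p = 1/(n_reps + 1), never zero
        assert calls.loc["g", "pvalue"] == pytest.approx(1 / 10_001)


class TestHitHistogram:
    def test_mean_length_per_hit_class(self, tiny_catalog):
        mat = pd.DataFrame(
            [[True, True], [True, True]], index=["geneB", "geneC"], columns=["C1", "C2"]
        )
        hits = pe.HitTable(matrix=mat, n_draws_observed=4)
        cat = GeneCatalog(pd.Series({"geneB": 900, "geneC": 1100}))
        hist = pe.hit_histogram(hits, cat)
        assert hist.loc[2, "n_genes"] == 2
        assert hist.loc[2, "mean_length_bp"] == pytest.approx(1000.0)

    def test_unhit_genes_excluded(self, tiny_catalog):
        hits = pe.HitTable(matrix=pd.DataFrame(dtype=bool), n_draws_observed=0)
        assert pe.hit_histogram(hits, tiny_catalog).empty

    def test_null_histogram_partitions_by_max(self, tiny_catalog):
        res = pe.simulate_null(pe.NullModelConfig(tiny_catalog, n_draws=10, n_reps=200, seed=0))
        hist = pe.null_hit_histogram(res, tiny_catalog)
        assert hist["n_genes"].sum() == (res.per_gene_max_hits >= 1).sum()


class TestDisplayFilter:
    def _rows(self, freqs, pops=None):
        pops = pops or [f"C{i}" for i in range(1, len(freqs) + 1)]
        return _table(
            [
                (p, "coculture", "LP", "geneA", 100 + i, "A", "G", "nonsynonymous", f)
                for i, (p, f) in enumerate(zip(pops, freqs))
            ]
        )

    def test_three_populations_one_above_point2(self):
        assert pe.display_filter(self._rows([0.05, 0.1, 0.21])) == ["geneA"]

    def test_all_at_point2_excluded_strict(self):
        assert pe.display_filter(self._rows([0.2, 0.2, 0.2])) == []

    def test_two_populations_excluded(self):
        assert pe.display_filter(self._rows([0.9, 0.9])) == []


def test_min_read_support():
    assert pe.min_read_support(0.05, 200) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        pe.min_read_support(0.0, 200)
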