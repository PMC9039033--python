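"""Multi-hit gene detection under a gene-length-weighted neutral null model.

In an evolve-and-resequence experiment, genes mutated in many independent
replicate populations ("multi-hit" genes) are candidate targets of natural
selection — but long genes collect mutations more often than short ones
under strictly neutral evolution.  This module implements:

* the frequency/class filtering rules applied to called mutations,
* the collapsing rules that turn per-population mutation lists into a
  gene x population hit matrix,
* a Monte-Carlo null in which the observed number of mutations is thrown
  at the gene catalog with probability proportional to gene length,
* the significance rule (a gene is a significant multi-hit gene when its
  observed hit count is at least 2 and strictly exceeds the maximum hit
  count that gene reached in any of the null replicates), and
* the hit-count / mean-gene-size grouping used to compare the observed
  spectrum of parallelism against the neutral expectation.

The significance rule is family-wise conservative by construction: with
10,000 null replicates it asks the observation to beat a ~99.99th
percentile of the per-gene null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import INTERGENIC, GeneCatalog, MutationClass, validate_mutation_table

__all__ = [
    "DEFAULT_FREQUENCY_THRESHOLDS",
    "CODING_CLASSES",
    "HitTable",
    "NullModelConfig",
    "NullModelResult",
    "filter_mutations",
    "collapse_to_hits",
    "simulate_null",
    "call_multihit",
    "hit_histogram",
    "null_hit_histogram",
    "display_filter",
]

#: Variant-frequency floors per species.  They reflect the minimum read
#: support at each species' sequencing depth (5% of ~200x for LP, 30% of
#: ~50x for SC, i.e. roughly ten supporting reads either way).
DEFAULT_FREQUENCY_THRESHOLDS: Mapping[str, float] = {"LP": 0.05, "SC": 0.30}

#: Classes that represent a change inside an ORF.
CODING_CLASSES = (
    MutationClass.synonymous.value,
    MutationClass.nonsynonymous.value,
    MutationClass.nonsense.value,
    MutationClass.indel.value,
)

#: Classes counted for the parallelism analyses (synonymous changes are
#: excluded by default: they are not expected to respond to selection).
AMINO_ACID_CHANGING = (
    MutationClass.nonsynonymous.value,
    MutationClass.nonsense.value,
    MutationClass.indel.value,
)


def min_read_support(frequency_threshold: float, coverage: float) -> float:
    """Read support implied by a frequency floor at a given sequencing depth.

    A variant at the 5% floor in a sample sequenced to ~200x depth is
    backed by about 10 reads — the usual justification for choosing the
    floor in the first place.
    """
    if not 0 < frequency_threshold <= 1:
        raise ValueError("frequency_threshold must be in (0, 1]")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    return frequency_threshold * coverage


def filter_mutations(
    table: pd.DataFrame,
    thresholds: Optional[Mapping[str, float]] = None,
    classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Apply the per-species frequency floor and drop intergenic calls.

    Parameters
    ----------
    table
        Mutation table (schema of :mod:`coevostab.io_formats`).
    thresholds
        Map of species code to minimum retained allele frequency
        (inclusive).  Defaults to :data:`DEFAULT_FREQUENCY_THRESHOLDS`.
        Every species present in the table must have a threshold.
    classes
        If given, additionally restrict to these mutation classes (e.g.
        :data:`AMINO_ACID_CHANGING` for the parallelism analyses).
        Intergenic rows are removed regardless.

    Returns
    -------
    pandas.DataFrame
        A new, filtered table; the input is not modified.
    """
    if thresholds is None:
        thresholds = DEFAULT_FREQUENCY_THRESHOLDS
    present = set(table["species"].unique())
    missing = present - set(thresholds)
    if missing:
        raise ValueError(f"no frequency threshold supplied for species {sorted(missing)}")
    if len(table) == 0:
        return table.copy()
    floor = table["species"].map(thresholds)
    keep = (table["frequency"] >= floor) & (table["class"] != MutationClass.intergenic.value)
    if classes is not None:
        keep &= table["class"].isin(list(classes))
    return table.loc[keep].copy()


@dataclass
class HitTable:
    """Gene x population presence matrix after the collapsing rules.

    Attributes
    ----------
    matrix
        Boolean DataFrame, rows = gene ids, columns = population ids, in
        the population order used for the "first instance" rule.
    n_draws_observed
        Number of mutation records surviving the cross-population
        identical-mutation deduplication — the M fed to the null model.
    """

    matrix: pd.DataFrame
    n_draws_observed: int
    species: Optional[str] = None
    treatment: Optional[str] = None

    @property
    def hits_per_gene(self) -> pd.Series:
        return self.matrix.sum(axis=1).astype(int)

    @property
    def n_populations(self) -> int:
        return self.matrix.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index


def collapse_to_hits(
    table: pd.DataFrame,
    population_order: Optional[Sequence[str]] = None,
) -> HitTable:
    """Collapse a filtered mutation table into per-gene hit counts.

    Two rules are applied, in order:

    1. An identical mutation (same position and alternate allele) observed
       in more than one population is counted only once, in the first
       population carrying it — such sharing indicates standing genetic
       variation rather than independent de novo events.  "First" follows
       ``population_order`` (default: lexicographic by population id).
    2. Within a population, any number of distinct mutations in one gene
       count as a single hit on that gene.

    ``n_draws_observed`` is the number of records surviving rule 1; it is
    the number of draws the matched null model should make.
    """
    if len(table) and (table["class"] == MutationClass.intergenic.value).any():
        raise ValueError("collapse_to_hits expects a filtered table without intergenic rows")
    if population_order is None:
        population_order = sorted(table["population_id"].unique())
    else:
        population_order = list(population_order)
        extra = set(table["population_id"].unique()) - set(population_order)
        if extra:
            raise ValueError(f"populations missing from supplied order: {sorted(extra)}")
    if len(table) == 0:
        return HitTable(matrix=pd.DataFrame(dtype=bool), n_draws_observed=0)

    rank = {p: i for i, p in enumerate(population_order)}
    df = table.copy()
    df["_rank"] = df["population_id"].map(rank)
    # rule 1: keep only the first population for each identical mutation
    df = df.sort_values("_rank", kind="stable")
    df = df.drop_duplicates(subset=["position", "alt"], keep="first")
    n_draws = len(df)
    # rule 2: one hit per (gene, population)
    hits = df.drop_duplicates(subset=["gene_id", "population_id"])
    matrix = pd.crosstab(hits["gene_id"], hits["population_id"]).astype(bool)
    matrix = matrix.reindex(columns=population_order, fill_value=False)
    species = table["species"].iloc[0] if table["species"].nunique() == 1 else None
    treatment = table["treatment"].iloc[0] if table["treatment"].nunique() == 1 else None
    return HitTable(matrix=matrix, n_draws_observed=n_draws,
                    species=species, treatment=treatment)


@dataclass
class NullModelConfig:
    """Configuration of the length-weighted Monte-Carlo null.

    ``n_draws`` (M) should equal the observed number of called mutations
    after the identical-mutation deduplication
    (:attr:`HitTable.n_draws_observed`).
    """

    gene_catalog: GeneCatalog
    n_draws: int
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 0:
            raise ValueError("n_draws must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_draws > 0 and self.gene_catalog.n_genes == 0:
            raise ValueError("cannot draw mutations from an empty gene catalog")


@dataclass
class NullModelResult:
    """Per-gene summaries of the Monte-Carlo null.

    ``tail_counts[g, k]`` is the number of null replicates in which gene
    ``g`` received at least ``k`` draws (k = 0 .. k_max); it supports both
    the max-rule significance test and empirical tail p-values without
    retaining the full replicate x gene matrix.
    """

    gene_ids: pd.Index
    per_gene_max_hits: pd.Series
    tail_counts: np.ndarray
    n_reps: int
    n_draws: int
    rng_seed: int

    def pvalues(self, observed_hits: Mapping[str, int]) -> pd.Series:
        """Empirical tail probability of >= the observed hit count per gene.

        Uses the +1 pseudo-count estimator ``(1 + r) / (1 + n_reps)`` where
        ``r`` is the number of null replicates reaching the observed count,
        so p-values are always strictly positive.
        """
        out = {}
        kmax = self.tail_counts.shape[1] - 1
        pos = pd.Series(np.arange(len(self.gene_ids)), index=self.gene_ids)
        for gene, obs in observed_hits.items():
            if gene not in pos.index:
                raise KeyError(f"gene {gene!r} absent from the null model catalog")
            r = self.tail_counts[pos[gene], min(int(obs), kmax)] if obs <= kmax else 0
            if obs > kmax:
                r = 0
            out[gene] = (1 + int(r)) / (1 + self.n_reps)
        return pd.Series(out, dtype=float)


def simulate_null(config: NullModelConfig, batch_size: int = 2000) -> NullModelResult:
    """Run the length-weighted Monte-Carlo null model.

    Each replicate throws ``n_draws`` mutations at the catalog with
    replacement, gene ``i`` receiving each draw with probability
    ``length_i / total_length``.  Replicates are generated in fixed-size
    batches so results are bit-identical for a given seed regardless of
    memory pressure.
    """
    catalog = config.gene_catalog
    n_genes = catalog.n_genes
    rng = np.random.default_rng(config.seed)
    if config.n_draws == 0 or n_genes == 0:
        empty = pd.Series(np.zeros(n_genes, dtype=int), index=catalog.gene_ids)
        tail = np.tile(
            np.array([[config.n_reps]], dtype=np.int64), (n_genes, 1)
        ) if n_genes else np.zeros((0, 1), dtype=np.int64)
        return NullModelResult(catalog.gene_ids, empty, tail,
                               config.n_reps, config.n_draws, config.seed)

    weights = catalog.weights()
    kcap = config.n_draws  # per-gene count can never exceed M
    # hist[g, k] = number of replicates in which gene g got exactly k draws
    # (k >= 1 only; zero-count replicates are implicit)
    hist = np.zeros((n_genes, kcap + 1), dtype=np.int64)
    per_gene_max = np.zeros(n_genes, dtype=np.int64)
    hist_flat = hist.ravel()
    done = 0
    while done < config.n_reps:
        nb = min(batch_size, config.n_reps - done)
        draws = rng.choice(n_genes, size=(nb, config.n_draws), p=weights)
        # sparse (gene, replicate) counting: gene-major keys so that one
        # sorted pass yields both the per-pair counts and per-gene maxima
        rep_idx = np.tile(np.arange(nb, dtype=np.int64), config.n_draws)
        key = draws.T.ravel() * np.int64(nb) + rep_idx
        uniq, cnt = np.unique(key, return_counts=True)
        genes_nz = (uniq // nb).astype(np.intp)
        seg_starts = np.concatenate([[0], np.flatnonzero(np.diff(genes_nz)) + 1])
        gene_of_seg = genes_nz[seg_starts]
        seg_max = np.maximum.reduceat(cnt, seg_starts)
        per_gene_max[gene_of_seg] = np.maximum(per_gene_max[gene_of_seg], seg_max)
        idx = genes_nz * (kcap + 1) + cnt
        hist_flat += np.bincount(idx, minlength=n_genes * (kcap + 1))
        done += nb
    kmax = int(per_gene_max.max())
    hist = hist[:, : kmax + 1]
    # tail_counts[g, k] = #replicates with count >= k; k = 0 is all replicates
    tail = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]
    tail[:, 0] = config.n_reps
    return NullModelResult(
        gene_ids=catalog.gene_ids,
        per_gene_max_hits=pd.Series(per_gene_max, index=catalog.gene_ids),
        tail_counts=tail,
        n_reps=config.n_reps,
        n_draws=config.n_draws,
        rng_seed=config.seed,
    )


def call_multihit(hits: HitTable, null: NullModelResult,
                  min_populations: int = 2) -> pd.DataFrame:
    """Call significant multi-hit genes against a matched null.

    A gene is significant when it is hit in at least ``min_populations``
    replicate populations **and** its observed hit count strictly exceeds
    the maximum count that gene attained in any null replicate.  Ties with
    the null maximum are not significant.

    Returns a DataFrame with one row per gene observed hit at least once:
    ``gene_id, observed_hits, null_max_hits, pvalue, significant``.
    """
    observed = hits.hits_per_gene
    observed = observed[observed > 0]
    missing = [g for g in observed.index if g not in null.gene_ids]
    if missing:
        raise KeyError(f"gene(s) {missing[:5]} in hit table but not in null model")
    pvals = null.pvalues(observed.to_dict())
    null_max = null.per_gene_max_hits.reindex(observed.index)
    out = pd.DataFrame(
        {
            "gene_id": observed.index,
            "observed_hits": observed.values,
            "null_max_hits": null_max.values.astype(int),
            "pvalue": pvals.reindex(observed.index).values,
            "significant": (observed.values >= min_populations)
            & (observed.values > null_max.values),
        }
    ).sort_values(["significant", "observed_hits"], ascending=False, kind="stable")
    return out.reset_index(drop=True)


def _histogram_from_counts(counts: pd.Series, catalog: GeneCatalog) -> pd.DataFrame:
    counts = counts[counts >= 1]
    if len(counts) == 0:
        return pd.DataFrame(columns=["n_genes", "mean_length_bp"], dtype=float)
    lengths = catalog.lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:5])
        raise KeyError(f"gene(s) {missing} not in catalog")
    grouped = pd.DataFrame({"k": counts.values, "length": lengths.values}).groupby("k")
    out = grouped.agg(n_genes=("length", "size"), mean_length_bp=("length", "mean"))
    out.index.name = "hits"
    return out


def hit_histogram(hits: HitTable, catalog: GeneCatalog) -> pd.DataFrame:
    """Group observed genes by hit count; report group size and mean length.

    Under neutral evolution the highly-hit classes should be dominated by
    long genes; an excess of genes (or of short genes) at high hit counts
    relative to the matched null signals selection acting genome-wide.
    """
    return _histogram_from_counts(hits.hits_per_gene, catalog)


def null_hit_histogram(null: NullModelResult, catalog: GeneCatalog) -> pd.DataFrame:
    """Same grouping applied to the per-gene maximum over null replicates."""
    return _histogram_from_counts(null.per_gene_max_hits, catalog)


def display_filter(table: pd.DataFrame, min_populations: int = 3,
                   min_peak_frequency: float = 0.2) -> list[str]:
    """Genes worth plotting: mutated in >= 3 populations with one allele above 0.2.

    The frequency comparison is strict (> 0.2).  Expects a table already
    passed through :func:`filter_mutations`.
    """
    coding = table[table["gene_id"] != INTERGENIC]
    if len(coding) == 0:
        return []
    by_gene = coding.groupby("gene_id")
    npop = by_gene["population_id"].nunique()
    peak = by_gene["frequency"].max()
    keep = (npop >= min_populations) & (peak > min_peak_frequency)
    return sorted(keep.index[keep])
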