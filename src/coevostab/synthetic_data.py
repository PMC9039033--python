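"""Synthetic inputs: a two-species serial-transfer simulator and a mutation-table generator.

The ecological arm is a Monod consumer-resource model for a bacterium (LP)
and a yeast (SC) sharing a batch culture.  Three resources give the model
just enough structure to represent the community of interest:

* ``glucose`` — the shared, most abundant carbon source;
* ``lp_private`` — a resource pool only LP uses (an amino-acid/by-product
  pool), replenished partly by SC secretion: the commensal (+, 0) link;
* ``sc_private`` — a resource pool only SC uses.

With the default "stable" parameters the two species occupy essentially
distinct niches, LP benefits from SC's secretions, and co-cultures
converge to an LP frequency near one half from a wide range of starting
ratios.  The "released" parameters move LP's niche onto the shared glucose
pool (higher glucose affinity, loss of the private-resource niche): LP
then does better alone than the stable type, but is competitively
excluded by SC in co-culture — an ecological-release phenotype that
breaks coexistence.

Parameter values are not calibrated to any organism; they are chosen to
reproduce the qualitative orderings above and are labelled synthetic.

The genomics arm draws per-population mutation counts and assigns them to
genes with probability proportional to gene length, optionally multiplied
by a per-gene enrichment factor ("planted" selection), producing tables in
the :mod:`coevostab.io_formats` schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .io_formats import INTERGENIC, GeneCatalog, MUTATION_COLUMNS
from .coexistence import CarryingCapacityPair, InvasionTreatment

__all__ = [
    "SPECIES",
    "RESOURCES",
    "CommunityParams",
    "TransferProtocol",
    "BatchTrajectory",
    "simulate_batch",
    "run_serial_transfers",
    "monoculture_carrying_capacities",
    "reciprocal_invasion_experiment",
    "SyntheticMutationConfig",
    "generate_mutation_table",
    "synthetic_gene_catalog",
]

SPECIES = ("LP", "SC")
RESOURCES = ("glucose", "lp_private", "sc_private")

_BASES = np.array(list("ACGT"))


@dataclass
class CommunityParams:
    """Monod parameters for the two species on the three resources.

    Arrays are indexed ``[species, resource]`` following :data:`SPECIES`
    and :data:`RESOURCES`.  Units: ``mu`` 1/h, ``K`` resource units,
    ``yield_`` cells per resource unit, ``secretion_rate`` lp_private
    units per SC cell per hour, ``resource_init`` resource units supplied
    by fresh medium.
    """

    mu: np.ndarray
    K: np.ndarray
    yield_: np.ndarray
    secretion_rate: float
    resource_init: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.yield_ = np.asarray(self.yield_, dtype=float)
        self.resource_init = np.asarray(self.resource_init, dtype=float)
        for arr, shape, label in (
            (self.mu, (2, 3), "mu"),
            (self.K, (2, 3), "K"),
            (self.yield_, (2, 3), "yield_"),
            (self.resource_init, (3,), "resource_init"),
        ):
            if arr.shape != shape:
                raise ValueError(f"{label} must have shape {shape}, got {arr.shape}")
            if (arr < 0).any():
                raise ValueError(f"{label} must be non-negative")
        if self.secretion_rate < 0:
            raise ValueError("secretion_rate must be >= 0")

    @classmethod
    def stable(cls) -> "CommunityParams":
        """Stable commensal community: distinct niches plus cross-feeding.

        LP barely uses glucose and lives mostly on the (partly secreted)
        private pool; SC uses glucose and its own private pool and ignores
        LP entirely.
        """
        return cls(
            #        glucose  lp_priv  sc_priv
            mu=[[0.04, 0.50, 0.0],     # LP
                [0.45, 0.0, 0.35]],    # SC
            K=[[0.05, 0.02, 0.05],
               [0.05, 0.05, 0.05]],
            yield_=[[2.0e9, 2.5e9, 1.0e9],   # unused channels (mu = 0) never consume
                    [1.2e9, 1.0e9, 1.2e9]],
            secretion_rate=8.0e-12,  # calibrated: co-culture equilibrium LP frequency ~0.5
            resource_init=[1.0, 0.02, 0.20],
            name="stable",
        )

    @classmethod
    def released(cls) -> "CommunityParams":
        """Ecological release of LP: niche shifted onto shared glucose.

        Relative to :meth:`stable`, LP's glucose growth rate is raised an
        order of magnitude while its use of the private pool collapses.
        Alone, this type reaches a much higher density than the stable
        type (it can exhaust the glucose); against SC it loses the race
        for glucose and retains no refuge, so coexistence fails.
        """
        base = cls.stable()
        mu = base.mu.copy()
        mu[0, 0] = 0.40   # LP on glucose: released niche
        mu[0, 1] = 0.01   # LP private-pool use nearly lost
        return replace(base, mu=mu, name="released")

    def with_lp_glucose_shift(self, mu_glucose: float, mu_private: float) -> "CommunityParams":
        """LP niche intermediate between the stable and released types."""
        mu = self.mu.copy()
        mu[0, 0] = mu_glucose
        mu[0, 1] = mu_private
        return replace(self, mu=mu, name="custom")


@dataclass
class TransferProtocol:
    """Serial batch-transfer schedule.

    The 32-fold dilution every 48 h gives log2(32) = 5 generations per
    transfer when the community regrows to its pre-dilution density.
    ``extinction_threshold`` is the density (cells/mL) below which a
    species is deterministically removed at a transfer — by default one
    cell per 4 uL transferred volume, i.e. 250 cells/mL.
    """

    dilution_factor: float = 32.0
    batch_duration_h: float = 48.0
    n_transfers: int = 5
    extinction_threshold: float = 250.0
    rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.batch_duration_h <= 0:
            raise ValueError("batch_duration_h must be > 0")
        if self.n_transfers < 0:
            raise ValueError("n_transfers must be >= 0")


@dataclass
class BatchTrajectory:
    """Time course of one batch: densities (2 x T) and resources (3 x T)."""

    t: np.ndarray
    densities: np.ndarray
    resources: np.ndarray

    @property
    def final_densities(self) -> np.ndarray:
        return self.densities[:, -1]

    @property
    def final_resources(self) -> np.ndarray:
        return self.resources[:, -1]


def _rhs(params: CommunityParams):
    mu, K, Y = params.mu, params.K, params.yield_
    sigma = params.secretion_rate
    inv_Y = np.where(Y > 0, 1.0 / np.where(Y > 0, Y, 1.0), 0.0)

    def rhs(t, y):
        N = np.maximum(y[:2], 0.0)
        R = np.maximum(y[2:], 0.0)
        phi = mu * R[None, :] / (K + R[None, :])  # per-capita uptake-limited growth
        growth = phi.sum(axis=1) * N
        consumption = (phi * inv_Y * N[:, None]).sum(axis=0)
        dR = -consumption
        dR[1] += sigma * N[1]  # SC secretes into the LP-private pool
        return np.concatenate([growth, dR])

    return rhs


def simulate_batch(
    params: CommunityParams,
    initial_densities: Sequence[float],
    duration_h: float = 48.0,
    initial_resources: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    n_points: int = 2,
) -> BatchTrajectory:
    """Integrate one batch of growth with adaptive stiff-capable ODE solving.

    ``n_points`` controls how many evenly spaced time points are recorded
    (2 = start and end only).  Negative inputs raise; integrator failure
    raises rather than returning a partial trajectory.
    """
    N0 = np.asarray(initial_densities, dtype=float)
    if N0.shape != (2,):
        raise ValueError("initial_densities must be length 2 (LP, SC)")
    if (N0 < 0).any():
        raise ValueError("initial densities must be non-negative")
    R0 = (params.resource_init if initial_resources is None
          else np.asarray(initial_resources, dtype=float))
    if (R0 < 0).any():
        raise ValueError("initial resources must be non-negative")
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    y0 = np.concatenate([N0, R0])
    t_eval = np.linspace(0.0, duration_h, max(2, n_points))
    atol = np.array([1e-3, 1e-3, 1e-14, 1e-14, 1e-14])
    sol = solve_ivp(
        _rhs(params), (0.0, duration_h), y0, method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"batch integration failed: {sol.message}")
    y = np.maximum(sol.y, 0.0)  # clip integrator undershoot below zero
    return BatchTrajectory(t=sol.t, densities=y[:2], resources=y[2:])


def run_serial_transfers(
    params: CommunityParams,
    protocol: TransferProtocol,
    initial_mix: Sequence[float],
    rng: Optional[np.random.Generator] = None,
    culture_volume_ul: float = 132.0,
) -> pd.DataFrame:
    """Propagate the community through repeated growth/dilution cycles.

    Returns one row per transfer with the end-of-batch densities
    (``N_LP``, ``N_SC`` in cells/mL, the CFU/mL analogue), the LP
    frequency, and cumulative generations assuming log2(D) generations
    per transfer.  Row 0 records the initial mix before any growth.

    If ``rng`` is given, the transfer bottleneck is sampled as a Poisson
    draw on the number of transferred cells (demographic stochasticity);
    otherwise dilution is deterministic and exact (``N / D``).
    """
    D = protocol.dilution_factor
    gen_per_transfer = math.log2(D)
    N = np.asarray(initial_mix, dtype=float)
    rows = [(0, 0.0, N[0], N[1], _freq(N))]
    for transfer in range(1, protocol.n_transfers + 1):
        batch = simulate_batch(params, N, protocol.batch_duration_h, rtol=protocol.rtol)
        N_end = batch.final_densities
        rows.append((transfer, transfer * gen_per_transfer, N_end[0], N_end[1], _freq(N_end)))
        if rng is None:
            N = N_end / D
        else:
            transferred_ml = culture_volume_ul / D / 1000.0
            cells = rng.poisson(N_end * transferred_ml)
            N = cells / (culture_volume_ul / 1000.0)
        N = np.where(N < protocol.extinction_threshold, 0.0, N)
    return pd.DataFrame(rows, columns=["transfer", "generations", "N_LP", "N_SC", "freq_LP"])


def _freq(N: np.ndarray) -> float:
    tot = N.sum()
    return float(N[0] / tot) if tot > 0 else float("nan")


def monoculture_carrying_capacities(
    params: CommunityParams,
    protocol: Optional[TransferProtocol] = None,
    inoculum: float = 1e6,
) -> CarryingCapacityPair:
    """Saturation density of each species grown alone for one batch.

    Monoculture growth has no partner secretion, so each species sees only
    the fresh-medium resources it can use.
    """
    protocol = protocol or TransferProtocol()
    K = []
    for i in range(2):
        N0 = np.zeros(2)
        N0[i] = inoculum
        batch = simulate_batch(params, N0, protocol.batch_duration_h, rtol=protocol.rtol)
        K.append(batch.final_densities[i])
    return CarryingCapacityPair(K_LP=float(K[0]), K_Y=float(K[1]))


def reciprocal_invasion_experiment(
    params: CommunityParams,
    protocol: Optional[TransferProtocol] = None,
    n_transfers: int = 1,
    common_frequency: float = 0.9,
) -> tuple[InvasionTreatment, InvasionTreatment, CarryingCapacityPair]:
    """Run the paired common/rare invasion assay in silico.

    Saturated monoculture stocks are mixed to the target initial LP
    frequency (treatment C: LP common at ``common_frequency``; treatment
    R: LP rare at ``1 - common_frequency``), diluted ``D``-fold into fresh
    medium and grown for ``n_transfers`` cycles.  Returns the two
    treatments plus the monoculture carrying capacities, ready for
    :func:`coevostab.coexistence.analyze_pairing`.
    """
    if not 0.5 < common_frequency < 1.0:
        raise ValueError("common_frequency must be in (0.5, 1)")
    protocol = protocol or TransferProtocol()
    K = monoculture_carrying_capacities(params, protocol)
    D = protocol.dilution_factor
    total0 = (K.K_LP + K.K_Y) / 2.0 / D
    treatments = []
    for label, f in (("C", common_frequency), ("R", 1.0 - common_frequency)):
        Ni = np.array([f * total0, (1.0 - f) * total0])
        N = Ni.copy()
        for t in range(n_transfers):
            if t > 0:
                N = N / D
                N = np.where(N < protocol.extinction_threshold, 0.0, N)
            batch = simulate_batch(params, N, protocol.batch_duration_h, rtol=protocol.rtol)
            N = batch.final_densities
        Nf = np.where(N < protocol.extinction_threshold, 0.0, N)
        treatments.append(
            InvasionTreatment(label=label, Ni_LP=Ni[0], Nf_LP=float(Nf[0]),
                              Ni_Y=Ni[1], Nf_Y=float(Nf[1]))
        )
    return treatments[0], treatments[1], K


# ---------------------------------------------------------------------------
# mutation-table generator
# ---------------------------------------------------------------------------


def synthetic_gene_catalog(
    n_genes: int = 3006,
    seed: int = 0,
    median_bp: float = 900.0,
    sigma: float = 0.45,
    min_bp: int = 90,
) -> GeneCatalog:
    """Log-normally distributed CDS lengths for a synthetic genome.

    Defaults give a bacterial-like catalog (median ~0.9 kb, right tail to
    several kb).  Gene ids are ``g0001`` ... in catalog order.
    """
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        min_bp, np.round(rng.lognormal(math.log(median_bp), sigma, size=n_genes))
    ).astype(int)
    width = len(str(n_genes))
    ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    return GeneCatalog(pd.Series(lengths, index=ids))


@dataclass
class SyntheticMutationConfig:
    """Shape of a synthetic resequencing experiment for one treatment.

    ``planted_genes`` maps gene ids to enrichment multipliers (>= 1)
    applied to their length weight — the planted-selection signal.
    ``shared_mutations`` injects that many identical variants into every
    population (standing genetic variation, as opposed to independent de
    novo hits).  Per-population mutation counts are drawn from a rounded
    normal clipped at zero; defaults emulate ten populations with a few
    dozen coding mutations each.
    """

    gene_catalog: GeneCatalog
    n_populations: int = 10
    mean_mutations: float = 30.0
    sd_mutations: float = 8.0
    planted_genes: Mapping[str, float] = field(default_factory=dict)
    high_frequency_weight: float = 0.3
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "nonsynonymous": 0.55,
            "synonymous": 0.20,
            "nonsense": 0.05,
            "indel": 0.10,
            "intergenic": 0.10,
        }
    )
    shared_mutations: int = 0
    species: str = "LP"
    treatment: str = "coculture"
    population_prefix: str = "C"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"class_mix fractions must sum to 1, got {total}")
        for gene, mult in self.planted_genes.items():
            if gene not in self.gene_catalog:
                raise ValueError(f"planted gene {gene!r} not in catalog")
            if mult < 1:
                raise ValueError(f"enrichment multiplier for {gene!r} must be >= 1")


def generate_mutation_table(config: SyntheticMutationConfig) -> pd.DataFrame:
    """Draw a mutation table with length-weighted (optionally planted) targets.

    Coding mutations choose their gene with probability proportional to
    ``length x multiplier``; positions are uniform within the gene on a
    concatenated coordinate system, so identical positions across
    populations (and hence the standing-variation collapsing rule) occur
    only where injected via ``shared_mutations``.  Frequencies come from a
    two-component mixture: near-fixed (uniform on [0.9, 1]) with
    probability ``high_frequency_weight``, else low-frequency (uniform on
    [0.05, 0.3]).
    """
    cat = config.gene_catalog
    rng = np.random.default_rng(config.seed)
    lengths = cat.lengths
    offsets = np.concatenate([[0], np.cumsum(lengths.values)])
    gene_pos = {g: i for i, g in enumerate(cat.gene_ids)}
    weights = lengths.values.astype(float).copy()
    for gene, mult in config.planted_genes.items():
        weights[gene_pos[gene]] *= mult
    weights = weights / weights.sum()
    total_bp = int(lengths.sum())

    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])

    rows: list[tuple] = []
    pop_ids = [f"{config.population_prefix}{i + 1}" for i in range(config.n_populations)]
    for pop in pop_ids:
        n_mut = int(max(0, round(rng.normal(config.mean_mutations, config.sd_mutations))))
        if n_mut == 0:
            continue
        klass = rng.choice(len(classes), size=n_mut, p=class_p)
        freqs = _draw_frequencies(rng, n_mut, config.high_frequency_weight)
        for k_idx, freq in zip(klass, freqs):
            klass_name = classes[k_idx]
            if klass_name == "intergenic":
                gene = INTERGENIC
                position = total_bp + int(rng.integers(1, 500_000))
                ref, alt = _snp_alleles(rng)
            else:
                gi = int(rng.choice(len(weights), p=weights))
                gene = cat.gene_ids[gi]
                position = int(offsets[gi] + rng.integers(0, lengths.iloc[gi]) + 1)
                if klass_name == "indel":
                    ref, alt = str(_BASES[rng.integers(4)]), "-"
                else:
                    ref, alt = _snp_alleles(rng)
            rows.append((pop, config.treatment, config.species, gene,
                         position, ref, alt, klass_name, float(freq)))

    for _ in range(config.shared_mutations):
        gi = int(rng.choice(len(weights), p=weights))
        gene = cat.gene_ids[gi]
        position = int(offsets[gi] + rng.integers(0, lengths.iloc[gi]) + 1)
        ref, alt = _snp_alleles(rng)
        freq = float(rng.uniform(0.9, 1.0))
        for pop in pop_ids:
            rows.append((pop, config.treatment, config.species, gene,
                         position, ref, alt, "nonsynonymous", freq))

    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    # independent draws can collide on (population, position, alt); keep the first
    df = df.drop_duplicates(subset=["population_id", "position", "alt"], keep="first")
    return df.reset_index(drop=True)


def _draw_frequencies(rng: np.random.Generator, n: int, high_weight: float) -> np.ndarray:
    high = rng.random(n) < high_weight
    freqs = np.where(high, rng.uniform(0.9, 1.0, size=n), rng.uniform(0.05, 0.3, size=n))
    return freqs


def _snp_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + int(rng.integers(1, 4))) % 4
    return str(_BASES[i]), str(_BASES[j])
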