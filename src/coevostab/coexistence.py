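"""Empirical coexistence-theory quantities from reciprocal invasion assays.

Modern coexistence theory frames stable coexistence as the joint outcome of
small fitness differences (equalising mechanisms) and low niche overlap
(stabilising mechanisms).  Both are estimated here operationally, from
culture densities, following the reciprocal-invasion protocol:

* **fitness difference** — ``log10(K_LP / K_Y)``, the log-ratio of the two
  species' monoculture carrying capacities;
* **Malthusian parameter** — ``m = ln(Nf / Ni)`` over a growth interval;
* **selection coefficient** — ``S_LP = m_LP - m_Y`` (and ``S_Y = -S_LP``),
  the relative realised growth of the two species in the same culture;
* **niche overlap** — the frequency dependence of the selection
  coefficient, ``(S_LP_C - S_LP_R) / (P_LP_C - P_LP_R)`` between a
  treatment where LP is common (C) and one where it is rare (R); negative
  values mean each species grows relatively better when rare, i.e.
  distinct niches;
* **strength of coexistence** — the smaller of the two invasion-from-rare
  selection coefficients; positive iff both species satisfy the mutual
  invasibility criterion.

LP denotes the bacterium (*Lactiplantibacillus plantarum*) and Y the yeast
(*Saccharomyces cerevisiae*) throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CarryingCapacityPair",
    "InvasionTreatment",
    "PairingResult",
    "PredictorFit",
    "fitness_difference",
    "malthusian",
    "selection_coefficients",
    "niche_overlap",
    "normalize_overlap",
    "coexistence_strength",
    "analyze_pairing",
    "fit_predictors",
    "pairings_to_frame",
]

logger = logging.getLogger(__name__)

_FREQ_TOL = 1e-6


@dataclass(frozen=True)
class CarryingCapacityPair:
    """Monoculture saturation densities of the two species, same units.

    Units may be CFU/mL or OD; they must match between the two entries
    (only the ratio is ever used).
    """

    K_LP: float
    K_Y: float
    units: str = "CFU/mL"

    def __post_init__(self) -> None:
        if self.K_LP <= 0 or self.K_Y <= 0:
            raise ValueError("carrying capacities must be > 0")


@dataclass(frozen=True)
class InvasionTreatment:
    """Densities of one invasion treatment (one label, C or R).

    ``C`` means LP is common (initial LP frequency > 0.5); ``R`` means LP
    is rare.  ``Nf`` may be 0, flagging extinction of that species during
    the assay.
    """

    label: str  # "C" or "R"
    Ni_LP: float
    Nf_LP: float
    Ni_Y: float
    Nf_Y: float

    def __post_init__(self) -> None:
        if self.label not in ("C", "R"):
            raise ValueError("label must be 'C' (LP common) or 'R' (LP rare)")
        if self.Ni_LP <= 0 or self.Ni_Y <= 0:
            raise ValueError("initial densities must be > 0")
        if self.Nf_LP < 0 or self.Nf_Y < 0:
            raise ValueError("final densities must be >= 0")
        if self.label == "C" and self.P_LP <= 0.5:
            raise ValueError(f"treatment C requires initial LP frequency > 0.5, got {self.P_LP:.4f}")
        if self.label == "R" and self.P_LP >= 0.5:
            raise ValueError(f"treatment R requires initial LP frequency < 0.5, got {self.P_LP:.4f}")

    @property
    def P_LP(self) -> float:
        """Initial LP frequency, recomputed from the inoculum densities."""
        return self.Ni_LP / (self.Ni_LP + self.Ni_Y)

    @property
    def extinct(self) -> bool:
        return self.Nf_LP == 0 or self.Nf_Y == 0


class PredictorFit(NamedTuple):
    r2_fitness: float
    p_fitness: float
    r2_niche: float
    p_niche: float
    n: int


@dataclass
class PairingResult:
    """All coexistence quantities for one LP x Y strain pairing."""

    pairing_id: str
    fitness_difference: float
    m_LP_C: float
    m_Y_C: float
    m_LP_R: float
    m_Y_R: float
    S_LP_C: float
    S_Y_C: float
    S_LP_R: float
    S_Y_R: float
    niche_overlap_raw: float
    niche_overlap_normalized: float
    coexistence_strength: float
    extinct: bool

    @property
    def coexisting(self) -> bool:
        return self.coexistence_strength > 0


def fitness_difference(K: CarryingCapacityPair) -> float:
    """log10 ratio of monoculture carrying capacities, ``log10(K_LP/K_Y)``.

    The sign tracks the (arbitrary) direction of the ratio; a larger
    magnitude means a larger fitness difference.
    """
    return math.log10(K.K_LP / K.K_Y)


def malthusian(Ni: float, Nf: float) -> float:
    """Malthusian parameter ``m = ln(Nf / Ni)`` over the assay interval.

    A species diluted 32-fold that regrows to its pre-dilution density has
    ``m = ln 32 ≈ 3.47``, i.e. five doublings.  ``Nf = 0`` (extinction)
    returns ``-inf``; callers should branch on :func:`math.isinf`.
    """
    if Ni <= 0:
        raise ValueError("initial density must be > 0")
    if Nf < 0:
        raise ValueError("final density must be >= 0")
    if Nf == 0:
        return float("-inf")
    return math.log(Nf / Ni)


def selection_coefficients(m_LP: float, m_Y: float) -> tuple[float, float]:
    """Selection coefficients ``(S_LP, S_Y) = (m_LP - m_Y, m_Y - m_LP)``.

    Antisymmetric by construction.  If one species went extinct its S is
    ``-inf`` and the survivor's is ``+inf``; both extinct is an error
    (the assay produced no information).
    """
    if math.isinf(m_LP) and math.isinf(m_Y):
        raise ValueError("both species extinct: selection coefficient undefined")
    if math.isinf(m_LP):
        return float("-inf"), float("inf")
    if math.isinf(m_Y):
        return float("inf"), float("-inf")
    s = m_LP - m_Y
    return s, -s


def niche_overlap(S_LP_C: float, S_LP_R: float, P_LP_C: float, P_LP_R: float) -> float:
    """Frequency dependence of the LP selection coefficient.

    ``(S_LP_C - S_LP_R) / (P_LP_C - P_LP_R)`` — negative when each species
    does relatively better from rare (distinct niches, stabilising),
    positive when being common pays (overlapping niches).
    """
    if not all(map(math.isfinite, (S_LP_C, S_LP_R))):
        raise ValueError("niche overlap undefined with an extinct species (infinite S)")
    denom = P_LP_C - P_LP_R
    if denom == 0:
        raise ValueError("degenerate design: common and rare treatments share the same "
                         "initial frequency")
    return (S_LP_C - S_LP_R) / denom


def normalize_overlap(raw: float, ancestral_raw: float) -> float:
    """Express a pairing's niche overlap relative to the ancestral pairing.

    Subtractive normalisation: the ancestral pairing maps to 0, negative
    values mean less overlap than the ancestors, positive more.
    """
    if not math.isfinite(ancestral_raw):
        raise ValueError("ancestral niche overlap must be finite")
    return raw - ancestral_raw


def coexistence_strength(S_LP_rare: float, S_Y_rare: float) -> float:
    """Smallest invasion-from-rare selection coefficient.

    Each argument is that species' selection coefficient measured in the
    treatment where *it* is the rare species: LP's from treatment R and
    Y's from treatment C.  Positive iff each species can increase from
    rare against the other — the operational mutual-invasibility
    criterion for stable coexistence.
    """
    return min(S_LP_rare, S_Y_rare)


def analyze_pairing(
    treatment_C: InvasionTreatment,
    treatment_R: InvasionTreatment,
    K: CarryingCapacityPair,
    ancestral_overlap: float = 0.0,
    pairing_id: str = "",
) -> PairingResult:
    """Chain all coexistence computations for one strain pairing.

    ``ancestral_overlap`` is the raw niche overlap of the ancestral
    pairing used for normalisation (0 leaves the raw value unchanged).
    Extinction in either treatment propagates to an ``extinct`` flag with
    infinite selection coefficients; niche overlap is then undefined (NaN).
    """
    if treatment_C.label != "C" or treatment_R.label != "R":
        raise ValueError("pass the LP-common treatment first and the LP-rare second")
    m_LP_C = malthusian(treatment_C.Ni_LP, treatment_C.Nf_LP)
    m_Y_C = malthusian(treatment_C.Ni_Y, treatment_C.Nf_Y)
    m_LP_R = malthusian(treatment_R.Ni_LP, treatment_R.Nf_LP)
    m_Y_R = malthusian(treatment_R.Ni_Y, treatment_R.Nf_Y)
    S_LP_C, S_Y_C = selection_coefficients(m_LP_C, m_Y_C)
    S_LP_R, S_Y_R = selection_coefficients(m_LP_R, m_Y_R)
    extinct = treatment_C.extinct or treatment_R.extinct
    if extinct:
        raw = float("nan")
        normalized = float("nan")
    else:
        raw = niche_overlap(S_LP_C, S_LP_R, treatment_C.P_LP, treatment_R.P_LP)
        normalized = normalize_overlap(raw, ancestral_overlap)
    return PairingResult(
        pairing_id=pairing_id,
        fitness_difference=fitness_difference(K),
        m_LP_C=m_LP_C, m_Y_C=m_Y_C, m_LP_R=m_LP_R, m_Y_R=m_Y_R,
        S_LP_C=S_LP_C, S_Y_C=S_Y_C, S_LP_R=S_LP_R, S_Y_R=S_Y_R,
        niche_overlap_raw=raw,
        niche_overlap_normalized=normalized,
        coexistence_strength=coexistence_strength(S_LP_R, S_Y_C),
        extinct=extinct,
    )


def pairings_to_frame(pairings: Iterable[PairingResult]) -> pd.DataFrame:
    """Flatten PairingResult objects into one row per pairing."""
    rows = [vars(p) for p in pairings]
    return pd.DataFrame(rows)


def fit_predictors(pairings: Sequence[PairingResult]) -> PredictorFit:
    """OLS fits of coexistence strength on its two theoretical predictors.

    Two separate simple regressions: strength on ``|fitness_difference|``
    (theory predicts larger fitness gaps erode coexistence regardless of
    which species is favoured) and strength on the normalised niche
    overlap.  Pairings with an extinction (infinite S) are excluded with a
    logged warning.  Returns R² and the slope p-value for each fit.
    """
    usable = [p for p in pairings if not p.extinct
              and math.isfinite(p.coexistence_strength)]
    n_dropped = len(list(pairings)) - len(usable)
    if n_dropped:
        logger.warning("fit_predictors: excluding %d pairing(s) with extinction", n_dropped)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 finite pairings, have {len(usable)}")
    y = np.array([p.coexistence_strength for p in usable])
    fits = []
    for x in (
        np.abs([p.fitness_difference for p in usable]),
        np.array([p.niche_overlap_normalized for p in usable]),
    ):
        if np.ptp(x) == 0:
            raise ValueError("predictor has zero variance across pairings")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        fits.append((float(model.rsquared), float(model.pvalues[1])))
    (r2_f, p_f), (r2_n, p_n) = fits
    return PredictorFit(r2_fitness=r2_f, p_fitness=p_f, r2_niche=r2_n, p_niche=p_n,
                        n=len(usable))
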