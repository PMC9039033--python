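"""End-to-end orchestration: simulate -> null model -> coexistence -> report.

The pipeline is deliberately thin: each stage calls the library modules
and writes plain-text tables plus a JSON metadata record carrying the
seed, parameters and SHA-256 hashes of every file written, so a rerun
with the same configuration is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import coexistence as cx
from . import parallel_evolution as pe
from . import synthetic_data as sd
from .io_formats import write_mutation_table

__all__ = ["RunConfig", "run_pipeline", "generations_per_transfer"]

logger = logging.getLogger(__name__)

_SCENARIOS = {"stable": sd.CommunityParams.stable, "released": sd.CommunityParams.released}


def generations_per_transfer(dilution_factor: float, rounded: bool = False) -> float:
    """Generations of regrowth implied by a D-fold serial dilution.

    A community regrowing to its pre-dilution density doubles log2(D)
    times; the experimental 32-fold dilution therefore yields 5
    generations per transfer.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    g = math.log2(dilution_factor)
    return float(round(g)) if rounded else g


@dataclass
class RunConfig:
    """Configuration for a full synthetic-data pipeline run."""

    out_dir: str = "coevostab_run"
    seed: int = 0
    scenario: str = "stable"
    species: str = "LP"
    n_transfers: int = 10
    null_reps: int = 10_000
    n_genes: int = 3006
    n_populations: int = 10
    mean_mutations: float = 30.0
    planted_genes: Mapping[str, float] = field(default_factory=dict)
    shared_mutations: int = 1
    frequency_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(pe.DEFAULT_FREQUENCY_THRESHOLDS)
    )
    mutations_path: Optional[str] = None  # use an existing table instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return paths and key results.

    Stages: (1) ecology — serial-transfer trajectories and a reciprocal
    invasion assay for the configured scenario plus the stable ancestor;
    (2) genomics — a synthetic (or supplied) mutation table filtered,
    collapsed and tested against the length-weighted null; (3) coexistence
    — the full pairing analysis normalised against the ancestral pairing.
    Any stage failure aborts with the stage name in the exception.
    """
    if config.scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {config.scenario!r}; choose from {sorted(_SCENARIOS)}")
    if config.mutations_path is not None and not Path(config.mutations_path).exists():
        raise FileNotFoundError(f"mutations file not found: {config.mutations_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    results: dict = {}

    # --- stage 1: ecology -------------------------------------------------
    stage = "simulate"
    try:
        protocol = sd.TransferProtocol(n_transfers=config.n_transfers)
        params = _SCENARIOS[config.scenario]()
        traj = sd.run_serial_transfers(params, protocol, _initial_mix(params, protocol))
        traj_path = out / "serial_transfers.csv"
        traj.to_csv(traj_path, index=False)
        written.append(traj_path)
        logger.info("stage %s: %d transfers -> %s", stage, config.n_transfers, traj_path)
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- stage 2: genomics ------------------------------------------------
    stage = "nullmodel"
    try:
        catalog = sd.synthetic_gene_catalog(n_genes=config.n_genes, seed=config.seed)
        if config.mutations_path is not None:
            from .io_formats import read_mutation_table

            mutations = read_mutation_table(config.mutations_path)
        else:
            mut_cfg = sd.SyntheticMutationConfig(
                gene_catalog=catalog,
                n_populations=config.n_populations,
                mean_mutations=config.mean_mutations,
                planted_genes=dict(config.planted_genes),
                shared_mutations=config.shared_mutations,
                species=config.species,
                seed=config.seed,
            )
            mutations = sd.generate_mutation_table(mut_cfg)
        mut_path = out / "mutations.tsv"
        write_mutation_table(mutations, mut_path)
        written.append(mut_path)

        filtered = pe.filter_mutations(
            mutations, config.frequency_thresholds, classes=pe.AMINO_ACID_CHANGING
        )
        hits = pe.collapse_to_hits(filtered)
        null = pe.simulate_null(
            pe.NullModelConfig(
                gene_catalog=catalog,
                n_draws=hits.n_draws_observed,
                n_reps=config.null_reps,
                seed=config.seed,
            )
        )
        calls = pe.call_multihit(hits, null)
        calls_path = out / "multihit_calls.tsv"
        calls.to_csv(calls_path, sep="\t", index=False)
        written.append(calls_path)

        hist_obs = pe.hit_histogram(hits, catalog)
        hist_null = pe.null_hit_histogram(null, catalog)
        hist = hist_obs.join(hist_null, lsuffix="_observed", rsuffix="_null", how="outer")
        hist_path = out / "hit_histogram.tsv"
        hist.to_csv(hist_path, sep="\t")
        written.append(hist_path)
        results["n_multihit_significant"] = int(calls["significant"].sum())
        results["n_draws_observed"] = hits.n_draws_observed
        results["display_genes"] = pe.display_filter(filtered)
        logger.info(
            "stage %s: %d mutations -> M=%d, %d significant multi-hit gene(s)",
            stage, len(mutations), hits.n_draws_observed,
            results["n_multihit_significant"],
        )
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- stage 3: coexistence --------------------------------------------
    stage = "coexist"
    try:
        assay_protocol = sd.TransferProtocol(n_transfers=1)
        anc_C, anc_R, anc_K = sd.reciprocal_invasion_experiment(
            sd.CommunityParams.stable(), assay_protocol
        )
        anc_raw = cx.analyze_pairing(anc_C, anc_R, anc_K).niche_overlap_raw
        ancestral = cx.analyze_pairing(anc_C, anc_R, anc_K,
                                       ancestral_overlap=anc_raw,
                                       pairing_id="ancestral")
        pairings = [ancestral]
        if config.scenario != "stable":
            evo_C, evo_R, evo_K = sd.reciprocal_invasion_experiment(params, assay_protocol)
            pairings.append(
                cx.analyze_pairing(
                    evo_C, evo_R, evo_K,
                    ancestral_overlap=ancestral.niche_overlap_raw,
                    pairing_id=config.scenario,
                )
            )
        pair_df = cx.pairings_to_frame(pairings)
        pair_path = out / "pairings.tsv"
        pair_df.to_csv(pair_path, sep="\t", index=False)
        written.append(pair_path)
        results["coexistence_strength"] = {
            p.pairing_id: p.coexistence_strength for p in pairings
        }
        logger.info("stage %s: %d pairing(s) -> %s", stage, len(pairings), pair_path)
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # --- metadata ---------------------------------------------------------
    meta = {
        "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(config).items()},
        "generations_per_transfer": generations_per_transfer(
            sd.TransferProtocol().dilution_factor
        ),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
        "elapsed_s": round(time.time() - t0, 3),
        "version": _package_version(),
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    results["metadata"] = meta
    results["out_dir"] = str(out)
    return results


def _initial_mix(params: sd.CommunityParams, protocol: sd.TransferProtocol):
    K = sd.monoculture_carrying_capacities(params, protocol)
    total = (K.K_LP + K.K_Y) / 2.0 / protocol.dilution_factor
    return [0.5 * total, 0.5 * total]


def _package_version() -> str:
    from . import __version__

    return __version__
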