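"""Readers/writers for mutation tables, gene catalogs and plate counts.

All tabular data move through :class:`pandas.DataFrame` objects with fixed
column schemas.  The mutation-table schema mirrors what a population
resequencing pipeline emits after annotation: one row per called variant per
population, with the gene it falls in, its functional class and its allele
frequency.  Intergenic calls carry the :data:`INTERGENIC` sentinel as their
gene id.

Two dialects are accepted for mutation tables:

``tsv``
    A plain tab-separated file with a mandatory header row and the columns
    of :data:`MUTATION_COLUMNS`.

``genomediff``
    A documented *subset* of the GenomeDiff format produced by breseq-style
    pipelines: only ``SNP``/``INS``/``DEL`` mutation lines are read, and the
    per-line ``frequency=``, ``gene_name=`` and ``snp_type=`` attributes are
    honoured.  Evidence lines and all other record types are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "INTERGENIC",
    "Treatment",
    "Species",
    "MutationClass",
    "MUTATION_COLUMNS",
    "PLATE_COUNT_COLUMNS",
    "MutationRecord",
    "GeneCatalog",
    "PlateCount",
    "read_mutation_table",
    "write_mutation_table",
    "validate_mutation_table",
    "read_plate_counts",
    "write_plate_counts",
    "cfu_per_ml",
    "densities_from_counts",
]

#: Sentinel gene id for variants that do not fall inside an annotated ORF.
INTERGENIC = "INTERGENIC"


class Treatment(str, Enum):
    monoculture = "monoculture"
    coculture = "coculture"


class Species(str, Enum):
    """The two community members: LP (*L. plantarum*), SC (*S. cerevisiae*)."""

    LP = "LP"
    SC = "SC"


class MutationClass(str, Enum):
    synonymous = "synonymous"
    nonsynonymous = "nonsynonymous"
    nonsense = "nonsense"
    indel = "indel"
    intergenic = "intergenic"


MUTATION_COLUMNS = [
    "population_id",
    "treatment",
    "species",
    "gene_id",
    "position",
    "ref",
    "alt",
    "class",
    "frequency",
]

PLATE_COUNT_COLUMNS = [
    "sample_id",
    "species",
    "colonies",
    "dilution_factor",
    "plated_volume_ul",
    "timepoint_generations",
    "replicate",
]


class FormatError(ValueError):
    """A required column or structural element is missing from an input file."""


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation in one population."""

    population_id: str
    treatment: str
    species: str
    gene_id: str
    position: int
    ref: str
    alt: str
    mutation_class: str
    frequency: float

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(
                f"frequency must be in (0, 1], got {self.frequency!r}"
            )
        intergenic_class = self.mutation_class == MutationClass.intergenic.value
        intergenic_gene = self.gene_id == INTERGENIC
        if intergenic_class != intergenic_gene:
            raise ValueError(
                "intergenic class and INTERGENIC gene id must co-occur "
                f"(gene_id={self.gene_id!r}, class={self.mutation_class!r})"
            )


@dataclass
class GeneCatalog:
    """Map of gene id to coding-sequence length in base pairs.

    Lengths act as the weights of the neutral null model: longer genes
    present a larger mutational target.
    """

    lengths: pd.Series  # index: gene_id (str), values: length in bp

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths, dtype=np.int64)
        self.lengths.index = self.lengths.index.astype(str)
        self.lengths.index.name = "gene_id"
        if self.lengths.index.has_duplicates:
            dupes = self.lengths.index[self.lengths.index.duplicated()]
            raise ValueError(f"duplicate gene ids in catalog: {list(dupes[:5])}")
        if (self.lengths < 1).any():
            bad = self.lengths[self.lengths < 1]
            raise ValueError(f"gene lengths must be >= 1 bp: {dict(bad[:5])}")
        if INTERGENIC in self.lengths.index:
            raise ValueError(f"{INTERGENIC!r} is reserved and cannot be a gene id")

    @property
    def n_genes(self) -> int:
        return len(self.lengths)

    @property
    def gene_ids(self) -> pd.Index:
        return self.lengths.index

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def weights(self) -> np.ndarray:
        """Length-proportional sampling probabilities (sum to 1)."""
        w = self.lengths.to_numpy(dtype=float)
        return w / w.sum()

    def __len__(self) -> int:
        return self.n_genes

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.lengths.index

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "GeneCatalog":
        """Read a two-column ``gene_id<TAB>length_bp`` table with header."""
        df = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "length_bp"):
            if col not in df.columns:
                raise FormatError(f"gene catalog {path}: missing column {col!r}")
        return cls(pd.Series(df["length_bp"].values, index=df["gene_id"].astype(str)))

    @classmethod
    def from_gff3(cls, path: Union[str, Path], feature_type: str = "gene") -> "GeneCatalog":
        """Extract gene lengths from a GFF3 file.

        Length is ``end - start + 1`` (GFF3 is 1-based, end-inclusive); the
        gene id is taken from the ``ID=`` attribute, falling back to
        ``Name=``/``locus_tag=``.
        """
        ids: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(
                        f"{path}:{lineno}: expected 9 tab-separated GFF3 columns"
                    )
                if parts[2] != feature_type:
                    continue
                start, end = int(parts[3]), int(parts[4])
                attrs = _parse_gff_attributes(parts[8])
                gid = attrs.get("ID") or attrs.get("Name") or attrs.get("locus_tag")
                if gid is None:
                    raise FormatError(
                        f"{path}:{lineno}: {feature_type} feature has no ID attribute"
                    )
                ids.append(gid)
                lengths.append(end - start + 1)
        if not ids:
            raise FormatError(f"{path}: no {feature_type!r} features found")
        return cls(pd.Series(lengths, index=ids))

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame({"gene_id": self.lengths.index, "length_bp": self.lengths.values})
        df.to_csv(path, sep="\t", index=False)


def _parse_gff_attributes(col9: str) -> dict:
    out = {}
    for item in col9.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


@dataclass(frozen=True)
class PlateCount:
    """A single selective-plate colony count with its dilution bookkeeping."""

    sample_id: str
    species: str
    colonies: int
    dilution_factor: float
    plated_volume_ul: float
    timepoint_generations: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.plated_volume_ul <= 0:
            raise ValueError("plated_volume_ul must be > 0")

    @property
    def density(self) -> float:
        return cfu_per_ml(self.colonies, self.dilution_factor, self.plated_volume_ul)


def cfu_per_ml(colonies, dilution_factor, plated_volume_ul):
    """Convert colony counts to a culture density in CFU/mL.

    Standard plate-count conversion: ``colonies * dilution_factor`` undoes
    the serial dilution, and dividing by the plated volume (in mL) yields a
    per-millilitre density.  Accepts scalars or aligned arrays.

    >>> cfu_per_ml(40, 1e5, 10.0)
    400000000.0
    """
    colonies = np.asarray(colonies, dtype=float)
    plated_volume_ul = np.asarray(plated_volume_ul, dtype=float)
    if np.any(plated_volume_ul <= 0):
        raise ValueError("plated_volume_ul must be > 0")
    if np.any(colonies < 0):
        raise ValueError("colonies must be >= 0")
    out = colonies * np.asarray(dilution_factor, dtype=float) / (plated_volume_ul / 1000.0)
    return float(out) if out.ndim == 0 else out


def read_mutation_table(path: Union[str, Path], dialect: str = "tsv", **gd_context) -> pd.DataFrame:
    """Read a mutation table in ``tsv`` or ``genomediff`` dialect.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` for the native tab-separated schema, ``"genomediff"`` for
        the GenomeDiff subset.  For GenomeDiff, pass ``population_id``,
        ``treatment`` and ``species`` as keyword context (a GD file
        describes a single sample and carries none of the three).

    Returns
    -------
    pandas.DataFrame
        Validated table with columns :data:`MUTATION_COLUMNS`.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "population_id": str})
        missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        df = df[MUTATION_COLUMNS].copy()
    elif dialect == "genomediff":
        df = _read_genomediff(path, **gd_context)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    validate_mutation_table(df, source=str(path))
    return df


_GD_CLASS_MAP = {
    "synonymous": MutationClass.synonymous.value,
    "nonsynonymous": MutationClass.nonsynonymous.value,
    "nonsense": MutationClass.nonsense.value,
    "intergenic": MutationClass.intergenic.value,
    "noncoding": MutationClass.intergenic.value,
}


def _read_genomediff(path, population_id: str = "", treatment: str = "coculture",
                     species: str = "LP") -> pd.DataFrame:
    """Parse SNP/INS/DEL mutation lines from a GenomeDiff file.

    Only the three point-mutation record types are supported; INS/DEL map to
    the ``indel`` class unless an explicit ``snp_type`` says otherwise.
    """
    rows = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#=GENOME_DIFF"):
            raise FormatError(f"{path}: not a GenomeDiff file (missing #=GENOME_DIFF header)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rec_type = parts[0]
            if rec_type not in ("SNP", "INS", "DEL"):
                continue  # evidence and other record types: documented non-support
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: truncated {rec_type} record")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: truncated {rec_type} record")
            position = int(parts[4])
            value_field = parts[5]  # new_seq for SNP/INS, size for DEL
            attrs = {}
            for item in parts[6:]:
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            freq = float(attrs.get("frequency", 1.0))
            gene = attrs.get("gene_name", INTERGENIC)
            if "/" in gene or gene in ("", "-"):  # breseq writes intergenic as geneA/geneB
                gene = INTERGENIC
            if rec_type == "SNP":
                klass = _GD_CLASS_MAP.get(attrs.get("snp_type", ""))
                if klass is None:
                    klass = (MutationClass.intergenic.value if gene == INTERGENIC
                             else MutationClass.nonsynonymous.value)
                ref, alt = attrs.get("ref_seq", "N"), value_field
            elif rec_type == "INS":
                klass = (MutationClass.intergenic.value if gene == INTERGENIC
                         else MutationClass.indel.value)
                ref, alt = "-", value_field
            else:  # DEL
                klass = (MutationClass.intergenic.value if gene == INTERGENIC
                         else MutationClass.indel.value)
                ref, alt = f"del{value_field}", "-"
            rows.append((population_id, treatment, species, gene, position, ref, alt, klass, freq))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def validate_mutation_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate schema and invariants; raise with the offending row number."""
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    freq = pd.to_numeric(df["frequency"], errors="coerce")
    bad = df.index[(freq.isna()) | (freq <= 0) | (freq > 1)]
    if len(bad):
        raise ValueError(
            f"{source}: frequency outside (0, 1] at row(s) {list(bad[:5])} "
            f"(values {list(df.loc[bad[:5], 'frequency'])})"
        )
    is_intergenic_class = df["class"] == MutationClass.intergenic.value
    is_intergenic_gene = df["gene_id"] == INTERGENIC
    mismatch = df.index[is_intergenic_class != is_intergenic_gene]
    if len(mismatch):
        raise ValueError(
            f"{source}: intergenic class/gene mismatch at row(s) {list(mismatch[:5])}"
        )
    valid_classes = {c.value for c in MutationClass}
    unknown = set(df["class"].unique()) - valid_classes
    if unknown:
        raise ValueError(f"{source}: unknown mutation class(es) {sorted(unknown)}")
    dup_key = df[["population_id", "position", "alt"]]
    dups = df.index[dup_key.duplicated()]
    if len(dups):
        raise ValueError(
            f"{source}: duplicate (population, position, alt) at row(s) {list(dups[:5])}"
        )
    return df


def write_mutation_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    validate_mutation_table(df)
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_plate_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Read a plate-count CSV (columns :data:`PLATE_COUNT_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if (df["colonies"] < 0).any():
        raise ValueError(f"{path}: negative colony count")
    if (df["dilution_factor"] < 1).any():
        raise ValueError(f"{path}: dilution_factor below 1")
    return df[PLATE_COUNT_COLUMNS].copy()


def write_plate_counts(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[PLATE_COUNT_COLUMNS].to_csv(path, index=False)


def densities_from_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``density_cfu_per_ml`` column to a plate-count table."""
    out = df.copy()
    out["density_cfu_per_ml"] = cfu_per_ml(
        df["colonies"].to_numpy(), df["dilution_factor"].to_numpy(),
        df["plated_volume_ul"].to_numpy(),
    )
    return out
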