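"""Core variant record types, tabular I/O, label mapping and residue attributes.

A variant table is a thin, DataFrame-backed container of missense variants.
Each row carries the protein identifier, the 1-based position, wild-type and
mutant amino acids, a raw predictor score (typically a log-likelihood ratio,
where more negative means more deleterious), an optional binary pathogenicity
label (1 = pathogenic, 0 = benign) and any number of *tri-state* binary
residue attributes: true, false, or missing.  Missing attribute values are
first-class citizens — they drive the fallback behaviour of the calibration
tree at inference time and are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Columns every variant table must provide (post-dialect renaming).
CORE_COLUMNS = ("protein_id", "position", "wt", "mut", "score")

#: Default column-name dialect.  Keys are canonical names used internally,
#: values are the column headers expected in the file.  Override any subset
#: to ingest heterogeneously named sources.
DEFAULT_DIALECT = {
    "protein_id": "protein_id",
    "position": "position",
    "wt": "wt",
    "mut": "mut",
    "score": "score",
    "label": "label",
    "disorder": "disorder",
    "ppi": "ppi",
    "cluster_size": "cluster_size",
    "length": "length",
}

#: Residue-set attributes: membership of the wild-type amino acid in a
#: physico-chemical class.  ``proline_or_glycine`` and ``helix_breaker``
#: are deliberately the same set under two field-standard names.
RESIDUE_SETS: dict[str, frozenset[str]] = {
    "polar": frozenset("STCYNQG"),
    "hydrophobic": frozenset("AVILMFYW"),
    "charged": frozenset("RHKDE"),
    "aromatic": frozenset("FWYH"),
    "acidic": frozenset("DE"),
    "basic": frozenset("RHK"),
    "uncharged_polar": frozenset("STNQCY"),
    "small": frozenset("GASTP"),
    "sulfur_binding": frozenset("CM"),
    "proline_or_glycine": frozenset("PG"),
    "helix_breaker": frozenset("GP"),
    "aliphatic": frozenset("VILMA"),
    "beta_branched": frozenset("IVT"),
}

# Clinical-significance strings accepted as pathogenic / benign.  Anything
# else (uncertain significance, conflicting, ...) is rejected.
_PATHOGENIC_TERMS = {
    "likely pathogenic",
    "pathogenic/likely pathogenic",
    "pathogenic",
}
_BENIGN_TERMS = {
    "benign",
    "benign/likely benign",
    "likely benign",
}


@dataclass(frozen=True)
class AttributeDefinition:
    """How a binary residue attribute is derived.

    kind
        ``residue-set``: wild-type amino acid membership in ``positive_residues``.
        ``threshold``: comparison of a numeric annotation against ``threshold``
        in the given ``direction``.
        ``external-binary``: supplied directly (e.g. interface predictions).
    """

    name: str
    kind: str
    positive_residues: Optional[frozenset[str]] = None
    threshold: Optional[float] = None
    direction: Optional[str] = None  # "greater" | "less-equal"

    def __post_init__(self) -> None:
        if self.kind not in ("residue-set", "threshold", "external-binary"):
            raise DataError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "residue-set" and not self.positive_residues:
            raise DataError(f"residue-set attribute {self.name!r} needs residues")
        if self.kind == "threshold" and (
            self.threshold is None or self.direction not in ("greater", "less-equal")
        ):
            raise DataError(f"threshold attribute {self.name!r} needs threshold and direction")


@dataclass(frozen=True)
class VariantRecord:
    """A single missense variant."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    score: float
    label: Optional[int] = None
    attributes: Mapping[str, Optional[bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in _CANONICAL_SET:
                raise DataError(f"non-canonical amino acid {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise DataError("wild-type and mutant amino acids must differ")
        if self.label is not None and self.label not in (0, 1):
            raise DataError(f"label must be 0, 1 or absent, got {self.label!r}")


class VariantTable:
    """Ordered collection of variants plus the declared attribute names.

    Internally a pandas DataFrame with canonical columns.  Attribute columns
    are stored as float: 1.0 (true), 0.0 (false), NaN (missing).  Labels are
    float 0/1 with NaN when absent.
    """

    def __init__(self, df: pd.DataFrame, attribute_names: Sequence[str]):
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        unknown = [a for a in attribute_names if a not in df.columns]
        if unknown:
            raise FormatError(f"declared attribute(s) absent from table: {unknown}")
        if "label" not in df.columns:
            df = df.assign(label=np.nan)
        self.df = df.reset_index(drop=True)
        self.attribute_names = list(attribute_names)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[VariantRecord],
                     attribute_names: Optional[Sequence[str]] = None) -> "VariantTable":
        if attribute_names is None:
            seen: list[str] = []
            for r in records:
                for k in r.attributes:
                    if k not in seen:
                        seen.append(k)
            attribute_names = seen
        rows = []
        for r in records:
            row = {
                "protein_id": r.protein_id,
                "position": r.position,
                "wt": r.wt_aa,
                "mut": r.mut_aa,
                "score": r.score,
                "label": np.nan if r.label is None else float(r.label),
            }
            for a in attribute_names:
                v = r.attributes.get(a)
                row[a] = np.nan if v is None else float(bool(v))
            rows.append(row)
        cols = list(CORE_COLUMNS) + ["label"] + list(attribute_names)
        df = pd.DataFrame(rows, columns=cols)
        return cls(df, attribute_names)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[VariantRecord]:
        for i in range(len(self.df)):
            yield self.record(i)

    def record(self, i: int) -> VariantRecord:
        row = self.df.iloc[i]
        label = None if pd.isna(row["label"]) else int(row["label"])
        attrs = {}
        for a in self.attribute_names:
            v = row[a]
            attrs[a] = None if pd.isna(v) else bool(v)
        return VariantRecord(
            protein_id=str(row["protein_id"]),
            position=int(row["position"]),
            wt_aa=str(row["wt"]),
            mut_aa=str(row["mut"]),
            score=float(row["score"]),
            label=label,
            attributes=attrs,
        )

    # -- array views -------------------------------------------------------

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Float labels with NaN where absent."""
        return self.df["label"].to_numpy(dtype=float)

    @property
    def protein_ids(self) -> np.ndarray:
        return self.df["protein_id"].to_numpy()

    def has_labels(self) -> bool:
        return bool(np.isfinite(self.labels).all()) and len(self) > 0

    def attribute_values(self, name: str) -> np.ndarray:
        """Tri-state attribute column as float 1/0/NaN."""
        if name not in self.attribute_names:
            raise DataError(f"unknown attribute {name!r}")
        return self.df[name].to_numpy(dtype=float)

    def record_attributes(self, i: int) -> dict[str, Optional[bool]]:
        row = self.df.iloc[i]
        return {
            a: (None if pd.isna(row[a]) else bool(row[a]))
            for a in self.attribute_names
        }

    def take(self, index: np.ndarray) -> "VariantTable":
        """Row subset (positional), preserving order of ``index``."""
        return VariantTable(self.df.iloc[np.asarray(index)].reset_index(drop=True),
                            self.attribute_names)

    def with_attribute(self, name: str, values: np.ndarray) -> "VariantTable":
        df = self.df.copy()
        df[name] = np.asarray(values, dtype=float)
        names = self.attribute_names + ([name] if name not in self.attribute_names else [])
        return VariantTable(df, names)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.to_csv(path, sep="\t", index=False, na_rep="")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"VariantTable({len(self)} records, "
                f"{len(self.attribute_names)} attributes)")


def _parse_tristate(series: pd.Series) -> pd.Series:
    """Parse an attribute column to float 1/0/NaN; unparseable cells → NaN."""
    def one(v):
        if isinstance(v, str):
            s = v.strip().lower()
            if s in ("true", "t", "yes", "1", "1.0"):
                return 1.0
            if s in ("false", "f", "no", "0", "0.0"):
                return 0.0
            return math.nan
        if pd.isna(v):
            return math.nan
        try:
            f = float(v)
        except (TypeError, ValueError):
            return math.nan
        if f in (0.0, 1.0):
            return f
        return math.nan

    return series.map(one)


def read_variant_table(path, dialect: Optional[Mapping[str, str]] = None) -> VariantTable:
    """Read a tab-separated variant table.

    ``dialect`` maps canonical column names to the headers used in the file
    (see :data:`DEFAULT_DIALECT`); only overrides need to be given.  Columns
    beyond the core ones and ``label`` are ingested as tri-state attributes;
    unparseable attribute cells become missing.  Row order is preserved.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    raw = pd.read_csv(path, sep="\t", header=0, dtype={d["protein_id"]: str},
                      float_precision="round_trip")
    rename = {v: k for k, v in d.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    missing = [c for c in CORE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    raw["wt"] = raw["wt"].astype(str).str.strip().str.upper()
    raw["mut"] = raw["mut"].astype(str).str.strip().str.upper()
    for i, (wt, mut) in enumerate(zip(raw["wt"], raw["mut"])):
        line = i + 2  # header is line 1
        if wt not in _CANONICAL_SET:
            raise FormatError(f"line {line}: invalid wild-type amino acid {wt!r}")
        if mut not in _CANONICAL_SET:
            raise FormatError(f"line {line}: invalid mutant amino acid {mut!r}")
        if wt == mut:
            raise FormatError(f"line {line}: wild-type equals mutant ({wt})")

    raw["position"] = raw["position"].astype(int)
    if (raw["position"] < 1).any():
        bad = int(np.argmax((raw["position"] < 1).to_numpy())) + 2
        raise FormatError(f"line {bad}: position must be >= 1")
    raw["score"] = raw["score"].astype(float)

    if "label" in raw.columns:
        raw["label"] = pd.to_numeric(raw["label"], errors="coerce").astype(float)
        ok = raw["label"].isna() | raw["label"].isin([0.0, 1.0])
        if not ok.all():
            bad = int(np.argmax(~ok.to_numpy())) + 2
            raise FormatError(f"line {bad}: label must be 0, 1 or empty")

    numeric_annotations = ("disorder", "cluster_size", "length")
    attr_cols = [c for c in raw.columns
                 if c not in CORE_COLUMNS and c != "label"
                 and c not in numeric_annotations]
    for c in attr_cols:
        raw[c] = _parse_tristate(raw[c])
    return VariantTable(raw, attr_cols)


def map_clinical_significance(text: str) -> Optional[int]:
    """Map a clinical-significance string to a binary label.

    Returns 1 for (likely) pathogenic categories, 0 for (likely) benign
    categories, and ``None`` for anything else (uncertain significance,
    conflicting interpretations, ...), which callers should drop.
    """
    s = text.strip().lower()
    if s in _PATHOGENIC_TERMS:
        return 1
    if s in _BENIGN_TERMS:
        return 0
    return None


def sequence_attributes(aa: str) -> dict[str, bool]:
    """Residue-set attribute memberships of one amino acid."""
    aa = aa.upper()
    if aa not in _CANONICAL_SET:
        raise DataError(f"non-canonical amino acid {aa!r}")
    return {name: aa in members for name, members in RESIDUE_SETS.items()}


def threshold_attributes(
    disorder_score: Optional[float],
    cluster_size: Optional[int],
    protein_length: int,
    *,
    disorder_cutoff: float = 0.7,
    homology_cutoff: int = 10,
    length_cutoff: int = 1022,
) -> dict[str, Optional[bool]]:
    """Threshold-derived residue/protein attributes.

    ``disordered`` is strict (> cutoff), ``low_homology`` is inclusive
    (<= cutoff homologs), ``long_protein`` is strict (> cutoff residues).
    Missing inputs yield missing outputs.
    """
    if protein_length < 1:
        raise DataError("protein_length must be >= 1")
    if cluster_size is not None and cluster_size < 0:
        raise DataError("cluster_size must be non-negative")
    out: dict[str, Optional[bool]] = {}
    out["disordered"] = (None if disorder_score is None or math.isnan(disorder_score)
                         else disorder_score > disorder_cutoff)
    out["low_homology"] = (None if cluster_size is None
                           else cluster_size <= homology_cutoff)
    out["long_protein"] = protein_length > length_cutoff
    return out


def attach_sequence_attributes(table: VariantTable,
                               names: Optional[Sequence[str]] = None) -> VariantTable:
    """Add residue-set attribute columns derived from the wild-type residue."""
    names = list(names) if names is not None else list(RESIDUE_SETS)
    out = table
    wt = table.df["wt"].to_numpy()
    for name in names:
        members = RESIDUE_SETS[name]
        out = out.with_attribute(name, np.array([float(a in members) for a in wt]))
    return out


def filter_well_annotated(table: VariantTable, min_total: int = 10,
                          min_pos: int = 4, min_neg: int = 4) -> VariantTable:
    """Keep only proteins with enough labeled variants of both classes.

    Defaults require at least ten labeled variants per protein, of which at
    least four pathogenic and four benign.  Record order is preserved; the
    filter is idempotent.
    """
    labels = table.labels
    df = table.df
    keep = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("protein_id", sort=False).indices.items():
        sub = labels[idx]
        lab = sub[np.isfinite(sub)]
        n_pos = int((lab == 1).sum())
        n_neg = int((lab == 0).sum())
        if len(lab) >= min_total and n_pos >= min_pos and n_neg >= min_neg:
            keep[idx] = True
    return table.take(np.flatnonzero(keep))
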