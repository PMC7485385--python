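"""Readers and writers for the pipeline's external representations.

Everything downstream of this module works on in-memory domain types:
:class:`CtMatrix` (raw qPCR cycle-threshold values), :class:`SampleSheet`
(genotype x treatment design with pooled-animal membership) and
:class:`GeneSetCollection` (GMT-style pathway collections).

Conventions
-----------
* Canonical dialect is TSV; CSV is accepted through ``sep=","``.
* Non-detected wells are encoded on disk as ``Undetermined`` (also accepted:
  empty cell, ``NA``, ``NaN``) and in memory as ``numpy.nan``.
* Feature identifiers (miRNA assay names such as ``mmu-miR-155`` or star
  names like ``mmu-miR-431*``) are opaque, case-sensitive strings; no
  miRBase version remapping is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_NONE",
    "NEGATIVE_CONTROL",
    "ENDOGENOUS_CONTROL",
    "MISSING_TOKENS",
    "MISSING_OUT",
    "CtMatrix",
    "Sample",
    "SampleSheet",
    "GeneSet",
    "GeneSetCollection",
    "read_ct_matrix",
    "write_ct_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
]

CONTROL_NONE = "none"
NEGATIVE_CONTROL = "negative_control"
ENDOGENOUS_CONTROL = "endogenous_control"
_CONTROL_FLAGS = {CONTROL_NONE, NEGATIVE_CONTROL, ENDOGENOUS_CONTROL}

#: Tokens read as a non-detected well.
MISSING_TOKENS = frozenset({"", "Undetermined", "undetermined", "NA", "NaN", "nan"})
#: Token written for a non-detected well.
MISSING_OUT = "Undetermined"


class FormatError(ValueError):
    """Raised when an on-disk file violates the dialect contract."""


@dataclass
class CtMatrix:
    """Raw Ct values, features x samples, with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids; ``NaN``
        marks a non-detected well.  Non-missing entries must be finite,
        positive PCR cycle numbers.
    control_flags
        Per-feature label from ``{none, negative_control,
        endogenous_control}``; features absent from the mapping are ``none``.
    """

    values: pd.DataFrame
    control_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature id(s): {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dupes}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isnan(arr) & (~np.isfinite(arr) | (arr <= 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"Ct value must be finite and > 0; offending cell "
                f"({idx[i]!r}, {cols[j]!r}) = {arr[i, j]!r}"
            )
        unknown = set(self.control_flags.values()) - _CONTROL_FLAGS
        if unknown:
            raise FormatError(f"unknown control flag(s): {sorted(unknown)}")
        missing_feats = set(self.control_flags) - set(idx)
        if missing_feats:
            raise FormatError(
                f"control flag for unknown feature(s): {sorted(missing_feats)}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def flag_of(self, feature_id: str) -> str:
        return self.control_flags.get(feature_id, CONTROL_NONE)

    def control_features(self) -> set[str]:
        return {f for f, fl in self.control_flags.items() if fl != CONTROL_NONE}

    def noncontrol_features(self) -> list[str]:
        ctrl = self.control_features()
        return [f for f in self.feature_ids if f not in ctrl]


@dataclass(frozen=True)
class Sample:
    """One profiled sample; ``pool_members`` lists the pooled animal ids."""

    sample_id: str
    genotype: str
    treatment: str
    pool_members: tuple[str, ...] = ()

    @property
    def group(self) -> str:
        """Group label: the genotype x treatment cross."""
        return f"{self.genotype}:{self.treatment}"


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample id(s) in sheet: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def groups(self) -> dict[str, list[str]]:
        """Mapping group label -> ordered sample ids."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def group_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.group
        raise KeyError(sample_id)

    def validate_against(self, ct: CtMatrix) -> None:
        """Hard error when the sheet and the Ct matrix disagree on samples."""
        sheet = set(self.sample_ids)
        matrix = set(ct.sample_ids)
        only_sheet = sorted(sheet - matrix)
        only_matrix = sorted(matrix - sheet)
        if only_sheet or only_matrix:
            raise FormatError(
                "sample sheet / Ct matrix mismatch: "
                f"in sheet only {only_sheet}, in matrix only {only_matrix}"
            )


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    terms: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate term id(s): {dupes}")
        for t in self.terms:
            if not t.genes:
                raise FormatError(f"empty gene set: {t.term_id}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def universe(self) -> set[str]:
        """All genes annotated to at least one term."""
        out: set[str] = set()
        for t in self.terms:
            out |= t.genes
        return out


def _parse_ct_cell(token: str, feature: str, sample: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"non-numeric Ct value {token!r} at feature {feature!r}, sample {sample!r}"
        ) from None


def read_ct_matrix(path, sep: str = "\t") -> CtMatrix:
    """Read a Ct matrix table.

    Layout: header ``feature_id<sep>sample1<sep>...``; an optional
    ``control_flag`` column (written by :func:`write_ct_matrix`) carries
    per-feature control labels.  Missing wells may be encoded as
    ``Undetermined``, ``NA`` or an empty cell.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a feature column plus >=1 sample column")
    feat_col = raw.columns[0]
    flags: dict[str, str] = {}
    sample_cols = list(raw.columns[1:])
    if "control_flag" in sample_cols:
        sample_cols.remove("control_flag")
    features = raw[feat_col].tolist()
    data = {
        s: [
            _parse_ct_cell(v, f, s)
            for f, v in zip(features, raw[s].tolist())
        ]
        for s in sample_cols
    }
    values = pd.DataFrame(data, index=pd.Index(features, name="feature_id"))
    if "control_flag" in raw.columns:
        for f, fl in zip(features, raw["control_flag"].tolist()):
            fl = fl.strip()
            if fl and fl != CONTROL_NONE:
                flags[f] = fl
    return CtMatrix(values=values, control_flags=flags)


def write_ct_matrix(ct: CtMatrix, path, sep: str = "\t") -> None:
    out = ct.values.copy()
    out = out.map(lambda v: MISSING_OUT if pd.isna(v) else repr(float(v)))
    if ct.control_flags:
        out["control_flag"] = [ct.flag_of(f) for f in ct.feature_ids]
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep)


def read_sample_sheet(path, sep: str = "\t") -> SampleSheet:
    """Read a sample sheet with columns sample_id, genotype, treatment
    and optional semicolon-separated pool_members."""
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty sample sheet") from None
    required = {"sample_id", "genotype", "treatment"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if len(raw) == 0:
        raise FormatError(f"{path}: sample sheet has no rows")
    samples = []
    for _, row in raw.iterrows():
        members: tuple[str, ...] = ()
        if "pool_members" in raw.columns and row["pool_members"].strip():
            members = tuple(
                m.strip() for m in row["pool_members"].split(";") if m.strip()
            )
        samples.append(
            Sample(
                sample_id=row["sample_id"].strip(),
                genotype=row["genotype"].strip(),
                treatment=row["treatment"].strip(),
                pool_members=members,
            )
        )
    return SampleSheet(samples=samples)


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genotype": s.genotype,
            "treatment": s.treatment,
            "pool_members": ";".join(s.pool_members),
        }
        for s in sheet.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: ``term_id<TAB>term_name<TAB>gene...``.

    Genes are deduplicated within a term; term order is preserved.
    """
    terms: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            terms.append(GeneSet(term_id=fields[0], term_name=fields[1], genes=genes))
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for t in collection.terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")
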