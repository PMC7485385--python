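"""Ct normalization: global-mean and reference-gene delta-Ct, 2^-ddCt.

Global-mean normalization (GMN) uses the arithmetic mean Ct of the reliably
detected assays within each sample as that sample's normalizer — on the
linear scale this is normalization to the geometric mean, the standard
choice for dense qPCR panels.  Reference-gene normalization subtracts a
single endogenous control (e.g. U6 snRNA).  Relative quantities follow the
2^-ddCt convention with perfect amplification efficiency (one cycle = one
log2 unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import CtMatrix, SampleSheet

__all__ = [
    "NormalizedMatrix",
    "global_mean_normalize",
    "reference_normalize",
    "relative_quantity",
    "group_delta_ct",
]

GLOBAL_MEAN = "global_mean"
REFERENCE_GENE = "reference_gene"


@dataclass
class NormalizedMatrix:
    """Delta-Ct values plus the per-sample normalizer record.

    ``delta_ct`` is features x samples in cycles (may be negative: below
    the normalizer means higher expression).  ``normalizer`` holds the
    per-sample value subtracted from every Ct.
    """

    delta_ct: pd.DataFrame
    method: str  # GLOBAL_MEAN | REFERENCE_GENE
    normalizer: pd.Series
    reference_feature: str | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_ct.columns)


def global_mean_normalize(ct: CtMatrix, detected: Iterable[str]) -> NormalizedMatrix:
    """Delta-Ct against the per-sample mean Ct over the detected set.

    Every feature in ``detected`` must have a non-missing Ct in every
    sample (the joint-detection filter guarantees this).
    """
    detected = list(dict.fromkeys(detected))
    if not detected:
        raise ValueError("detected feature set is empty")
    unknown = set(detected) - set(ct.feature_ids)
    if unknown:
        raise ValueError(f"detected feature(s) not in matrix: {sorted(unknown)}")
    sub = ct.values.loc[detected]
    if sub.isna().any().any():
        bad = sorted(sub.index[sub.isna().any(axis=1)])
        raise ValueError(f"missing Ct in detected feature(s): {bad}")
    normalizer = sub.mean(axis=0)
    delta = sub.sub(normalizer, axis=1)
    return NormalizedMatrix(
        delta_ct=delta, method=GLOBAL_MEAN, normalizer=normalizer
    )


def reference_normalize(ct: CtMatrix, reference_feature: str) -> NormalizedMatrix:
    """Delta-Ct against a single reference assay (e.g. ``U6 rRNA``)."""
    if reference_feature not in ct.feature_ids:
        raise ValueError(f"reference feature {reference_feature!r} not in matrix")
    ref_row = ct.values.loc[reference_feature]
    absent = sorted(ref_row.index[ref_row.isna()])
    if absent:
        raise ValueError(
            f"reference {reference_feature!r} undetected in sample(s): {absent}"
        )
    delta = ct.values.sub(ref_row, axis=1)
    return NormalizedMatrix(
        delta_ct=delta,
        method=REFERENCE_GENE,
        normalizer=ref_row,
        reference_feature=reference_feature,
    )


def relative_quantity(delta_ct_sample: float, delta_ct_reference: float) -> float:
    """2^-ddCt relative quantity; ddCt = dCt(sample) - dCt(reference)."""
    ddct = float(delta_ct_sample) - float(delta_ct_reference)
    if not np.isfinite(ddct):
        raise ValueError("delta-Ct values must be finite")
    return float(2.0 ** (-ddct))


def group_delta_ct(norm: NormalizedMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-feature, per-group mean delta-Ct with SEM and n.

    SEM uses the n-1 sample standard deviation; for n = 1 the SEM is NaN
    (undefined) and the mean is the single value.  Tidy output columns:
    feature_id, group, mean_delta_ct, sem, n.
    """
    groups = sheet.groups()
    missing = set(norm.sample_ids) - set(sheet.sample_ids)
    if missing:
        raise ValueError(f"samples without a group assignment: {sorted(missing)}")
    rows = []
    for group, sample_ids in groups.items():
        in_matrix = [s for s in sample_ids if s in norm.sample_ids]
        if not in_matrix:
            raise ValueError(f"group {group!r} has no samples in the matrix")
        sub = norm.delta_ct[in_matrix]
        n = len(in_matrix)
        mean = sub.mean(axis=1)
        sem = sub.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(
            np.nan, index=sub.index
        )
        for feature in sub.index:
            rows.append(
                {
                    "feature_id": feature,
                    "group": group,
                    "mean_delta_ct": float(mean[feature]),
                    "sem": float(sem[feature]),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
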