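"""Fold-change computation and threshold-based regulation calling.

With n = 3 pooled samples per group the study design has too little power
for FDR-corrected per-feature testing, so regulation is called from fold
changes alone: FC > 1.5 up, FC < 0.6 down, strict at both boundaries.
Fold changes come from the difference of group-mean delta-Ct values
(a geometric-mean ratio on the linear scale):

    FC(f) = 2^-( mean dCt(f, test) - mean dCt(f, reference) )

An optional two-sided pooled t-test on the per-sample delta-Ct values is
attached for reporting, never for calling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import SampleSheet
from .normalization import NormalizedMatrix
from . import group_stats

__all__ = [
    "UP",
    "DOWN",
    "UNCHANGED",
    "FoldChangeRecord",
    "classify_fc",
    "group_fold_change",
    "regulated_sets",
]

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

DEFAULT_UP_THRESHOLD = 1.5
DEFAULT_DOWN_THRESHOLD = 0.6


@dataclass(frozen=True)
class FoldChangeRecord:
    feature_id: str
    comparison: str  # "test_group vs reference_group"
    fc: float
    regulation: str  # UP | DOWN | UNCHANGED
    p: float | None = None


def classify_fc(
    fc: float,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> str:
    """Classify a fold change; both boundaries are strict inequalities."""
    if fc <= 0:
        raise ValueError(f"fold change must be > 0, got {fc!r}")
    if not down_threshold < up_threshold:
        raise ValueError("down_threshold must be below up_threshold")
    if fc > up_threshold:
        return UP
    if fc < down_threshold:
        return DOWN
    return UNCHANGED


def group_fold_change(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    test_group: str,
    reference_group: str,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    with_pvalues: bool = False,
) -> list[FoldChangeRecord]:
    """One fold-change record per feature for test vs reference group."""
    groups = sheet.groups()
    for label in (test_group, reference_group):
        if label not in groups:
            raise ValueError(
                f"unknown group {label!r}; known: {sorted(groups)}"
            )
    test_ids = [s for s in groups[test_group] if s in norm.sample_ids]
    ref_ids = [s for s in groups[reference_group] if s in norm.sample_ids]
    if not test_ids or not ref_ids:
        raise ValueError("both groups need at least one sample in the matrix")
    comparison = f"{test_group} vs {reference_group}"
    test = norm.delta_ct[test_ids]
    ref = norm.delta_ct[ref_ids]
    mean_diff = test.mean(axis=1) - ref.mean(axis=1)
    records = []
    for feature in norm.feature_ids:
        fc = float(2.0 ** (-mean_diff[feature]))
        p = None
        if with_pvalues:
            p = group_stats.ttest_raw(
                test.loc[feature].tolist(), ref.loc[feature].tolist()
            ).p
        records.append(
            FoldChangeRecord(
                feature_id=feature,
                comparison=comparison,
                fc=fc,
                regulation=classify_fc(fc, up_threshold, down_threshold),
                p=p,
            )
        )
    return records


def regulated_sets(
    records: list[FoldChangeRecord],
) -> tuple[frozenset[str], frozenset[str]]:
    """(up, down) feature-id sets from a single comparison's records."""
    comparisons = {r.comparison for r in records}
    if len(comparisons) > 1:
        raise ValueError(f"records mix comparisons: {sorted(comparisons)}")
    up = frozenset(r.feature_id for r in records if r.regulation == UP)
    down = frozenset(r.feature_id for r in records if r.regulation == DOWN)
    return up, down
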