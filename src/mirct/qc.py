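"""Detection filtering and internal-control QC for Ct matrices.

An assay is *detected* only when it amplified (non-missing Ct) with a Ct
strictly below the detection threshold (default 28 cycles) in **every**
sample in scope; panels typically include a negative control (expected not
to amplify) and endogenous small-RNA controls (expected everywhere), which
are checked but never silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_formats import CtMatrix, NEGATIVE_CONTROL, ENDOGENOUS_CONTROL

__all__ = ["DetectionReport", "ControlFinding", "filter_detected", "check_controls"]

DEFAULT_CT_THRESHOLD = 28.0


@dataclass(frozen=True)
class ControlFinding:
    control_id: str
    status: str  # "pass" | "warn"
    message: str


@dataclass
class DetectionReport:
    """Partition of the non-control panel into detected and dropped assays.

    ``dropped_features`` maps feature id -> per-sample failure reasons
    (``missing`` or ``Ct >= threshold``).
    """

    threshold: float
    scope: tuple[str, ...]
    detected_features: frozenset[str]
    dropped_features: dict[str, list[str]]
    control_findings: list[ControlFinding] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return len(self.detected_features)


def filter_detected(
    ct: CtMatrix,
    threshold: float = DEFAULT_CT_THRESHOLD,
    scope: Iterable[str] | None = None,
) -> DetectionReport:
    """Apply the detected-in-all-samples filter.

    A non-control feature is detected iff its Ct is non-missing and
    strictly below ``threshold`` in every sample of ``scope`` (default:
    all samples).  Control-flagged features are never detected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    scope_ids = list(scope) if scope is not None else list(ct.sample_ids)
    if not scope_ids:
        raise ValueError("empty sample scope")
    unknown = set(scope_ids) - set(ct.sample_ids)
    if unknown:
        raise ValueError(f"scope sample(s) not in matrix: {sorted(unknown)}")

    detected: set[str] = set()
    dropped: dict[str, list[str]] = {}
    sub = ct.values[scope_ids]
    for feature in ct.noncontrol_features():
        row = sub.loc[feature]
        reasons = []
        for sample_id, value in row.items():
            if np.isnan(value):
                reasons.append(f"{sample_id}: missing")
            elif value >= threshold:
                reasons.append(f"{sample_id}: Ct {value:g} >= {threshold:g}")
        if reasons:
            dropped[feature] = reasons
        else:
            detected.add(feature)
    return DetectionReport(
        threshold=threshold,
        scope=tuple(scope_ids),
        detected_features=frozenset(detected),
        dropped_features=dropped,
    )


def check_controls(
    ct: CtMatrix, threshold: float = DEFAULT_CT_THRESHOLD
) -> list[ControlFinding]:
    """Advisory QC on control assays; findings annotate, never remove.

    * negative control amplifying below ``threshold`` anywhere -> warn
      (possible contamination);
    * endogenous control missing in any sample -> warn.
    """
    findings: list[ControlFinding] = []
    for feature in ct.feature_ids:
        flag = ct.flag_of(feature)
        if flag == NEGATIVE_CONTROL:
            row = ct.values.loc[feature]
            hot = [
                f"{s} (Ct {v:g})"
                for s, v in row.items()
                if not np.isnan(v) and v < threshold
            ]
            if hot:
                findings.append(
                    ControlFinding(
                        feature,
                        "warn",
                        f"negative control amplified below Ct {threshold:g} in: "
                        + ", ".join(hot),
                    )
                )
            else:
                findings.append(
                    ControlFinding(feature, "pass", "negative control silent")
                )
        elif flag == ENDOGENOUS_CONTROL:
            row = ct.values.loc[feature]
            absent = [s for s, v in row.items() if np.isnan(v)]
            if absent:
                findings.append(
                    ControlFinding(
                        feature,
                        "warn",
                        "endogenous control undetected in: " + ", ".join(absent),
                    )
                )
            else:
                findings.append(
                    ControlFinding(feature, "pass", "endogenous control detected everywhere")
                )
    return findings
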