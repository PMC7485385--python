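"""miRNA -> gene target-table integration across databases.

Validated interaction databases (miRTarBase, TarBase) contribute binary
evidence; prediction databases (TargetScan, miRDB) contribute scored
edges whose scores live on incompatible scales.  Scores are therefore
rescaled per source onto [0, 1] with 1 = strongest support:

* miRDB publishes scores on [50, 100] (entries below 50 are pre-filtered
  upstream), mapped linearly onto [0.5, 1] — i.e. raw/100;
* TargetScan-style context scores are more negative when stronger, handled
  by min-max rescaling with a ``lower_is_stronger`` orientation flag;
* validated records carry an implicit rescaled score of 1 and bypass the
  score filter.

Predicted edges with rescaled score < 0.5 are discarded; sources are then
merged per (miRNA, gene) pair, and genes are kept only when targeted by at
least ``min_support`` (default 2) regulated miRNAs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace, field
from typing import Iterable, Sequence

__all__ = [
    "VALIDATED",
    "PREDICTED",
    "FixedRange",
    "MinMax",
    "SourceConfig",
    "TargetRecord",
    "GeneSupport",
    "MIRDB_CONFIG",
    "TARGETSCAN_CONFIG",
    "MIRTARBASE_CONFIG",
    "TARBASE_CONFIG",
    "rescale_scores",
    "filter_by_score",
    "merge_sources",
    "aggregate_gene_support",
    "read_target_table",
    "write_target_table",
]

VALIDATED = "validated"
PREDICTED = "predicted"

HIGHER_IS_STRONGER = "higher_is_stronger"
LOWER_IS_STRONGER = "lower_is_stronger"


@dataclass(frozen=True)
class FixedRange:
    """Linear map [lo_raw, hi_raw] -> [lo_scaled, hi_scaled]."""

    lo_raw: float
    hi_raw: float
    lo_scaled: float
    hi_scaled: float

    def apply(self, raw: float) -> float:
        span = self.hi_raw - self.lo_raw
        frac = (raw - self.lo_raw) / span
        return self.lo_scaled + frac * (self.hi_scaled - self.lo_scaled)


@dataclass(frozen=True)
class MinMax:
    """Observed-extreme rescale: strongest -> 1, weakest -> 0."""


@dataclass(frozen=True)
class SourceConfig:
    name: str
    evidence: str  # VALIDATED | PREDICTED
    score_direction: str = HIGHER_IS_STRONGER
    rescale: FixedRange | MinMax | None = None

    def __post_init__(self) -> None:
        if self.evidence == PREDICTED and self.rescale is None:
            raise ValueError(
                f"predicted source {self.name!r} must define a rescale rule"
            )


#: Canonical source configurations.
MIRDB_CONFIG = SourceConfig(
    "miRDB", PREDICTED, HIGHER_IS_STRONGER, FixedRange(50.0, 100.0, 0.5, 1.0)
)
TARGETSCAN_CONFIG = SourceConfig(
    "TargetScan", PREDICTED, LOWER_IS_STRONGER, MinMax()
)
MIRTARBASE_CONFIG = SourceConfig("miRTarBase", VALIDATED)
TARBASE_CONFIG = SourceConfig("TarBase", VALIDATED)


@dataclass(frozen=True)
class TargetRecord:
    mirna: str
    gene: str
    source: str
    evidence: str  # VALIDATED | PREDICTED
    raw_score: float | None = None
    rescaled_score: float | None = None
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sources:
            object.__setattr__(self, "sources", frozenset({self.source}))


@dataclass(frozen=True)
class GeneSupport:
    gene: str
    supporting_mirnas: frozenset[str]

    @property
    def support_count(self) -> int:
        return len(self.supporting_mirnas)


def rescale_scores(
    records: Sequence[TargetRecord], config: SourceConfig
) -> list[TargetRecord]:
    """Attach rescaled scores per the source's rule.

    Validated records pass through with rescaled score 1.0.  A raw score
    outside a declared fixed range is a hard error naming the record.
    """
    off_source = [r for r in records if r.source != config.name]
    if off_source:
        r = off_source[0]
        raise ValueError(
            f"record ({r.mirna}, {r.gene}) has source {r.source!r}, "
            f"config is for {config.name!r}"
        )
    if config.evidence == VALIDATED:
        return [replace(r, rescaled_score=1.0) for r in records]

    missing = [r for r in records if r.raw_score is None]
    if missing:
        r = missing[0]
        raise ValueError(
            f"predicted record ({r.mirna}, {r.gene}) from {config.name} "
            "has no raw score"
        )
    rule = config.rescale
    if isinstance(rule, FixedRange):
        out = []
        for r in records:
            raw = float(r.raw_score)
            lo, hi = sorted((rule.lo_raw, rule.hi_raw))
            if not lo <= raw <= hi:
                raise ValueError(
                    f"raw score {raw:g} of ({r.mirna}, {r.gene}) outside the "
                    f"declared range [{lo:g}, {hi:g}] for {config.name}"
                )
            out.append(replace(r, rescaled_score=rule.apply(raw)))
        return out
    if isinstance(rule, MinMax):
        if not records:
            return []
        raws = [float(r.raw_score) for r in records]
        lo, hi = min(raws), max(raws)
        if lo == hi:
            # degenerate spread: every score is the strongest observed
            return [replace(r, rescaled_score=1.0) for r in records]
        if config.score_direction == LOWER_IS_STRONGER:
            return [
                replace(r, rescaled_score=(hi - float(r.raw_score)) / (hi - lo))
                for r in records
            ]
        return [
            replace(r, rescaled_score=(float(r.raw_score) - lo) / (hi - lo))
            for r in records
        ]
    raise ValueError(f"source {config.name!r} has no usable rescale rule")


def filter_by_score(
    records: Sequence[TargetRecord], min_rescaled: float = 0.5
) -> list[TargetRecord]:
    """Drop predicted records with rescaled score strictly below the cut.

    Validated records are always retained.
    """
    out = []
    for r in records:
        if r.evidence == VALIDATED:
            out.append(r)
            continue
        if r.rescaled_score is None:
            raise ValueError(
                f"predicted record ({r.mirna}, {r.gene}) not rescaled yet"
            )
        if r.rescaled_score < min_rescaled:
            continue
        out.append(r)
    return out


def merge_sources(per_source: Iterable[Sequence[TargetRecord]]) -> list[TargetRecord]:
    """Union per-source tables into one record per (miRNA, gene) pair.

    Evidence is validated if any contributing source is validated;
    otherwise predicted with the maximum rescaled score.  Provenance keeps
    the union of supporting source names.  Output is sorted by (miRNA,
    gene) and therefore independent of input order.
    """
    merged: dict[tuple[str, str], TargetRecord] = {}
    for table in per_source:
        for r in table:
            key = (r.mirna, r.gene)
            prev = merged.get(key)
            if prev is None:
                merged[key] = r
                continue
            sources = prev.sources | r.sources
            if VALIDATED in (prev.evidence, r.evidence):
                keeper = prev if prev.evidence == VALIDATED else r
                merged[key] = replace(
                    keeper, rescaled_score=1.0, sources=sources
                )
            else:
                keeper = prev if prev.rescaled_score >= r.rescaled_score else r
                merged[key] = replace(keeper, sources=sources)
    return [merged[k] for k in sorted(merged)]


def aggregate_gene_support(
    records: Sequence[TargetRecord],
    regulated: Iterable[str],
    min_support: int = 2,
) -> list[GeneSupport]:
    """Genes targeted by at least ``min_support`` regulated miRNAs.

    ``regulated`` is one direction (up or down) of one condition; support
    counts distinct regulated miRNAs with a retained record to the gene.
    """
    regulated = frozenset(regulated)
    if not regulated:
        return []
    per_gene: dict[str, set[str]] = {}
    for r in records:
        if r.mirna in regulated:
            per_gene.setdefault(r.gene, set()).add(r.mirna)
    return [
        GeneSupport(gene=g, supporting_mirnas=frozenset(m))
        for g, m in sorted(per_gene.items())
        if len(m) >= min_support
    ]


def read_target_table(path, config: SourceConfig, sep: str = "\t") -> list[TargetRecord]:
    """Read a per-source TSV with columns mirna, gene, score (score may be
    blank for validated sources)."""
    records: list[TargetRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        required = {"mirna", "gene"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"{path}: needs columns mirna, gene (optional score)")
        for row in reader:
            score_txt = (row.get("score") or "").strip()
            raw = float(score_txt) if score_txt else None
            records.append(
                TargetRecord(
                    mirna=row["mirna"].strip(),
                    gene=row["gene"].strip(),
                    source=config.name,
                    evidence=config.evidence,
                    raw_score=raw,
                )
            )
    return records


def write_target_table(records: Sequence[TargetRecord], path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["mirna", "gene", "score"])
        for r in records:
            writer.writerow(
                [r.mirna, r.gene, "" if r.raw_score is None else repr(r.raw_score)]
            )
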