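"""End-to-end orchestration: qc -> normalize -> fold changes -> Venn ->
target aggregation -> enrichment, from a single run configuration.

Stages only communicate through their declared inputs, so removing a
comparison or a downstream stage leaves every other report unchanged.
Each run writes TSV reports plus a JSON manifest recording thresholds,
stage counts and input checksums; reruns of the same configuration are
byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import qc, normalization, differential, set_partition, targets, enrichment
from .io_formats import read_ct_matrix, read_sample_sheet, read_gmt

__all__ = ["Comparison", "TargetSource", "RunConfig", "run_pipeline"]

#: The five canonical genotype x treatment contrasts: each genotype and
#: treatment against the vehicle-injected wild-type baseline, the
#: knockout-vs-wild-type contrast after status epilepticus, and the
#: knockout's own treatment contrast.
DEFAULT_COMPARISONS = (
    ("KO-veh_vs_wt-veh", "P2rx7-KO:vehicle", "wt:vehicle"),
    ("wt-SE_vs_wt-veh", "wt:KA", "wt:vehicle"),
    ("KO-SE_vs_wt-veh", "P2rx7-KO:KA", "wt:vehicle"),
    ("KO-SE_vs_wt-SE", "P2rx7-KO:KA", "wt:KA"),
    ("KO-SE_vs_KO-veh", "P2rx7-KO:KA", "P2rx7-KO:vehicle"),
)


@dataclass(frozen=True)
class Comparison:
    name: str
    test_group: str
    reference_group: str


@dataclass(frozen=True)
class TargetSource:
    config: targets.SourceConfig
    path: str


@dataclass
class RunConfig:
    ct_path: str
    samples_path: str
    detection_threshold: float = 28.0
    normalization_method: str = "global_mean"
    reference_feature: str | None = None
    comparisons: list[Comparison] = field(
        default_factory=lambda: [Comparison(*c) for c in DEFAULT_COMPARISONS]
    )
    up_threshold: float = 1.5
    down_threshold: float = 0.6
    with_pvalues: bool = False
    venn_pairs: list[tuple[str, str]] = field(default_factory=list)
    target_sources: list[TargetSource] = field(default_factory=list)
    min_rescaled: float = 0.5
    min_support: int = 2
    target_conditions: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    alpha: float = 0.05
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comparisons = [
            Comparison(c["name"], c["test_group"], c["reference_group"])
            for c in raw.get("comparisons", [])
        ] or [Comparison(*c) for c in DEFAULT_COMPARISONS]
        sources = []
        for s in raw.get("target_sources", []):
            rule = s.get("rescale", {})
            kind = rule.get("type", "none")
            if kind == "fixed_range":
                rescale = targets.FixedRange(
                    rule["lo_raw"], rule["hi_raw"], rule["lo_scaled"], rule["hi_scaled"]
                )
            elif kind == "minmax":
                rescale = targets.MinMax()
            else:
                rescale = None
            sources.append(
                TargetSource(
                    config=targets.SourceConfig(
                        name=s["name"],
                        evidence=s["evidence"],
                        score_direction=s.get(
                            "score_direction", targets.HIGHER_IS_STRONGER
                        ),
                        rescale=rescale,
                    ),
                    path=s["path"],
                )
            )
        return cls(
            ct_path=raw["ct_path"],
            samples_path=raw["samples_path"],
            detection_threshold=raw.get("detection_threshold", 28.0),
            normalization_method=raw.get("normalization_method", "global_mean"),
            reference_feature=raw.get("reference_feature"),
            comparisons=comparisons,
            up_threshold=raw.get("up_threshold", 1.5),
            down_threshold=raw.get("down_threshold", 0.6),
            with_pvalues=raw.get("with_pvalues", False),
            venn_pairs=[tuple(p) for p in raw.get("venn_pairs", [])],
            target_sources=sources,
            min_rescaled=raw.get("min_rescaled", 0.5),
            min_support=raw.get("min_support", 2),
            target_conditions=raw.get("target_conditions", []),
            gmt_path=raw.get("gmt_path"),
            alpha=raw.get("alpha", 0.05),
            top_k=raw.get("top_k", 20),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _stage(name):
    """Wrap a stage so failures name the stage and the cause."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every configured stage; returns the manifest dict.

    Reports written under ``out_dir``: detection_report.tsv,
    normalized.tsv, foldchange_<comparison>.tsv, venn_<A>__<B>.tsv,
    gene_support_<comparison>_<direction>.tsv,
    enrichment_<comparison>_<direction>.tsv and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "detection_threshold": config.detection_threshold,
            "normalization_method": config.normalization_method,
            "up_threshold": config.up_threshold,
            "down_threshold": config.down_threshold,
            "min_rescaled": config.min_rescaled,
            "min_support": config.min_support,
            "alpha": config.alpha,
            "top_k": config.top_k,
        },
        "inputs": {},
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    @_stage("load")
    def load():
        ct = read_ct_matrix(config.ct_path)
        sheet = read_sample_sheet(config.samples_path)
        sheet.validate_against(ct)
        manifest["inputs"]["ct"] = {
            "path": str(config.ct_path),
            "sha256": _sha256(config.ct_path),
        }
        manifest["inputs"]["samples"] = {
            "path": str(config.samples_path),
            "sha256": _sha256(config.samples_path),
        }
        return ct, sheet

    ct, sheet = load()

    @_stage("qc")
    def stage_qc():
        report = qc.filter_detected(ct, threshold=config.detection_threshold)
        findings = qc.check_controls(ct, threshold=config.detection_threshold)
        rows = [[f, "detected", ""] for f in sorted(report.detected_features)]
        rows += [
            [f, "dropped", "; ".join(reasons)]
            for f, reasons in sorted(report.dropped_features.items())
        ]
        _write_tsv(out / "detection_report.tsv", ["feature_id", "status", "reasons"], rows)
        manifest["stages"]["qc"] = {
            "n_detected": report.n_detected,
            "n_dropped": len(report.dropped_features),
            "control_warnings": [
                f"{f.control_id}: {f.message}" for f in findings if f.status == "warn"
            ],
        }
        return report

    detection = stage_qc()

    @_stage("normalize")
    def stage_normalize():
        if config.normalization_method == "global_mean":
            norm = normalization.global_mean_normalize(
                ct, sorted(detection.detected_features)
            )
        elif config.normalization_method == "reference_gene":
            if not config.reference_feature:
                raise ValueError("reference_gene normalization needs reference_feature")
            norm = normalization.reference_normalize(ct, config.reference_feature)
            norm.delta_ct = norm.delta_ct.loc[sorted(detection.detected_features)]
        else:
            raise ValueError(f"unknown method {config.normalization_method!r}")
        norm.delta_ct.round(6).to_csv(out / "normalized.tsv", sep="\t")
        manifest["stages"]["normalize"] = {
            "method": norm.method,
            "n_features": len(norm.feature_ids),
        }
        return norm

    norm = stage_normalize()

    regulated: dict[str, tuple[frozenset, frozenset]] = {}

    @_stage("diffexpr")
    def stage_diffexpr():
        diff_counts = {}
        for comp in config.comparisons:
            records = differential.group_fold_change(
                norm,
                sheet,
                comp.test_group,
                comp.reference_group,
                up_threshold=config.up_threshold,
                down_threshold=config.down_threshold,
                with_pvalues=config.with_pvalues,
            )
            records.sort(key=lambda r: -r.fc)
            rows = [
                [
                    r.feature_id,
                    r.comparison,
                    f"{r.fc:.6g}",
                    r.regulation,
                    "" if r.p is None else f"{r.p:.6g}",
                ]
                for r in records
            ]
            _write_tsv(
                out / f"foldchange_{comp.name}.tsv",
                ["feature_id", "comparison", "fc", "regulation", "p"],
                rows,
            )
            up, down = differential.regulated_sets(records)
            regulated[comp.name] = (up, down)
            diff_counts[comp.name] = {"up": len(up), "down": len(down)}
        manifest["stages"]["diffexpr"] = diff_counts

    stage_diffexpr()

    @_stage("venn")
    def stage_venn():
        venn_counts = {}
        for name_a, name_b in config.venn_pairs:
            for name in (name_a, name_b):
                if name not in regulated:
                    raise ValueError(f"venn pair references unknown comparison {name!r}")
            part = set_partition.venn_partition(
                *regulated[name_a], *regulated[name_b], labels=(name_a, name_b)
            )
            rows = [
                [cell, len(members), ";".join(sorted(members))]
                for cell, members in part.cells().items()
            ]
            _write_tsv(
                out / f"venn_{name_a}__{name_b}.tsv",
                ["cell", "count", "feature_ids"],
                rows,
            )
            venn_counts[f"{name_a}__{name_b}"] = set_partition.overlap_summary(part)
        manifest["stages"]["venn"] = venn_counts

    stage_venn()

    if config.target_sources:

        @_stage("targets")
        def stage_targets():
            per_source = []
            for src in config.target_sources:
                table = targets.read_target_table(src.path, src.config)
                table = targets.rescale_scores(table, src.config)
                table = targets.filter_by_score(table, config.min_rescaled)
                per_source.append(table)
                manifest["inputs"][f"targets_{src.config.name}"] = {
                    "path": str(src.path),
                    "sha256": _sha256(src.path),
                }
            merged = targets.merge_sources(per_source)
            conditions = config.target_conditions or [c.name for c in config.comparisons]
            supported: dict[tuple[str, str], list] = {}
            counts = {}
            for cond in conditions:
                if cond not in regulated:
                    raise ValueError(f"target condition references unknown comparison {cond!r}")
                up, down = regulated[cond]
                for direction, reg in (("up", up), ("down", down)):
                    support = targets.aggregate_gene_support(
                        merged, reg, config.min_support
                    )
                    supported[(cond, direction)] = support
                    rows = [
                        [s.gene, s.support_count, ";".join(sorted(s.supporting_mirnas))]
                        for s in support
                    ]
                    _write_tsv(
                        out / f"gene_support_{cond}_{direction}.tsv",
                        ["gene", "support_count", "supporting_mirnas"],
                        rows,
                    )
                    counts[f"{cond}_{direction}"] = len(support)
            manifest["stages"]["targets"] = counts
            return supported

        supported = stage_targets()

        if config.gmt_path:

            @_stage("enrich")
            def stage_enrich():
                collection = read_gmt(config.gmt_path)
                manifest["inputs"]["gene_sets"] = {
                    "path": str(config.gmt_path),
                    "sha256": _sha256(config.gmt_path),
                }
                counts = {}
                for (cond, direction), support in supported.items():
                    genes = {s.gene for s in support}
                    if not genes:
                        counts[f"{cond}_{direction}"] = 0
                        continue
                    try:
                        results = enrichment.enrich(
                            genes, collection, alpha=config.alpha
                        )
                    except ValueError:
                        counts[f"{cond}_{direction}"] = 0
                        continue
                    rows = [
                        [
                            r.term_id,
                            r.term_name,
                            r.k,
                            r.K,
                            r.n,
                            r.N,
                            f"{r.p:.6g}",
                            f"{r.p_adj:.6g}",
                            r.significant,
                        ]
                        for r in enrichment.top_k(results, config.top_k)
                    ]
                    _write_tsv(
                        out / f"enrichment_{cond}_{direction}.tsv",
                        ["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj", "significant"],
                        rows,
                    )
                    counts[f"{cond}_{direction}"] = sum(
                        1 for r in results if r.significant
                    )
                manifest["stages"]["enrich"] = counts

            stage_enrich()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
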