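"""Synthetic OpenArray-style qPCR data with known ground truth.

The generator emulates a 754-assay murine miRNA panel profiled over four
genotype x treatment groups of three samples each, every sample a pool of
two animals, with four internal controls (one negative).  Expression acts
on the Ct scale with the perfect-efficiency idealization (one log2 unit of
expression = one cycle, sign inverted).  Per feature:

    Ct(f, sample) = baseline(f) - log2 effect(f, group)
                    + mean of pool-size animal draws + technical noise

where animal draws and the technical replicate term are both Gaussian with
the configured noise SD.  Wells whose Ct exceeds the dropout threshold
become non-detected (missing); the negative control never amplifies.

Baselines are drawn from N(28, 3) cycles so that, under the default
Ct < 28-in-all-12-samples detection filter, roughly 44% of the panel is
jointly detected — the detection fraction characteristic of hippocampal
OpenArray runs.  Planted features are given a fixed low baseline (24
cycles by default) so a planted down-regulation cannot silently fall out
of the detected set.

Every generator is a pure function of (config, seed): the same inputs
produce bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CtMatrix,
    GeneSet,
    GeneSetCollection,
    Sample,
    SampleSheet,
    NEGATIVE_CONTROL,
    ENDOGENOUS_CONTROL,
)
from .targets import (
    SourceConfig,
    TargetRecord,
    FixedRange,
    MinMax,
    PREDICTED,
    VALIDATED,
    LOWER_IS_STRONGER,
)

__all__ = [
    "GroupSpec",
    "PlantedEffect",
    "SimulationConfig",
    "TruthTable",
    "DEFAULT_GROUPS",
    "generate_ct_dataset",
    "generate_target_db",
    "generate_gene_sets",
]

NEGATIVE_CONTROL_ID = "ath-miR159a"
ENDOGENOUS_CONTROL_IDS = ("RNU48", "RNU44", "U6 rRNA")


@dataclass(frozen=True)
class GroupSpec:
    genotype: str
    treatment: str
    n_samples: int = 3

    @property
    def label(self) -> str:
        return f"{self.genotype}:{self.treatment}"


DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("wt", "vehicle"),
    GroupSpec("wt", "KA"),
    GroupSpec("P2rx7-KO", "vehicle"),
    GroupSpec("P2rx7-KO", "KA"),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A true log2 expression shift of one feature in one group
    (relative to all unshifted groups)."""

    feature_id: str
    group: str
    log2fc: float


@dataclass
class SimulationConfig:
    n_features: int = 754
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    pool_size: int = 2
    baseline_ct_mean: float = 28.0
    baseline_ct_sd: float = 3.0
    noise_sd: float = 0.25
    dropout_ct: float = 35.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    planted_baseline_ct: float | None = 24.0
    control_ct: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= len(ENDOGENOUS_CONTROL_IDS) + 1:
            raise ValueError("n_features must exceed the number of controls")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        group_labels = {g.label for g in self.groups}
        feature_ids = set(feature_names(self.n_features))
        for e in self.planted_effects:
            if e.group not in group_labels:
                raise ValueError(f"planted effect on unknown group {e.group!r}")
            if e.feature_id not in feature_ids:
                raise ValueError(f"planted effect on unknown feature {e.feature_id!r}")


@dataclass
class TruthTable:
    """Ground truth of a simulation.

    ``group_effects`` maps (feature_id, group_label) -> true log2 shift;
    the true log2 fold change for a test-vs-reference comparison is the
    difference of the two group shifts.  Target-database / gene-set truth
    is attached by the corresponding generators.
    """

    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    gene_support: dict[str, int] = field(default_factory=dict)
    planted_term_id: str | None = None

    def true_log2fc(self, feature_id: str, test_group: str, reference_group: str) -> float:
        return self.group_effects.get((feature_id, test_group), 0.0) - \
            self.group_effects.get((feature_id, reference_group), 0.0)


def feature_names(n_features: int) -> list[str]:
    return [f"mmu-miR-sim-{i + 1:04d}" for i in range(n_features)]


def generate_ct_dataset(
    config: SimulationConfig,
) -> tuple[CtMatrix, SampleSheet, TruthTable]:
    """Simulate a Ct matrix, its sample sheet and the ground truth."""
    rng = np.random.default_rng(config.seed)
    features = feature_names(config.n_features)

    baselines = rng.normal(
        config.baseline_ct_mean, config.baseline_ct_sd, size=config.n_features
    )
    baselines = np.clip(baselines, 10.0, None)
    index_of = {f: i for i, f in enumerate(features)}
    if config.planted_baseline_ct is not None:
        for e in config.planted_effects:
            baselines[index_of[e.feature_id]] = config.planted_baseline_ct

    effects = np.zeros((config.n_features, len(config.groups)))
    truth = TruthTable()
    group_index = {g.label: j for j, g in enumerate(config.groups)}
    for e in config.planted_effects:
        effects[index_of[e.feature_id], group_index[e.group]] += e.log2fc
        key = (e.feature_id, e.group)
        truth.group_effects[key] = truth.group_effects.get(key, 0.0) + e.log2fc

    samples: list[Sample] = []
    columns: dict[str, np.ndarray] = {}
    animal_counter = itertools.count(1)
    sample_counter = itertools.count(1)
    for j, g in enumerate(config.groups):
        for _ in range(g.n_samples):
            sid = f"S{next(sample_counter):02d}_{g.genotype}_{g.treatment}"
            members = tuple(f"animal{next(animal_counter):03d}" for _ in range(config.pool_size))
            samples.append(
                Sample(
                    sample_id=sid,
                    genotype=g.genotype,
                    treatment=g.treatment,
                    pool_members=members,
                )
            )
            # higher expression -> lower Ct, hence the minus sign
            animal_ct = (
                baselines[:, None]
                - effects[:, j][:, None]
                + rng.normal(0.0, config.noise_sd, size=(config.n_features, config.pool_size))
            )
            ct = animal_ct.mean(axis=1) + rng.normal(
                0.0, config.noise_sd, size=config.n_features
            )
            ct[ct > config.dropout_ct] = np.nan
            columns[sid] = ct

    values = pd.DataFrame(columns, index=pd.Index(features, name="feature_id"))

    # internal controls: one silent negative, three stable endogenous
    flags: dict[str, str] = {NEGATIVE_CONTROL_ID: NEGATIVE_CONTROL}
    control_rows = {NEGATIVE_CONTROL_ID: np.full(len(samples), np.nan)}
    for ctrl in ENDOGENOUS_CONTROL_IDS:
        flags[ctrl] = ENDOGENOUS_CONTROL
        control_rows[ctrl] = config.control_ct + rng.normal(
            0.0, config.noise_sd, size=len(samples)
        )
    control_df = pd.DataFrame(
        control_rows, index=[s.sample_id for s in samples]
    ).T
    control_df.index.name = "feature_id"
    values = pd.concat([values, control_df])

    return CtMatrix(values=values, control_flags=flags), SampleSheet(samples), truth


def generate_target_db(
    mirnas: int | Sequence[str],
    n_genes: int,
    density: float,
    sources: Sequence[SourceConfig],
    planted_hubs: Sequence[tuple[str, int]] = (),
    regulated: Sequence[str] = (),
    seed: int = 0,
) -> tuple[dict[str, list[TargetRecord]], TruthTable]:
    """Random per-source miRNA -> gene tables with planted hub genes.

    Background edges are Bernoulli(density) per (miRNA, gene, source) with
    source-appropriate score distributions: miRDB-style fixed-range scores
    uniform on the declared raw range, TargetScan-style scores on a
    negative scale (more negative = stronger), validated sources unscored.
    Each planted hub gene receives edges from the requested number of
    regulated miRNAs with scores guaranteed to survive rescaling and the
    0.5 score filter; the truth table records the planted support counts.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mirna_ids = (
        [f"mmu-miR-sim-{i + 1:04d}" for i in range(mirnas)]
        if isinstance(mirnas, int)
        else list(mirnas)
    )
    genes = [f"Gene{i + 1:05d}" for i in range(n_genes)]
    regulated = list(regulated)
    for gene, count in planted_hubs:
        if count > len(regulated):
            raise ValueError(
                f"hub {gene!r} demands {count} regulated miRNAs, "
                f"only {len(regulated)} available"
            )

    def draw_score(cfg: SourceConfig, strong: bool) -> float | None:
        if cfg.evidence == VALIDATED:
            return None
        if isinstance(cfg.rescale, FixedRange):
            lo, hi = sorted((cfg.rescale.lo_raw, cfg.rescale.hi_raw))
            if strong:
                return float(rng.uniform(lo + 0.5 * (hi - lo), hi))
            return float(rng.uniform(lo, hi))
        # min-max scored source (TargetScan-like): negative scale
        if cfg.score_direction == LOWER_IS_STRONGER:
            return float(rng.uniform(-1.2, -0.9) if strong else rng.uniform(-1.2, -0.01))
        return float(rng.uniform(0.9, 1.2) if strong else rng.uniform(0.01, 1.2))

    tables: dict[str, list[TargetRecord]] = {cfg.name: [] for cfg in sources}
    for cfg in sources:
        mask = rng.random((len(mirna_ids), len(genes))) < density
        for i, j in np.argwhere(mask):
            tables[cfg.name].append(
                TargetRecord(
                    mirna=mirna_ids[i],
                    gene=genes[j],
                    source=cfg.name,
                    evidence=cfg.evidence,
                    raw_score=draw_score(cfg, strong=False),
                )
            )

    truth = TruthTable()
    hub_sources = [c for c in sources if not isinstance(c.rescale, MinMax)]
    if planted_hubs and not hub_sources:
        raise ValueError(
            "planted hubs need at least one validated or fixed-range source "
            "(min-max rescaling cannot guarantee filter survival)"
        )
    for gene, count in planted_hubs:
        if gene not in genes:
            genes.append(gene)
        chosen = list(rng.choice(regulated, size=count, replace=False))
        for mirna in chosen:
            cfg = hub_sources[int(rng.integers(len(hub_sources)))]
            tables[cfg.name].append(
                TargetRecord(
                    mirna=mirna,
                    gene=gene,
                    source=cfg.name,
                    evidence=cfg.evidence,
                    raw_score=draw_score(cfg, strong=True),
                )
            )
        truth.gene_support[gene] = count
    return tables, truth


def generate_gene_sets(
    n_terms: int,
    term_size_range: tuple[int, int],
    planted_fraction: float,
    query_size: int,
    universe: Sequence[str],
    seed: int = 0,
) -> tuple[GeneSetCollection, set[str], TruthTable]:
    """Random gene-set collection with one planted enriched term.

    The first term is the planted one; the returned query draws
    ``planted_fraction`` of its genes from that term and the rest from
    the remaining universe, so at fraction 1 the query sits entirely
    inside the planted term and at the term's base rate the query carries
    no enrichment signal.
    """
    if not 0 < planted_fraction <= 1:
        raise ValueError("planted_fraction must be in (0, 1]")
    lo, hi = term_size_range
    universe = list(universe)
    if hi > len(universe):
        raise ValueError("term sizes exceed the universe")
    if query_size > len(universe):
        raise ValueError("query size exceeds the universe")
    rng = np.random.default_rng(seed)

    terms = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        terms.append(
            GeneSet(
                term_id=f"TERM{t + 1:04d}",
                term_name=f"synthetic pathway {t + 1}",
                genes=frozenset(genes.tolist()),
            )
        )
    collection = GeneSetCollection(terms=terms)
    planted = terms[0]

    n_inside = min(round(planted_fraction * query_size), len(planted.genes))
    inside = rng.choice(sorted(planted.genes), size=n_inside, replace=False).tolist()
    outside_pool = sorted(set(universe) - planted.genes)
    n_outside = min(query_size - n_inside, len(outside_pool))
    outside = rng.choice(outside_pool, size=n_outside, replace=False).tolist()
    query = set(inside) | set(outside)

    truth = TruthTable(planted_term_id=planted.term_id)
    return collection, query, truth
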