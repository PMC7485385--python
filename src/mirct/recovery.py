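"""Simulation studies: how well the pipeline recovers planted truth.

Two stock experiments at the profiled study's design:

* :func:`classification_recovery` — plant log2 fold changes on a 754-assay
  panel (4 groups x 3 pooled samples, 0.25-cycle noise), run detection ->
  global-mean normalization -> fold-change calling, and score sensitivity
  (planted features called in the true direction) and false-positive rate
  (unplanted detected features called regulated at all).
* :func:`target_enrichment_recovery` — plant hub genes in synthetic target
  databases and a single enriched term in a synthetic gene-set collection,
  run score rescaling -> filtering -> merging -> support aggregation ->
  over-representation, and score exact hub-support recovery and the
  fraction of runs ranking the planted term first by adjusted p.

Both iterate over independent seeds derived from a base seed, so results
are reproducible and the per-seed scores are honest replicates.
"""

from __future__ import annotations

import numpy as np

from . import differential, enrichment, normalization, qc, targets
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    feature_names,
    generate_ct_dataset,
    generate_gene_sets,
    generate_target_db,
)

__all__ = ["classification_recovery", "target_enrichment_recovery"]

_TEST_GROUP = "P2rx7-KO:vehicle"
_REFERENCE_GROUP = "wt:vehicle"


def classification_recovery(
    n_seeds: int = 20,
    n_features: int = 754,
    n_planted: int = 20,
    log2fc_magnitude: float = 1.58,
    noise_sd: float = 0.25,
    base_seed: int = 0,
) -> dict:
    """Mean sensitivity and false-positive rate over planted simulations.

    Half the planted features are shifted up, half down, by the given
    log2 magnitude in the test group.
    """
    names = feature_names(n_features)[:n_planted]
    effects = tuple(
        PlantedEffect(f, _TEST_GROUP, log2fc_magnitude if i % 2 == 0 else -log2fc_magnitude)
        for i, f in enumerate(names)
    )
    truth_direction = {
        f: (differential.UP if i % 2 == 0 else differential.DOWN)
        for i, f in enumerate(names)
    }

    sensitivities, fprs, detected_counts = [], [], []
    for s in range(n_seeds):
        config = SimulationConfig(
            n_features=n_features,
            noise_sd=noise_sd,
            seed=base_seed + s,
            planted_effects=effects,
        )
        ct, sheet, _ = generate_ct_dataset(config)
        detected = qc.filter_detected(ct).detected_features
        norm = normalization.global_mean_normalize(ct, sorted(detected))
        records = differential.group_fold_change(
            norm, sheet, _TEST_GROUP, _REFERENCE_GROUP
        )
        by_id = {r.feature_id: r.regulation for r in records}
        hits = sum(
            1 for f, direction in truth_direction.items()
            if by_id.get(f) == direction
        )
        sensitivities.append(hits / n_planted)
        unplanted = [f for f in by_id if f not in truth_direction]
        false_calls = sum(
            1 for f in unplanted if by_id[f] != differential.UNCHANGED
        )
        fprs.append(false_calls / len(unplanted))
        detected_counts.append(len(detected))
    return {
        "sensitivity": float(np.mean(sensitivities)),
        "false_positive_rate": float(np.mean(fprs)),
        "mean_detected": float(np.mean(detected_counts)),
        "n_seeds": n_seeds,
    }


def target_enrichment_recovery(
    n_seeds: int = 50,
    n_regulated: int = 10,
    planted_hubs: tuple[tuple[str, int], ...] = (
        ("HubGene1", 3),
        ("HubGene2", 2),
        ("HubGene3", 4),
    ),
    n_genes: int = 400,
    density: float = 0.004,
    planted_fraction: float = 0.8,
    base_seed: int = 0,
) -> dict:
    """Hub-gene and enriched-term recovery over independent seeds.

    Hub recovery is exact when every planted hub's aggregated support
    equals its true support — the number of distinct regulated miRNAs
    with any surviving edge to the gene, counted directly from the
    generated tables (planted edges plus chance background edges).
    """
    sources = [targets.MIRDB_CONFIG, targets.MIRTARBASE_CONFIG]
    regulated = feature_names(n_regulated)
    universe = [f"Gene{i + 1:05d}" for i in range(n_genes)]

    hub_exact, term_first = 0, 0
    for s in range(n_seeds):
        seed = base_seed + s
        tables, _ = generate_target_db(
            mirnas=regulated,
            n_genes=n_genes,
            density=density,
            sources=sources,
            planted_hubs=list(planted_hubs),
            regulated=regulated,
            seed=seed,
        )
        # true support, counted straight off the generated edge lists
        # (every miRDB edge scores >= 50, so everything survives the filter)
        true_support: dict[str, set[str]] = {}
        for table in tables.values():
            for r in table:
                if r.mirna in regulated:
                    true_support.setdefault(r.gene, set()).add(r.mirna)

        processed = [
            targets.filter_by_score(targets.rescale_scores(tables[c.name], c))
            for c in sources
        ]
        merged = targets.merge_sources(processed)
        support = {
            g.gene: g.support_count
            for g in targets.aggregate_gene_support(merged, regulated, min_support=2)
        }
        hub_exact += all(
            support.get(gene) == len(true_support[gene]) for gene, _ in planted_hubs
        )

        collection, query, truth = generate_gene_sets(
            n_terms=12,
            term_size_range=(25, 45),
            planted_fraction=planted_fraction,
            query_size=30,
            universe=universe,
            seed=seed,
        )
        results = enrichment.enrich(query, collection)
        term_first += results[0].term_id == truth.planted_term_id
    return {
        "hub_support_exact_fraction": hub_exact / n_seeds,
        "planted_term_first_fraction": term_first / n_seeds,
        "n_seeds": n_seeds,
    }
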