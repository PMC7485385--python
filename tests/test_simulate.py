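"""Determinism and ground-truth fidelity of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from mirct.differential import group_fold_change, regulated_sets
from mirct.normalization import global_mean_normalize
from mirct.qc import filter_detected
from mirct.simulate import (
    DEFAULT_GROUPS,
    PlantedEffect,
    SimulationConfig,
    generate_ct_dataset,
    generate_gene_sets,
    generate_target_db,
)
from mirct.targets import MIRDB_CONFIG, MIRTARBASE_CONFIG


class TestGenerateCtDataset:
    def test_design_dimensions(self):
        ct, sheet, _ = generate_ct_dataset(SimulationConfig(seed=0))
        assert len(ct.noncontrol_features()) == 754
        assert len(ct.control_features()) == 4
        assert len(sheet.samples) == 12
        assert len(sheet.groups()) == 4
        assert all(len(s.pool_members) == 2 for s in sheet.samples)

    def test_fixed_seed_is_bit_identical(self):
        a, _, _ = generate_ct_dataset(SimulationConfig(n_features=60, seed=9))
        b, _, _ = generate_ct_dataset(SimulationConfig(n_features=60, seed=9))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a, _, _ = generate_ct_dataset(SimulationConfig(n_features=60, seed=1))
        b, _, _ = generate_ct_dataset(SimulationConfig(n_features=60, seed=2))
        assert not a.values.equals(b.values)

    def test_negative_control_never_amplifies(self):
        ct, _, _ = generate_ct_dataset(SimulationConfig(n_features=30, seed=4))
        assert ct.values.loc["ath-miR159a"].isna().all()

    def test_noiseless_null_gives_unit_fold_changes(self):
        config = SimulationConfig(n_features=40, noise_sd=0.0, seed=5)
        ct, sheet, _ = generate_ct_dataset(config)
        detected = filter_detected(ct).detected_features
        norm = global_mean_normalize(ct, sorted(detected))
        records = group_fold_change(norm, sheet, "P2rx7-KO:KA", "wt:vehicle")
        assert all(r.fc == pytest.approx(1.0, abs=1e-12) for r in records)

    def test_dropout_applies_above_threshold(self):
        config = SimulationConfig(
            n_features=40, seed=6, baseline_ct_mean=34.0, baseline_ct_sd=2.0,
            dropout_ct=35.0,
        )
        ct, _, _ = generate_ct_dataset(config)
        noncontrol = ct.values.loc[ct.noncontrol_features()]
        assert noncontrol.isna().any().any()
        assert (noncontrol.fillna(0) <= 35.0).all().all()

    def test_unknown_planted_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            SimulationConfig(
                n_features=10,
                planted_effects=(PlantedEffect("mmu-miR-sim-9999", "wt:KA", 1.0),),
            )

    def test_unknown_planted_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            SimulationConfig(
                n_features=10,
                planted_effects=(PlantedEffect("mmu-miR-sim-0001", "mars:KA", 1.0),),
            )

    def test_truth_table_log2fc(self):
        config = SimulationConfig(
            n_features=10,
            planted_effects=(
                PlantedEffect("mmu-miR-sim-0001", "wt:KA", 2.0),
                PlantedEffect("mmu-miR-sim-0002", "P2rx7-KO:KA", -1.0),
            ),
        )
        _, _, truth = generate_ct_dataset(config)
        assert truth.true_log2fc("mmu-miR-sim-0001", "wt:KA", "wt:vehicle") == 2.0
        assert truth.true_log2fc("mmu-miR-sim-0001", "P2rx7-KO:KA", "wt:KA") == -2.0
        assert truth.true_log2fc("mmu-miR-sim-0002", "P2rx7-KO:KA", "wt:vehicle") == -1.0
        assert truth.true_log2fc("mmu-miR-sim-0003", "wt:KA", "wt:vehicle") == 0.0

    def test_type_one_error_controlled_under_null(self):
        # with no planted effects the fraction of regulated calls stays
        # below 5% at the 1.5 / 0.6 thresholds (averaged over seeds)
        rates = []
        for seed in range(10):
            ct, sheet, _ = generate_ct_dataset(
                SimulationConfig(n_features=200, seed=seed)
            )
            detected = filter_detected(ct).detected_features
            norm = global_mean_normalize(ct, sorted(detected))
            records = group_fold_change(norm, sheet, "P2rx7-KO:vehicle", "wt:vehicle")
            up, down = regulated_sets(records)
            rates.append((len(up) + len(down)) / len(records))
        assert np.mean(rates) < 0.05


class TestGenerateTargetDb:
    def test_fixed_seed_identical(self):
        args = dict(
            mirnas=10, n_genes=30, density=0.1,
            sources=[MIRDB_CONFIG, MIRTARBASE_CONFIG], seed=3,
        )
        a, _ = generate_target_db(**args)
        b, _ = generate_target_db(**args)
        assert a == b

    def test_scores_match_source_conventions(self):
        tables, _ = generate_target_db(
            mirnas=10, n_genes=30, density=0.3,
            sources=[MIRDB_CONFIG, MIRTARBASE_CONFIG], seed=0,
        )
        assert all(50 <= r.raw_score <= 100 for r in tables["miRDB"])
        assert all(r.raw_score is None for r in tables["miRTarBase"])

    def test_bad_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            generate_target_db(5, 5, 0.0, [MIRDB_CONFIG], seed=0)


class TestGenerateGeneSets:
    def test_fixed_seed_identical(self):
        universe = [f"G{i}" for i in range(200)]
        args = dict(
            n_terms=10, term_size_range=(10, 20), planted_fraction=0.8,
            query_size=20, universe=universe, seed=7,
        )
        a_col, a_query, a_truth = generate_gene_sets(**args)
        b_col, b_query, b_truth = generate_gene_sets(**args)
        assert a_query == b_query
        assert [t.genes for t in a_col.terms] == [t.genes for t in b_col.terms]
        assert a_truth.planted_term_id == b_truth.planted_term_id

    def test_fraction_one_query_inside_planted_term(self):
        universe = [f"G{i}" for i in range(100)]
        col, query, truth = generate_gene_sets(
            n_terms=5, term_size_range=(20, 30), planted_fraction=1.0,
            query_size=15, universe=universe, seed=1,
        )
        planted = next(t for t in col.terms if t.term_id == truth.planted_term_id)
        assert query <= planted.genes

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            generate_gene_sets(3, (5, 50), 0.5, 5, [f"G{i}" for i in range(10)], 0)

    def test_base_rate_query_rarely_significant(self):
        # when the query samples the planted term at its base rate there is
        # no signal: significance at alpha 0.05 in <= 10% of seeds
        universe = [f"G{i}" for i in range(400)]
        from mirct.enrichment import enrich

        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            col, _, truth = generate_gene_sets(
                n_terms=10, term_size_range=(40, 40), planted_fraction=0.1,
                query_size=30, universe=universe, seed=seed,
            )
            # fraction 0.1 = term base rate (40/400)
            _, query, _ = generate_gene_sets(
                n_terms=10, term_size_range=(40, 40), planted_fraction=0.1,
                query_size=30, universe=universe, seed=seed,
            )
            results = enrich(query, col)
            planted = next(r for r in results if r.term_id == truth.planted_term_id)
            hits += planted.significant
        assert hits / n_seeds <= 0.10
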