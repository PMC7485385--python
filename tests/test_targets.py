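"""Target-table rescaling, filtering, merging and gene-support aggregation."""

import numpy as np
import pytest

from mirct.simulate import generate_target_db
from mirct.targets import (
    FixedRange,
    MIRDB_CONFIG,
    MIRTARBASE_CONFIG,
    TARGETSCAN_CONFIG,
    PREDICTED,
    VALIDATED,
    SourceConfig,
    TargetRecord,
    aggregate_gene_support,
    filter_by_score,
    merge_sources,
    read_target_table,
    rescale_scores,
    write_target_table,
)


def mirdb(mirna, gene, score):
    return TargetRecord(mirna, gene, "miRDB", PREDICTED, raw_score=score)


def targetscan(mirna, gene, score):
    return TargetRecord(mirna, gene, "TargetScan", PREDICTED, raw_score=score)


def validated(mirna, gene, source="miRTarBase"):
    return TargetRecord(mirna, gene, source, VALIDATED)


class TestRescaleScores:
    @pytest.mark.parametrize(
        "raw, expected", [(50.0, 0.5), (100.0, 1.0), (75.0, 0.75), (60.0, 0.6)]
    )
    def test_mirdb_fixed_range_is_raw_over_100(self, raw, expected):
        (rec,) = rescale_scores([mirdb("m1", "G1", raw)], MIRDB_CONFIG)
        assert rec.rescaled_score == pytest.approx(expected)

    def test_mirdb_score_outside_declared_range_is_error(self):
        with pytest.raises(ValueError, match="G1"):
            rescale_scores([mirdb("m1", "G1", 42.0)], MIRDB_CONFIG)

    def test_targetscan_minmax_endpoints(self):
        # context-style scores: more negative = stronger
        recs = rescale_scores(
            [targetscan("m1", "G1", -1.2), targetscan("m1", "G2", -0.1),
             targetscan("m1", "G3", -0.65)],
            TARGETSCAN_CONFIG,
        )
        by_gene = {r.gene: r.rescaled_score for r in recs}
        assert by_gene["G1"] == pytest.approx(1.0)   # strongest observed
        assert by_gene["G2"] == pytest.approx(0.0)   # weakest observed
        assert 0.0 < by_gene["G3"] < 1.0

    def test_validated_records_get_score_one(self):
        (rec,) = rescale_scores([validated("m1", "G1")], MIRTARBASE_CONFIG)
        assert rec.rescaled_score == 1.0

    def test_all_rescaled_scores_in_unit_interval(self):
        rng = np.random.default_rng(0)
        recs = [mirdb(f"m{i}", f"G{i}", rng.uniform(50, 100)) for i in range(50)]
        recs += [validated(f"m{i}", f"H{i}") for i in range(10)]
        out = rescale_scores(recs[:50], MIRDB_CONFIG) + rescale_scores(
            recs[50:], MIRTARBASE_CONFIG
        )
        assert all(0.0 <= r.rescaled_score <= 1.0 for r in out)

    def test_wrong_source_record_rejected(self):
        with pytest.raises(ValueError, match="source"):
            rescale_scores([mirdb("m1", "G1", 60.0)], TARGETSCAN_CONFIG)

    def test_predicted_source_requires_rescale_rule(self):
        with pytest.raises(ValueError, match="rescale"):
            SourceConfig("X", PREDICTED, rescale=None)


class TestFilterByScore:
    def test_strict_boundary(self):
        kept = filter_by_score(
            rescale_scores(
                [mirdb("m1", "G1", 49.999 + 0.001), mirdb("m1", "G2", 50.0)],
                SourceConfig("miRDB", PREDICTED, rescale=FixedRange(0, 100, 0, 1)),
            )
        )
        # raw 50 -> rescaled 0.50 retained; raw 50.0 under [0,100] -> 0.5 kept,
        # 49.999+0.001 = 50 -> kept too; check the genuinely sub-threshold case:
        assert {r.gene for r in kept} == {"G1", "G2"}
        dropped = filter_by_score(
            rescale_scores(
                [mirdb("m1", "G3", 49.0)],
                SourceConfig("miRDB", PREDICTED, rescale=FixedRange(0, 100, 0, 1)),
            )
        )
        assert dropped == []  # rescaled 0.49 < 0.5 removed

    def test_validated_always_retained(self):
        recs = rescale_scores([validated("m1", "G1")], MIRTARBASE_CONFIG)
        assert filter_by_score(recs, min_rescaled=0.99) == recs

    def test_unrescaled_predicted_record_is_error(self):
        with pytest.raises(ValueError, match="rescaled"):
            filter_by_score([mirdb("m1", "G1", 60.0)])


class TestMergeSources:
    def test_validated_wins_over_predicted(self):
        a = rescale_scores([validated("m1", "G1")], MIRTARBASE_CONFIG)
        b = rescale_scores([mirdb("m1", "G1", 80.0)], MIRDB_CONFIG)
        (merged,) = merge_sources([a, b])
        assert merged.evidence == VALIDATED
        assert merged.rescaled_score == 1.0
        assert merged.sources == {"miRTarBase", "miRDB"}

    def test_disjoint_pairs_concatenate(self):
        a = rescale_scores([validated("m1", "G1")], MIRTARBASE_CONFIG)
        b = rescale_scores([mirdb("m2", "G2", 80.0)], MIRDB_CONFIG)
        assert len(merge_sources([a, b])) == 2

    def test_predicted_keeps_max_rescaled(self):
        a = rescale_scores([mirdb("m1", "G1", 60.0)], MIRDB_CONFIG)
        b = rescale_scores([mirdb("m1", "G1", 90.0)], MIRDB_CONFIG)
        (merged,) = merge_sources([a, b])
        assert merged.rescaled_score == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_union_and_is_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        tables = []
        for source, cfg in [("miRDB", MIRDB_CONFIG), ("miRTarBase", MIRTARBASE_CONFIG)]:
            recs = []
            for _ in range(40):
                m, g = f"m{rng.integers(8)}", f"G{rng.integers(8)}"
                if source == "miRDB":
                    recs.append(mirdb(m, g, float(rng.uniform(50, 100))))
                else:
                    recs.append(validated(m, g))
            tables.append(rescale_scores(recs, cfg))
        merged = merge_sources(tables)
        # brute force: pair-keyed dictionary union
        expected_pairs = {(r.mirna, r.gene) for t in tables for r in t}
        assert {(r.mirna, r.gene) for r in merged} == expected_pairs
        assert len(merged) == len(expected_pairs)
        # permutation of inputs yields identical output
        assert merge_sources(tables[::-1]) == merged
        # idempotence
        assert merge_sources([merged]) == merged


class TestAggregateGeneSupport:
    def _records(self):
        recs = [
            validated("m1", "G1"),
            mirdb("m2", "G1", 80.0),
            validated("m1", "G2"),
            validated("m3", "G3"),
            validated("m4", "G3"),
            validated("m5", "G3"),
        ]
        out = rescale_scores([r for r in recs if r.source == "miRDB"], MIRDB_CONFIG)
        out += rescale_scores(
            [r for r in recs if r.source == "miRTarBase"], MIRTARBASE_CONFIG
        )
        return merge_sources([out])

    def test_single_mirna_gene_excluded(self):
        support = aggregate_gene_support(self._records(), {"m1", "m2", "m3", "m4", "m5"})
        genes = {s.gene for s in support}
        assert "G2" not in genes  # only one regulated miRNA targets it
        assert genes == {"G1", "G3"}

    def test_cross_source_support_counts(self):
        support = {s.gene: s for s in aggregate_gene_support(
            self._records(), {"m1", "m2", "m3", "m4", "m5"})}
        assert support["G1"].support_count == 2
        assert support["G3"].support_count == 3

    def test_empty_regulated_set_gives_empty_output(self):
        assert aggregate_gene_support(self._records(), set()) == []

    def test_monotone_shrinkage_in_min_support(self):
        recs = self._records()
        reg = {"m1", "m2", "m3", "m4", "m5"}
        sizes = [len(aggregate_gene_support(recs, reg, k)) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)


class TestRoundTripAndSyntheticDb:
    def test_table_roundtrip(self, tmp_path):
        recs = [mirdb("m1", "G1", 72.5), mirdb("m2", "G2", 55.0)]
        p = tmp_path / "targets_miRDB.tsv"
        write_target_table(recs, p)
        back = read_target_table(p, MIRDB_CONFIG)
        assert [(r.mirna, r.gene, r.raw_score) for r in back] == [
            ("m1", "G1", 72.5), ("m2", "G2", 55.0)
        ]

    def test_planted_hub_recovered_with_exact_support(self):
        regulated = [f"mmu-miR-sim-{i + 1:04d}" for i in range(10)]
        tables, truth = generate_target_db(
            mirnas=20, n_genes=50, density=0.01,
            sources=[MIRDB_CONFIG, MIRTARBASE_CONFIG],
            planted_hubs=[("HubGene", 3)], regulated=regulated, seed=5,
        )
        processed = [
            filter_by_score(rescale_scores(tables["miRDB"], MIRDB_CONFIG)),
            filter_by_score(rescale_scores(tables["miRTarBase"], MIRTARBASE_CONFIG)),
        ]
        merged = merge_sources(processed)
        support = {s.gene: s for s in aggregate_gene_support(merged, regulated, 2)}
        assert support["HubGene"].support_count == truth.gene_support["HubGene"] == 3

    def test_hub_demanding_too_many_mirnas_is_error(self):
        with pytest.raises(ValueError, match="Hub"):
            generate_target_db(
                5, 10, 0.5, [MIRDB_CONFIG], planted_hubs=[("Hub", 3)],
                regulated=["m1"], seed=0,
            )

    def test_full_density_two_by_two(self):
        tables, _ = generate_target_db(
            ["m1", "m2"], 2, 1.0, [MIRDB_CONFIG], seed=1
        )
        assert len(tables["miRDB"]) == 4
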