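import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from panproteo import differential
from panproteo.io_tables import IntensityMatrix, SampleMetadata, TISSUES
from panproteo.simulate import SimConfig, generate_cohort


def diff_cohort(seed=0, **overrides):
    base = dict(
        samples_per_tissue={t: (8, 8) for t in TISSUES},
        n_proteins=500, n_housekeeping=0,
        n_tissue_enriched={"1": 0, "2": 0, "3": 0, "4+": 0},
        n_cancer_up=5, n_cancer_down=5, cancer_log2_effect=2.0,
        noise_log2_sd=0.3, missing_rate=0.0, n_outlier_samples=0,
        rng_seed=seed,
    )
    base.update(overrides)
    return generate_cohort(SimConfig(**base))


def tables_from_calls(call_frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Wrap a proteins x cancers call matrix as differential tables."""
    out = {}
    for c in call_frame.columns:
        out[c] = pd.DataFrame(
            {
                "log2_fc": np.where(call_frame[c] == "up", 1.5,
                                    np.where(call_frame[c] == "down", -1.5, 0.0)),
                "p": 0.01,
                "adj_p": np.where(call_frame[c] == "none", 0.9, 0.01),
                "call": call_frame[c],
            },
            index=call_frame.index,
        )
    return out


class TestTumorVsNormal:
    def test_planted_effects_called_with_correct_direction(self):
        matrix, metadata, truth = diff_cohort(seed=1)
        t = differential.tumor_vs_normal(matrix, metadata, "kidney")
        for pid, cancers in truth.cancer_up_map.items():
            if "kidney" in cancers:
                assert t.loc[pid, "call"] == "up"
        for pid, cancers in truth.cancer_down_map.items():
            if "kidney" in cancers:
                assert t.loc[pid, "call"] == "down"

    def test_fc_gate_blocks_significant_but_small_changes(self):
        # 1.7-fold (log2 fc ~0.77) with tiny variance: significant p, no call
        rng = np.random.default_rng(2)
        samples = [f"t{i}" for i in range(8)] + [f"n{i}" for i in range(8)]
        vals = np.vstack([
            np.concatenate([2.0 ** rng.normal(15.77, 0.05, 8),
                            2.0 ** rng.normal(15.0, 0.05, 8)]),
            2.0 ** rng.normal(12, 0.05, 16),
        ])
        m = IntensityMatrix(pd.DataFrame(vals, index=["small", "flat"],
                                         columns=samples))
        md = SampleMetadata(pd.DataFrame({
            "sample_id": samples, "patient_id": samples,
            "tissue": "liver", "state": ["tumor"] * 8 + ["NAT"] * 8,
        }))
        t = differential.tumor_vs_normal(m, md, "liver")
        assert t.loc["small", "adj_p"] < 0.05
        assert t.loc["small", "call"] == "none"

    def test_null_cohort_call_rate_bounded_by_fdr(self):
        matrix, metadata, _ = diff_cohort(seed=3, n_cancer_up=0,
                                          n_cancer_down=0)
        tables = differential.differential_all_cancers(matrix, metadata)
        calls = differential.call_matrix(tables)
        frac = float((calls != "none").to_numpy().mean())
        assert frac <= 0.05

    def test_tumor_only_cancer_is_skipped(self):
        matrix, metadata, _ = diff_cohort(
            seed=4,
            samples_per_tissue={"liver": (6, 6), "brain": (6, 0)},
        )
        tables = differential.differential_all_cancers(matrix, metadata)
        assert "brain" not in tables
        assert "liver" in tables


class TestAggregation:
    def test_strict_40_percent_boundary(self):
        cancers = list(TISSUES)
        calls = pd.DataFrame("none", index=["seven", "six", "all"],
                             columns=cancers)
        calls.loc["seven", cancers[:7]] = "up"    # 7/16 = 43.75% > 40%
        calls.loc["six", cancers[:6]] = "up"      # 6/16 = 37.5%
        calls.loc["all", :] = "up"
        common = differential.aggregate_cross_cancer(tables_from_calls(calls))
        assert "seven" in common.index
        assert "six" not in common.index
        assert "all" in common.index

    def test_invariant_to_cancer_ordering(self):
        matrix, metadata, _ = diff_cohort(seed=5, n_archetype_per_class=5)
        tables = differential.differential_all_cancers(matrix, metadata)
        reversed_tables = dict(reversed(list(tables.items())))
        a = differential.aggregate_cross_cancer(tables)
        b = differential.aggregate_cross_cancer(reversed_tables)
        pd.testing.assert_frame_equal(a, b)

    def test_common_and_unique_lists_disjoint(self):
        matrix, metadata, _ = diff_cohort(seed=6, n_archetype_per_class=5)
        tables = differential.differential_all_cancers(matrix, metadata)
        common = set(differential.aggregate_cross_cancer(tables).index)
        unique = set(differential.unique_cancer_proteins(tables).index)
        assert not common & unique


class TestUniqueProteins:
    def test_single_cancer_up_proteins_mapped(self):
        matrix, metadata, truth = diff_cohort(seed=7)
        tables = differential.differential_all_cancers(matrix, metadata)
        unique = differential.unique_cancer_proteins(tables)
        for pid, cancers in truth.cancer_up_map.items():
            (cancer,) = cancers
            assert unique.get(pid) == cancer

    def test_multi_cancer_protein_excluded(self):
        calls = pd.DataFrame("none", index=["multi", "solo"],
                             columns=["liver", "colon", "kidney"])
        calls.loc["multi", ["liver", "colon"]] = "up"
        calls.loc["solo", "kidney"] = "up"
        unique = differential.unique_cancer_proteins(tables_from_calls(calls))
        assert "multi" not in unique.index
        assert unique["solo"] == "kidney"


class TestClustering:
    def test_zscore_rows_are_standardized(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(rng.normal(10, 3, (20, 15)))
        z = differential.zscore_rows(frame)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.std(z.to_numpy(), axis=1), 1.0, atol=1e-9)

    def test_k1_puts_everything_in_one_group(self, small_cohort):
        matrix, metadata, _ = small_cohort
        ids = list(matrix.protein_ids[:10])
        asg = differential.cluster_protein_groups(matrix, metadata, ids, k=1)
        assert set(asg.labels) == {"PG-1"}

    def test_fewer_proteins_than_k_rejected(self, small_cohort):
        matrix, metadata, _ = small_cohort
        with pytest.raises(ValueError, match="cannot form"):
            differential.cluster_protein_groups(
                matrix, metadata, list(matrix.protein_ids[:3]), k=4)

    def test_two_separated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(9)
        samples = [f"t{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
        high_t = np.hstack([rng.normal(18, 0.2, (15, 10)),
                            rng.normal(12, 0.2, (15, 10))])
        high_n = np.hstack([rng.normal(12, 0.2, (15, 10)),
                            rng.normal(18, 0.2, (15, 10))])
        m = IntensityMatrix(pd.DataFrame(
            2.0 ** np.vstack([high_t, high_n]),
            index=[f"a{i}" for i in range(15)] + [f"b{i}" for i in range(15)],
            columns=samples))
        md = SampleMetadata(pd.DataFrame({
            "sample_id": samples, "patient_id": samples,
            "tissue": "liver", "state": ["tumor"] * 10 + ["NAT"] * 10,
        }))
        asg = differential.cluster_protein_groups(
            m, md, list(m.protein_ids), k=2)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, asg.labels.tolist()) == 1.0
        # tumor-elevated block gets the first label
        assert asg.labels["a0"] == "PG-1"

    def test_four_archetypes_recovered(self):
        matrix, metadata, truth = diff_cohort(
            seed=10, n_cancer_up=0, n_cancer_down=0,
            n_archetype_per_class=25,
        )
        ids = sorted(truth.archetype_map)
        asg = differential.cluster_protein_groups(matrix, metadata, ids, k=4)
        ari = adjusted_rand_score(
            [truth.archetype_map[p] for p in asg.labels.index],
            asg.labels.tolist(),
        )
        assert ari >= 0.9

    def test_deterministic_given_inputs(self):
        matrix, metadata, truth = diff_cohort(seed=11, n_archetype_per_class=10)
        ids = sorted(truth.archetype_map)
        a = differential.cluster_protein_groups(matrix, metadata, ids, k=4)
        b = differential.cluster_protein_groups(matrix, metadata, ids, k=4)
        pd.testing.assert_series_equal(a.labels, b.labels)
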