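import numpy as np
import pandas as pd
import pytest

from panproteo import enrichment
from panproteo.io_tables import IntensityMatrix, SampleMetadata, TISSUES
from panproteo.quantfilter import impute_missing
from panproteo.simulate import SimConfig, generate_cohort


def enrichment_cohort(seed=0, **overrides):
    base = dict(
        n_proteins=800, n_housekeeping=0,
        n_tissue_enriched={"1": 20, "2": 8, "3": 4, "4+": 2},
        n_cancer_up=0, n_cancer_down=0,
        enrichment_log2_effect=3.0, noise_log2_sd=0.3,
        missing_rate=0.0, n_outlier_samples=0, rng_seed=seed,
    )
    base.update(overrides)
    return generate_cohort(SimConfig(**base))


class TestRequiredWins:
    @pytest.mark.parametrize(
        "n_comparators,coverage,expected",
        [(15, 0.7, 11), (15, 1.0, 15), (14, 0.7, 10), (2, 0.7, 2)],
    )
    def test_ceiling_integerization(self, n_comparators, coverage, expected):
        assert enrichment.required_wins(n_comparators, coverage) == expected


class TestPairwiseStats:
    def test_antisymmetric_fold_changes(self):
        matrix, metadata, _ = enrichment_cohort(seed=1, n_proteins=100,
                                                n_tissue_enriched={"1": 2})
        stats = enrichment.pairwise_tissue_stats(matrix, metadata)
        fc_lc = stats.log2_fc["liver"]["colon"]
        fc_cl = stats.log2_fc["colon"]["liver"]
        np.testing.assert_allclose(fc_lc.to_numpy(), -fc_cl.to_numpy())
        # the two-sided adjusted p is shared between the orders
        np.testing.assert_allclose(
            stats.adj_p["liver"]["colon"].to_numpy(),
            stats.adj_p["colon"]["liver"].to_numpy(),
        )

    def test_planted_16fold_liver_protein_shows_log2fc_4(self):
        matrix, metadata, truth = enrichment_cohort(
            seed=2, n_tissue_enriched={"1": 1}, enrichment_log2_effect=4.0,
        )
        (pid, tissues), = truth.enriched_map.items()
        (tissue,) = tissues
        stats = enrichment.pairwise_tissue_stats(matrix, metadata)
        fcs = stats.log2_fc[tissue].loc[pid]
        assert fcs.to_numpy() == pytest.approx(4.0, abs=0.5)


class TestClassification:
    def test_coverage_boundary_11_of_15(self):
        # constructed stats: protein beats exactly 11 (enriched) or 10 (not)
        tissues = list(TISSUES)
        proteins = pd.Index(["hit", "miss"])
        fc, ap = {}, {}
        for t in tissues:
            others = [u for u in tissues if u != t]
            fc[t] = pd.DataFrame(0.0, index=proteins, columns=others)
            ap[t] = pd.DataFrame(1.0, index=proteins, columns=others)
        others = [u for u in tissues if u != "liver"]
        fc["liver"].loc["hit", others[:11]] = 3.0
        ap["liver"].loc["hit", others[:11]] = 0.001
        fc["liver"].loc["miss", others[:10]] = 3.0
        ap["liver"].loc["miss", others[:10]] = 0.001
        stats = enrichment.PairwiseStats(
            proteins=proteins, tissues=tissues, log2_fc=fc, adj_p=ap)
        result = enrichment.classify_enriched(stats)
        assert result.enriched.loc["hit", "liver"]
        assert not result.enriched.loc["miss", "liver"]
        assert result.multiplicity["hit"] == 1
        assert result.category["hit"] == "1"

    def test_coverage_out_of_range_rejected(self):
        matrix, metadata, _ = enrichment_cohort(seed=3, n_proteins=50,
                                                n_tissue_enriched={"1": 1})
        stats = enrichment.pairwise_tissue_stats(matrix, metadata)
        with pytest.raises(ValueError, match="coverage"):
            enrichment.classify_enriched(stats, coverage=1.5)

    def test_planted_multiplicities_recovered(self):
        matrix, metadata, truth = enrichment_cohort(seed=4)
        imputed = impute_missing(matrix, metadata)
        stats = enrichment.pairwise_tissue_stats(imputed, metadata)
        result = enrichment.classify_enriched(stats)
        for pid, tissues in truth.enriched_map.items():
            called = set(result.enriched.columns[result.enriched.loc[pid]])
            assert called == tissues
        # nothing beyond the planted proteins is called
        called_any = set(result.enriched_proteins())
        assert called_any == set(truth.enriched_map)

    def test_null_cohort_has_no_enrichment(self):
        matrix, metadata, _ = enrichment_cohort(
            seed=5, n_proteins=300,
            n_tissue_enriched={"1": 0, "2": 0, "3": 0, "4+": 0},
        )
        stats = enrichment.pairwise_tissue_stats(matrix, metadata)
        result = enrichment.classify_enriched(stats)
        assert int((result.multiplicity > 0).sum()) == 0

    def test_permuting_tissue_labels_destroys_calls(self):
        matrix, metadata, truth = enrichment_cohort(seed=6, n_proteins=400,
                                                    n_tissue_enriched={"1": 10})
        rng = np.random.default_rng(0)
        shuffled = metadata.table.copy().drop(columns="group")
        shuffled["tissue"] = rng.permutation(shuffled["tissue"].to_numpy())
        md_perm = SampleMetadata(shuffled)
        stats = enrichment.pairwise_tissue_stats(matrix, md_perm)
        result = enrichment.classify_enriched(stats)
        planted = set(truth.enriched_map)
        recovered = set(result.enriched_proteins()) & planted
        assert len(recovered) / len(planted) < 0.2


class TestMultiplicityBreakdown:
    def test_counts_partition_the_enriched_total(self):
        matrix, metadata, _ = enrichment_cohort(seed=7)
        stats = enrichment.pairwise_tissue_stats(matrix, metadata)
        result = enrichment.classify_enriched(stats)
        breakdown = enrichment.multiplicity_breakdown(result)
        assert breakdown["count"].sum() == int((result.multiplicity > 0).sum())
        assert breakdown["percent"].sum() == pytest.approx(100.0)

    def test_empty_result_gives_zero_counts(self):
        matrix, metadata, _ = enrichment_cohort(
            seed=8, n_proteins=100,
            n_tissue_enriched={"1": 0, "2": 0, "3": 0, "4+": 0},
        )
        stats = enrichment.pairwise_tissue_stats(matrix, metadata)
        result = enrichment.classify_enriched(stats)
        breakdown = enrichment.multiplicity_breakdown(result)
        assert (breakdown["count"] == 0).all()
        assert (breakdown["percent"] == 0.0).all()


class TestGroupEnrichment:
    def test_protein_elevated_in_all_digestive_tissues_is_group_enriched(self):
        matrix, metadata, _ = enrichment_cohort(
            seed=9, n_proteins=200,
            n_tissue_enriched={"1": 0, "2": 0, "3": 0, "4+": 0},
        )
        # plant a 16-fold effect across every digestive tissue by hand
        digestive = ["colon", "stomach", "esophagus", "pancreas", "liver"]
        samples = [s for t in digestive for s in metadata.samples(tissue=t)]
        data = matrix.data.copy()
        data.loc["P00001", samples] *= 16.0
        planted = IntensityMatrix(data)
        groups = enrichment.group_enrichment(planted, metadata)
        assert "P00001" in groups["digestive"]

    def test_constant_protein_not_group_enriched(self):
        matrix, metadata, _ = enrichment_cohort(
            seed=10, n_proteins=100,
            n_tissue_enriched={"1": 0, "2": 0, "3": 0, "4+": 0},
        )
        groups = enrichment.group_enrichment(matrix, metadata)
        assert all(len(ids) == 0 for ids in groups.values())
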