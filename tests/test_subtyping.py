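import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from renalmatch.errors import DegenerateInputError, InvalidArgumentError
from renalmatch.harmonize import ALLELE, GeneMatrix, SegmentProfile, segments_to_genes
from renalmatch.subtyping import (arm_loh_fraction, arm_loss_fraction,
                                  assign_cell_line_subtype, cluster_profiles,
                                  combined_3p_call, cut_and_summarize,
                                  fraction_genome_altered)
from renalmatch.synthetic import (balanced_diploid_scenario, default_archetypes,
                                  masked_loss_scenario,
                                  ploidy_relative_scenario,
                                  simulate_allele_specific, simulate_cna_cohort)
from tests.conftest import random_profile


def log2_profile(rows, sample="S"):
    return SegmentProfile(sample, pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "value"]))


class TestFga:
    def test_nothing_altered(self):
        p = log2_profile([("1", 1, 100, 0.1), ("2", 1, 100, -0.19)])
        assert fraction_genome_altered(p).fga == 0.0

    def test_everything_altered(self):
        p = log2_profile([("1", 1, 100, 0.2), ("2", 1, 100, -0.7)])
        assert fraction_genome_altered(p).fga == 1.0

    def test_hand_ratio(self):
        p = log2_profile([("1", 1, 100, 0.5), ("1", 101, 400, 0.0)])
        assert fraction_genome_altered(p).fga == pytest.approx(0.25)

    def test_matches_per_bp_oracle(self, tiny_genome):
        rng = np.random.default_rng(9)
        for i in range(20):
            p = random_profile(rng, tiny_genome, f"S{i}")
            fga = fraction_genome_altered(p).fga
            num = den = 0
            for seg in p.segments.itertuples(index=False):
                length = seg.end - seg.start + 1
                den += length
                if abs(seg.value) >= 0.2:
                    num += length
            assert fga == pytest.approx(num / den, abs=0)

    def test_monotone_in_threshold(self, tiny_genome):
        rng = np.random.default_rng(10)
        p = random_profile(rng, tiny_genome)
        fgas = [fraction_genome_altered(p, t).fga for t in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(fgas, fgas[1:]))

    def test_empty_profile_degenerate(self):
        p = SegmentProfile("S", pd.DataFrame(
            columns=["chromosome", "start", "end", "value"]))
        with pytest.raises(DegenerateInputError):
            fraction_genome_altered(p)


class TestArmLoss:
    def test_whole_arm_lost(self, genome):
        cent = genome.centromeres["3"]
        p = log2_profile([("3", 1, cent, -0.5)])
        assert arm_loss_fraction(p, genome, "3p") == 1.0

    def test_whole_arm_neutral(self, genome):
        cent = genome.centromeres["3"]
        p = log2_profile([("3", 1, cent, 0.0)])
        assert arm_loss_fraction(p, genome, "3p") == 0.0

    def test_half_arm_matches_oracle(self, genome):
        cent = genome.centromeres["3"]
        half = cent // 2
        p = log2_profile([("3", 1, half, -0.3), ("3", half + 1, cent, 0.0)])
        assert arm_loss_fraction(p, genome, "3p") == pytest.approx(half / cent)

    def test_uncovered_arm_indeterminate(self, genome):
        p = log2_profile([("5", 1, 100, -0.5)])
        assert arm_loss_fraction(p, genome, "3p") is None

    def test_segments_clipped_to_arm(self, genome):
        length = genome.chromosome_length("3")
        cent = genome.centromeres["3"]
        p = log2_profile([("3", 1, length, -0.5)])  # spans both arms
        assert arm_loss_fraction(p, genome, "3p") == 1.0


class TestArmLoh:
    def test_masked_loss_split_between_estimators(self, genome):
        """Minor-allele estimator sees the loss that major-allele
        amplification hides from the total-copy log2 view."""
        (allele,) = simulate_allele_specific(genome, {"s": masked_loss_scenario()})
        zm, rel, mean_total = arm_loh_fraction(allele, genome, "3p")
        assert zm == 1.0
        from renalmatch.harmonize import integral_to_log2
        log2_view = integral_to_log2(allele)
        assert arm_loss_fraction(log2_view, genome, "3p") <= 0.01

    def test_balanced_diploid_no_loh(self, genome):
        (allele,) = simulate_allele_specific(genome, {"s": balanced_diploid_scenario()})
        zm, rel, mean_total = arm_loh_fraction(allele, genome, "3p")
        assert zm == 0.0
        assert mean_total == pytest.approx(2.0)

    def test_ploidy_relative_loss(self, genome):
        (allele,) = simulate_allele_specific(genome, {"s": ploidy_relative_scenario()})
        zm, rel, mean_total = arm_loh_fraction(allele, genome, "3p")
        assert zm == 0.0
        assert rel == 1.0
        assert mean_total > 2.5

    def test_estimators_agree_without_allelic_imbalance(self, genome):
        """One whole copy lost on 3p: both estimators report the full arm."""
        scen = {"default": (2, 1), "arms": {"3p": (1, 0)}}
        (allele,) = simulate_allele_specific(genome, {"s": scen})
        zm, _, _ = arm_loh_fraction(allele, genome, "3p")
        from renalmatch.harmonize import integral_to_log2
        log2_view = integral_to_log2(allele)
        frac = arm_loss_fraction(log2_view, genome, "3p")
        assert abs(zm - frac) <= 0.01


class TestCombinedCall:
    @pytest.mark.parametrize("log2_frac,zm,expected", [
        (0.95, 0.9, "lost"),
        (0.05, None, "negligible"),
        (0.1, 0.9, "lost"),        # either-method rule
        (0.79, 0.79, "negligible"),
        (0.8, None, "lost"),       # inclusive cutoff
        (None, None, "indeterminate"),
    ])
    def test_rule(self, log2_frac, zm, expected):
        assert combined_3p_call(log2_frac, zm) == expected


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        m = GeneMatrix(pd.DataFrame(
            {"a": col, "b": col, "c": rng.normal(size=30)},
            index=[f"g{i}" for i in range(30)]), "log2")
        linkage, ids = cluster_profiles(m)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_sample_average_linkage_trace(self):
        """Hand-traced agglomeration on a known 3x3 Spearman distance."""
        # construct samples with known rank correlations
        base = np.arange(10.0)
        a = base                        # rho(a,b)=1 after small monotone map
        b = base ** 2
        rng = np.random.default_rng(1)
        c = rng.permutation(base)
        m = GeneMatrix(pd.DataFrame({"a": a, "b": b, "c": c},
                                    index=[f"g{i}" for i in range(10)]), "log2")
        from scipy.stats import spearmanr
        d_ab = 1 - spearmanr(a, b).statistic
        d_ac = 1 - spearmanr(a, c).statistic
        d_bc = 1 - spearmanr(b, c).statistic
        linkage, ids = cluster_profiles(m)
        # first merge: a,b at distance 0; then c joins at mean(d_ac, d_bc)
        assert linkage[0, 2] == pytest.approx(d_ab, abs=1e-12)
        assert linkage[1, 2] == pytest.approx((d_ac + d_bc) / 2, abs=1e-12)

    def test_cut_heights(self):
        rng = np.random.default_rng(2)
        m = GeneMatrix(pd.DataFrame(rng.normal(size=(40, 6)),
                                    index=[f"g{i}" for i in range(40)],
                                    columns=list("abcdef")), "log2")
        linkage, ids = cluster_profiles(m)
        groups = pd.Series("x", index=ids)
        low = cut_and_summarize(linkage, ids, groups, 0.0)
        assert low.labels.nunique() == 6  # all distinct -> singletons
        high = cut_and_summarize(linkage, ids, groups, float(linkage[:, 2].max()))
        assert high.labels.nunique() == 1

    def test_cluster_count_vs_tree_walk_oracle(self):
        rng = np.random.default_rng(3)
        m = GeneMatrix(pd.DataFrame(rng.normal(size=(30, 12)),
                                    index=[f"g{i}" for i in range(30)],
                                    columns=[f"s{i}" for i in range(12)]), "log2")
        linkage, ids = cluster_profiles(m)
        groups = pd.Series("x", index=ids)
        for h in np.linspace(0, linkage[:, 2].max(), 15):
            res = cut_and_summarize(linkage, ids, groups, float(h))
            expected = len(ids) - int((linkage[:, 2] <= h).sum())
            assert res.labels.nunique() == expected

    def test_cluster_count_nonincreasing_in_height(self):
        rng = np.random.default_rng(4)
        m = GeneMatrix(pd.DataFrame(rng.normal(size=(25, 10)),
                                    index=[f"g{i}" for i in range(25)],
                                    columns=[f"s{i}" for i in range(10)]), "log2")
        linkage, ids = cluster_profiles(m)
        groups = pd.Series("x", index=ids)
        counts = [cut_and_summarize(linkage, ids, groups, float(h)).labels.nunique()
                  for h in np.linspace(0, linkage[:, 2].max() + 0.1, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_composition_row_sums(self, genome):
        profiles, truth = simulate_cna_cohort(genome, n_per_group=10,
                                              n_cell_lines_per_group=2, seed=6)
        m = segments_to_genes(profiles, genome)
        linkage, ids = cluster_profiles(m)
        res = cut_and_summarize(linkage, ids, truth.group_of(), 0.9)
        sizes = res.labels.value_counts().sort_index()
        assert (res.composition.sum(axis=1).sort_index() == sizes).all()


@pytest.fixture(scope="module")
def clustered(genome):
    profiles, truth = simulate_cna_cohort(genome, default_archetypes(),
                                          n_per_group=30,
                                          n_cell_lines_per_group=5, seed=13)
    m = segments_to_genes(profiles, genome)
    linkage, ids = cluster_profiles(m)
    res = cut_and_summarize(linkage, ids, truth.group_of(), 0.9)
    return res, truth


class TestSubtypeRecovery:

    def test_clusters_recover_subtypes(self, clustered):
        res, truth = clustered
        groups = truth.group_of()
        ari = adjusted_rand_score(groups[res.labels.index], res.labels)
        assert ari >= 0.9

    def test_cell_lines_called_by_majority(self, clustered):
        res, truth = clustered
        groups = truth.group_of()
        tumour_subtypes = groups[groups.index.isin(truth.tumour_ids)]
        calls = assign_cell_line_subtype(res, tumour_subtypes, truth.cell_line_ids)
        ccrcc_lines = [c for c in truth.cell_line_ids if groups[c] == "ccRCC"]
        assert all(calls[c] == "ccRCC-like" for c in ccrcc_lines)

    def test_pure_cell_line_cluster_is_outlier(self):
        linkage = np.array([[0.0, 1.0, 0.1, 2],
                            [2.0, 3.0, 0.1, 2],
                            [4.0, 5.0, 1.5, 4]])
        ids = ["cl1", "cl2", "t1", "t2"]
        groups = pd.Series({"cl1": "x", "cl2": "x", "t1": "ccRCC", "t2": "ccRCC"})
        res = cut_and_summarize(linkage, ids, groups, 0.9)
        calls = assign_cell_line_subtype(
            res, pd.Series({"t1": "ccRCC", "t2": "ccRCC"}), ["cl1", "cl2"],
            min_tumours=1)
        assert calls["cl1"] == "outlier"

    def test_majority_call(self):
        linkage = np.array([[0.0, 1.0, 0.1, 2], [2.0, 3.0, 1.5, 3]])
        ids = ["cl", "t1", "t2"]
        res = cut_and_summarize(linkage, ids, pd.Series("x", index=ids), 0.9)
        tum = pd.Series({"t1": "ccRCC"})
        calls = assign_cell_line_subtype(res, tum, ["cl"], min_tumours=1)
        assert calls["cl"] == "ccRCC-like"
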