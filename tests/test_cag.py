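"""Co-abundance groups: distances, Ward cut, profiles, dynamics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import noise_rho, planted_block_counts
from cagflow.cag import (
    CagAssignment,
    cag_abundance_profiles,
    cag_group_dynamics,
    cluster_cags,
    correlation_distance,
    invader_correlates,
    permanova_cut,
    ward_dendrogram,
)
from cagflow.sparcc import SparccResult, sparcc_estimate


def rho_frame(mat, ids=None):
    ids = ids or [f"O{i}" for i in range(len(mat))]
    return pd.DataFrame(mat, index=ids, columns=ids)


def two_block_rho(n_per=6, within=0.9, between=-0.2):
    p = 2 * n_per
    mat = np.full((p, p), between)
    mat[:n_per, :n_per] = within
    mat[n_per:, n_per:] = within
    np.fill_diagonal(mat, 1.0)
    return rho_frame(mat)


class TestCorrelationDistance:
    def test_bounds_and_monotonicity(self):
        rho = rho_frame([[1.0, 1.0, -1.0], [1.0, 1.0, 0.5], [-1.0, 0.5, 1.0]])
        D = correlation_distance(rho)
        assert D["O0", "O1"] == 0.0
        assert D["O0", "O2"] == 2.0
        assert D["O1", "O2"] == pytest.approx(0.5)


class TestWardCut:
    def test_two_perfect_blocks_give_two_cags(self):
        rho = two_block_rho()
        D = correlation_distance(rho)
        asg = permanova_cut(ward_dendrogram(D), D, seed=0)
        labels = asg.assignment
        truth = [0] * 6 + [1] * 6
        assert asg.n_cags == 2
        assert adjusted_rand_score(truth, labels.loc[list(D.ids)]) == 1.0
        # the accepted root split carries a recorded p-value below alpha
        assert min(asg.split_pvalues.values()) < 0.005

    def test_null_rho_collapses_to_one_cag(self):
        rho = noise_rho(11)
        D = correlation_distance(rho)
        asg = permanova_cut(ward_dendrogram(D), D, seed=1)
        assert asg.n_cags == 1

    def test_two_otus_form_single_merge_one_cag(self):
        rho = rho_frame([[1.0, 0.3], [0.3, 1.0]])
        D = correlation_distance(rho)
        Z = ward_dendrogram(D)
        assert Z.shape == (1, 4)
        asg = permanova_cut(Z, D, seed=0)
        assert asg.n_cags == 1

    def test_single_otu_is_one_cag(self):
        res = SparccResult(
            rho=rho_frame([[1.0]], ids=["solo"]),
            omega=pd.Series([1.0], index=["solo"]),
        )
        asg = cluster_cags(res, seed=0)
        assert asg.n_cags == 1
        assert asg.assignment["solo"] == "CAG01"

    def test_partition_is_disjoint_and_exhaustive(self):
        counts = planted_block_counts(3)
        res = sparcc_estimate(counts, seed=3)
        asg = cluster_cags(res, seed=3)
        assert set(asg.assignment.index) == set(res.rho.index)
        assert asg.assignment.notna().all()

    def test_more_permissive_alpha_never_merges_cags(self):
        counts = planted_block_counts(4)
        res = sparcc_estimate(counts, seed=4)
        D = correlation_distance(res.rho)
        Z = ward_dendrogram(D)
        n_strict = permanova_cut(Z, D, alpha=0.005, seed=5).n_cags
        n_loose = permanova_cut(Z, D, alpha=0.05, seed=5).n_cags
        assert n_loose >= n_strict

    def test_newick_export_contains_every_otu(self):
        rho = two_block_rho(n_per=3)
        D = correlation_distance(rho)
        asg = permanova_cut(ward_dendrogram(D), D, seed=0)
        nwk = asg.to_newick()
        assert all(otu in nwk for otu in D.ids)


class TestProfilesAndDynamics:
    @pytest.fixture()
    def profile_inputs(self):
        rel = pd.DataFrame(
            [[0.5, 0.3, 0.2], [0.1, 0.6, 0.3]],
            index=["s1", "s2"],
            columns=["O1", "O2", "O3"],
        )
        assignment = pd.Series(
            {"O1": "CAG01", "O2": "CAG01", "O3": "CAG02"}, name="cag"
        )
        return rel, assignment

    def test_profiles_match_hand_arithmetic(self, profile_inputs):
        rel, assignment = profile_inputs
        prof = cag_abundance_profiles(rel, assignment)
        assert prof.loc["s1", "CAG01"] == pytest.approx(0.8)
        assert prof.loc["s1", "CAG02"] == pytest.approx(0.2)
        assert prof.loc["s2", "CAG01"] == pytest.approx(0.7)

    def test_cag_totals_conserve_member_abundance(self, profile_inputs):
        rel, assignment = profile_inputs
        prof = cag_abundance_profiles(rel, assignment)
        np.testing.assert_allclose(
            prof.sum(axis=1), rel[assignment.index].sum(axis=1), atol=1e-9
        )

    def test_missing_otu_rejected(self, profile_inputs):
        rel, assignment = profile_inputs
        assignment = pd.concat([assignment, pd.Series({"O9": "CAG03"})])
        with pytest.raises(ValueError, match="not in the table"):
            cag_abundance_profiles(rel, assignment)

    def make_dynamics_inputs(self, shift=0.0, seed=0, n=12):
        rng = np.random.default_rng(seed)
        groups = ["DSS"] * n + ["T"] * n
        days = [0] * (2 * n)
        vals = rng.normal(0.3, 0.05, size=2 * n)
        vals[n:] += shift
        profile = pd.DataFrame(
            {"CAG01": vals}, index=[f"s{i}" for i in range(2 * n)]
        )
        meta = pd.DataFrame(
            {"group": groups, "day": days, "subject": profile.index},
            index=profile.index,
        )
        return profile, meta

    def test_planted_shift_reaches_fdr_significance(self):
        profile, meta = self.make_dynamics_inputs(shift=0.3, seed=1)
        out = cag_group_dynamics(profile, meta)
        assert (out["adjusted_p"] < 0.05).all()
        assert out["stars"].iloc[0] != ""

    def test_single_group_errors(self):
        profile, meta = self.make_dynamics_inputs()
        meta["group"] = "DSS"
        with pytest.raises(ValueError):
            cag_group_dynamics(profile, meta)

    def test_adjusted_never_below_raw(self, default_cohort):
        table, _ = default_cohort
        rel = table.relative_abundances()
        assignment = pd.Series(
            {o: f"CAG{(i % 3) + 1:02d}" for i, o in enumerate(rel.columns[:30])},
            name="cag",
        )
        prof = cag_abundance_profiles(rel, assignment)
        out = cag_group_dynamics(prof, table.metadata)
        assert (out["adjusted_p"] >= out["raw_p"] - 1e-12).all()


class TestInvaderCorrelates:
    def test_threshold_rule_and_empty_cases(self):
        ids = ["INV", "A", "B", "C"]
        rho = rho_frame(
            [
                [1.0, 0.7, -0.6, 0.2],
                [0.7, 1.0, 0.0, 0.0],
                [-0.6, 0.0, 1.0, 0.0],
                [0.2, 0.0, 0.0, 1.0],
            ],
            ids=ids,
        )
        res = SparccResult(rho=rho, omega=pd.Series(np.ones(4), index=ids))
        pos, neg = invader_correlates(res, "INV")
        assert pos == {"A"} and neg == {"B"}
        pos1, neg1 = invader_correlates(res, "INV", threshold=1.0)
        assert pos1 == set() and neg1 == set()  # clipped rho never exceeds 1
        with pytest.raises(ValueError):
            invader_correlates(res, "missing")

    def test_planted_correlates_recovered_within_invader_group(
        self, default_cohort
    ):
        table, truth = default_cohort
        inv_ids = table.metadata.index[table.metadata["group"] == "DSS+BPB5"]
        sub = table.select_samples(inv_ids)
        res = sparcc_estimate(sub.counts, seed=0)
        pos, neg = invader_correlates(res, truth.invader_otu)
        assert truth.invader_correlates <= pos
        assert not (truth.invader_correlates & neg)
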