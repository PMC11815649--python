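"""Razor assignment, normalization, roll-up, clustering and fold changes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmtproc import simgen, timecourse as tc


class TestRazorAssignment:
    def test_shared_peptide_goes_to_protein_with_most_unique(self):
        candidates = {
            "pepA": ["P1"], "pepB": ["P1"], "pepC": ["P1"],
            "pepD": ["P2"],
            "shared": ["P1", "P2"],
        }
        assignment = tc.assign_peptides_to_proteins(candidates)
        assert assignment["shared"] == "P1"

    def test_unique_peptide_assigned_directly(self):
        assert tc.assign_peptides_to_proteins({"pep": ["P3"]})["pep"] == "P3"

    def test_tie_breaks_lexicographically(self):
        candidates = {"a1": ["PB"], "a2": ["PB"], "b1": ["PA"], "b2": ["PA"],
                      "shared": ["PB", "PA"]}
        assert tc.assign_peptides_to_proteins(candidates)["shared"] == "PA"

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            tc.assign_peptides_to_proteins({"pep": []})


def _qm(values, proteins=None, anchors=None):
    df = pd.DataFrame(values, columns=[f"s{i+1}" for i in range(np.shape(values)[1])])
    df.index = [f"pep{i}" for i in range(len(df))]
    meta = pd.DataFrame(index=df.index)
    meta["protein"] = proteins if proteins is not None else df.index
    meta["is_anchor"] = anchors if anchors is not None else False
    return tc.QuantMatrix(df, meta)


class TestAnchorNormalization:
    def test_constant_anchor_is_fixed_point(self):
        qm = _qm([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], anchors=[True, False])
        out = tc.normalize_to_anchor(qm)
        assert np.allclose(out.values, qm.values, atol=1e-12)

    def test_column_sums_equalized_and_mean_preserved(self):
        qm = _qm([[100.0, 200.0]], anchors=[True])
        out = tc.normalize_to_anchor(qm)
        assert out.values.to_numpy()[0] == pytest.approx([150.0, 150.0])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        qm = _qm(rng.uniform(1, 10, (6, 4)), anchors=[True, True] + [False] * 4)
        once = tc.normalize_to_anchor(qm)
        twice = tc.normalize_to_anchor(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_zero_anchor_column_rejected(self):
        qm = _qm([[1.0, 0.0], [2.0, 3.0]], anchors=[True, False])
        with pytest.raises(ValueError, match="zero anchor"):
            tc.normalize_to_anchor(qm)

    def test_no_anchors_rejected(self):
        qm = _qm([[1.0, 2.0]])
        with pytest.raises(ValueError, match="anchor"):
            tc.normalize_to_anchor(qm)

    def test_acquisition_drift_removed(self):
        """Per-stage efficiency drift cancels exactly after normalization."""
        qm, _ = simgen.simulate_timecourse(n_proteins=40, noise_sd=0.05, seed=6)
        drift = np.linspace(0.6, 1.7, len(qm.stages))
        drifted = tc.QuantMatrix(qm.values * drift, qm.meta)
        a = tc.normalize_to_anchor(qm).values.to_numpy()
        b = tc.normalize_to_anchor(drifted).values.to_numpy()
        # drift is removed up to one global scale factor
        ratio = b / a
        assert np.allclose(ratio, ratio.mean(), rtol=1e-10)


class TestRollup:
    def test_single_peptide_protein_keeps_profile(self):
        qm = _qm([[1.0, 2.0, 3.0]], proteins=["P1"])
        out = tc.rollup_proteins(qm)
        assert out.values.loc["P1"].to_numpy() == pytest.approx([1.0, 2.0, 3.0])

    def test_identical_peptides_keep_shape(self):
        profile = np.array([2.0, 4.0, 6.0])
        qm = _qm([profile, profile, profile], proteins=["P"] * 3)
        out = tc.rollup_proteins(qm)
        shape = out.values.loc["P"].to_numpy()
        assert shape / shape.sum() == pytest.approx(profile / profile.sum())

    def test_median_suppresses_outlier_profile(self):
        base = np.array([1.0, 1.0, 1.0, 1.0])
        outlier = np.array([4.0, 0.1, 0.1, 0.1])
        qm = _qm([base, base * 2, outlier], proteins=["P"] * 3)
        out = tc.rollup_proteins(qm)
        shape = out.values.loc["P"].to_numpy()
        # brute-force oracle: median of mean-scaled profiles
        scaled = np.array([p / p.mean() for p in (base, base * 2, outlier)])
        oracle = np.median(scaled, axis=0)
        assert shape / shape.sum() == pytest.approx(oracle / oracle.sum())

    def test_peptide_order_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 5, (8, 5))
        proteins = ["P1"] * 4 + ["P2"] * 4
        qm = _qm(values, proteins=proteins)
        perm = rng.permutation(8)
        qm_shuffled = tc.QuantMatrix(qm.values.iloc[perm], qm.meta.iloc[perm])
        a = tc.rollup_proteins(qm).values
        b = tc.rollup_proteins(qm_shuffled).values
        assert np.allclose(a, b.loc[a.index])

    def test_unquantified_protein_dropped(self):
        qm = _qm([[0.0, 0.0], [1.0, 2.0]], proteins=["P0", "P1"])
        out = tc.rollup_proteins(qm)
        assert list(out.values.index) == ["P1"]


class TestClustering:
    def test_k1_single_cluster(self):
        labels, centroids = tc.hkmeans_cluster(np.random.default_rng(0).uniform(1, 2, (5, 3)), 1)
        assert (labels == 0).all() and centroids.shape == (1, 3)

    def test_every_row_labeled_with_k_clusters(self):
        rng = np.random.default_rng(1)
        labels, centroids = tc.hkmeans_cluster(rng.uniform(1, 2, (30, 4)), 5)
        assert len(labels) == 30 and centroids.shape == (5, 4)
        assert set(labels) == set(range(5))

    def test_separated_archetypes_recovered_exactly(self):
        qm, truth = simgen.simulate_timecourse(
            n_proteins=90, cluster_archetypes=("constant", "increasing", "decreasing"),
            anchor_fraction=0.0, noise_sd=0.02, seed=5)
        proteins = tc.rollup_proteins(qm)
        labels, _ = tc.hkmeans_cluster(proteins.values.to_numpy(), k=3)
        ari = adjusted_rand_score(truth.loc[proteins.values.index, "archetype"], labels)
        assert ari == 1.0

    def test_row_order_invariance_up_to_relabeling(self):
        qm, _ = simgen.simulate_timecourse(n_proteins=60, noise_sd=0.05, seed=7)
        x = tc.rollup_proteins(qm).values.to_numpy()
        labels_a, _ = tc.hkmeans_cluster(x, 4)
        perm = np.random.default_rng(3).permutation(len(x))
        labels_b, _ = tc.hkmeans_cluster(x[perm], 4)
        assert adjusted_rand_score(labels_a[perm], labels_b) == 1.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            tc.hkmeans_cluster(np.ones((3, 2)), 4)

    def test_two_pass_schedule_isolates_and_reclusters(self):
        qm, truth = simgen.simulate_timecourse(n_proteins=80, anchor_fraction=0.0,
                                               noise_sd=0.02, seed=9)
        x = tc.rollup_proteins(qm).values.to_numpy()
        labels = tc.two_pass_cluster(x, k_first=4, k_second=3)
        assert set(labels) <= set(range(4))
        assert (labels == 0).any()


class TestFoldChanges:
    def test_fourfold_decrease_counted(self):
        summary = tc.fold_change_summary(np.array([[4.0, 2.0, 1.0]]))
        assert summary.log2_first_last[0] == pytest.approx(2.0)
        assert summary.fraction_decreasing == 1.0

    def test_constant_profile_has_zero_ratio(self):
        summary = tc.fold_change_summary(np.array([[3.0, 5.0, 3.0]]))
        assert summary.log2_first_last[0] == 0.0
        assert summary.fraction_within == 1.0

    def test_fractions_partition(self):
        rng = np.random.default_rng(4)
        summary = tc.fold_change_summary(rng.lognormal(0, 1.5, (200, 5)))
        total = (summary.fraction_decreasing + summary.fraction_increasing
                 + summary.fraction_within)
        assert total == pytest.approx(1.0)

    def test_zero_values_floored(self):
        summary = tc.fold_change_summary(np.array([[0.0, 1.0, 4.0], [4.0, 1.0, 2.0]]))
        assert summary.n_floored == 1
        assert np.isfinite(summary.log2_first_last).all()

    def test_known_decreasing_fraction_recovered(self):
        """A planted 7% decreasing class is recovered within binomial error."""
        rng = np.random.default_rng(11)
        n = 1000
        rows = []
        for i in range(n):
            if i < 70:
                profile = np.array([4.0, 2.0, 1.0])
            else:
                profile = np.array([1.0, 1.0, 1.0])
            rows.append(profile * rng.lognormal(0, 0.1, 3))
        summary = tc.fold_change_summary(np.array(rows))
        assert abs(summary.fraction_decreasing - 0.07) < 3 * np.sqrt(0.07 * 0.93 / n)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            tc.fold_change_summary(np.ones((2, 2)), threshold_fold=1.0)


class TestOrthogroups:
    def _table(self):
        return pd.DataFrame([
            ("OG1", "fly", "FP1"), ("OG1", "fly", "FP2"), ("OG1", "frog", "XP1"),
            ("OG2", "fly", "FP3"), ("OG2", "squirt", "CP1"), ("OG2", "frog", "XP9"),
            ("OG3", "squirt", "CP2"),
        ], columns=["orthogroup_id", "organism", "protein_id"])

    def test_most_quantified_peptides_wins(self):
        counts = {"FP1": 5, "FP2": 2, "XP1": 1, "FP3": 3, "CP1": 4, "CP2": 1, "XP9": 2}
        reps = tc.orthogroup_representatives(self._table(), counts)
        assert reps[("OG1", "fly")] == "FP1"

    def test_singleton_orthogroup(self):
        reps = tc.orthogroup_representatives(self._table(), {"CP2": 1})
        assert reps[("OG3", "squirt")] == "CP2"

    def test_unquantified_proteins_ignored(self):
        reps = tc.orthogroup_representatives(self._table(), {"FP2": 2})
        assert reps[("OG1", "fly")] == "FP2"
        assert ("OG1", "frog") not in reps

    def test_tie_breaks_lexicographically(self):
        reps = tc.orthogroup_representatives(self._table(), {"FP1": 2, "FP2": 2})
        assert reps[("OG1", "fly")] == "FP1"

    def test_cross_organism_overlap_matches_set_oracle(self):
        rng = np.random.default_rng(13)
        organisms = ["fly", "squirt", "frog"]
        rows, counts = [], {}
        for og in range(40):
            for org in organisms:
                for j in range(rng.integers(0, 3)):
                    pid = f"{org}_{og}_{j}"
                    rows.append((f"OG{og}", org, pid))
                    if rng.random() < 0.7:
                        counts[pid] = int(rng.integers(1, 9))
        table = pd.DataFrame(rows, columns=["orthogroup_id", "organism", "protein_id"])
        reps = tc.orthogroup_representatives(table, counts)
        # brute-force set-intersection oracle for "detected in all organisms"
        detected = {org: {og for (og, o) in reps if o == org} for org in organisms}
        oracle = set.intersection(*detected.values())
        mine = {og for og in table.orthogroup_id.unique()
                if all((og, org) in reps for org in organisms)}
        assert mine == oracle

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="organism"):
            tc.orthogroup_representatives(pd.DataFrame({"orthogroup_id": []}), {})
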