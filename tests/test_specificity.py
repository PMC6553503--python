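import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ricetf.io import aggregate_by_group
from ricetf.specificity import (
    SpecificityConfig,
    TissueSpecificityClassifier,
    assign_labels,
    classify_by_tau,
    kmeans_refine,
    sprent_outliers,
    tau,
)
from ricetf.synthetic import GeneratorSpec, make_expression_matrix

profiles = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=12
).filter(lambda xs: max(xs) > 0)


class TestTau:
    def test_uniform_profile_scores_zero(self):
        assert tau([5, 5, 5, 5]) == 0.0

    def test_one_hot_profile_scores_one(self):
        assert tau([9, 0, 0]) == 1.0

    def test_hand_evaluated_case(self):
        # sum(1 - x/4) = 0 + 4 * 0.75 = 3.0; 3.0 / (5 - 1) = 0.75
        assert tau([4, 1, 1, 1, 1]) == pytest.approx(0.75)

    def test_rejects_all_zero_and_negative(self):
        with pytest.raises(ValueError):
            tau([0, 0, 0])
        with pytest.raises(ValueError):
            tau([1, -1, 2])

    @settings(deadline=None, max_examples=100)
    @given(profiles, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, xs, c):
        assert tau(np.array(xs) * c) == pytest.approx(tau(xs), abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(profiles, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, xs, rnd):
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        assert tau(shuffled) == pytest.approx(tau(xs), abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(profiles, st.floats(min_value=0.0, max_value=1e3))
    def test_concentrating_mass_never_decreases_tau(self, xs, delta):
        x = np.array(xs, dtype=float)
        bumped = x.copy()
        bumped[np.argmax(x)] += delta
        assert tau(bumped) >= tau(x) - 1e-12

    def test_bounds(self):
        for xs in ([1, 2, 3], [0.1, 9.0], [7, 7, 1]):
            assert 0.0 <= tau(xs) <= 1.0


class TestScreening:
    def test_threshold_classes(self):
        table = classify_by_tau(pd.Series({"a": 0.10, "b": 0.80, "c": 0.40}))
        assert table.loc["a", "tau_class"] == "ubiquitous"
        assert table.loc["b", "tau_class"] == "candidate"
        assert table.loc["c", "tau_class"] == "unclassified"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SpecificityConfig(ubiquitous_cutoff=0.7, preferential_cutoff=0.6)


class TestKmeansRefine:
    def test_recovers_two_planted_blocks(self):
        rng = np.random.default_rng(0)
        groups = ["root", "seed", "leaf"]
        rows, idx = [], []
        for i in range(20):
            base = rng.normal(2, 0.2, 3)
            hot = 0 if i < 10 else 1
            base[hot] += 8.0
            rows.append(base)
            idx.append(f"g{i:02d}")
        prof = pd.DataFrame(rows, index=idx, columns=groups)
        cfg = SpecificityConfig(kmeans_k=2)
        assignment, labels = kmeans_refine(prof, cfg)
        assert set(labels.values()) == {"root", "seed"}
        root_cluster = {c for c, g in labels.items() if g == "root"}.pop()
        assert all(assignment[f"g{i:02d}"] == root_cluster for i in range(10))
        assert not any(assignment[f"g{i:02d}"] == root_cluster for i in range(10, 20))

    def test_identical_profiles_single_cluster(self):
        prof = pd.DataFrame([[1.0, 2.0]] * 5, index=list("abcde"), columns=["x", "y"])
        assignment, _ = kmeans_refine(prof, SpecificityConfig(kmeans_k=1))
        assert set(assignment.values()) == {0}

    def test_two_distinct_profiles_two_clusters(self):
        prof = pd.DataFrame(
            [[8.0, 1.0], [1.0, 8.0]], index=["a", "b"], columns=["x", "y"]
        )
        assignment, labels = kmeans_refine(prof, SpecificityConfig(kmeans_k=2))
        assert assignment["a"] != assignment["b"]
        assert labels[assignment["a"]] == "x"
        assert labels[assignment["b"]] == "y"

    def test_k_larger_than_candidates_is_error(self):
        prof = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError):
            kmeans_refine(prof, SpecificityConfig(kmeans_k=3))

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("wxyz"),
        )
        cfg = SpecificityConfig(kmeans_k=3, kmeans_seed=7)
        a1, l1 = kmeans_refine(prof, cfg)
        a2, l2 = kmeans_refine(prof, cfg)
        assert a1 == a2 and l1 == l2


class TestSprent:
    def make_scatter(self):
        rng = np.random.default_rng(4)
        x = rng.normal(6, 2, 200)
        y = x + rng.normal(0, 0.3, 200)
        x = np.append(x, 6.0 + 10.0)  # displaced toward tissue A
        y = np.append(y, 6.0)
        return x, y

    def test_displaced_gene_flagged_toward_A(self):
        x, y = self.make_scatter()
        flags = sprent_outliers(x, y, alpha=0.05)
        assert flags[-1] == "toward_A"

    def test_role_swap_exchanges_directions(self):
        x, y = self.make_scatter()
        f_xy = sprent_outliers(x, y)
        f_yx = sprent_outliers(y, x)
        swap = {"toward_A": "toward_B", "toward_B": "toward_A", "none": "none"}
        assert [swap[f] for f in f_xy] == list(f_yx)

    def test_gene_on_axis_not_flagged(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(5, 2, 50), [5.0]])
        y = np.concatenate([x[:50] + rng.normal(0, 0.5, 50), [5.0 + 0.0]])
        # last gene sits essentially on the fitted axis through the centroid
        flags = sprent_outliers(x, y)
        assert flags[-1] == "none"

    def test_zero_residual_variance_is_error(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(ValueError):
            sprent_outliers(x, 2 * x)


class TestAssignLabels:
    def table(self):
        return pd.DataFrame(
            {
                "tau": [0.1, 0.8, 0.4, 0.5],
                "tau_class": ["ubiquitous", "candidate", "unclassified", "unclassified"],
            },
            index=["u1", "p1", "s1", "n1"],
        )

    def test_precedence_and_provenance(self):
        calls = assign_labels(
            self.table(),
            kmeans_assignment={"p1": 0},
            cluster_labels={0: "root"},
            sprent_flags={"u1": "seed", "s1": "seed"},
        )
        by_id = {c.locus_id: c for c in calls}
        assert by_id["u1"].label == "ubiquitous"  # tau outranks sprent
        assert by_id["p1"].label == "preferential:root"
        assert by_id["p1"].method == "kmeans_refined"
        assert by_id["s1"].label == "preferential:seed"
        assert by_id["s1"].method == "sprent"
        assert by_id["n1"].label == "unclassified"

    def test_duplicate_loci_rejected(self):
        t = self.table()
        dup = pd.concat([t, t.iloc[[0]]])
        with pytest.raises(ValueError):
            assign_labels(dup)


class TestClassifierEstimator:
    def test_planted_recovery_on_synthetic_matrix(self):
        spec = GeneratorSpec(n_genes=500, seed=42)
        matrix, truth = make_expression_matrix(spec)
        profiles = aggregate_by_group(matrix).values
        est = TissueSpecificityClassifier(n_clusters=5).fit(profiles)
        planted = truth[truth["class"] == "tissue_specific"]
        hits = sum(
            est.labels_[r.locus_id] == f"preferential:{r.group}"
            for r in planted.itertuples()
        )
        assert hits / len(planted) >= 0.95
        background = truth_background = set(matrix.row_ids) - set(truth["locus_id"])
        false_pref = sum(
            str(est.labels_[g]).startswith("preferential") for g in background
        )
        assert false_pref / len(background) <= 0.05

    def test_ubiquitous_planted_genes_called_ubiquitous(self):
        matrix, truth = make_expression_matrix(GeneratorSpec(n_genes=300, seed=9))
        profiles = aggregate_by_group(matrix).values
        est = TissueSpecificityClassifier().fit(profiles)
        ubi = truth[truth["class"] == "ubiquitous"]["locus_id"]
        frac = np.mean([est.labels_[g] == "ubiquitous" for g in ubi])
        assert frac >= 0.95

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = TissueSpecificityClassifier(n_clusters=3, random_state=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
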