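"""Second-moment decomposition, crossnobis dissimilarity, and decoding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chordlearn import rsa
from chordlearn import synthetic as syn
from chordlearn.patterns import TrialBetas

ALPHA0 = dict(H0=0, HR=0, HCT=0, HCU=0, HST=0, HSU=0, HT=0, HU=0)


def betas_from(patterns, meta=None):
    patterns = np.asarray(patterns, dtype=float)
    if meta is None:
        meta = syn.make_pattern_metadata(1, 1, 1, 1)[: len(patterns)]
    return TrialBetas(patterns, meta)


class TestSecondMoment:
    def test_two_identical_patterns(self):
        meta = pd.DataFrame(
            {"run": [0, 0], "seq_type": ["a", "b"], "trained": [True, True]}
        )
        G = rsa.compute_G(betas_from([[1, 1], [1, 1]], meta)).G
        assert np.allclose(G, [[1, 1], [1, 1]])

    def test_orthogonal_patterns_have_zero_off_diagonal(self):
        meta = pd.DataFrame(
            {"run": [0, 0], "seq_type": ["a", "b"], "trained": [True, True]}
        )
        G = rsa.compute_G(betas_from([[1, 0], [0, 1]], meta)).G
        assert G[0, 1] == 0 and G[1, 0] == 0

    def test_matches_naive_double_loop(self, rng):
        X = rng.standard_normal((7, 30))
        meta = pd.DataFrame(
            {"run": 0, "seq_type": "a", "trained": True}, index=range(7)
        )
        G = rsa.compute_G(betas_from(X, meta)).G
        for i, j in itertools.product(range(7), repeat=2):
            assert G[i, j] == pytest.approx(X[i] @ X[j] / 30, abs=1e-10)


class TestComponentBasis:
    def test_run_component_is_block_diagonal(self):
        meta = pd.DataFrame(
            {
                "run": [0, 0, 1, 1],
                "seq_type": ["a", "b", "a", "b"],
                "trained": True,
            }
        )
        HR = rsa.build_component_basis(meta).matrices["HR"]
        assert np.allclose(
            HR, [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]]
        )

    def test_all_trained_empties_untrained_components(self):
        meta = syn.make_pattern_metadata(2, 2, 0, 2)
        b = rsa.build_component_basis(meta)
        for k in ("HCU", "HSU", "HU"):
            assert not b.matrices[k].any()

    def test_entrywise_brute_force_oracle(self, rng):
        meta = pd.DataFrame(
            {
                "run": rng.integers(0, 3, 12),
                "seq_type": rng.choice(["a", "b", "c", "d"], 12),
                "trained": rng.random(12) < 0.5,
            }
        )
        b = rsa.build_component_basis(meta)
        for i, j in itertools.product(range(12), repeat=2):
            ri, rj = meta.loc[i], meta.loc[j]
            expect = {
                "H0": 1,
                "HR": ri.run == rj.run,
                "HCT": ri.trained and rj.trained,
                "HCU": not ri.trained and not rj.trained,
                "HST": ri.trained
                and rj.trained
                and ri.seq_type == rj.seq_type,
                "HSU": not ri.trained
                and not rj.trained
                and ri.seq_type == rj.seq_type,
                "HT": i == j and ri.trained,
                "HU": i == j and not ri.trained,
            }
            for k, v in expect.items():
                assert b.matrices[k][i, j] == float(v), (k, i, j)

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError, match="required column"):
            rsa.build_component_basis(pd.DataFrame({"run": [0]}))


def nnls_by_active_set_enumeration(A, y):
    """Constrained least squares by enumerating all sign patterns of the
    8-dimensional problem: independent oracle for scipy's NNLS."""
    p = A.shape[1]
    best, best_obj = None, np.inf
    for active in itertools.product([0, 1], repeat=p):
        idx = [i for i in range(p) if active[i]]
        x = np.zeros(p)
        if idx:
            sol, *_ = np.linalg.lstsq(A[:, idx], y, rcond=None)
            if np.any(sol < -1e-12):
                continue
            x[idx] = sol
        obj = np.sum((A @ x - y) ** 2)
        if obj < best_obj - 1e-12:
            best_obj, best = obj, x
    return best, np.sqrt(best_obj)


class TestComponentEstimation:
    TRUTH = dict(
        H0=1.0, HR=0.5, HCT=0.3, HCU=0.2, HST=0.4, HSU=0.1, HT=0.6, HU=0.7
    )

    def test_exact_recovery_of_constructed_G(self):
        meta = syn.make_pattern_metadata(2, 2, 2, 3)
        basis = rsa.build_component_basis(meta)
        G = sum(
            self.TRUTH[k] * basis.matrices[k] for k in rsa.COMPONENT_NAMES
        )
        got = rsa.estimate_components(
            rsa.SecondMomentMatrix(G, 100, meta), basis
        )
        for k in rsa.COMPONENT_NAMES:
            assert got.alpha[k] == pytest.approx(self.TRUTH[k], abs=1e-8)
        assert got.residual_norm < 1e-8

    def test_pure_intercept(self):
        meta = syn.make_pattern_metadata(2, 2, 2, 2)
        basis = rsa.build_component_basis(meta)
        got = rsa.estimate_components(
            rsa.SecondMomentMatrix(np.ones((len(meta),) * 2), 10, meta),
            basis,
        )
        assert got.alpha["H0"] == pytest.approx(1.0, abs=1e-10)
        assert sum(got.alpha.values()) == pytest.approx(1.0, abs=1e-8)

    def test_negative_truth_clamped_at_zero(self):
        meta = syn.make_pattern_metadata(2, 2, 2, 3)
        basis = rsa.build_component_basis(meta)
        truth = self.TRUTH | dict(HCT=-0.4)
        G = sum(truth[k] * basis.matrices[k] for k in rsa.COMPONENT_NAMES)
        got = rsa.estimate_components(
            rsa.SecondMomentMatrix(G, 100, meta), basis
        )
        assert got.alpha["HCT"] == 0.0
        assert got.residual_norm > 0
        oracle, oracle_norm = nnls_by_active_set_enumeration(
            basis.stacked(), G.ravel()
        )
        assert got.as_array() == pytest.approx(oracle, abs=1e-8)
        assert got.residual_norm == pytest.approx(oracle_norm, abs=1e-8)

    def test_degenerate_design_warns(self):
        meta = syn.make_pattern_metadata(1, 1, 1, 2)  # one run, one type/class
        basis = rsa.build_component_basis(meta)
        G = rsa.SecondMomentMatrix(np.eye(len(meta)), 10, meta)
        with pytest.warns(UserWarning, match="not uniquely identified"):
            rsa.estimate_components(G, basis)


class TestVariabilityIndex:
    @pytest.mark.parametrize("a,expected", [(1.0, 0.0), (np.e, 1.0)])
    def test_log_of_diagonal_coefficient(self, a, expected):
        coef = rsa.ComponentCoefficients(
            alpha={k: a for k in rsa.COMPONENT_NAMES}, residual_norm=0.0
        )
        s = rsa.variability_index(coef)
        assert s["trained"].value == pytest.approx(expected)
        assert s["untrained"].value == pytest.approx(expected)
        assert s["trained"].defined

    def test_clamped_coefficient_flagged_undefined(self):
        coef = rsa.ComponentCoefficients(
            alpha={k: 0.0 for k in rsa.COMPONENT_NAMES}, residual_norm=0.0
        )
        s = rsa.variability_index(coef)
        assert not s["trained"].defined
        assert np.isnan(s["trained"].value)


class TestRunAverages:
    def test_identical_trials_average_to_themselves(self):
        meta = syn.make_pattern_metadata(2, 1, 0, 2)
        tb = betas_from(np.ones((4, 3)), meta)
        means = rsa.run_average_betas(tb)
        assert np.allclose(means.loc[("T0", 0), "pattern"], 1.0)

    def test_mean_of_two_trials(self):
        meta = syn.make_pattern_metadata(1, 1, 0, 2)
        tb = betas_from([[0, 2], [2, 0]], meta)
        means = rsa.run_average_betas(tb)
        assert np.allclose(means.loc[("T0", 0), "pattern"], [1, 1])

    def test_matches_groupby_average(self, rng):
        meta = syn.make_pattern_metadata(3, 2, 2, 4)
        X = rng.standard_normal((len(meta), 6))
        means = rsa.run_average_betas(betas_from(X, meta))
        for (t, r), row in means.iterrows():
            mask = (meta["seq_type"] == t) & (meta["run"] == r)
            assert np.allclose(row["pattern"], X[mask.to_numpy()].mean(0))

    def test_type_absent_from_run_raises(self):
        meta = pd.DataFrame(
            {
                "run": [0, 0, 1],
                "seq_type": ["a", "b", "a"],
                "trained": True,
            }
        )
        with pytest.raises(ValueError, match="absent"):
            rsa.run_average_betas(betas_from(np.zeros((3, 2)), meta))


class TestCrossnobis:
    def _means(self, per_run_patterns):
        rows = [
            {"seq_type": t, "run": r, "pattern": np.asarray(p, float)}
            for (t, r), p in per_run_patterns.items()
        ]
        return pd.DataFrame(rows).set_index(["seq_type", "run"])

    def test_identical_types_give_exact_zero(self):
        m = self._means(
            {("a", r): [1.0, 2.0] for r in range(3)}
            | {("b", r): [1.0, 2.0] for r in range(3)}
        )
        assert rsa.crossnobis(m, "a", "b", 2).value == 0.0

    def test_noiseless_distance_is_squared_norm_per_voxel(self):
        m = self._means(
            {("a", r): [1.0, 0.0] for r in range(3)}
            | {("b", r): [0.0, 1.0] for r in range(3)}
        )
        assert rsa.crossnobis(m, "a", "b", 2).value == pytest.approx(1.0)

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_symmetry_exact(self, seed):
        rng = np.random.default_rng(seed)
        m = self._means(
            {
                (t, r): rng.standard_normal(5)
                for t in "ab"
                for r in range(4)
            }
        )
        ab = rsa.crossnobis(m, "a", "b", 5).value
        ba = rsa.crossnobis(m, "b", "a", 5).value
        assert ab == ba

    def test_two_run_value_matches_G_block_contrast(self, rng):
        """For 2 runs, crossnobis equals the corresponding contrast of the
        second-moment matrix of run-mean patterns."""
        pats = {
            (t, r): rng.standard_normal(20) for t in "ab" for r in range(2)
        }
        m = self._means(pats)
        cn = rsa.crossnobis(m, "a", "b", 20).value
        order = [("a", 0), ("b", 0), ("a", 1), ("b", 1)]
        V = np.stack([pats[k] for k in order])
        G = V @ V.T / 20
        # <a0-b0, a1-b1> / P = G[0,2] - G[0,3] - G[1,2] + G[1,3]
        expected = G[0, 2] - G[0, 3] - G[1, 2] + G[1, 3]
        assert cn == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_runs_raises(self):
        m = self._means({("a", 0): [1.0], ("b", 0): [0.0]})
        with pytest.raises(ValueError, match="at least 2 runs"):
            rsa.crossnobis(m, "a", "b", 1)

    def test_category_assignment(self):
        m = self._means(
            {(t, r): [float(t == "a")] for t in "ab" for r in range(2)}
        )
        res = rsa.crossnobis(m, "a", "b", 1, trained_types=frozenset("a"))
        assert res.category == "trained-untrained"


class TestDecoding:
    def test_perfectly_separable_classes(self):
        meta = syn.make_pattern_metadata(4, 1, 1, 4)
        X = np.where(
            meta["seq_type"].to_numpy()[:, None] == "T0", 1.0, -1.0
        ) * np.ones((len(meta), 10))
        acc = rsa.pairwise_decode(betas_from(X, meta), "T0", "U0")
        assert acc == 1.0

    def test_accuracy_monotone_in_signal(self):
        meta = syn.make_pattern_metadata(4, 1, 1, 6)
        accs = []
        for amp in (0.0, 0.5, 1.0, 2.0):
            vals = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                signal = rng.standard_normal(40)
                X = rng.standard_normal((len(meta), 40))
                X[meta["seq_type"] == "T0"] += amp * signal
                vals.append(
                    rsa.pairwise_decode(betas_from(X, meta), "T0", "U0")
                )
            accs.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]

    def test_class_absent_from_fold_raises(self):
        meta = pd.DataFrame(
            {
                "run": [0, 0, 1, 1, 2, 2],
                "seq_type": ["a", "b", "a", "b", "a", "a"],
                "trained": True,
            }
        )
        with pytest.raises(ValueError, match="absent"):
            rsa.pairwise_decode(
                betas_from(np.random.default_rng(0).standard_normal((6, 4)), meta),
                "a",
                "b",
            )


class TestAggregationAndFilter:
    def test_single_pair_per_category(self):
        res = [
            rsa.CrossnobisResult("a", "b", 0.2, "trained-trained", 5),
            rsa.CrossnobisResult("c", "d", -0.1, "untrained-untrained", 5),
        ]
        out = rsa.aggregate_pair_categories(res)
        assert out["trained-trained"] == pytest.approx(0.2)
        assert out["untrained-untrained"] == pytest.approx(-0.1)

    def test_two_pairs_average(self):
        res = [
            rsa.CrossnobisResult("a", "b", 0.2, "trained-trained", 5),
            rsa.CrossnobisResult("a", "c", 0.4, "trained-trained", 5),
        ]
        assert rsa.aggregate_pair_categories(res)[
            "trained-trained"
        ] == pytest.approx(0.3)

    def test_eligible_run_filter_drops_deficient_runs(self):
        meta = syn.make_pattern_metadata(3, 2, 2, 3)
        # run 2: knock one type below 3 correct trials
        idx = meta[(meta["run"] == 2) & (meta["seq_type"] == "T0")].index[:1]
        meta.loc[idx, "correct"] = False
        tb = betas_from(np.zeros((len(meta), 2)), meta)
        kept = rsa.eligible_run_filter(tb, min_correct=3)
        assert set(kept.meta["run"]) == {0, 1}
        assert kept.meta["correct"].all()

    def test_session_summary_schema(self, rng):
        alpha = ALPHA0 | dict(H0=0.2, HR=0.3, HT=1.0, HU=1.0, HST=0.5, HSU=0.5)
        spec = syn.PatternGenSpec(
            alpha=alpha, n_voxels=60, meta=syn.make_pattern_metadata(3, 2, 2, 4)
        )
        tb = syn.simulate_pattern_dataset(spec, rng)
        out = rsa.session_pattern_summary(tb, trained_types=frozenset(["T0", "T1"]))
        assert {"metric", "category", "value"} <= set(out.columns)
        cats = set(out.loc[out["metric"] == "crossnobis", "category"])
        assert cats == {
            "trained-trained",
            "untrained-untrained",
            "trained-untrained",
        }
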