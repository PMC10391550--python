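"""Feature transforms, correlation filter, PCA, and trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from corticotroph.features import (FeatureMatrix, correlation_filter,
                                   run_pca, trajectories, transform_features)


def _fm(arr, cols=None, index=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return FeatureMatrix(data=pd.DataFrame(arr, columns=cols, index=index))


class TestTransform:
    def test_ones_to_zeros(self):
        out = transform_features(_fm(np.ones((5, 1))), ["f0"])
        assert np.allclose(out.data["f0"], 0.0)

    def test_log_ladder(self):
        col = np.array([[1.0], [math.e], [math.e ** 2]])
        out = transform_features(_fm(col), ["f0"])
        assert np.allclose(out.data["f0"], [0.0, 1.0, 2.0])

    def test_zero_handled_by_half_minimum_offset(self):
        col = np.array([[0.0], [2.0], [8.0]])
        out = transform_features(_fm(col), ["f0"])
        assert np.isfinite(out.data["f0"]).all()
        assert out.meta["log_offsets"]["f0"] == 1.0  # half of min positive

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_features(_fm([[-1.0], [2.0]]), ["f0"])


class TestCorrelationFilter:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        fm = _fm(np.column_stack([x, x + 1e-9 * rng.normal(size=50), z]),
                 ["x", "x_copy", "z"])
        out = correlation_filter(fm)
        assert len(out.removal_log) == 1
        assert out.removal_log[0] in ("x", "x_copy")
        assert "z" in out.columns

    def test_orthogonal_columns_untouched(self):
        rng = np.random.default_rng(1)
        fm = _fm(rng.normal(size=(200, 4)))
        out = correlation_filter(fm)
        assert out.removal_log == ()
        assert out.columns == fm.columns

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        fm = _fm(np.column_stack([x, x * 2 + 0.01 * rng.normal(size=60),
                                  rng.normal(size=60)]))
        once = correlation_filter(fm)
        twice = correlation_filter(once)
        assert twice.columns == once.columns
        assert len(twice.removal_log) == len(once.removal_log)

    def test_named_removal_mode(self):
        rng = np.random.default_rng(3)
        fm = _fm(rng.normal(size=(30, 5)))
        out = correlation_filter(fm, remove=["f1", "f3"])
        assert out.columns == ["f0", "f2", "f4"]
        with pytest.raises(KeyError):
            correlation_filter(fm, remove=["nope"])

    @staticmethod
    def collinear_cohort(n=80, seed=4):
        """Twelve features where active time, burst factor, event frequency
        and event duration are linear blends of retained features."""
        rng = np.random.default_rng(seed)
        base = {name: rng.normal(size=n) for name in
                ("capacitance_pf", "membrane_potential_mv", "spike_freq_hz",
                 "burst_freq_hz", "spike_duration_ms", "burst_duration_ms",
                 "event_amplitude_mv", "days_in_culture")}
        eps = lambda: 0.05 * rng.normal(size=n)
        df = pd.DataFrame(base)
        # each redundant feature blends a distinct pair of retained ones
        df["active_time_frac"] = base["burst_duration_ms"] \
            + 0.3 * base["days_in_culture"] + eps()
        df["burst_factor"] = base["burst_freq_hz"] \
            + 0.3 * base["capacitance_pf"] + eps()
        df["event_freq_hz"] = base["spike_freq_hz"] \
            + 0.3 * base["membrane_potential_mv"] + eps()
        df["event_duration_ms"] = base["spike_duration_ms"] \
            + 0.3 * base["event_amplitude_mv"] + eps()
        return FeatureMatrix(data=df)

    def test_engineered_cohort_removes_exactly_the_redundant_four(self):
        out = correlation_filter(self.collinear_cohort())
        assert sorted(out.removal_log) == ["active_time_frac", "burst_factor",
                                           "event_duration_ms",
                                           "event_freq_hz"]
        assert len(out.columns) == 8


class TestPCA:
    def test_points_on_a_line(self):
        t = np.linspace(-2, 2, 40)
        fm = _fm(np.column_stack([3 * t, -t, 0.5 * t]))
        res = run_pca(fm)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_variance_split(self):
        rng = np.random.default_rng(5)
        res = run_pca(_fm(rng.normal(size=(10_000, 3))))
        assert np.allclose(res.variance_explained, 1 / 3, atol=0.02)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(6)
        fm = _fm(rng.normal(size=(30, 5)))
        res = run_pca(fm)
        Z = (fm.data - res.mean) / res.scale
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Z.to_numpy()).max() < 1e-8

    def test_orthonormal_loadings_and_centred_scores(self):
        rng = np.random.default_rng(7)
        res = run_pca(_fm(rng.normal(size=(50, 6))))
        V = res.loadings.to_numpy()
        assert np.abs(V.T @ V - np.eye(6)).max() < 1e-10
        assert np.abs(res.scores.mean(axis=0).to_numpy()).max() < 1e-10
        ve = res.variance_explained
        assert ve.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(ve) <= 1e-12)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 4))
        a = run_pca(_fm(X))
        b = run_pca(_fm(X.copy()))
        assert a.loadings.equals(b.loadings)
        for j in range(4):
            col = a.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 5))
        res = run_pca(_fm(X))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = sklearn.PCA().fit(Z)
        ref_var = ref.explained_variance_ratio_
        assert np.allclose(res.variance_explained, ref_var, atol=1e-10)
        # scores agree up to component sign
        ref_scores = ref.transform(Z)
        for j in range(5):
            c = np.corrcoef(res.scores.iloc[:, j], ref_scores[:, j])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_column_rejected(self):
        fm = _fm(np.column_stack([np.ones(10), np.arange(10.0)]),
                 ["const", "ramp"])
        with pytest.raises(ValueError, match="const"):
            run_pca(fm)


class TestTrajectories:
    @staticmethod
    def _scores(vals, ids):
        return pd.DataFrame(vals, index=ids, columns=["PC1", "PC2"])

    def test_zero_displacement(self):
        s = self._scores([[1.0, 2.0], [3.0, 4.0]], ["c1", "c2"])
        disp = trajectories(s, s.copy())
        assert np.allclose(disp[["dPC1", "dPC2"]], 0.0)

    def test_unmatched_ids_rejected(self):
        a = self._scores([[0, 0]], ["c1"])
        b = self._scores([[0, 0]], ["c2"])
        with pytest.raises(ValueError):
            trajectories(a, b)

    def test_uniform_cohort_moves_in_consistent_direction(self):
        """Cells that all gain bursting move the same way along the
        bursting-loaded component."""
        rng = np.random.default_rng(10)
        n = 30
        basal = pd.DataFrame({
            "burst_freq_hz": rng.normal(0.1, 0.02, n),
            "spike_freq_hz": rng.normal(0.5, 0.1, n),
            "capacitance_pf": rng.normal(4.5, 1.5, n),
        }, index=[f"c{i}" for i in range(n)])
        stim = basal.copy()
        stim["burst_freq_hz"] += rng.normal(0.5, 0.05, n)  # all gain bursting
        joint = pd.concat([basal, stim])
        res = run_pca(FeatureMatrix(data=joint))
        disp = trajectories(res.scores.iloc[:n], res.scores.iloc[n:]
                            .set_axis(basal.index))
        j = int(np.argmax(np.abs(res.loadings.loc["burst_freq_hz"])))
        d = disp.iloc[:, j].to_numpy()
        dominant_sign = np.sign(np.median(d))
        assert np.mean(np.sign(d) == dominant_sign) >= 0.9

    def test_two_response_phenotypes_separate(self):
        """A mixed cohort (spike-responders vs burst-responders) forms two
        displacement clusters."""
        rng = np.random.default_rng(11)
        n_a, n_b = 12, 18
        ids = [f"c{i}" for i in range(n_a + n_b)]
        basal = pd.DataFrame({
            "burst_freq_hz": rng.normal(0.1, 0.02, n_a + n_b),
            "spike_freq_hz": rng.normal(0.5, 0.1, n_a + n_b),
            "capacitance_pf": rng.normal(4.5, 1.5, n_a + n_b),
        }, index=ids)
        stim = basal.copy()
        stim.iloc[:n_a, 1] += rng.normal(1.5, 0.1, n_a)   # A: faster spiking
        stim.iloc[n_a:, 0] += rng.normal(0.6, 0.05, n_b)  # B: bursting
        joint = pd.concat([basal, stim])
        res = run_pca(FeatureMatrix(data=joint))
        disp = trajectories(res.scores.iloc[:n_a + n_b],
                            res.scores.iloc[n_a + n_b:].set_axis(ids))
        from sklearn.cluster import KMeans
        X = disp[["dPC1", "dPC2"]].to_numpy()
        labels = KMeans(n_clusters=2, n_init=10, random_state=0) \
            .fit_predict(X)
        truth = np.array([0] * n_a + [1] * n_b)
        acc = max((labels == truth).mean(), (labels != truth).mean())
        assert acc >= 0.9
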