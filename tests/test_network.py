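"""Lasso path, covariance test, noise variance, per-gene models, assembly."""

import numpy as np
import pandas as pd
import pytest

import gliomanet as g
from gliomanet.io import ConsistencyError
from gliomanet.network import possible_links
from tests.conftest import make_lr


def orthogonal_design(n, c, seed=0):
    """Columns with mean 0, norm sqrt(n), mutually orthogonal, and
    X^T y = c exactly (the soft-thresholding regime)."""
    rng = np.random.default_rng(seed)
    p = len(c)
    raw = rng.normal(size=(n, p + 1))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    X = q[:, :p] * np.sqrt(n)
    y = X @ (np.asarray(c, dtype=float) / n)
    return X, y


def soft_threshold(c, lam, n):
    c = np.asarray(c, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0) / n


class TestLassoPath:
    def test_orthogonal_design_matches_soft_thresholding(self):
        c = [3.0, 1.0, 0.5]
        X, y = orthogonal_design(40, c)
        path = g.lasso_path(X, y)
        # standardization must be a no-op on this design
        assert np.allclose(path.X, X, atol=1e-10)
        assert np.allclose(sorted(path.knots, reverse=True), [3.0, 1.0, 0.5, 0.0])
        for m, lam in enumerate(path.knots):
            assert np.allclose(
                path.coefs[:, m], soft_threshold(c, lam, 40), atol=1e-10
            )
        # at lambda = 2 only the first predictor is active, coefficient
        # sign(3) * (3 - 2) on the unit-norm scale
        interp = np.array(
            [
                np.interp(2.0, path.knots[::-1], path.coefs[j, ::-1])
                for j in range(3)
            ]
        )
        assert np.allclose(interp * 40, [1.0, 0.0, 0.0], atol=1e-10)

    def test_orthogonal_response_gives_empty_path(self):
        X, _ = orthogonal_design(30, [1.0, 1.0])
        rng = np.random.default_rng(5)
        v = rng.normal(size=30)
        v -= v.mean()
        y = v - X @ (X.T @ v) / 30  # project out the columns
        path = g.lasso_path(X, y)
        assert path.entries == []

    def test_single_predictor_entry(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x
        path = g.lasso_path(x[:, None], y)
        assert len(path.entries) == 1
        ev = path.entries[0]
        assert ev.sign == 1
        assert path.knots[ev.knot] == pytest.approx(abs(x @ y))

    def test_constant_predictor_rejected_by_name(self):
        X = pd.DataFrame({"tfA": [1.0, 2.0, 3.0], "tfB": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="tfB"):
            g.lasso_path(X, np.array([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kkt_conditions_at_every_knot(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 8))
        beta = np.zeros(8)
        beta[:3] = [2.0, -1.5, 1.0]
        y = X @ beta + rng.normal(0, 0.5, 60)
        path = g.lasso_path(X, y)
        g.check_kkt(path, tol=1e-8)


class TestCovarianceTest:
    def test_vanishing_statistic_gives_p_near_one(self):
        # a predictor entering at the very end of the path has T ~ 0,
        # hence p = exp(-T) ~ 1
        X, y = orthogonal_design(40, [1.0, 1e-9, 1e-12])
        path = g.lasso_path(X, y)
        stats = g.covariance_test(path, sigma2=1.0)
        assert (stats["p"] <= 1.0).all()
        last = stats.iloc[-1]
        assert last["p"] == pytest.approx(np.exp(-last["statistic"]), rel=1e-12)
        assert last["p"] == pytest.approx(1.0, abs=0.05)

    def test_strong_signal_is_significant(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 10))
        y = 5.0 * X[:, 3] + rng.normal(0, 0.5, 100)
        path = g.lasso_path(X, y)
        sigma2 = g.estimate_noise_variance(X, y)
        pvals = g.first_entry_pvalues(path, sigma2)
        assert pvals["x3"] < 5e-5
        assert (pvals.drop("x3") > 5e-5).all()

    def test_invalid_sigma2_rejected(self):
        X, y = orthogonal_design(40, [3.0, 1.0])
        path = g.lasso_path(X, y)
        with pytest.raises(ValueError):
            g.covariance_test(path, sigma2=0.0)


class TestNoiseVariance:
    def test_unit_noise_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = x + rng.normal(0, 1.0, 200)
        assert g.estimate_noise_variance(x[:, None], y) == pytest.approx(1.0, rel=0.25)

    def test_pure_noise_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 5))
        y = rng.normal(0, 2.0, 150)
        assert g.estimate_noise_variance(X, y) == pytest.approx(4.0, rel=0.3)

    def test_exact_fit_hits_floor_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        y = X @ np.array([1.0, -2.0])
        with pytest.warns(RuntimeWarning):
            sigma2 = g.estimate_noise_variance(X, y)
        assert sigma2 == pytest.approx(1e-8)

    def test_high_dimensional_branch(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 40))
        y = 3.0 * X[:, 0] + rng.normal(0, 1.0, 30)
        sigma2 = g.estimate_noise_variance(X, y)
        assert 0.2 < sigma2 < 5.0

    def test_rank_deficient_rejected(self):
        X = np.ones((20, 2))
        X[:, 1] = X[:, 0]
        with pytest.raises(ValueError):
            g.estimate_noise_variance(X, np.arange(20.0))


class TestGeneModels:
    def _lr(self, n=100, n_tfs=20, seed=12):
        rng = np.random.default_rng(seed)
        tfs = [f"TF{j:02d}" for j in range(n_tfs)]
        X = rng.normal(size=(n_tfs, n))
        y = 2.0 * X[2] - 1.5 * X[6] + rng.normal(0, 0.5, n)
        values = pd.DataFrame(
            np.vstack([X, y]), index=tfs + ["target"],
            columns=[f"s{i}" for i in range(n)],
        )
        return make_lr(values, ["GBM4"] * n), tfs

    def test_planted_regulators_recovered_with_signs(self):
        lr, tfs = self._lr()
        sel = g.fit_gene_model("target", lr, tfs)
        assert set(sel["tf"]) == {"TF02", "TF06"}
        by_tf = sel.set_index("tf")
        assert by_tf.loc["TF02", "sign"] == "activator"
        assert by_tf.loc["TF06", "sign"] == "repressor"
        assert by_tf.loc["TF02", "coefficient"] == pytest.approx(2.0, abs=0.3)
        assert by_tf.loc["TF06", "coefficient"] == pytest.approx(-1.5, abs=0.3)

    def test_lasso_coefficient_mode_shrinks(self):
        lr, tfs = self._lr()
        refit = g.fit_gene_model("target", lr, tfs).set_index("tf")
        shrunk = g.fit_gene_model(
            "target", lr, tfs, coefficient_mode="lasso"
        ).set_index("tf")
        assert set(shrunk.index) == set(refit.index)
        assert (shrunk["coefficient"].abs() <= refit["coefficient"].abs() + 1e-9).all()

    def test_response_equal_to_tf_profile(self):
        rng = np.random.default_rng(13)
        tfs = [f"TF{j}" for j in range(5)]
        X = rng.normal(size=(5, 60))
        values = pd.DataFrame(
            np.vstack([X, X[1]]), index=tfs + ["target"],
            columns=[f"s{i}" for i in range(60)],
        )
        lr = make_lr(values, ["AS2"] * 60)
        with pytest.warns(RuntimeWarning):  # exact fit -> variance floor
            sel = g.fit_gene_model("target", lr, tfs)
        assert list(sel["tf"]) == ["TF1"]
        assert sel["sign"].iloc[0] == "activator"

    def test_self_exclusion_for_tf_responses(self, small_cohort, small_lr):
        _, truth = small_cohort
        tfs = list(truth.coeff_matrix.index)
        sel = g.fit_gene_model(tfs[0], small_lr, tfs)
        assert tfs[0] not in set(sel["tf"])

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [0.5, 1.5]], index=["TF1", "tgt"], columns=["a", "b"]
        )
        lr = make_lr(values, ["PA1", "PA1"])
        with pytest.raises(ConsistencyError):
            g.fit_gene_model("tgt", lr, ["TF1"])


class TestInferNetwork:
    def test_possible_link_counts(self):
        tfs = [f"t{i}" for i in range(20)]
        genes = tfs + [f"g{i}" for i in range(180)]
        total, excl = possible_links(tfs, genes)
        assert total == 4000
        assert excl == 4000 - 20

    def test_network_has_no_self_edges_and_summary_consistent(
        self, small_cohort, small_lr
    ):
        _, truth = small_cohort
        tfs = list(truth.coeff_matrix.index)
        genes = tfs + list(truth.coeff_matrix.columns)
        net = g.infer_network(genes, small_lr, tfs)
        assert not (net.edges["tf"] == net.edges["target"]).any()
        s = net.summary
        assert s["selected_links"] == len(net.edges)
        assert s["activators"] + s["repressors"] == s["selected_links"]
        assert s["selected_links"] <= s["possible_links"]
        assert len(s["genes_without_regulators"]) == len(
            set(genes) - set(net.edges["target"])
        )

    def test_sign_recovery_on_planted_edges(self, small_cohort, small_lr):
        _, truth = small_cohort
        tfs = list(truth.coeff_matrix.index)
        net = g.infer_network(list(truth.coeff_matrix.columns), small_lr, tfs)
        true = truth.true_edges()
        for _, row in net.edges.iterrows():
            if (row["tf"], row["target"]) in true:
                assert np.sign(row["coefficient"]) == np.sign(
                    truth.coeff_matrix.loc[row["tf"], row["target"]]
                )
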