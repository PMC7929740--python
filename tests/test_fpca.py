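import numpy as np
import pytest

from actifda.basis import MINUTES_PER_DAY, FourierBasis
from actifda.errors import DegenerateInputError, InvalidConfigError
from actifda.fpca import DailyFPCA, DailyFPCAResults, select_num_components
from actifda.simulate import SimulationConfig, simulate_covariates, simulate_curves

from conftest import flat_mean_coefficients


def principal_angle_deg(u, v):
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(min(c, 1.0)))


def discretized_pca_oracle(curves):
    """Brute-force PCA of the 1440-point discretized curves."""
    Yc = curves - curves.mean(axis=0)
    cov = Yc.T @ Yc / (curves.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return np.clip(w[order], 0, None), V[:, order]


def _noiseless_curves(n_days=50, eigenvalues=(4000.0, 2000.0, 1000.0), seed=0):
    comp = np.eye(9)[:3]
    cfg = SimulationConfig.with_eigenvalues(
        eigenvalues,
        n_subjects=max(2, n_days // 14 + 1),
        component_coefficients=comp,
        mean_coefficients=flat_mean_coefficients(),
        effect_matrix=np.zeros((3, 16)),
        noise_sd=0.0,
        gap_rate=0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n_days, 3)) * np.sqrt(eigenvalues)
    coef = cfg.mean_coefficients + scores @ comp
    return cfg.basis.reconstruct(coef), comp


class TestSelectNumComponents:
    def test_printed_percentages_retain_four_components(self):
        # the four leading daily-variation shares plus the remainder
        props = [0.343, 0.165, 0.148, 0.118, 0.08, 0.06, 0.05, 0.036]
        k = select_num_components(props)
        assert k == 4
        assert sum(props[:4]) == pytest.approx(0.774)

    @pytest.mark.parametrize(
        "props, threshold, expected",
        [
            ([0.80, 0.10, 0.05, 0.05], 0.75, 1),
            ([0.30, 0.30, 0.30, 0.10], 0.75, 3),
            ([0.5, 0.5], 1.0, 2),
        ],
    )
    def test_cumulative_rule(self, props, threshold, expected):
        assert select_num_components(props, threshold) == expected

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.01])
    def test_threshold_outside_unit_interval_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            select_num_components([0.8, 0.2], bad)

    def test_unsorted_proportions_rejected(self):
        with pytest.raises(ValueError):
            select_num_components([0.2, 0.8])


class TestFit:
    def test_identical_curves_have_zero_eigenvalues(self, basis):
        curves = np.tile(basis.reconstruct(np.arange(9.0) * 10), (12, 1))
        res = DailyFPCA(curves, basis=basis).fit()
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-6)

    def test_rank_one_structure_recovers_the_single_direction(self, basis):
        mu = flat_mean_coefficients()
        coef = np.concatenate(
            [np.tile(mu + 3 * np.eye(9)[1], (6, 1)), np.tile(mu - 3 * np.eye(9)[1], (6, 1))]
        )
        res = DailyFPCA.from_coefficients(coef, basis=basis).fit()
        assert res.eigenvalues[0] > 0
        assert np.allclose(res.eigenvalues[1:], 0.0, atol=1e-8)
        assert np.allclose(np.abs(res.eigen_coefficients[0]), np.eye(9)[1], atol=1e-8)
        # sign convention: dominant coefficient oriented positive
        assert res.eigen_coefficients[0, 1] > 0

    def test_fewer_than_two_curves_is_degenerate(self, basis):
        with pytest.raises(DegenerateInputError):
            DailyFPCA(np.ones((1, MINUTES_PER_DAY)), basis=basis).fit()

    def test_matches_discretized_pca_oracle(self, basis):
        curves, _ = _noiseless_curves(n_days=50)
        res = DailyFPCA(curves, basis=basis).fit()
        w_oracle, V_oracle = discretized_pca_oracle(curves)
        # identical spectra (orthonormal basis; unit minute spacing)
        nz = w_oracle > 1e-6 * w_oracle[0]
        assert np.allclose(
            res.eigenvalues[: nz.sum()], w_oracle[nz], rtol=1e-8
        )
        for k in range(3):
            fn = basis.reconstruct(res.eigen_coefficients[k])
            assert principal_angle_deg(fn, V_oracle[:, k]) < 1e-6 * 180 / np.pi

    def test_recovers_the_generating_eigenstructure(self, basis):
        # eigenvector sampling error shrinks like 1/sqrt(n): use many days
        curves, comp = _noiseless_curves(n_days=8000, seed=4)
        res = DailyFPCA(curves, basis=basis).fit()
        for k in range(3):
            fn = basis.reconstruct(res.eigen_coefficients[k])
            assert principal_angle_deg(fn, basis.reconstruct(comp[k])) < 2.0
        props = res.variance_proportions[:3]
        assert np.allclose(props, np.array([4, 2, 1]) / 7, atol=0.02)

    def test_duplicating_every_curve_changes_nothing(self, basis):
        curves, _ = _noiseless_curves(n_days=30, seed=3)
        res1 = DailyFPCA(curves, basis=basis).fit()
        res2 = DailyFPCA(np.vstack([curves, curves]), basis=basis).fit()
        assert np.allclose(
            res1.variance_proportions, res2.variance_proportions, atol=1e-10
        )
        assert np.allclose(
            res1.eigen_coefficients, res2.eigen_coefficients, atol=1e-8
        )

    def test_variance_proportions_sum_to_one(self, basis):
        curves, _ = _noiseless_curves(n_days=40, seed=5)
        res = DailyFPCA(curves, basis=basis).fit()
        assert res.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def fitted(basis):
    curves, _ = _noiseless_curves(n_days=80, seed=8)
    model = DailyFPCA(curves, basis=basis)
    return model, model.fit()


class TestScores:
    def test_mean_curve_scores_zero(self, fitted, basis):
        _, res = fitted
        xi = res.scores(res.mean_coefficients[None, :])
        assert np.allclose(xi, 0.0, atol=1e-8)

    def test_unit_component_displacement_scores_exactly(self, fitted, basis):
        _, res = fitted
        coef = res.mean_coefficients + 2.0 * res.eigen_coefficients[0]
        xi = res.scores(coef[None, :])
        assert xi[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(xi[0, 1:], 0.0, atol=1e-8)
        std = res.scores(coef[None, :], standardized=True)
        assert std[0, 0] == pytest.approx(2.0 / res.score_sd[0], abs=1e-8)

    def test_scores_match_dense_projection_oracle(self, fitted):
        model, res = fitted
        C = model.coefficients
        xi = res.scores()
        K = res.n_retained
        oracle = np.empty((C.shape[0], K))
        for i in range(C.shape[0]):
            for k in range(K):
                oracle[i, k] = (C[i] - res.mean_coefficients) @ res.eigen_coefficients[k]
        assert np.allclose(xi, oracle, atol=1e-10)

    def test_full_reconstruction_reproduces_centered_coefficients(self, fitted):
        model, res = fitted
        C = model.coefficients
        xi_all = (C - res.mean_coefficients) @ res.eigen_coefficients.T
        back = xi_all @ res.eigen_coefficients
        assert np.allclose(back, C - res.mean_coefficients, atol=1e-8)


class TestEffectCurves:
    def test_zero_variance_component_collapses_the_band(self, basis):
        mu = flat_mean_coefficients()
        coef = np.tile(mu, (8, 1))
        coef[:4, 1] += 5.0
        coef[4:, 1] -= 5.0
        res = DailyFPCA.from_coefficients(coef, basis=basis).fit()
        c = res.effect_curves(9)  # trailing component has zero eigenvalue
        assert np.allclose(c["plus"], c["mean"], atol=1e-6)
        assert np.allclose(c["minus"], c["mean"], atol=1e-6)

    def test_plus_minus_average_to_the_mean_exactly(self, basis):
        curves, _ = _noiseless_curves(n_days=30, seed=2)
        res = DailyFPCA(curves, basis=basis).fit()
        c = res.effect_curves(1)
        assert np.allclose((c["plus"] + c["minus"]) / 2, c["mean"], atol=1e-9)

    def test_overall_level_component_orders_the_curves(self, basis):
        # component 1 of the default truth is an overall-level contrast
        curves, _ = _noiseless_curves(n_days=60, seed=6)
        res = DailyFPCA(curves, basis=basis).fit()
        c = res.effect_curves(1)
        assert np.all(c["plus"] >= c["minus"] - 1e-9)

    def test_out_of_range_component_raises(self, basis):
        curves, _ = _noiseless_curves(n_days=20, seed=1)
        res = DailyFPCA(curves, basis=basis).fit()
        with pytest.raises(IndexError):
            res.effect_curves(10)


def test_json_roundtrip(basis, tmp_path):
    curves, _ = _noiseless_curves(n_days=25, seed=9)
    res = DailyFPCA(curves, basis=basis).fit()
    path = tmp_path / "model.json"
    res.to_json(path)
    back = DailyFPCAResults.from_json(path)
    assert np.allclose(back.eigen_coefficients, res.eigen_coefficients)
    assert back.n_retained == res.n_retained
    assert np.allclose(back.score_sd, res.score_sd)
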