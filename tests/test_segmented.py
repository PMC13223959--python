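import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasvar import (
    Breakpoints,
    DegenerateDataError,
    GridSpec,
    SurfaceParams,
    ValidationError,
    assign_quadrant,
    build_design,
    distance_weighted_ci,
    fit_bivariate_segmented,
    fit_univariate_segmented,
    generate_surface_data,
    mad_sigma,
    predict,
    predict_surface,
    train_test_validate,
    variance_attribution,
)

PSI = Breakpoints(0.2, 0.0)
PFOS_BETA = np.array([-0.4, -0.2, 1.2, 0.1, -0.1, 0.1])


def _exact_data(beta, psi=PSI, n=40, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    c = rng.uniform(-2.5, 2.5, n)
    nn = rng.uniform(-2.5, 2.5, n)
    z = build_design(c, nn, psi) @ beta + rng.normal(0, noise, n)
    return pd.DataFrame({"c": c, "n": nn, "z": z})


# ---------------------------------------------------------------------------
# primitives


@pytest.mark.parametrize(
    "c,n,expected",
    [(0.1, -0.5, "LL"), (0.2, 0.0, "LL"), (1.0, 1.0, "HH"),
     (0.21, -0.1, "HL"), (-1.0, 0.5, "LH")],
)
def test_assign_quadrant(c, n, expected):
    assert assign_quadrant(c, n, PSI) == expected


def test_hinge_design_zeros_and_values():
    row = build_design(0.2, -1.0, PSI)[0]
    np.testing.assert_allclose(row, [1.0, 0.2, 0.0, -1.0, 0.0, -0.2], atol=1e-15)
    row = build_design(1.2, 0.5, PSI)[0]
    np.testing.assert_allclose(row, [1.0, 1.2, 1.0, 0.5, 0.5, 0.6], atol=1e-15)


@given(
    beta=st.lists(st.floats(-3, 3), min_size=6, max_size=6),
    n=st.floats(-2, 2),
)
@settings(max_examples=50, deadline=None)
def test_hinge_prediction_continuous_at_breakpoint(beta, n):
    beta = np.asarray(beta)
    eps = 1e-9
    left = build_design(PSI.psi_c - eps, n, PSI) @ beta
    right = build_design(PSI.psi_c + eps, n, PSI) @ beta
    assert abs(left[0] - right[0]) < 1e-6  # slope-bounded gap over 2 eps


def test_mad_sigma_values():
    assert mad_sigma([-1, 0, 1]) == pytest.approx(1.4826)
    assert mad_sigma([3.3, 3.3, 3.3]) == 0.0
    with pytest.raises(ValueError):
        mad_sigma([])
    draws = np.random.default_rng(0).standard_normal(100_000)
    assert mad_sigma(draws) == pytest.approx(1.0, rel=0.02)


# ---------------------------------------------------------------------------
# bivariate fit


def test_noiseless_recovery_exact():
    data = _exact_data(PFOS_BETA, n=60, seed=1)
    fit = fit_bivariate_segmented(data, PSI, min_quadrant_n=1)
    np.testing.assert_allclose(fit.beta, PFOS_BETA, atol=1e-10)
    for st_ in fit.quadrant_stats.values():
        assert st_.mad_sigma == pytest.approx(0.0, abs=1e-10)
    assert fit.r2 == pytest.approx(1.0)


def test_stochastic_recovery_within_3_robust_se():
    data = generate_surface_data(SurfaceParams(), n=2000, seed=2)
    fit = fit_bivariate_segmented(data, PSI)
    err = np.abs(fit.beta - PFOS_BETA)
    assert (err <= 3 * fit.se).all()


def test_ols_matches_normal_equations_oracle():
    data = _exact_data(PFOS_BETA, n=50, seed=3, noise=0.5)
    fit = fit_bivariate_segmented(data, PSI, min_quadrant_n=1)
    x = build_design(data["c"].to_numpy(), data["n"].to_numpy(), PSI)
    beta_ne = np.linalg.solve(x.T @ x, x.T @ data["z"].to_numpy())
    np.testing.assert_allclose(fit.beta, beta_ne, atol=1e-8)


def test_small_quadrant_excluded_and_fit_equivalent():
    rng = np.random.default_rng(4)
    # 30 LL, 30 HH, 6 HL -> HL excluded
    c = np.concatenate([rng.uniform(-2, 0.1, 30), rng.uniform(0.4, 2, 30),
                        rng.uniform(0.4, 2, 6)])
    n = np.concatenate([rng.uniform(-2, -0.1, 30), rng.uniform(0.1, 2, 30),
                        rng.uniform(-2, -0.1, 6)])
    z = build_design(c, n, PSI) @ PFOS_BETA + rng.normal(0, 0.5, 66)
    data = pd.DataFrame({"c": c, "n": n, "z": z})
    fit = fit_bivariate_segmented(data, PSI, min_quadrant_n=10)
    assert set(fit.excluded_quadrants) == {"HL"}
    assert "n = 6" in fit.excluded_quadrants["HL"]
    assert sum(s.n for s in fit.quadrant_stats.values()) == 60
    # fitting the retained rows directly gives identical coefficients
    direct = fit_bivariate_segmented(data.iloc[:60], PSI, min_quadrant_n=0)
    np.testing.assert_allclose(fit.beta, direct.beta, atol=1e-12)


def test_rank_deficient_and_tiny_cohorts_error():
    rng = np.random.default_rng(5)
    one_quadrant = pd.DataFrame(
        {"c": rng.uniform(-2, 0, 30), "n": rng.uniform(-2, -0.5, 30),
         "z": rng.normal(size=30)}
    )
    with pytest.raises(DegenerateDataError, match="rank"):
        fit_bivariate_segmented(one_quadrant, PSI, min_quadrant_n=1)
    tiny = _exact_data(PFOS_BETA, n=10, seed=6)
    with pytest.raises(DegenerateDataError, match="12"):
        fit_bivariate_segmented(tiny, PSI, min_quadrant_n=1)


# ---------------------------------------------------------------------------
# uncertainty


def _noisy_fit(seed=7, n=400, noise=0.6):
    data = _exact_data(PFOS_BETA, n=n, seed=seed, noise=noise)
    return fit_bivariate_segmented(data, PSI)


def test_ci_half_width_at_centroid_and_monotonicity():
    fit = _noisy_fit()
    q = "HH"
    st_ = fit.quadrant_stats[q]
    cx, cy = st_.centroid
    lo, hi = distance_weighted_ci(fit, cx, cy)
    assert (hi - lo) / 2 == pytest.approx(1.959963985 * st_.mad_sigma, rel=1e-9)
    # half-width strictly increases with distance inside the quadrant
    widths = []
    for d in (0.0, 0.1, 0.3, 0.6):
        lo, hi = distance_weighted_ci(fit, cx + d, cy + d)
        widths.append(hi - lo)
    assert all(b > a for a, b in zip(widths, widths[1:]))


def test_ci_zero_sigma_zero_width():
    data = _exact_data(PFOS_BETA, n=60, seed=8)
    fit = fit_bivariate_segmented(data, PSI, min_quadrant_n=1)
    st_ = fit.quadrant_stats["HH"]
    lo, hi = distance_weighted_ci(fit, *st_.centroid)
    assert hi - lo == pytest.approx(0.0, abs=1e-9)
    assert lo == pytest.approx(predict(fit, *st_.centroid)[0], abs=1e-9)


def test_ci_errors_in_excluded_quadrant():
    rng = np.random.default_rng(9)
    c = np.concatenate([rng.uniform(-2, 0.1, 30), rng.uniform(0.4, 2, 30),
                        rng.uniform(0.4, 2, 6), rng.uniform(-2, 0, 15)])
    n = np.concatenate([rng.uniform(-2, -0.1, 30), rng.uniform(0.1, 2, 30),
                        rng.uniform(-2, -0.1, 6), rng.uniform(0.1, 2, 15)])
    z = build_design(c, n, PSI) @ PFOS_BETA + rng.normal(0, 0.5, len(c))
    fit = fit_bivariate_segmented(pd.DataFrame({"c": c, "n": n, "z": z}), PSI)
    with pytest.raises(ValidationError, match="excluded"):
        distance_weighted_ci(fit, 1.0, -1.0)  # HL


def test_centroid_interval_coverage():
    """Empirical coverage of the distance-weighted interval at the quadrant
    centroid stays near the nominal 95% for Gaussian noise."""
    truth = PFOS_BETA
    noise = 0.8
    rng = np.random.default_rng(10)
    covered, total = 0, 0
    for _ in range(500):
        data = _exact_data(truth, n=200, seed=rng.integers(2**31), noise=noise)
        fit = fit_bivariate_segmented(data, PSI, min_quadrant_n=5)
        q = "LL"
        if q not in fit.quadrant_stats:
            continue
        cx, cy = fit.quadrant_stats[q].centroid
        lo, hi = distance_weighted_ci(fit, cx, cy)
        y_new = build_design(cx, cy, PSI)[0] @ truth + rng.normal(0, noise)
        covered += lo <= y_new <= hi
        total += 1
    assert covered / total >= 0.90


# ---------------------------------------------------------------------------
# validation and attribution


def test_split_sizes_published_design():
    """106 retained birds in quadrant sizes 65/15/26 split 84 train / 22 test."""
    rng = np.random.default_rng(11)
    parts = []
    for q, size in (("LL", 65), ("LH", 15), ("HH", 26)):
        lo_c, hi_c = (-2.4, 0.1) if q[0] == "L" else (0.3, 2.4)
        lo_n, hi_n = (-2.4, -0.1) if q[1] == "L" else (0.1, 2.4)
        parts.append(pd.DataFrame({
            "c": rng.uniform(lo_c, hi_c, size),
            "n": rng.uniform(lo_n, hi_n, size),
        }))
    data = pd.concat(parts, ignore_index=True)
    data["z"] = build_design(data["c"].to_numpy(), data["n"].to_numpy(), PSI) @ PFOS_BETA \
        + rng.normal(0, 0.8, len(data))
    metrics = train_test_validate(data, PSI, seed=0)
    assert (metrics.n_train, metrics.n_test) == (84, 22)


def test_validation_noiseless_perfect():
    data = _exact_data(PFOS_BETA, n=200, seed=12)
    m = train_test_validate(data, PSI, seed=0, min_quadrant_n=5)
    assert m.r2_test == pytest.approx(1.0, abs=1e-10)
    assert m.rmse_test == pytest.approx(0.0, abs=1e-10)


def test_validation_independent_response_r2_near_zero():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        data = pd.DataFrame({
            "c": rng.uniform(-2.5, 2.5, 2000),
            "n": rng.uniform(-2.5, 2.5, 2000),
            "z": rng.normal(size=2000),
        })
        m = train_test_validate(data, PSI, seed=seed)
        hits += abs(m.r2_test) < 0.1
    assert hits >= 4


def test_attribution_single_term_and_sum():
    rng = np.random.default_rng(13)
    c = rng.uniform(-2.5, 2.5, 300)
    n = rng.uniform(-2.5, 2.5, 300)
    data = pd.DataFrame({"c": c, "n": n, "z": 0.7 * c})
    fit = fit_bivariate_segmented(data, PSI, min_quadrant_n=1)
    shares = variance_attribution(fit)
    assert shares["c_slope"] == pytest.approx(100.0, abs=1e-6)
    data2 = _exact_data(PFOS_BETA, n=300, seed=14, noise=0.8)
    fit2 = fit_bivariate_segmented(data2, PSI)
    assert sum(variance_attribution(fit2).values()) == pytest.approx(100.0, abs=1e-8)


def test_attribution_orthogonal_covariates_projection_oracle():
    """With orthogonalized design columns, sequential shares equal the
    squared projections onto each column (Gram-Schmidt oracle)."""
    rng = np.random.default_rng(15)
    raw = _exact_data(PFOS_BETA, n=250, seed=15, noise=0.7)
    x = build_design(raw["c"].to_numpy(), raw["n"].to_numpy(), PSI)
    # orthogonalize in attribution order: intercept, c, n, hC, hN, c*n
    order = [0, 1, 3, 2, 4, 5]
    qmat, _ = np.linalg.qr(x[:, order])
    y = raw["z"].to_numpy()
    proj = qmat.T @ y
    oracle = proj[1:] ** 2 / np.sum(proj[1:] ** 2) * 100
    fit = fit_bivariate_segmented(raw, PSI, min_quadrant_n=1)
    shares = variance_attribution(fit)
    got = [shares[k] for k in ("c_slope", "n_slope", "c_segment", "n_segment", "c_x_n")]
    np.testing.assert_allclose(got, oracle, atol=1e-8)


# ---------------------------------------------------------------------------
# univariate


def test_univariate_exact_two_segments():
    x = np.concatenate([np.linspace(-2.5, 0, 20), np.linspace(0.01, 2.5, 20)])
    z = np.where(x <= 0, 0.3 - 0.1 * x, 0.3 - 0.1 * x - 0.6 * x)
    fit = fit_univariate_segmented(z, x, 0.0)
    assert fit.beta_pre == pytest.approx(-0.1, abs=1e-10)
    assert fit.beta_post == pytest.approx(-0.7, abs=1e-10)
    assert fit.beta_post == fit.beta_pre + fit.segment_coef


def test_univariate_flat_response():
    x = np.linspace(-2, 2, 30)
    fit = fit_univariate_segmented(np.full_like(x, 1.3), x, 0.0)
    assert fit.beta_pre == pytest.approx(0.0, abs=1e-10)
    assert fit.beta_post == pytest.approx(0.0, abs=1e-10)


def test_univariate_stochastic_recovery():
    rng = np.random.default_rng(16)
    x = rng.uniform(-2.5, 2.5, 2000)
    z = 0.3 - 0.1 * x - 0.6 * np.maximum(x, 0.0) + rng.normal(0, 0.9, 2000)
    fit = fit_univariate_segmented(z, x, 0.0)
    assert abs(fit.beta_pre + 0.1) <= 3 * fit.se["beta_pre"]
    se_post = np.sqrt(
        fit.se["beta_pre"] ** 2 + fit.se["segment"] ** 2
    )  # conservative (ignores the negative covariance)
    assert abs(fit.beta_post + 0.7) <= 3 * se_post


def test_univariate_one_side_empty_errors():
    x = np.linspace(0.5, 2.0, 20)
    with pytest.raises(DegenerateDataError):
        fit_univariate_segmented(np.zeros_like(x), x, 0.0)


# ---------------------------------------------------------------------------
# surface


def test_surface_node_count_labels_and_continuity():
    fit = _noisy_fit()
    surf = predict_surface(fit, GridSpec(-2.5, 2.5, -2.5, 2.5, 101, 101))
    assert len(surf.table) == 10201
    assert set(surf.table["quadrant"]) <= {"LL", "LH", "HL", "HH"}
    # continuity across the psi_c line
    eps = 1e-11
    for n in (-1.0, 0.5):
        left = predict(fit, PSI.psi_c - eps, n)[0]
        right = predict(fit, PSI.psi_c + eps, n)[0]
        assert abs(left - right) < 1e-9
    # CI present in retained quadrants, bounded below by 1.96 sigma_q
    for q, st_ in fit.quadrant_stats.items():
        rows = surf.table[surf.table["quadrant"] == q].dropna()
        half = (rows["ci_hi"] - rows["ci_lo"]) / 2
        assert (half >= 1.959963 * st_.mad_sigma - 1e-9).all()


def test_surface_centroid_prediction_near_quadrant_mean():
    data = generate_surface_data(SurfaceParams(), n=2000, seed=17)
    fit = fit_bivariate_segmented(data, PSI)
    for q, st_ in fit.quadrant_stats.items():
        pred = predict(fit, *st_.centroid)[0]
        assert abs(pred - st_.mean_response) <= 2 * max(st_.mad_sigma, 0.05)
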