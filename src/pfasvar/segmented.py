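"""Bivariate segmented regression of PFAS variability on isotopic consistency.

The model is a continuous piecewise-linear (hinge) regression in the two
consistency scores c = d13c_consist and n = d15n_consist with FIXED
breakpoints psi = (psi_c, psi_n):

    z = b0 + b1*c + b2*(c - psi_c)+ + b3*n + b4*(n - psi_n)+ + b5*c*n + e

where (u)+ = u * I(u > 0). b2 and b4 are "segment" coefficients — the slope
change after the breakpoint — so the post-breakpoint slope equals the base
slope plus the segment coefficient, and the fitted surface is continuous
across both breakpoint lines. The breakpoints partition the isotopic plane
into four foraging-strategy quadrants (LL, LH, HL, HH; equality assigned to
the low side, matching the hinge indicator). Quadrants with too few birds
are excluded from fitting.

Inference uses heteroskedasticity-robust (HC1) standard errors with normal
two-tailed p-values. Per-quadrant residual scale is the MAD-rescaled sigma
(1.4826 * median absolute deviation), which feeds distance-weighted 95%
confidence intervals: the half-width grows linearly with the distance of a
prediction point from the quadrant's training centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError, ValidationError

QUADRANTS = ("LL", "LH", "HL", "HH")
DEFAULT_MIN_QUADRANT_N = 10
COEF_NAMES = (
    "intercept",
    "c_slope",
    "c_segment",
    "n_slope",
    "n_segment",
    "c_x_n",
)
#: sequential sum-of-squares order for variance attribution
ATTRIBUTION_ORDER = ("c_slope", "n_slope", "c_segment", "n_segment", "c_x_n")

MAD_SCALE = 1.4826  # normal-consistency factor for the MAD


@dataclass(frozen=True)
class Breakpoints:
    """Fixed isotopic thresholds in consistency z-units."""

    psi_c: float = 0.2
    psi_n: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.psi_c) and math.isfinite(self.psi_n)):
            raise ValueError("breakpoints must be finite")


@dataclass
class QuadrantStats:
    n: int
    mean_response: float
    mad_sigma: float
    centroid: tuple[float, float]
    rms_distance: float


@dataclass
class SegmentedFit:
    beta: np.ndarray  # 6-vector, COEF_NAMES order
    vcov_robust: np.ndarray  # 6 x 6 HC1 sandwich
    se: np.ndarray
    p: np.ndarray  # two-tailed, normal approximation
    psi: Breakpoints
    quadrant_stats: dict[str, QuadrantStats]
    excluded_quadrants: dict[str, str]
    r2: float
    alpha: float = 0.05
    min_quadrant_n: int = DEFAULT_MIN_QUADRANT_N
    # retained training data (post-exclusion), kept for attribution/surfaces
    data_: pd.DataFrame = field(default=None, repr=False)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(COEF_NAMES, self.beta))

    def post_slope(self, axis: str) -> float:
        """Post-breakpoint slope = base slope + segment coefficient."""
        c = self.coef
        if axis == "c":
            return c["c_slope"] + c["c_segment"]
        if axis == "n":
            return c["n_slope"] + c["n_segment"]
        raise KeyError(axis)


@dataclass
class UnivariateSegmentedFit:
    intercept: float
    beta_pre: float
    segment_coef: float
    psi: float
    se: dict[str, float]
    p: dict[str, float]
    r2: float

    @property
    def beta_post(self) -> float:
        return self.beta_pre + self.segment_coef


@dataclass
class ValidationMetrics:
    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    n_train: int
    n_test: int
    seed: int
    split_attempts: int = 1


@dataclass
class ExposureSurface:
    table: pd.DataFrame  # columns c, n, quadrant, z_hat, ci_lo, ci_hi
    psi: Breakpoints
    level: float


# ---------------------------------------------------------------------------
# primitives


def assign_quadrant(c, n, psi: Breakpoints = Breakpoints()):
    """Quadrant label(s) for consistency coordinates.

    First letter is the carbon side, second the nitrogen side; equality goes
    to the low side so labels agree with the hinge indicator I(x > psi).
    Scalar in, scalar out; array in, array out.
    """
    c_arr = np.asarray(c, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if not (np.all(np.isfinite(c_arr)) and np.all(np.isfinite(n_arr))):
        raise ValueError("quadrant assignment requires finite coordinates")
    hi_c = c_arr > psi.psi_c
    hi_n = n_arr > psi.psi_n
    labels = np.char.add(
        np.where(hi_c, "H", "L"), np.where(hi_n, "H", "L")
    )
    if labels.ndim == 0:
        return str(labels)
    return labels


def build_design(c, n, psi: Breakpoints = Breakpoints()) -> np.ndarray:
    """Hinge design rows [1, c, (c-psi_c)+, n, (n-psi_n)+, c*n]."""
    c = np.atleast_1d(np.asarray(c, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    h_c = np.where(c > psi.psi_c, c - psi.psi_c, 0.0)
    h_n = np.where(n > psi.psi_n, n - psi.psi_n, 0.0)
    return np.column_stack([np.ones_like(c), c, h_c, n, h_n, c * n])


def mad_sigma(residuals) -> float:
    """Robust residual scale: 1.4826 * median(|r - median(r)|).

    Consistent for the standard deviation under normality."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("mad_sigma requires at least one residual")
    return float(MAD_SCALE * np.median(np.abs(r - np.median(r))))


# ---------------------------------------------------------------------------
# fitting


def _check_data(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("c", "n", "z"):
        if col not in data.columns:
            raise ValidationError(f"data missing column {col!r}")
    if data[["c", "n", "z"]].isna().any().any():
        raise ValidationError("data contain missing values")
    return data


def apply_quadrant_exclusion(
    data: pd.DataFrame,
    psi: Breakpoints = Breakpoints(),
    min_quadrant_n: int = DEFAULT_MIN_QUADRANT_N,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop birds in quadrants with fewer than ``min_quadrant_n`` members.

    Returns the retained rows (with a ``quadrant`` column) and a mapping of
    excluded quadrant labels to the recorded reason.
    """
    data = _check_data(data).copy()
    data["quadrant"] = assign_quadrant(data["c"].to_numpy(), data["n"].to_numpy(), psi)
    counts = data["quadrant"].value_counts()
    excluded = {}
    for q in QUADRANTS:
        n_q = int(counts.get(q, 0))
        if 0 < n_q < min_quadrant_n:
            excluded[q] = f"insufficient sample size (n = {n_q} < {min_quadrant_n})"
    retained = data[~data["quadrant"].isin(excluded)].copy()
    return retained, excluded


def _ols_hc1(y: np.ndarray, x: np.ndarray):
    model = sm.OLS(y, x)
    return model.fit(cov_type="HC1", use_t=False)


def fit_bivariate_segmented(
    data: pd.DataFrame,
    psi: Breakpoints = Breakpoints(),
    min_quadrant_n: int = DEFAULT_MIN_QUADRANT_N,
) -> SegmentedFit:
    """OLS on the hinge design over quadrant-retained birds.

    ``data`` has columns ``c``, ``n`` (consistency scores) and ``z``
    (variability score). Quadrants with fewer than ``min_quadrant_n`` birds
    are excluded with a recorded reason. Robust HC1 covariance; per-quadrant
    MAD sigma, mean response ("segment means"), centroid and RMS spread.
    """
    retained, excluded = apply_quadrant_exclusion(data, psi, min_quadrant_n)
    if len(retained) < 12:
        raise DegenerateDataError(
            f"only {len(retained)} birds retained after quadrant exclusion; need >= 12"
        )
    x = build_design(retained["c"].to_numpy(), retained["n"].to_numpy(), psi)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DegenerateDataError(
            "hinge design is rank deficient (data may span too few quadrants)"
        )
    y = retained["z"].to_numpy()
    res = _ols_hc1(y, x)
    resid = y - x @ res.params

    qstats = {}
    for q, grp in retained.groupby("quadrant"):
        idx = retained["quadrant"] == q
        pts = retained.loc[idx, ["c", "n"]].to_numpy()
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        qstats[q] = QuadrantStats(
            n=len(grp),
            mean_response=float(grp["z"].mean()),
            mad_sigma=mad_sigma(resid[idx.to_numpy()]),
            centroid=(float(centroid[0]), float(centroid[1])),
            rms_distance=float(np.sqrt(np.mean(d**2))),
        )

    return SegmentedFit(
        beta=np.asarray(res.params),
        vcov_robust=np.asarray(res.cov_params()),
        se=np.asarray(res.bse),
        p=np.asarray(res.pvalues),
        psi=psi,
        quadrant_stats=qstats,
        excluded_quadrants=excluded,
        r2=float(res.rsquared),
        min_quadrant_n=min_quadrant_n,
        data_=retained,
    )


def predict(fit: SegmentedFit, c, n) -> np.ndarray:
    return build_design(c, n, fit.psi) @ fit.beta


def distance_weighted_ci(
    fit: SegmentedFit, c: float, n: float, level: float = 0.95
) -> tuple[float, float]:
    """Distance-weighted confidence interval at one point.

    Half-width = z_crit * sigma_q * (1 + d / s_q), with sigma_q the MAD
    sigma of the point's quadrant, d the Euclidean distance to that
    quadrant's training centroid and s_q the RMS of training distances
    (s_q = 0 gives weight 1). Centered on the model prediction. Errors for
    points in excluded quadrants, where no uncertainty is defined.
    """
    q = assign_quadrant(c, n, fit.psi)
    if q in fit.excluded_quadrants:
        raise ValidationError(
            f"point ({c}, {n}) lies in excluded quadrant {q}: "
            + fit.excluded_quadrants[q]
        )
    if q not in fit.quadrant_stats:
        raise ValidationError(f"no training data in quadrant {q}")
    st = fit.quadrant_stats[q]
    z_crit = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    d = math.hypot(c - st.centroid[0], n - st.centroid[1])
    weight = 1.0 if st.rms_distance == 0 else 1.0 + d / st.rms_distance
    half = z_crit * st.mad_sigma * weight
    center = float(predict(fit, c, n)[0])
    return center - half, center + half


# ---------------------------------------------------------------------------
# validation


def _stratified_test_counts(sizes: dict[str, int], test_frac: float) -> dict[str, int]:
    """Largest-remainder allocation of ceil(n * test_frac) test slots across
    quadrants, proportional to quadrant size, leaving >= 1 training point
    per quadrant."""
    n = sum(sizes.values())
    n_test = math.ceil(n * test_frac)
    raw = {q: s * test_frac for q, s in sizes.items()}
    alloc = {q: min(int(math.floor(v)), sizes[q] - 1) for q, v in raw.items()}
    remainder = n_test - sum(alloc.values())
    order = sorted(sizes, key=lambda q: (-(raw[q] - math.floor(raw[q])), -sizes[q], q))
    i = 0
    while remainder > 0:
        q = order[i % len(order)]
        if alloc[q] < sizes[q] - 1:
            alloc[q] += 1
            remainder -= 1
        i += 1
        if i > 10 * len(order) * (n_test + 1):
            raise DegenerateDataError("cannot allocate stratified test split")
    return alloc


def _r2_rmse(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - y_hat) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("constant response; R2 undefined")
    return 1.0 - ss_res / ss_tot, float(np.sqrt(np.mean((y - y_hat) ** 2)))


def train_test_validate(
    data: pd.DataFrame,
    psi: Breakpoints = Breakpoints(),
    test_frac: float = 0.2,
    seed: int = 0,
    min_quadrant_n: int = DEFAULT_MIN_QUADRANT_N,
    max_attempts: int = 100,
) -> ValidationMetrics:
    """Quadrant-stratified 80/20 hold-out validation of the hinge model.

    Quadrant exclusion is applied before splitting; the test count is
    ceil(n_retained * test_frac), allocated across quadrants by largest
    remainder. The model is fitted on the training partition only; R2 and
    RMSE are reported for both partitions, with the test R2 computed against
    the test-set mean. If a retained quadrant ends up absent from the
    training partition the split is redrawn with a bumped seed (at most
    ``max_attempts`` times).
    """
    retained, _ = apply_quadrant_exclusion(data, psi, min_quadrant_n)
    sizes = retained["quadrant"].value_counts().to_dict()
    alloc = _stratified_test_counts(sizes, test_frac)

    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        test_idx = []
        for q, k in alloc.items():
            members = retained.index[retained["quadrant"] == q].to_numpy()
            test_idx.extend(rng.choice(members, size=k, replace=False))
        train = retained.drop(index=test_idx)
        test = retained.loc[test_idx]
        if set(train["quadrant"]) == set(retained["quadrant"]):
            break
    else:
        raise DegenerateDataError(
            f"no valid stratified split after {max_attempts} attempts"
        )

    fit = fit_bivariate_segmented(train, psi, min_quadrant_n=0)
    y_tr = train["z"].to_numpy()
    y_te = test["z"].to_numpy()
    r2_tr, rmse_tr = _r2_rmse(y_tr, predict(fit, train["c"].to_numpy(), train["n"].to_numpy()))
    r2_te, rmse_te = _r2_rmse(y_te, predict(fit, test["c"].to_numpy(), test["n"].to_numpy()))
    return ValidationMetrics(
        r2_train=r2_tr,
        r2_test=r2_te,
        rmse_train=rmse_tr,
        rmse_test=rmse_te,
        n_train=len(train),
        n_test=len(test),
        seed=seed,
        split_attempts=attempt + 1,
    )


# ---------------------------------------------------------------------------
# attribution / univariate / surface


def variance_attribution(fit: SegmentedFit, data: pd.DataFrame | None = None) -> dict[str, float]:
    """Percent of model sum of squares per term, by sequential (type-I) SS.

    Terms enter in the fixed order C, N, C-segment, N-segment, CxN after the
    intercept; each share is term SS / model SS * 100 and the shares sum to
    100. Errors when the model SS is zero.
    """
    d = fit.data_ if data is None else apply_quadrant_exclusion(data, fit.psi, fit.min_quadrant_n)[0]
    x_full = build_design(d["c"].to_numpy(), d["n"].to_numpy(), fit.psi)
    y = d["z"].to_numpy()
    col_of = {name: j for j, name in enumerate(COEF_NAMES)}

    def rss(cols: list[int]) -> float:
        beta, *_ = np.linalg.lstsq(x_full[:, cols], y, rcond=None)
        r = y - x_full[:, cols] @ beta
        return float(r @ r)

    cols = [0]  # intercept
    prev = rss(cols)
    term_ss = {}
    for name in ATTRIBUTION_ORDER:
        cols = cols + [col_of[name]]
        cur = rss(cols)
        term_ss[name] = prev - cur
        prev = cur
    model_ss = sum(term_ss.values())
    if model_ss <= 0:
        raise DegenerateDataError("model sum of squares is zero; attribution undefined")
    return {name: 100.0 * ss / model_ss for name, ss in term_ss.items()}


def fit_univariate_segmented(z, x, psi_x: float) -> UnivariateSegmentedFit:
    """Single-predictor hinge fit: z ~ 1 + x + (x - psi_x)+.

    beta_pre is the slope below the breakpoint; the post-breakpoint slope is
    beta_pre + segment_coef exactly, and the fitted line is continuous at
    psi_x. Robust (HC1) SEs with normal two-tailed p-values. Requires at
    least 3 points strictly on each side of the breakpoint.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    n_lo = int(np.sum(x <= psi_x))
    n_hi = int(np.sum(x > psi_x))
    if n_lo < 3 or n_hi < 3:
        raise DegenerateDataError(
            f"need >= 3 points on each side of psi = {psi_x} (got {n_lo}/{n_hi})"
        )
    design = np.column_stack(
        [np.ones_like(x), x, np.where(x > psi_x, x - psi_x, 0.0)]
    )
    res = _ols_hc1(z, design)
    b0, b1, b2 = res.params
    fitted = UnivariateSegmentedFit(
        intercept=float(b0),
        beta_pre=float(b1),
        segment_coef=float(b2),
        psi=float(psi_x),
        se=dict(zip(("intercept", "beta_pre", "segment"), map(float, res.bse))),
        p=dict(zip(("intercept", "beta_pre", "segment"), map(float, res.pvalues))),
        r2=float(res.rsquared),
    )
    # structural identity of the hinge parameterisation
    assert fitted.beta_post == fitted.beta_pre + fitted.segment_coef
    return fitted


@dataclass(frozen=True)
class GridSpec:
    c_min: float
    c_max: float
    n_min: float
    n_max: float
    num_c: int = 101
    num_n: int = 101


def default_grid(fit: SegmentedFit, pad: float = 0.25, num: int = 101) -> GridSpec:
    d = fit.data_
    return GridSpec(
        c_min=float(d["c"].min() - pad),
        c_max=float(d["c"].max() + pad),
        n_min=float(d["n"].min() - pad),
        n_max=float(d["n"].max() + pad),
        num_c=num,
        num_n=num,
    )


def predict_surface(
    fit: SegmentedFit, grid_spec: GridSpec | None = None, level: float = 0.95
) -> ExposureSurface:
    """Predicted variability surface over a regular isotopic-consistency grid.

    Each node carries the hinge-model prediction, its quadrant label and the
    distance-weighted CI; nodes in excluded or data-free quadrants keep the
    prediction but have no CI (NaN bounds).
    """
    gs = grid_spec or default_grid(fit)
    if gs.num_c < 1 or gs.num_n < 1:
        raise ValueError("grid must have at least one node per axis")
    cc, nn = np.meshgrid(
        np.linspace(gs.c_min, gs.c_max, gs.num_c),
        np.linspace(gs.n_min, gs.n_max, gs.num_n),
    )
    c_flat, n_flat = cc.ravel(), nn.ravel()
    z_hat = predict(fit, c_flat, n_flat)
    quadrants = assign_quadrant(c_flat, n_flat, fit.psi)
    lo = np.full_like(z_hat, np.nan)
    hi = np.full_like(z_hat, np.nan)
    z_crit = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    for q, st in fit.quadrant_stats.items():
        mask = quadrants == q
        d = np.hypot(c_flat[mask] - st.centroid[0], n_flat[mask] - st.centroid[1])
        w = np.ones_like(d) if st.rms_distance == 0 else 1.0 + d / st.rms_distance
        half = z_crit * st.mad_sigma * w
        lo[mask] = z_hat[mask] - half
        hi[mask] = z_hat[mask] + half
    table = pd.DataFrame(
        {"c": c_flat, "n": n_flat, "quadrant": quadrants,
         "z_hat": z_hat, "ci_lo": lo, "ci_hi": hi}
    )
    return ExposureSurface(table=table, psi=fit.psi, level=level)


def breakpoint_profile(
    data: pd.DataFrame,
    psi_c_grid,
    psi_n_grid,
    min_quadrant_n: int = DEFAULT_MIN_QUADRANT_N,
) -> pd.DataFrame:
    """Diagnostic R2 profile over a grid of candidate breakpoints.

    Provided for inspection only; breakpoints are fixed inputs and are never
    selected from this profile.
    """
    rows = []
    for pc in psi_c_grid:
        for pn in psi_n_grid:
            try:
                fit = fit_bivariate_segmented(
                    data, Breakpoints(pc, pn), min_quadrant_n
                )
                rows.append(dict(psi_c=pc, psi_n=pn, r2=fit.r2))
            except DegenerateDataError:
                rows.append(dict(psi_c=pc, psi_n=pn, r2=np.nan))
    return pd.DataFrame(rows)
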