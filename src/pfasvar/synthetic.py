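"""Synthetic cohort generation.

Two deliberately separate levels:

* a full-cohort generator (concentration panel + dual-tissue isotopes +
  metadata) that emulates the statistical structure the pipeline assumes —
  a two-species, five-colony design (112 birds: 67 UA, 45 UL), censored
  lognormal compound panels whose detection frequencies and detected-value
  medians follow the published summary table, a north-south colony gradient
  in delta13C/delta15N with plasma-RBC correlation rho = 0.7;
* score-space generators that draw directly from the hinge exposure surface
  or the three-component Gaussian exposure-state mixture, for parameter-
  recovery and cluster-recovery testing (PCA scores of a generated panel do
  not follow the configured surface exactly, so recovery tests use these).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import CompoundDef, default_panel
from .errors import ValidationError
from .ingest import BirdMeta, IsotopeTable, MeasurementPanel
from .segmented import Breakpoints, build_design

# ---------------------------------------------------------------------------
# published cohort summary used to parameterise the default generator
# per species/compound: (detection frequency %, detected median, min, max);
# None marks a "<MDL" entry.

COHORT_SUMMARY: dict[str, dict[str, tuple]] = {
    "UL": {
        "PFPeA": (0, None, None, None),
        "PFHxA": (0, None, None, None),
        "PFHpA": (49, 0.1, None, 0.9),
        "PFOA": (47, 0.4, None, 1.8),
        "PFNA": (100, 3.4, 0.9, 16.5),
        "PFDA": (100, 2.7, 0.4, 15.5),
        "PFUnDA": (100, 10.0, 1.3, 48.1),
        "PFDoDA": (100, 2.4, 0.3, 9.3),
        "PFTrDA": (100, 6.6, 1.2, 20.4),
        "PFBS": (33, None, None, 0.1),
        "PFHxS": (27, 0.4, None, 1.2),
        "PFHpS": (7, 1.9, 0.6, 1.9),
        "PFOS": (100, 69.8, 22.8, 203.0),
        "PFDS": (69, 1.5, None, 12.7),
        "HFPO-DA": (0, None, None, None),
    },
    "UA": {
        "PFPeA": (0, None, None, None),
        "PFHxA": (0, None, None, None),
        "PFHpA": (27, 0.1, None, 0.4),
        "PFOA": (40, 0.5, None, 2.8),
        "PFNA": (100, 4.4, 1.1, 24.2),
        "PFDA": (100, 5.6, 1.0, 21.5),
        "PFUnDA": (100, 23.3, 5.9, 95.5),
        "PFDoDA": (100, 5.0, 1.6, 17.9),
        "PFTrDA": (100, 12.9, 4.2, 38.7),
        "PFBS": (21, None, None, 0.2),
        "PFHxS": (40, 0.4, None, 1.7),
        "PFHpS": (4, 2.2, 1.6, 5.0),
        "PFOS": (100, 103.0, 23.1, 409.7),
        "PFDS": (70, 0.7, None, 7.0),
    },
}

#: published Table-2-style quadrant sample sizes (LL, LH, HH retained; HL excluded)
QUADRANT_COUNTS = {"LL": 65, "LH": 15, "HH": 26, "HL": 6}
#: published quadrant mean z_PFOS values
QUADRANT_MEANS_PFOS = {"LL": -0.3, "LH": -0.4, "HH": 0.8}

SIGMA_BOUNDS = (0.2, 2.5)


def solve_lognormal(
    df_pct: float,
    detected_median: float | None,
    vmin: float | None,
    vmax: float | None,
    mdl: float,
) -> tuple[float, float]:
    """(mu, sigma) of the lognormal generating one compound/species cell.

    Fully detected compounds: mu = log(median), sigma chosen so the printed
    min-max range holds >= 95% of the distribution. Partially detected:
    closed-form solution so that P(X > MDL) = DF and the median of the
    detected (top-DF) tail equals the printed detected median (sigma clipped
    to a physical range; DF then holds exactly and the detected median may
    drift for extreme DF). Never-detected compounds sit essentially
    entirely below the MDL.
    """
    if df_pct >= 100:
        mu = math.log(detected_median)
        sigma = min(
            math.log(detected_median / vmin), math.log(vmax / detected_median)
        ) / stats.norm.ppf(0.975)
        return mu, float(np.clip(sigma, *SIGMA_BOUNDS))
    if df_pct <= 0:
        return math.log(mdl / 3.0), 0.3
    med = detected_median if detected_median else math.sqrt(mdl * vmax)
    q1 = stats.norm.ppf(1.0 - df_pct / 100.0)  # MDL quantile
    q2 = stats.norm.ppf(1.0 - df_pct / 200.0)  # detected-tail median quantile
    sigma = (math.log(med) - math.log(mdl)) / (q2 - q1)
    sigma = float(np.clip(sigma, *SIGMA_BOUNDS))
    mu = math.log(mdl) - sigma * q1
    return mu, sigma


# ---------------------------------------------------------------------------
# configuration


@dataclass
class IsotopeColonyParams:
    """Colony-level tissue means (per mil), shared SDs and plasma-RBC rho."""

    d13c_rbc_mean: float
    d15n_rbc_mean: float
    d13c_plasma_offset: float = -0.4
    d15n_plasma_offset: float = 0.5
    d13c_sd: float = 0.7
    d15n_sd: float = 0.6
    rho_d13c: float = 0.7
    rho_d15n: float = 0.7

    def __post_init__(self) -> None:
        for rho in (self.rho_d13c, self.rho_d15n):
            if not -1 < rho < 1:
                raise ValidationError(f"rho must be in (-1, 1), got {rho}")
        if self.d13c_sd <= 0 or self.d15n_sd <= 0:
            raise ValidationError("isotope SDs must be > 0")


@dataclass
class ClusterParams:
    """Three-component Gaussian mixture in (z_PFCA, z_PFOS) space."""

    sizes: tuple[int, ...] = (46, 48, 18)
    centroids: tuple[tuple[float, float], ...] = ((0.4, -0.8), (-0.8, 0.3), (1.1, 1.3))
    sds: tuple[tuple[float, float], ...] = ((0.6, 0.6), (0.6, 0.6), (0.8, 0.9))

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.centroids) or len(self.sizes) != len(self.sds):
            raise ValidationError("cluster parameter lengths differ")
        if any(s <= 0 for sd in self.sds for s in sd):
            raise ValidationError("cluster SDs must be > 0")
        if any(n < 0 for n in self.sizes):
            raise ValidationError("cluster sizes must be >= 0")


@dataclass
class SurfaceParams:
    """Hinge-model truth for score-space generation.

    ``beta`` in the order (intercept, C slope, C segment, N slope,
    N segment, CxN); default is the published PFOS coefficient column.
    """

    beta: tuple[float, ...] = (-0.4, -0.2, 1.2, 0.1, -0.1, 0.1)
    psi_c: float = 0.2
    psi_n: float = 0.0
    noise_sd: float = 0.8
    cov_low: float = -2.5
    cov_high: float = 2.5

    def __post_init__(self) -> None:
        if len(self.beta) != 6:
            raise ValidationError("surface beta must have 6 coefficients")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")

    @property
    def psi(self) -> Breakpoints:
        return Breakpoints(self.psi_c, self.psi_n)


@dataclass
class SyntheticConfig:
    """Full parameterisation of the cohort generator."""

    design: tuple[tuple[str, str, int], ...] = (
        ("NW", "UA", 15), ("NW", "UL", 15),
        ("N", "UA", 15), ("N", "UL", 15),
        ("NE", "UA", 15), ("NE", "UL", 15),
        ("SE", "UA", 15),
        ("SW", "UA", 7),
    )
    compound_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    isotope_params: dict[str, IsotopeColonyParams] = field(default_factory=dict)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    surface_params: SurfaceParams = field(default_factory=SurfaceParams)
    #: within-class correlation of log concentrations via a shared per-bird
    #: factor; gives the PFCA-block PC1 / PFOS PC2 covariation structure
    class_rho: dict[str, float] = field(
        default_factory=lambda: {"PFCA": 0.9, "PFSA": 0.5, "ether": 0.0}
    )
    seed: int = 0

    def total_birds(self) -> int:
        return sum(n for _, _, n in self.design)

    def validate(self) -> None:
        for colony, species, n in self.design:
            if n < 0:
                raise ValidationError("design counts must be >= 0")
            if species == "UL" and colony in ("SE", "SW"):
                raise ValidationError("UL cannot be designed into southern colonies")

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["design"] = tuple(tuple(row) for row in d["design"])
        d["compound_params"] = {
            sp: {c: tuple(v) for c, v in comps.items()}
            for sp, comps in d["compound_params"].items()
        }
        d["isotope_params"] = {
            col: IsotopeColonyParams(**p) for col, p in d["isotope_params"].items()
        }
        cp = d["cluster_params"]
        d["cluster_params"] = ClusterParams(
            sizes=tuple(cp["sizes"]),
            centroids=tuple(tuple(c) for c in cp["centroids"]),
            sds=tuple(tuple(s) for s in cp["sds"]),
        )
        sp_ = dict(d["surface_params"])
        sp_["beta"] = tuple(sp_["beta"])
        d["surface_params"] = SurfaceParams(**sp_)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


_DEFAULT_ISOTOPES = {
    # north-south gradient: RBC d13C more negative in Arctic-influenced
    # northern colonies, less negative in Atlantic-influenced southern ones
    # (individual values span roughly -22 to -19); d15N highest at SE
    "NW": dict(d13c_rbc_mean=-21.2, d15n_rbc_mean=12.0),
    "N": dict(d13c_rbc_mean=-20.9, d15n_rbc_mean=12.2),
    "NE": dict(d13c_rbc_mean=-20.6, d15n_rbc_mean=12.4),
    "SE": dict(d13c_rbc_mean=-19.8, d15n_rbc_mean=13.6),
    "SW": dict(d13c_rbc_mean=-19.9, d15n_rbc_mean=13.2),
}
_D13C_SD = 0.7
_D15N_SD = 0.6
POOLED_TISSUE_R = 0.7


def _within_colony_rho(
    design, means: dict[str, float], sd: float, target: float
) -> float:
    """Within-colony plasma-RBC correlation that yields the pooled target.

    Both tissues share the colony mean structure (constant tissue offset),
    so the cohort-pooled correlation is (Vb + rho_w * Vw) / (Vb + Vw) with
    Vb the design-weighted between-colony variance of the means and
    Vw = sd^2. Solving for rho_w calibrates the generator so the pooled
    cross-colony correlation matches the published value.
    """
    weights = {}
    for colony, _, count in design:
        weights[colony] = weights.get(colony, 0) + count
    n = sum(weights.values())
    mbar = sum(w * means[c] for c, w in weights.items()) / n
    vb = sum(w * (means[c] - mbar) ** 2 for c, w in weights.items()) / n
    vw = sd**2
    rho = (target * (vb + vw) - vb) / vw
    return float(np.clip(rho, -0.99, 0.99))


def default_study_config(compounds: list[CompoundDef] | None = None) -> SyntheticConfig:
    """Default generator configuration mirroring the study cohort.

    112 birds (67 UA, 45 UL) over five colonies, compound lognormals solved
    from the published detection frequencies and detected medians, the
    north-south isotopic gradient with plasma-RBC rho = 0.7, the published
    three-component exposure-state mixture, and the published PFOS hinge
    coefficient column with noise SD 0.8.
    """
    compounds = compounds or default_panel()
    mdl_of = {c.name: c.mdl for c in compounds}
    compound_params: dict[str, dict[str, tuple[float, float]]] = {}
    for species, rows in COHORT_SUMMARY.items():
        compound_params[species] = {}
        for comp in compounds:
            df_pct, med, vmin, vmax = rows.get(comp.name, (0, None, None, None))
            compound_params[species][comp.name] = solve_lognormal(
                df_pct, med, vmin, vmax, mdl_of[comp.name]
            )
    design = SyntheticConfig().design
    rho_c = _within_colony_rho(
        design,
        {c: p["d13c_rbc_mean"] for c, p in _DEFAULT_ISOTOPES.items()},
        _D13C_SD,
        POOLED_TISSUE_R,
    )
    rho_n = _within_colony_rho(
        design,
        {c: p["d15n_rbc_mean"] for c, p in _DEFAULT_ISOTOPES.items()},
        _D15N_SD,
        POOLED_TISSUE_R,
    )
    isotope_params = {
        col: IsotopeColonyParams(
            **p, d13c_sd=_D13C_SD, d15n_sd=_D15N_SD,
            rho_d13c=rho_c, rho_d15n=rho_n,
        )
        for col, p in _DEFAULT_ISOTOPES.items()
    }
    return SyntheticConfig(
        compound_params=compound_params, isotope_params=isotope_params
    )


# ---------------------------------------------------------------------------
# generators


def generate_cohort(
    config: SyntheticConfig,
    seed: int | None = None,
    compounds: list[CompoundDef] | None = None,
) -> tuple[MeasurementPanel, IsotopeTable, BirdMeta]:
    """Draw a full synthetic cohort.

    Concentrations are lognormal, censored at the compound MDL (below-MDL
    cells carry the NaN sentinel and a censored flag, as after reading a raw
    file); isotopes are bivariate-normal (plasma, RBC) pairs with the
    configured colony means and correlation. Bit-identical under a fixed
    seed.
    """
    config.validate()
    compounds = compounds or default_panel()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    meta_rows = []
    for colony, species, count in config.design:
        for _ in range(count):
            meta_rows.append((species, colony))
    bird_ids = [f"B{i + 1:03d}" for i in range(len(meta_rows))]
    meta = BirdMeta(
        pd.DataFrame(meta_rows, columns=["species", "colony"], index=bird_ids)
    )

    values = pd.DataFrame(index=bird_ids, columns=[c.name for c in compounds], dtype=float)
    censored = pd.DataFrame(False, index=bird_ids, columns=[c.name for c in compounds])
    species_arr = meta.table["species"]
    n_birds = len(bird_ids)
    # per-bird latent exposure factor per compound class: log concentrations
    # within a class share it with weight sqrt(rho), preserving the
    # lognormal(mu, sigma) marginal while inducing the class covariation
    factors = {
        cls: rng.standard_normal(n_birds) for cls in ("PFCA", "PFSA", "ether")
    }
    for comp in compounds:
        rho = float(config.class_rho.get(comp.compound_class, 0.0))
        zlat = factors[comp.compound_class]
        eps = rng.standard_normal(n_birds)
        zmix = math.sqrt(rho) * zlat + math.sqrt(1.0 - rho) * eps
        draws = np.empty(n_birds)
        for species in ("UA", "UL"):
            mask = (species_arr == species).to_numpy()
            mu, sigma = config.compound_params[species][comp.name]
            draws[mask] = np.exp(mu + sigma * zmix[mask])
        below = draws < comp.mdl
        values[comp.name] = np.where(below, np.nan, draws)
        censored[comp.name] = below
    panel = MeasurementPanel(values=values, censored=censored, compounds=compounds)

    iso_rows = []
    colony_arr = meta.table["colony"]
    for bird in bird_ids:
        p = config.isotope_params[colony_arr[bird]]

        def cov(sd: float, rho: float) -> np.ndarray:
            return np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])

        c_pair = rng.multivariate_normal(
            [p.d13c_rbc_mean + p.d13c_plasma_offset, p.d13c_rbc_mean],
            cov(p.d13c_sd, p.rho_d13c),
        )
        n_pair = rng.multivariate_normal(
            [p.d15n_rbc_mean + p.d15n_plasma_offset, p.d15n_rbc_mean],
            cov(p.d15n_sd, p.rho_d15n),
        )
        iso_rows.append((bird, "plasma", c_pair[0], n_pair[0]))
        iso_rows.append((bird, "rbc", c_pair[1], n_pair[1]))
    iso = IsotopeTable(
        pd.DataFrame(iso_rows, columns=["bird_id", "tissue", "d13C", "d15N"])
    )
    return panel, iso, meta


def _sample_quadrant_covariates(
    rng: np.random.Generator, params: SurfaceParams, counts: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = params.cov_low, params.cov_high
    pc, pn = params.psi_c, params.psi_n
    ranges = {
        "LL": ((lo, pc), (lo, pn)),
        "LH": ((lo, pc), (pn, hi)),
        "HL": ((pc, hi), (lo, pn)),
        "HH": ((pc, hi), (pn, hi)),
    }
    cs, ns = [], []
    for q in ("LL", "LH", "HL", "HH"):
        k = counts.get(q, 0)
        (c0, c1), (n0, n1) = ranges[q]
        cs.append(rng.uniform(c0, c1, size=k))
        ns.append(rng.uniform(n0, n1, size=k))
    return np.concatenate(cs), np.concatenate(ns)


def generate_surface_data(
    params: SurfaceParams,
    n: int | None = None,
    seed: int = 0,
    quadrant_counts: dict[str, int] | None = None,
    quadrant_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score-space triples (c, n, z) from the hinge model.

    Covariates are uniform on [cov_low, cov_high]^2, or drawn per quadrant
    when ``quadrant_counts`` is given (exact per-quadrant tallies by
    construction). The response is the hinge prediction plus Gaussian noise;
    with ``quadrant_means`` the systematic part is instead the given
    per-quadrant mean (segment-mean emulation mode).
    """
    rng = np.random.default_rng(seed)
    if quadrant_counts is not None:
        c, nn = _sample_quadrant_covariates(rng, params, quadrant_counts)
    else:
        if n is None or n <= 0:
            raise ValidationError(f"n must be a positive integer, got {n}")
        c = rng.uniform(params.cov_low, params.cov_high, size=n)
        nn = rng.uniform(params.cov_low, params.cov_high, size=n)
    if quadrant_means is not None:
        from .segmented import assign_quadrant

        quads = assign_quadrant(c, nn, params.psi)
        systematic = np.array([quadrant_means.get(q, 0.0) for q in quads])
    else:
        systematic = build_design(c, nn, params.psi) @ np.asarray(params.beta)
    z = systematic + rng.normal(0.0, params.noise_sd, size=len(c))
    return pd.DataFrame({"c": c, "n": nn, "z": z})


def generate_cluster_scores(
    params: ClusterParams, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian-mixture (z_PFCA, z_PFOS) pairs with true component labels."""
    rng = np.random.default_rng(seed)
    xs, labels = [], []
    for j, (size, centroid, sd) in enumerate(
        zip(params.sizes, params.centroids, params.sds)
    ):
        xs.append(
            np.column_stack(
                [
                    rng.normal(centroid[0], sd[0], size=size),
                    rng.normal(centroid[1], sd[1], size=size),
                ]
            )
        )
        labels.extend([j] * size)
    x = np.vstack(xs)
    ids = [f"S{i + 1:03d}" for i in range(len(x))]
    scores = pd.DataFrame(x, columns=["z_pfca", "z_pfos"], index=ids)
    return scores, np.asarray(labels)
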