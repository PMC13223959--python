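"""Per-bird PFAS variability z-scores from correlation-based PCA.

The log-concentration panel is column-standardized (so the decomposition is
of the compound correlation matrix), decomposed into principal components,
and the two leading components are mapped to compound classes: one axis
dominated by the long-chain PFCAs (C9-C13) and one dominated by PFOS.
Standardized scores on those axes are the per-bird variability indices
z_PFCA and z_PFOS: zero is the cohort mean expression of the covariation
pattern, positive values mark birds whose panel deviates strongly along it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .compounds import FULLY_DETECTED, LONG_CHAIN_PFCAS
from .errors import DegenerateDataError
from .ingest import MeasurementPanel

DEFAULT_COMPOUND_SET = FULLY_DETECTED


@dataclass
class PCAResult:
    """Fitted decomposition with deterministic sign orientation.

    ``loadings`` is compound x component (unit columns); orientation signs
    are the +/-1 factors applied to the raw eigenvectors so that the PFCA
    component has positive total C9-C13 loading and the PFOS component has a
    positive PFOS loading. ``component_of_class`` maps ``"PFCA"``/``"PFOS"``
    to a component index.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    orientation_signs: np.ndarray
    compound_set: tuple[str, ...]
    component_of_class: dict[str, int]
    ambiguous_assignment: bool
    mean_: np.ndarray
    scale_: np.ndarray


@dataclass
class VariabilityScores:
    table: pd.DataFrame  # index bird_id, columns z_pfca, z_pfos


def _standardize(x: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0).to_numpy()
    scale = x.std(axis=0, ddof=1).to_numpy()
    if np.any(scale == 0) or np.any(~np.isfinite(scale)):
        bad = [c for c, s in zip(x.columns, scale) if not s > 0]
        raise DegenerateDataError(f"zero-variance compound column(s): {bad}")
    return (x.to_numpy() - mean) / scale, mean, scale


def _assign_components(loadings: pd.DataFrame) -> tuple[dict[str, int], bool]:
    """Map each compound class to the component with the largest absolute
    loading mass for that class; flag when both map to the same component."""
    pfca_mass = loadings.loc[loadings.index.isin(LONG_CHAIN_PFCAS)].abs().sum(axis=0)
    pfos_mass = (
        loadings.loc[["PFOS"]].abs().sum(axis=0)
        if "PFOS" in loadings.index
        else pd.Series(0.0, index=loadings.columns)
    )
    pfca_comp = int(np.argmax(pfca_mass.to_numpy()))
    pfos_comp = int(np.argmax(pfos_mass.to_numpy()))
    return {"PFCA": pfca_comp, "PFOS": pfos_comp}, pfca_comp == pfos_comp


def fit_variability_pca(
    log_panel: MeasurementPanel,
    compound_set: tuple[str, ...] | None = None,
    n_components: int = 2,
) -> PCAResult:
    """Fit the correlation-mode PCA of the log panel.

    ``compound_set`` defaults to the six compounds detected in every sample
    of both species (five long-chain PFCAs plus PFOS). Components are
    ordered by explained variance; signs are fixed deterministically by the
    orientation rule so scores are reproducible across linear-algebra
    backends.
    """
    compound_set = tuple(compound_set or DEFAULT_COMPOUND_SET)
    x = log_panel.values[list(compound_set)]
    if len(x) < 3:
        raise DegenerateDataError(f"need >= 3 birds, got {len(x)}")
    z, mean, scale = _standardize(x)

    pca = PCA(n_components=min(n_components, len(compound_set)))
    pca.fit(z)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=list(compound_set),
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)],
    )
    assignment, ambiguous = _assign_components(loadings)

    # deterministic orientation: PFCA component flipped so the total C9-C13
    # loading is positive, PFOS component so the PFOS loading is positive;
    # any remaining (or ambiguous) component by positive total PFCA loading,
    # falling back to a positive dominant loading
    signs = np.ones(loadings.shape[1])
    pfca_rows = [c for c in compound_set if c in LONG_CHAIN_PFCAS]
    for j in range(loadings.shape[1]):
        col = loadings.iloc[:, j]
        if not ambiguous and j == assignment["PFOS"] and "PFOS" in loadings.index:
            ref = col.loc["PFOS"]
        elif pfca_rows:
            ref = col.loc[pfca_rows].sum()
        else:
            ref = 0.0
        if ref == 0.0:
            ref = col.iloc[int(np.argmax(col.abs().to_numpy()))]
        if ref < 0:
            signs[j] = -1.0
    loadings = loadings * signs

    # correlation-matrix eigenvalue ratios (denominator = total variance p)
    evr = pca.explained_variance_ratio_.copy()
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=evr,
        orientation_signs=signs,
        compound_set=compound_set,
        component_of_class=assignment,
        ambiguous_assignment=ambiguous,
        mean_=mean,
        scale_=scale,
    )


def variability_scores(pca: PCAResult, log_panel: MeasurementPanel) -> VariabilityScores:
    """Project the log panel on the fitted axes and standardize.

    z_pfca / z_pfos are the scores on the PFCA- and PFOS-dominated
    components, standardized to cohort mean 0 and sample SD 1 (ddof=1).
    """
    if pca.ambiguous_assignment:
        raise DegenerateDataError(
            "component assignment ambiguous: the same component carries the "
            "largest loading mass for both compound classes.\n"
            f"{pca.loadings}"
        )
    x = log_panel.values[list(pca.compound_set)]
    z = (x.to_numpy() - pca.mean_) / pca.scale_
    raw = z @ pca.loadings.to_numpy()  # oriented loadings
    out = {}
    for cls, col in (("PFCA", "z_pfca"), ("PFOS", "z_pfos")):
        j = pca.component_of_class[cls]
        if pca.explained_variance_ratio[j] < 1e-10:
            raise DegenerateDataError(
                f"{cls} component carries no variance; scores undefined"
            )
        s = raw[:, j]
        sd = s.std(ddof=1)
        if not sd > 0:
            raise DegenerateDataError(f"degenerate {cls} score axis (zero SD)")
        out[col] = (s - s.mean()) / sd
    return VariabilityScores(pd.DataFrame(out, index=x.index))
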