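"""Dual-tissue isotopic consistency scores and the delta-notation primitive.

Plasma integrates diet over days to weeks while red blood cells integrate
over weeks to months; a bird whose delta values agree across the two tissues
has foraged consistently across those time scales. For each isotope a
two-variable PCA of the standardized (plasma, RBC) pair extracts the shared
level axis; the standardized first-component score is the consistency index
(d13c_consist, d15n_consist), positive when a bird sits consistently above
the cohort mean in both tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .ingest import IsotopeTable

ISOTOPES = ("d13C", "d15N")


@dataclass(frozen=True)
class TissueCorrelation:
    isotope: str
    r: float
    p: float
    n: int


@dataclass
class ConsistencyScores:
    table: pd.DataFrame  # index bird_id, columns d13c_consist, d15n_consist


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Delta notation in per mil: (R_sample / R_standard - 1) * 1000."""
    if not r_standard > 0:
        raise ValueError(f"reference isotope ratio must be > 0, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"sample isotope ratio must be >= 0, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


def tissue_correlation(iso: IsotopeTable) -> dict[str, TissueCorrelation]:
    """Pearson correlation between plasma and RBC values per isotope.

    Two-tailed p from the t distribution with n - 2 degrees of freedom.
    Requires >= 3 birds with both tissues and non-degenerate variance.
    """
    out = {}
    for isotope in ISOTOPES:
        w = iso.wide(isotope)
        n = len(w)
        if n < 3:
            raise DegenerateDataError(
                f"{isotope}: need >= 3 birds with both tissues, got {n}"
            )
        plasma = w["plasma"].to_numpy()
        rbc = w["rbc"].to_numpy()
        if plasma.std() == 0 or rbc.std() == 0:
            raise DegenerateDataError(f"{isotope}: zero variance in a tissue")
        r, p = stats.pearsonr(plasma, rbc)
        out[isotope] = TissueCorrelation(isotope=isotope, r=float(r), p=float(p), n=n)
    return out


def _consist_axis(w: pd.DataFrame, isotope: str) -> np.ndarray:
    """Standardized PC1 score of the standardized (plasma, rbc) pair.

    For a standardized 2-variable system the leading eigenvector of the
    correlation matrix is (1, 1)/sqrt(2) when r >= 0 (shared-level axis) and
    (1, -1)/sqrt(2) when r < 0 (difference axis). The construct is undefined
    in the anti-correlated case, which errors.
    """
    sd = w.std(ddof=1)
    if (sd <= 0).any():
        raise DegenerateDataError(f"{isotope}: zero variance in a tissue")
    z = (w - w.mean()) / sd
    r = float(np.corrcoef(z["plasma"], z["rbc"])[0, 1])
    if r < 0:
        raise DegenerateDataError(
            f"{isotope}: plasma and RBC values are anti-correlated (r = {r:.3f}); "
            "the shared-consistency axis is undefined. Supply an explicit sign "
            "override after inspecting the data."
        )
    score = (z["plasma"].to_numpy() + z["rbc"].to_numpy()) / np.sqrt(2.0)
    ssd = score.std(ddof=1)
    if not ssd > 0:
        raise DegenerateDataError(f"{isotope}: degenerate consistency axis")
    return (score - score.mean()) / ssd


def consistency_scores(iso: IsotopeTable) -> ConsistencyScores:
    """Per-bird consistency z-scores for both isotopes.

    Every bird must have both tissues; cohort mean 0 and sample SD 1 per
    column by construction. Orientation: both tissue loadings positive, so a
    bird consistently above the cohort mean in both tissues scores positive.
    """
    wides = {}
    for isotope in ISOTOPES:
        w = iso.wide(isotope)
        all_birds = set(iso.table["bird_id"])
        missing = sorted(all_birds - set(w.index))
        if missing:
            raise ValidationError(
                f"{isotope}: birds missing a tissue value: {missing}"
            )
        wides[isotope] = w
    if not wides["d13C"].index.equals(wides["d15N"].index):
        raise ValidationError("isotopes cover different bird sets")
    table = pd.DataFrame(
        {
            "d13c_consist": _consist_axis(wides["d13C"], "d13C"),
            "d15n_consist": _consist_axis(wides["d15N"], "d15N"),
        },
        index=wides["d13C"].index,
    )
    return ConsistencyScores(table)


def pc1_variance_ratio(r: float) -> float:
    """Explained-variance ratio of PC1 for a standardized 2-variable PCA."""
    return (1.0 + abs(r)) / 2.0
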