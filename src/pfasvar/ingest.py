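"""Reading, validation and preprocessing of cohort inputs.

Handles the three input tables (concentration panel, dual-tissue isotope
table, bird metadata), censoring of non-detects against per-compound method
detection limits, deterministic below-MDL substitution, log transformation
and Table-1-style detection summaries.

Censoring convention: a censored cell carries ``NaN`` as a value sentinel
until :func:`substitute_nondetects` replaces it; the boolean censored flag is
retained through every downstream transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import CompoundDef, default_panel, validate_panel
from .errors import SchemaError, ValidationError

SPECIES = ("UA", "UL")
COLONIES = ("NW", "N", "NE", "SE", "SW")
#: Brunnich's guillemot (UL) breeds only at the three northern colonies.
UL_COLONIES = ("NW", "N", "NE")
TISSUES = ("plasma", "rbc")

CENSORED_TOKEN = "<MDL"

SUBSTITUTION_RULES = ("half_mdl", "mdl_over_sqrt2", "zero")


@dataclass
class MeasurementPanel:
    """Bird x compound concentration matrix with per-cell censoring flags.

    ``values`` is a DataFrame indexed by bird_id with one column per
    compound; censored cells hold NaN before substitution. ``censored`` is a
    boolean DataFrame of identical shape. ``log_scale`` records whether the
    values are natural-log transformed.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    compounds: list[CompoundDef] = field(default_factory=default_panel)
    log_scale: bool = False

    def __post_init__(self) -> None:
        validate_panel(self.compounds)
        names = [c.name for c in self.compounds]
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise SchemaError(f"missing compound column(s): {', '.join(missing)}")
        self.values = self.values[names]
        self.censored = self.censored[names].astype(bool)
        self.values.index.name = "bird_id"
        self.censored.index.name = "bird_id"
        self.values.columns.name = None
        self.censored.columns.name = None
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate bird_id(s): {list(dupes)}")
        if not self.values.index.equals(self.censored.index):
            raise ValidationError("values/censored indices differ")

    @property
    def bird_ids(self) -> list[str]:
        return list(self.values.index)

    def mdl_of(self, compound: str) -> float:
        for c in self.compounds:
            if c.name == compound:
                return c.mdl
        raise KeyError(compound)


@dataclass
class BirdMeta:
    """Per-bird species and colony assignment."""

    table: pd.DataFrame  # index bird_id, columns species, colony

    def __post_init__(self) -> None:
        t = self.table
        for col in ("species", "colony"):
            if col not in t.columns:
                raise SchemaError(f"metadata missing column {col!r}")
        if not t.index.is_unique:
            raise ValidationError("duplicate bird_id in metadata")
        t.index.name = "bird_id"
        bad_sp = set(t["species"]) - set(SPECIES)
        if bad_sp:
            raise ValidationError(f"unknown species code(s): {sorted(bad_sp)}")
        bad_col = set(t["colony"]) - set(COLONIES)
        if bad_col:
            raise ValidationError(f"unknown colony code(s): {sorted(bad_col)}")
        ul_south = t[(t["species"] == "UL") & (~t["colony"].isin(UL_COLONIES))]
        if len(ul_south):
            raise ValidationError(
                "UL recorded at a southern colony (UL breeds only at NW/N/NE): "
                f"{list(ul_south.index)}"
            )


@dataclass
class IsotopeTable:
    """Long-form bird x tissue delta13C / delta15N table (per mil)."""

    table: pd.DataFrame  # columns bird_id, tissue, d13C, d15N

    def __post_init__(self) -> None:
        t = self.table
        for col in ("bird_id", "tissue", "d13C", "d15N"):
            if col not in t.columns:
                raise SchemaError(f"isotope table missing column {col!r}")
        bad = set(t["tissue"]) - set(TISSUES)
        if bad:
            raise ValidationError(f"unknown tissue code(s): {sorted(bad)}")
        if t.duplicated(subset=["bird_id", "tissue"]).any():
            raise ValidationError("duplicate (bird_id, tissue) rows")

    def wide(self, isotope: str) -> pd.DataFrame:
        """Birds x (plasma, rbc) for one isotope, complete cases only."""
        if isotope not in ("d13C", "d15N"):
            raise KeyError(isotope)
        w = self.table.pivot(index="bird_id", columns="tissue", values=isotope)
        return w.dropna()[list(TISSUES)]


# ---------------------------------------------------------------------------
# readers / writers


def _panel_from_wide(df: pd.DataFrame, compounds: list[CompoundDef]) -> MeasurementPanel:
    names = [c.name for c in compounds]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise SchemaError(f"missing compound column(s): {', '.join(missing)}")
    raw = df.set_index("bird_id")[names]
    censored = raw.apply(
        lambda s: s.astype(str).str.strip().eq(CENSORED_TOKEN), axis=0
    )
    values = raw.mask(censored).apply(pd.to_numeric)
    return MeasurementPanel(values=values, censored=censored, compounds=compounds)


def _panel_from_long(df: pd.DataFrame, compounds: list[CompoundDef]) -> MeasurementPanel:
    values = df.pivot(index="bird_id", columns="compound", values="value")
    censored = (
        df.pivot(index="bird_id", columns="compound", values="censored")
        .astype(bool)
    )
    values = values.mask(censored)
    return MeasurementPanel(values=values, censored=censored, compounds=compounds)


def read_cohort(
    conc_path: str | Path,
    iso_path: str | Path,
    meta_path: str | Path,
    compounds: list[CompoundDef] | None = None,
) -> tuple[MeasurementPanel, IsotopeTable, BirdMeta]:
    """Read and cross-validate the three cohort tables.

    The concentration file may be wide (one column per compound, ``<MDL``
    tokens for non-detects) or long (``bird_id, compound, value, censored``).
    Every panel bird must appear in the metadata.
    """
    compounds = compounds or default_panel()
    conc = pd.read_csv(conc_path)
    if "bird_id" not in conc.columns:
        raise SchemaError("concentration file missing 'bird_id' column")
    if {"compound", "value", "censored"} <= set(conc.columns):
        panel = _panel_from_long(conc, compounds)
    else:
        panel = _panel_from_wide(conc, compounds)

    meta = BirdMeta(pd.read_csv(meta_path).set_index("bird_id"))
    iso_raw = pd.read_csv(iso_path)
    iso_raw = iso_raw.rename(
        columns={"d13C_permil": "d13C", "d15N_permil": "d15N"}
    )
    iso = IsotopeTable(iso_raw)

    unknown = set(panel.bird_ids) - set(meta.table.index)
    if unknown:
        raise ValidationError(f"panel bird(s) missing metadata: {sorted(unknown)}")
    unknown_iso = set(iso.table["bird_id"]) - set(meta.table.index)
    if unknown_iso:
        raise ValidationError(
            f"isotope bird(s) missing metadata: {sorted(unknown_iso)}"
        )
    return panel, iso, meta


def write_cohort(
    panel: MeasurementPanel,
    iso: IsotopeTable,
    meta: BirdMeta,
    conc_path: str | Path,
    iso_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write the three tables in the dialects :func:`read_cohort` accepts.

    The panel is written wide with ``<MDL`` tokens, so an unsubstituted panel
    round-trips exactly (values, flags, metadata)."""
    out = panel.values.astype(object).copy()
    out = out.mask(panel.censored, CENSORED_TOKEN)
    out.index.name = "bird_id"
    out.reset_index().to_csv(conc_path, index=False)
    iso.table.rename(
        columns={"d13C": "d13C_permil", "d15N": "d15N_permil"}
    ).to_csv(iso_path, index=False)
    meta.table.reset_index().rename(columns={"index": "bird_id"}).to_csv(
        meta_path, index=False
    )


# ---------------------------------------------------------------------------
# preprocessing


def substitute_nondetects(panel: MeasurementPanel, rule: str = "half_mdl") -> MeasurementPanel:
    """Replace censored cells by a deterministic below-MDL value.

    Rules: ``half_mdl`` (MDL/2, default), ``mdl_over_sqrt2`` (MDL/sqrt(2)),
    ``zero``. Uncensored cells are untouched; censoring flags are retained.
    Idempotent: re-applying the same rule is a no-op.
    """
    if rule not in SUBSTITUTION_RULES:
        raise ValueError(f"unknown substitution rule {rule!r}")
    values = panel.values.copy()
    for comp in panel.compounds:
        if rule == "half_mdl":
            sub = comp.mdl / 2.0
        elif rule == "mdl_over_sqrt2":
            sub = comp.mdl / math.sqrt(2.0)
        else:
            sub = 0.0
        mask = panel.censored[comp.name]
        values.loc[mask, comp.name] = sub
    return replace(panel, values=values)


def log_transform(panel: MeasurementPanel) -> MeasurementPanel:
    """Natural-log transform every cell; censoring flags preserved.

    Raises on non-positive cells (e.g. after the ``zero`` substitution rule),
    naming the offending bird and compound.
    """
    if panel.log_scale:
        raise ValueError("panel is already on the log scale")
    vals = panel.values
    if vals.isna().any().any():
        bad = vals.isna().stack()
        bird, comp = bad[bad].index[0]
        raise ValidationError(
            f"unsubstituted censored cell at bird {bird!r}, compound {comp!r}; "
            "run substitute_nondetects first"
        )
    nonpos = vals <= 0
    if nonpos.any().any():
        bad = nonpos.stack()
        bird, comp = bad[bad].index[0]
        raise ValidationError(
            f"non-positive concentration at bird {bird!r}, compound {comp!r}: "
            "log transform undefined (did you substitute non-detects with zero?)"
        )
    return replace(panel, values=np.log(vals), log_scale=True)


def detection_summary(panel: MeasurementPanel, meta: BirdMeta) -> pd.DataFrame:
    """Per (species, compound) detection frequency and detected-value summary.

    DF is 100 * n_detected / n, rounded to integer percent. Median, min and
    max are computed over uncensored (detected) values only. A compound with
    no detected value in a species reports DF ``"n.d."`` and summaries
    ``"<MDL"`` in the formatted columns (numeric columns carry NaN).
    """
    rows = []
    for species in SPECIES:
        ids = meta.table.index[meta.table["species"] == species]
        ids = [b for b in ids if b in panel.values.index]
        if not ids:
            raise ValidationError(f"no birds for species {species!r}")
        vals = panel.values.loc[ids]
        cens = panel.censored.loc[ids]
        for comp in panel.compounds:
            det = vals.loc[~cens[comp.name], comp.name].dropna()
            n = len(ids)
            n_det = int((~cens[comp.name]).sum())
            df_pct = 100.0 * n_det / n
            if n_det == 0:
                rows.append(
                    dict(species=species, compound=comp.name, n=n, n_detected=0,
                         df_pct=np.nan, median=np.nan, min=np.nan, max=np.nan,
                         df_label="n.d.", median_label=CENSORED_TOKEN,
                         min_label=CENSORED_TOKEN, max_label=CENSORED_TOKEN)
                )
            else:
                rows.append(
                    dict(species=species, compound=comp.name, n=n, n_detected=n_det,
                         df_pct=float(round(df_pct)), median=float(det.median()),
                         min=float(det.min()), max=float(det.max()),
                         df_label=f"{round(df_pct):.0f}",
                         median_label=f"{det.median():g}",
                         min_label=f"{det.min():g}", max_label=f"{det.max():g}")
                )
    return pd.DataFrame(rows)
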