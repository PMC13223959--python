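"""Compound panel definitions.

The default panel is the 15-analyte plasma PFAS panel used throughout the
package: nine perfluoroalkyl carboxylic acids (PFCAs, C5-C13), five
perfluoroalkyl sulfonic acids (PFSAs, C4-C10) and the ether carboxylic acid
HFPO-DA. Method detection limits (MDLs) are in panel units (ng g-1 dry mass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .errors import ValidationError

COMPOUND_CLASSES = ("PFCA", "PFSA", "ether")

#: Long-chain PFCAs (C9-C13) that dominate the carboxylate covariation axis.
LONG_CHAIN_PFCAS = ("PFNA", "PFDA", "PFUnDA", "PFDoDA", "PFTrDA")

#: Compounds detected in every sample of both species; default PCA set.
FULLY_DETECTED = ("PFNA", "PFDA", "PFUnDA", "PFDoDA", "PFTrDA", "PFOS")


@dataclass(frozen=True)
class CompoundDef:
    """One analyte of the concentration panel.

    Parameters
    ----------
    name
        Analyte label, e.g. ``"PFOS"``.
    compound_class
        One of ``"PFCA"``, ``"PFSA"``, ``"ether"``.
    chain_length
        Carbon count of the perfluorinated backbone.
    mdl
        Method detection limit in ng g-1 dry mass; must be positive.
    """

    name: str
    compound_class: str
    chain_length: int
    mdl: float

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(
                f"unknown compound class {self.compound_class!r} for {self.name}"
            )
        if not self.mdl > 0:
            raise ValidationError(f"MDL must be > 0 for {self.name}, got {self.mdl}")
        if self.chain_length < 1:
            raise ValidationError(f"chain length must be >= 1 for {self.name}")


_DEFAULT_MDL = 0.06  # midpoint of the reported 0.05-0.07 MDL range

_DEFAULT_SPECS = [
    # (name, class, chain length)
    ("PFPeA", "PFCA", 5),
    ("PFHxA", "PFCA", 6),
    ("PFHpA", "PFCA", 7),
    ("PFOA", "PFCA", 8),
    ("PFNA", "PFCA", 9),
    ("PFDA", "PFCA", 10),
    ("PFUnDA", "PFCA", 11),
    ("PFDoDA", "PFCA", 12),
    ("PFTrDA", "PFCA", 13),
    ("PFBS", "PFSA", 4),
    ("PFHxS", "PFSA", 6),
    ("PFHpS", "PFSA", 7),
    ("PFOS", "PFSA", 8),
    ("PFDS", "PFSA", 10),
    ("HFPO-DA", "ether", 6),
]


def default_panel() -> list[CompoundDef]:
    """The default 15-compound panel with a uniform 0.06 ng g-1 DM MDL."""
    return [
        CompoundDef(name, cls, chain, _DEFAULT_MDL)
        for name, cls, chain in _DEFAULT_SPECS
    ]


def validate_panel(compounds: list[CompoundDef]) -> None:
    names = [c.name for c in compounds]
    if len(set(names)) != len(names):
        raise ValidationError("compound names must be unique")


def write_compounds(compounds: list[CompoundDef], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(c) for c in compounds], indent=2))


def read_compounds(path: str | Path) -> list[CompoundDef]:
    records = json.loads(Path(path).read_text())
    compounds = [CompoundDef(**r) for r in records]
    validate_panel(compounds)
    return compounds
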