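"""Reference compound library and monoisotopic-mass computation.

A :class:`CompoundLibrary` is the annotation target set: named
metabolites with monoisotopic masses (computed from elemental formulas
where available) and database cross-references (HMDB, PubChem, LIPID
MAPS). Records flagged as common drugs or non-human metabolites are
loaded but excluded from the default matching set.

The six MS/MS-confirmed plasma mTBI panel analytes ship built in, with
their expected ESI modes and the direction of abundance change with
injury as metadata; a larger packaged library of common plasma
metabolites and lipid series supports realistic simulation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from pyteomics import mass as _pyteomics_mass

#: maximum tolerated disagreement between a stored mass and the mass
#: recomputed from the record's formula
FORMULA_MASS_TOL = 0.005

_FORMULA_RE = re.compile(r"^(?:[A-Z][a-z]?\d*)+$")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, in Da.

    >>> round(monoisotopic_mass("C18H36O2"), 4)
    284.2715
    """
    if not formula or not _FORMULA_RE.match(formula):
        raise ValueError(f"cannot parse elemental formula {formula!r}")
    try:
        return float(_pyteomics_mass.calculate_mass(formula=formula))
    except Exception as exc:  # unknown element symbol
        raise ValueError(f"cannot compute mass for formula {formula!r}: {exc}") from None


@dataclass(frozen=True)
class CompoundRecord:
    """A reference metabolite."""

    name: str
    monoisotopic_mass: float
    formula: str | None = None
    compound_class: str = ""
    hmdb_id: str | None = None
    pubchem_id: str | None = None
    lipidmaps_id: str | None = None
    is_drug_or_nonhuman: bool = False
    #: preferred ESI mode for detection (used by the simulator); None = either
    esi_mode: str | None = None
    #: direction of abundance change in cases ("up"/"down"); None if unknown
    tbi_direction: str | None = None

    def __post_init__(self):
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: monoisotopic mass must be positive")
        if self.formula:
            computed = monoisotopic_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) > FORMULA_MASS_TOL:
                raise ValueError(
                    f"{self.name}: stored mass {self.monoisotopic_mass} disagrees with "
                    f"formula mass {computed:.4f} by more than {FORMULA_MASS_TOL} Da"
                )


@dataclass
class CompoundLibrary:
    """An ordered set of uniquely named reference metabolites."""

    records: list[CompoundRecord]
    source_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def matchable(self) -> list[CompoundRecord]:
        """Records eligible for m/z matching (drugs/non-human excluded)."""
        return [r for r in self.records if not r.is_drug_or_nonhuman]

    def filter_class(self, classes: set[str] | list[str]) -> "CompoundLibrary":
        """Whitelist by compound class (e.g. a targeted-kit membership filter)."""
        keep = set(classes)
        return CompoundLibrary(
            records=[r for r in self.records if r.compound_class in keep],
            source_names=self.source_names,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "formula": [r.formula or "" for r in self.records],
                "monoisotopic_mass": [r.monoisotopic_mass for r in self.records],
                "compound_class": [r.compound_class for r in self.records],
                "hmdb_id": [r.hmdb_id or "" for r in self.records],
                "pubchem_id": [r.pubchem_id or "" for r in self.records],
                "lipidmaps_id": [r.lipidmaps_id or "" for r in self.records],
                "is_drug_or_nonhuman": [r.is_drug_or_nonhuman for r in self.records],
                "esi_mode": [r.esi_mode or "" for r in self.records],
                "tbi_direction": [r.tbi_direction or "" for r in self.records],
            }
        )


def load_library(path: str | Path) -> CompoundLibrary:
    """Load a compound library from delimited text.

    Each record needs a ``name`` plus a ``formula`` and/or a
    ``monoisotopic_mass``; records whose stored mass disagrees with their
    formula mass by more than ``FORMULA_MASS_TOL`` Da are rejected with a
    warning rather than silently kept.
    """
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValueError(f"{path}: library file needs a 'name' column")
    records = []
    for _, row in df.iterrows():
        formula = str(row["formula"]) if ("formula" in df.columns and pd.notna(row.get("formula")) and str(row.get("formula"))) else None
        mass_val = row.get("monoisotopic_mass")
        has_mass = "monoisotopic_mass" in df.columns and pd.notna(mass_val)
        if not formula and not has_mass:
            raise ValueError(f"{path}: record {row['name']!r} has neither formula nor mass")
        stored = float(mass_val) if has_mass else monoisotopic_mass(formula)
        try:
            records.append(
                CompoundRecord(
                    name=str(row["name"]),
                    formula=formula,
                    monoisotopic_mass=stored,
                    compound_class=str(row.get("compound_class", "") or ""),
                    hmdb_id=_opt(row.get("hmdb_id")),
                    pubchem_id=_opt(row.get("pubchem_id")),
                    lipidmaps_id=_opt(row.get("lipidmaps_id")),
                    is_drug_or_nonhuman=bool(row.get("is_drug_or_nonhuman", False)),
                    esi_mode=_opt(row.get("esi_mode")),
                    tbi_direction=_opt(row.get("tbi_direction")),
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting library record {row['name']!r}: {exc}")
    return CompoundLibrary(records=records, source_names=[str(path)])


def _opt(v) -> str | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or str(v) in ("", "nan"):
        return None
    return str(v)


# ----------------------------------------------------------------------
# built-in libraries

# The MS/MS-confirmed six-metabolite plasma mTBI panel: monoisotopic
# masses, database IDs, detection mode and direction of change in cases.
_PANEL_SIX = [
    CompoundRecord(
        name="FA 2-OH C16:0", formula="C16H32O3", monoisotopic_mass=272.2350,
        compound_class="FA", hmdb_id="HMDB31057", pubchem_id="92836",
        lipidmaps_id="LMFA01050047", esi_mode="NEG", tbi_direction="down",
    ),
    CompoundRecord(
        name="FA C18:0", formula="C18H36O2", monoisotopic_mass=284.2720,
        compound_class="FA", hmdb_id="HMDB00827", pubchem_id="5281",
        lipidmaps_id="LMFA01010018", esi_mode="NEG", tbi_direction="up",
    ),
    CompoundRecord(
        name="TUDCA", formula="C26H45NO6S", monoisotopic_mass=499.2968,
        compound_class="bile acid", hmdb_id="HMDB00874", pubchem_id="9848818",
        lipidmaps_id="LMST05040015", esi_mode="NEG", tbi_direction="down",
    ),
    CompoundRecord(
        # plasmalogen PE P-16:0/20:4; two HMDB entries exist for the species
        name="PE ae C36:4", formula="C41H74NO7P", monoisotopic_mass=723.5203,
        compound_class="PE", hmdb_id="HMDB11352;HMDB11353", pubchem_id="52925126",
        lipidmaps_id="LMGP02030093", esi_mode="NEG", tbi_direction="up",
    ),
    CompoundRecord(
        name="PE aa C38:6", formula="C43H74NO8P", monoisotopic_mass=763.5152,
        compound_class="PE", hmdb_id="HMDB08946", pubchem_id="9546799",
        lipidmaps_id="LMGP02010095", esi_mode="NEG", tbi_direction="down",
    ),
    CompoundRecord(
        name="LysoPC a C20:4", formula="C28H50NO7P", monoisotopic_mass=543.3325,
        compound_class="LysoPC", hmdb_id="HMDB10395", pubchem_id="24779476",
        lipidmaps_id="LMGP01050048", esi_mode="POS", tbi_direction="up",
    ),
]


def builtin_panel_library() -> CompoundLibrary:
    """The six MS/MS-confirmed mTBI plasma panel metabolites."""
    return CompoundLibrary(records=list(_PANEL_SIX), source_names=["builtin-panel"])


def builtin_reference_library() -> CompoundLibrary:
    """Packaged plasma-metabolome reference library (~300 compounds).

    A synthetic stand-in for an HMDB/Metlin/LIPID MAPS snapshot: common
    polar metabolites plus homologous lipid series with formula-derived
    masses spanning the 50-1200 Da scan range. Includes the six
    confirmed panel analytes; intended for annotation exercises and
    simulation, not compound identification against real data.
    """
    data = resources.files("mzpanel").joinpath("data/synthetic_reference_library.csv")
    with resources.as_file(data) as p:
        lib = load_library(p)
    lib.source_names = ["builtin-synthetic-reference"]
    return lib
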