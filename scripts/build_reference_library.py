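"""Regenerate the packaged synthetic reference library CSV.

Builds ~300 plasma-relevant compound records: common polar metabolites
with literature formulas, plus homologous lipid series (FA, 2-OH FA,
acylcarnitine, DAG, LysoPA, LysoPC, LysoPE, LysoPI, PC, PE, PG, PS)
whose formulas follow class backbone arithmetic (backbone + fatty acyl
chains - water). Masses are computed from the formulas, so every record
satisfies the library's formula/mass agreement invariant by
construction. The file is a synthetic stand-in for a metabolome
database snapshot; compound names are real species-level labels but the
set membership is curated for simulation, not identification.

Run from the repository root:  python scripts/build_reference_library.py
"""

from pathlib import Path

import pandas as pd

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from mzpanel.library import monoisotopic_mass  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src" / "mzpanel" / "data" / "synthetic_reference_library.csv"


def chain(n: int, d: int) -> tuple[int, int]:
    """(C, H) of a fatty acyl Cn:d as free acid CnH(2n-2d)O2."""
    return n, 2 * n - 2 * d


def formula(c: int, h: int, n: int = 0, o: int = 0, p: int = 0, s: int = 0) -> str:
    parts = []
    for sym, cnt in (("C", c), ("H", h), ("N", n), ("O", o), ("P", p), ("S", s)):
        if cnt == 1:
            parts.append(sym)
        elif cnt > 1:
            parts.append(f"{sym}{cnt}")
    return "".join(parts)


def lipid_series() -> list[dict]:
    rows = []

    def add(name, cls, f, mode):
        rows.append(dict(name=name, compound_class=cls, formula=f, esi_mode=mode))

    # free fatty acids FA Cn:d = CnH(2n-2d)O2
    for n in range(10, 29):
        for d in range(0, min(6, max(0, (n - 4) // 3)) + 1):
            if (n, d) in {(18, 0), (28, 7)}:
                continue  # curated separately
            if d > 0 and n < 14:
                continue
            add(f"FA C{n}:{d}", "FA", formula(n, 2 * n - 2 * d, o=2), "NEG")
    # 2-hydroxy fatty acids (+O); skip C16:0 (panel member, curated)
    for n in (12, 14, 18, 20, 22, 24):
        add(f"FA 2-OH C{n}:0", "FA", formula(n, 2 * n, o=3), "NEG")
    # acylcarnitines: carnitine C7H15NO3 + acyl - H2O
    for n, d in [(2, 0), (3, 0), (4, 0), (5, 0), (6, 0), (8, 0), (10, 0), (12, 0),
                 (14, 0), (16, 0), (16, 2), (18, 0), (18, 1), (18, 2)]:
        c, h = chain(n, d)
        add(f"AC C{n}:{d}", "AC", formula(c + 7, h + 13, n=1, o=4), "POS")
    # diacylglycerols: glycerol + 2 acyls - 2 H2O (total carbons:double bonds)
    for n, d in [(32, 0), (32, 1), (33, 2), (34, 1), (34, 2), (36, 2), (36, 4), (38, 4), (38, 6)]:
        add(f"DAG aa C{n}:{d}", "DAG", formula(n + 3, 2 * n - 2 * d + 4, o=5), "POS")
    # lysophosphatidic acids: glycerophosphate + acyl - H2O
    for n, d in [(15, 1), (16, 0), (18, 0), (18, 1), (18, 2), (20, 4), (22, 6)]:
        add(f"LysoPA a C{n}:{d}", "LysoPA", formula(n + 3, 2 * n - 2 * d + 7, o=7, p=1), "NEG")
    # lysophosphatidylcholines (skip C20:4, panel member)
    for n, d in [(14, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2), (18, 3),
                 (20, 0), (20, 3), (20, 5), (22, 4), (22, 6), (24, 0)]:
        add(f"LysoPC a C{n}:{d}", "LysoPC", formula(n + 8, 2 * n - 2 * d + 18, n=1, o=7, p=1), "POS")
    # lysophosphatidylethanolamines
    for n, d in [(16, 0), (18, 0), (18, 1), (18, 2), (20, 4), (22, 6)]:
        add(f"LysoPE a C{n}:{d}", "LysoPE", formula(n + 5, 2 * n - 2 * d + 12, n=1, o=7, p=1), "NEG")
    # lysophosphatidylinositols
    for n, d in [(16, 0), (18, 0), (18, 1), (20, 4), (20, 5)]:
        add(f"LysoPI a C{n}:{d}", "LysoPI", formula(n + 9, 2 * n - 2 * d + 17, o=12, p=1), "NEG")
    # phosphatidylcholines, diacyl and plasmalogen (ae = aa - O)
    for n, d in [(30, 0), (32, 0), (32, 1), (34, 1), (34, 2), (34, 3), (36, 2), (36, 3),
                 (36, 4), (38, 4), (38, 5), (38, 6), (40, 6)]:
        add(f"PC aa C{n}:{d}", "PC", formula(n + 8, 2 * n - 2 * d + 16, n=1, o=8, p=1), "POS")
    for n, d in [(34, 1), (34, 4), (36, 4), (38, 4)]:
        add(f"PC ae C{n}:{d}", "PC", formula(n + 8, 2 * n - 2 * d + 16, n=1, o=7, p=1), "POS")
    # phosphatidylethanolamines (skip aa 38:6 and ae 36:4, panel members)
    for n, d in [(34, 1), (34, 2), (36, 1), (36, 2), (36, 3), (38, 4), (38, 5), (40, 6)]:
        add(f"PE aa C{n}:{d}", "PE", formula(n + 5, 2 * n - 2 * d + 10, n=1, o=8, p=1), "NEG")
    for n, d in [(34, 2), (36, 2), (36, 5), (38, 4), (38, 6), (40, 6)]:
        add(f"PE ae C{n}:{d}", "PE", formula(n + 5, 2 * n - 2 * d + 10, n=1, o=7, p=1), "NEG")
    # phosphatidylglycerols (ae = plasmalogen, -O)
    for n, d in [(32, 0), (34, 1), (36, 2)]:
        add(f"PG aa C{n}:{d}", "PG", formula(n + 6, 2 * n - 2 * d + 11, o=10, p=1), "NEG")
    for n, d in [(33, 3), (34, 1)]:
        add(f"PG ae C{n}:{d}", "PG", formula(n + 6, 2 * n - 2 * d + 11, o=9, p=1), "NEG")
    # phosphatidylserines
    for n, d in [(36, 1), (38, 4), (40, 6), (42, 6)]:
        add(f"PS aa C{n}:{d}", "PS", formula(n + 6, 2 * n - 2 * d + 10, n=1, o=10, p=1), "NEG")
    # oxylipins / curated singletons
    add("13-HODE", "oxylipin", "C18H32O3", "NEG")
    add("9-HODE", "oxylipin", "C18H32O3", "NEG")
    add("FA C28:7 n-6", "FA", formula(28, 42, o=2), "NEG")
    return rows


POLAR = [
    # (name, class, formula, mode)
    ("Glycine", "amino acid", "C2H5NO2", "POS"),
    ("Alanine", "amino acid", "C3H7NO2", "POS"),
    ("Serine", "amino acid", "C3H7NO3", "POS"),
    ("Proline", "amino acid", "C5H9NO2", "POS"),
    ("Valine", "amino acid", "C5H11NO2", "POS"),
    ("Threonine", "amino acid", "C4H9NO3", "POS"),
    ("Cysteine", "amino acid", "C3H7NO2S", "POS"),
    ("Leucine", "amino acid", "C6H13NO2", "POS"),
    ("Isoleucine", "amino acid", "C6H13NO2", "POS"),
    ("Asparagine", "amino acid", "C4H8N2O3", "NEG"),
    ("Aspartate", "amino acid", "C4H7NO4", "NEG"),
    ("Glutamine", "amino acid", "C5H10N2O3", "POS"),
    ("Glutamate", "amino acid", "C5H9NO4", "NEG"),
    ("Methionine", "amino acid", "C5H11NO2S", "POS"),
    ("Histidine", "amino acid", "C6H9N3O2", "POS"),
    ("Phenylalanine", "amino acid", "C9H11NO2", "POS"),
    ("Arginine", "amino acid", "C6H14N4O2", "POS"),
    ("Tyrosine", "amino acid", "C9H11NO3", "POS"),
    ("Tryptophan", "amino acid", "C11H12N2O2", "POS"),
    ("Lysine", "amino acid", "C6H14N2O2", "POS"),
    ("Citrulline", "amino acid", "C6H13N3O3", "POS"),
    ("Ornithine", "amino acid", "C5H12N2O2", "POS"),
    ("Carnosine", "peptide", "C9H14N4O3", "POS"),
    ("Anserine", "peptide", "C10H16N4O3", "POS"),
    ("Glutathione", "peptide", "C10H17N3O6S", "NEG"),
    ("Creatine", "organic acid", "C4H9N3O2", "POS"),
    ("Creatinine", "organic acid", "C4H7N3O", "POS"),
    ("Taurine", "organic acid", "C2H7NO3S", "NEG"),
    ("Lactate", "organic acid", "C3H6O3", "NEG"),
    ("Pyruvate", "organic acid", "C3H4O3", "NEG"),
    ("Citrate", "organic acid", "C6H8O7", "NEG"),
    ("Succinate", "organic acid", "C4H6O4", "NEG"),
    ("Fumarate", "organic acid", "C4H4O4", "NEG"),
    ("Malate", "organic acid", "C4H6O5", "NEG"),
    ("Alpha-ketoglutarate", "organic acid", "C5H6O5", "NEG"),
    ("3-Hydroxybutyrate", "organic acid", "C4H8O3", "NEG"),
    ("Kynurenine", "organic acid", "C10H12N2O3", "POS"),
    ("Kynurenic acid", "organic acid", "C10H7NO3", "NEG"),
    ("Indoxyl sulfate", "organic acid", "C8H7NO4S", "NEG"),
    ("Hippurate", "organic acid", "C9H9NO3", "NEG"),
    ("Uric acid", "purine", "C5H4N4O3", "NEG"),
    ("Hypoxanthine", "purine", "C5H4N4O", "POS"),
    ("Xanthine", "purine", "C5H4N4O2", "NEG"),
    ("Inosine", "nucleoside", "C10H12N4O5", "NEG"),
    ("Adenosine", "nucleoside", "C10H13N5O4", "POS"),
    ("Uridine", "nucleoside", "C9H12N2O6", "NEG"),
    ("Glucose", "sugar", "C6H12O6", "NEG"),
    ("Fructose", "sugar", "C6H12O6", "NEG"),
    ("Myo-inositol", "sugar", "C6H12O6", "NEG"),
    ("Sucrose", "sugar", "C12H22O11", "NEG"),
    ("Choline", "amine", "C5H13NO", "POS"),
    ("Betaine", "amine", "C5H11NO2", "POS"),
    ("Carnitine", "amine", "C7H15NO3", "POS"),
    ("Trimethylamine N-oxide", "amine", "C3H9NO", "POS"),
    ("Spermidine", "amine", "C7H19N3", "POS"),
    ("Serotonin", "amine", "C10H12N2O", "POS"),
    ("Cortisol", "steroid", "C21H30O5", "POS"),
    ("Cortisone", "steroid", "C21H28O5", "POS"),
    ("Dehydroepiandrosterone sulfate", "steroid", "C19H28O5S", "NEG"),
    ("Cholic acid", "bile acid", "C24H40O5", "NEG"),
    ("Chenodeoxycholic acid", "bile acid", "C24H40O4", "NEG"),
    ("Deoxycholic acid", "bile acid", "C24H40O4", "NEG"),
    ("Glycocholic acid", "bile acid", "C26H43NO6", "NEG"),
    ("Glycoursodeoxycholic acid", "bile acid", "C26H43NO5", "NEG"),
    ("Taurocholic acid", "bile acid", "C26H45NO7S", "NEG"),
    ("Sphingosine", "sphingolipid", "C18H37NO2", "POS"),
    ("Sphingosine 1-phosphate", "sphingolipid", "C18H38NO5P", "POS"),
    ("Pantothenate", "vitamin", "C9H17NO5", "NEG"),
    ("Riboflavin", "vitamin", "C17H20N4O6", "POS"),
    ("Nicotinamide", "vitamin", "C6H6N2O", "POS"),
    ("Biotin", "vitamin", "C10H16N2O3S", "NEG"),
]

# common drugs / xenobiotics: loaded but excluded from default matching
DRUGS = [
    ("Caffeine", "xenobiotic", "C8H10N4O2", "POS"),
    ("Acetaminophen", "xenobiotic", "C8H9NO2", "POS"),
    ("Ibuprofen", "xenobiotic", "C13H18O2", "NEG"),
    ("Salicylate", "xenobiotic", "C7H6O3", "NEG"),
]

# the six confirmed panel analytes (duplicated here so the reference
# library is self-contained for annotation and simulation)
PANEL = [
    ("FA 2-OH C16:0", "FA", "C16H32O3", "NEG", "down", "HMDB31057", "92836", "LMFA01050047"),
    ("FA C18:0", "FA", "C18H36O2", "NEG", "up", "HMDB00827", "5281", "LMFA01010018"),
    ("TUDCA", "bile acid", "C26H45NO6S", "NEG", "down", "HMDB00874", "9848818", "LMST05040015"),
    ("PE ae C36:4", "PE", "C41H74NO7P", "NEG", "up", "HMDB11352;HMDB11353", "52925126", "LMGP02030093"),
    ("PE aa C38:6", "PE", "C43H74NO8P", "NEG", "down", "HMDB08946", "9546799", "LMGP02010095"),
    ("LysoPC a C20:4", "LysoPC", "C28H50NO7P", "POS", "up", "HMDB10395", "24779476", "LMGP01050048"),
]


def main() -> None:
    rows = []
    for name, cls, f, mode, direction, hmdb, pubchem, lm in PANEL:
        rows.append(dict(name=name, compound_class=cls, formula=f, esi_mode=mode,
                         tbi_direction=direction, hmdb_id=hmdb, pubchem_id=pubchem,
                         lipidmaps_id=lm, is_drug_or_nonhuman=False))
    for r in lipid_series():
        rows.append(dict(**r, tbi_direction="", hmdb_id="", pubchem_id="",
                         lipidmaps_id="", is_drug_or_nonhuman=False))
    for name, cls, f, mode in POLAR:
        rows.append(dict(name=name, compound_class=cls, formula=f, esi_mode=mode,
                         tbi_direction="", hmdb_id="", pubchem_id="", lipidmaps_id="",
                         is_drug_or_nonhuman=False))
    for name, cls, f, mode in DRUGS:
        rows.append(dict(name=name, compound_class=cls, formula=f, esi_mode=mode,
                         tbi_direction="", hmdb_id="", pubchem_id="", lipidmaps_id="",
                         is_drug_or_nonhuman=True))
    df = pd.DataFrame(rows)
    df["monoisotopic_mass"] = [round(monoisotopic_mass(f), 4) for f in df["formula"]]
    assert df["name"].is_unique, "duplicate names in generated library"
    assert df["monoisotopic_mass"].between(50, 1200).all()
    df = df[["name", "formula", "monoisotopic_mass", "compound_class", "hmdb_id",
             "pubchem_id", "lipidmaps_id", "is_drug_or_nonhuman", "esi_mode", "tbi_direction"]]
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, index=False)
    print(f"wrote {len(df)} records to {OUT}")


if __name__ == "__main__":
    main()
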