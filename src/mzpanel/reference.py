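"""Published reference values of the plasma mTBI biomarker study.

These are the printed inputs and results that the workflow can
recompute at desk scale: the confirmed six-metabolite panel's observed
m/z and monoisotopic masses, the panel ROC AUCs with their cohort group
sizes, and the cohort demographic contingency counts. They serve as
worked examples for the ``reference-stats`` command and the test suite.
"""

from __future__ import annotations

#: internal-validation (10-fold CV LR) group sizes: season <=6h mTBI
#: cases vs pooled season non-concussed controls
INTERNAL_N = (27, 36)
#: external replication cohort group sizes: TBI vs non-concussed
EXTERNAL_N = (31, 53)

#: panel name -> (internal-validation AUC, replication AUC, printed z, printed p)
PANEL_ROC_COMPARISONS = {
    "Linear SVM 6": (0.851, 0.830, 0.293, 0.770),
    "LASSO 8": (0.848, 0.811, 0.502, 0.616),
    "MS/MS 6": (0.791, 0.738, 0.633, 0.527),
}

#: confirmed panel: label -> (observed m/z, monoisotopic mass, ESI mode)
PANEL_MZ = {
    "FA 2-OH C16:0": (271.2266, 272.2350, "NEG"),
    "FA C18:0": (283.2629, 284.2720, "NEG"),
    "TUDCA": (498.2936, 499.2968, "NEG"),
    "PE ae C36:4": (722.5130, 723.5203, "NEG"),
    "PE aa C38:6": (762.5081, 763.5152, "NEG"),
    "LysoPC a C20:4": (544.3411, 543.3325, "POS"),
}

#: formula -> printed monoisotopic mass (stearic acid; TUDCA)
FORMULA_MASSES = {
    "C18H36O2": 284.272,
    "C26H45NO6S": 499.2968,
}

#: external-cohort TBI sex ratio (26 male, 5 female) vs equal proportions
SEX_GOF_COUNTS = (26, 5)
SEX_GOF_CHI2 = 14.23

#: athlete-mTBI vs external-TBI sex 2x2 table ([[22 M, 16 F], [26 M, 5 F]])
SEX_2X2_TABLE = ((22, 16), (26, 5))
SEX_2X2_CHI2 = 5.44
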