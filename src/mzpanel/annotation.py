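"""Monoisotopic-mass annotation of untargeted m/z features.

Features are matched against a compound library under singly charged
protonation adducts: a compound of neutral monoisotopic mass M is
expected at m/z = M - 1.007276 in NEG mode ([M-H]-) and M + 1.007276 in
POS mode ([M+H]+). Matching is a globally greedy best-first assignment:
all (feature, compound) candidate pairs within the mass threshold are
ordered by ascending absolute mass error, the smallest-error pair is
assigned as a primary annotation, and both members leave the primary
pool; remaining in-threshold candidates touching an already-claimed
feature or compound are emitted as flagged secondary matches. Features
with no in-threshold candidate are dropped from the annotated output
(data reduction). Annotated features are relabelled ``Name_N`` /
``Name_P`` by ESI mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureRecord, FeatureTable
from .library import CompoundLibrary, CompoundRecord
from .selection import PanelDefinition

#: mass of a proton in Da; relates neutral mass to singly charged m/z
PROTON_MASS = 1.007276

#: default matching threshold in Da (the stricter of the two documented choices)
DEFAULT_THRESHOLD = 0.01

_MODE_SUFFIX = {"NEG": "N", "POS": "P"}


def mode_label(name: str, esi_mode: str) -> str:
    """``Name_N`` / ``Name_P`` annotation label."""
    return f"{name}_{_MODE_SUFFIX[esi_mode]}"


def expected_mz(M: float, mode: str) -> float:
    """Expected m/z of a neutral mass M under [M-H]-/[M+H]+ (z = 1).

    >>> round(expected_mz(272.235, "NEG"), 4)
    271.2277
    """
    if mode == "NEG":
        if M <= PROTON_MASS:
            raise ValueError(f"neutral mass {M} too small to deprotonate")
        return M - PROTON_MASS
    if mode == "POS":
        return M + PROTON_MASS
    raise ValueError(f"unknown ESI mode {mode!r}")


@dataclass(frozen=True)
class AnnotationMatch:
    """One feature <-> compound assignment."""

    feature_id: str
    mz: float
    esi_mode: str
    compound_name: str
    mass_error: float  # observed m/z minus expected m/z, Da (signed)
    rank: str  # "primary" | "secondary"
    compound: CompoundRecord | None = None

    @property
    def label(self) -> str:
        return mode_label(self.compound_name, self.esi_mode)


@dataclass
class AnnotationResult:
    """Primary assignments plus flagged secondary matches."""

    primary: list[AnnotationMatch]
    flagged: list[AnnotationMatch]
    threshold: float
    n_input_features: int

    @property
    def n_annotated(self) -> int:
        return len(self.primary)

    def to_frame(self, which: str = "primary") -> pd.DataFrame:
        matches = self.primary if which == "primary" else self.flagged
        return pd.DataFrame(
            {
                "label": [m.label for m in matches],
                "feature_id": [m.feature_id for m in matches],
                "mz": [m.mz for m in matches],
                "esi_mode": [m.esi_mode for m in matches],
                "compound_name": [m.compound_name for m in matches],
                "mass_error": [m.mass_error for m in matches],
            }
        )


def match_features(
    features: list[FeatureRecord] | pd.DataFrame,
    library: CompoundLibrary,
    threshold: float = DEFAULT_THRESHOLD,
) -> AnnotationResult:
    """Greedy best-first matching of features to library masses.

    Candidate pairs are every (feature, compound) combination whose
    absolute mass error under the feature's ESI-mode adduct is within
    ``threshold``. Assignment proceeds in ascending |error| order
    (exact ties broken by ascending m/z, then compound name); each
    feature and each (compound, mode) can be primary only once, and all
    other in-threshold candidates become flagged secondaries.
    """
    if threshold <= 0:
        raise ValueError("matching threshold must be positive")
    matchable = library.matchable()
    if not matchable:
        raise ValueError("compound library has no matchable records")
    if isinstance(features, pd.DataFrame):
        features = [
            FeatureRecord(fid, row["mz"], row["esi_mode"], row.get("annotation"))
            for fid, row in features.iterrows()
        ]

    # candidate generation: vectorized threshold scan per mode
    names = [c.name for c in matchable]
    masses = np.array([c.monoisotopic_mass for c in matchable])
    candidates = []  # (|err|, mz, name, feature, compound, err)
    for mode, sign in (("NEG", -1.0), ("POS", +1.0)):
        exp = masses + sign * PROTON_MASS
        feats = [f for f in features if f.esi_mode == mode]
        if not feats:
            continue
        mzs = np.array([f.mz for f in feats])
        err = mzs[:, None] - exp[None, :]
        hit_i, hit_j = np.nonzero(np.abs(err) <= threshold)
        for i, j in zip(hit_i, hit_j):
            f = feats[i]
            candidates.append((abs(err[i, j]), f.mz, names[j], f, matchable[j], err[i, j]))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_features: set[str] = set()
    used_compounds: set[tuple[str, str]] = set()
    primary, flagged = [], []
    for _aerr, _mz, name, feat, comp, err in candidates:
        if feat.feature_id not in used_features and (name, feat.esi_mode) not in used_compounds:
            primary.append(
                AnnotationMatch(feat.feature_id, feat.mz, feat.esi_mode, name, err, "primary", comp)
            )
            used_features.add(feat.feature_id)
            used_compounds.add((name, feat.esi_mode))
        else:
            flagged.append(
                AnnotationMatch(feat.feature_id, feat.mz, feat.esi_mode, name, err, "secondary", comp)
            )
    return AnnotationResult(
        primary=primary, flagged=flagged, threshold=threshold, n_input_features=len(features)
    )


def annotate_table(
    table: FeatureTable, library: CompoundLibrary, threshold: float = DEFAULT_THRESHOLD
) -> tuple[FeatureTable, AnnotationResult]:
    """Annotate a feature table, keeping only primary-matched features.

    Returns the reduced table (columns relabelled ``Name_Mode``,
    abundances preserved) together with the full annotation result.
    Already-annotated tables pass through unchanged when every label
    matches the library exactly.
    """
    ann = table.features["annotation"]
    if len(table.features) and ann.notna().all():
        lib_labels = {mode_label(c.name, m) for c in library.matchable() for m in ("NEG", "POS")}
        if set(table.features.index) <= lib_labels:
            result = AnnotationResult([], [], threshold, table.n_features)
            return table, result

    records = [
        FeatureRecord(fid, row["mz"], row["esi_mode"], row["annotation"])
        for fid, row in table.features.iterrows()
    ]
    result = match_features(records, library, threshold)
    if not result.primary:
        warnings.warn("no features matched the library within threshold; annotated table is empty")
    order = [m for m in result.primary]
    new_ids = [m.label for m in order]
    abundances = table.abundances[[m.feature_id for m in order]].copy()
    abundances.columns = new_ids
    features = pd.DataFrame(
        {
            "mz": [m.mz for m in order],
            "esi_mode": [m.esi_mode for m in order],
            "annotation": [m.compound_name for m in order],
        },
        index=pd.Index(new_ids, name="feature_id"),
    )
    annotated = FeatureTable(
        samples=table.samples,
        features=features,
        abundances=abundances,
        transform_state=table.transform_state,
    )
    return annotated, result


def intersect_common(panel: PanelDefinition, other: FeatureTable) -> PanelDefinition:
    """Restrict a panel to labels present in another annotated table.

    Mirrors cross-cohort panel matching: analytes annotated in the
    discovery cohort but absent from the replication cohort are dropped
    (with a log message), preserving the original ordering.
    """
    present = set(other.features.index)
    kept = [lab for lab in panel.labels if lab in present]
    dropped = [lab for lab in panel.labels if lab not in present]
    if dropped:
        warnings.warn(
            f"{len(dropped)} of {len(panel.labels)} panel analyte(s) absent from the "
            f"other cohort and dropped: {dropped}"
        )
    if not kept:
        warnings.warn("no panel analytes shared with the other cohort; panel is empty")
    return PanelDefinition(labels=kept, method=panel.method, k=panel.k)
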