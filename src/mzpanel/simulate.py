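"""Two-cohort synthetic untargeted feature tables.

The generator emulates the statistical structure of an untargeted LC-MS
case/control study so every pipeline stage is testable without real
data: library compounds appear at their adduct-expected m/z plus a small
mass error; unannotatable noise features fill the 50-1200 m/z scan
range; abundances are log-normal; marker compounds are shifted on the
log scale in cases by a standardized effect d (sign = direction of
change with injury); the second cohort carries a multiplicative batch
effect and drops a configurable set of features, reproducing the
cross-cohort panel-intersection phenomenon.

Defaults describe a discovery cohort of 27 cases / 36 controls and a
replication cohort of 31 cases / 53 controls, with the six confirmed
panel metabolites at |d| = 1.5 and four decoy analytes at |d| = 1.2
that are absent from cohort 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .annotation import expected_mz
from .io import MZ_MAX, MZ_MIN, FeatureRecord, FeatureTable, SampleRecord, feature_id_for
from .library import CompoundLibrary, builtin_reference_library

#: markers: the six confirmed panel analytes, signed per direction of
#: change in cases (positive = up with injury)
DEFAULT_MARKER_EFFECTS = {
    "FA 2-OH C16:0": -1.5,
    "FA C18:0": +1.5,
    "TUDCA": -1.5,
    "PE ae C36:4": +1.5,
    "PE aa C38:6": -1.5,
    "LysoPC a C20:4": +1.5,
    # decoys: informative in cohort 1 but absent from cohort 2, so a
    # discovery top-10 panel shrinks on cross-cohort intersection
    "LysoPI a C20:5": +1.2,
    "PS aa C42:6": -1.2,
    "AC C16:2": +1.2,
    "LysoPA a C15:1": -1.2,
}

DEFAULT_DROPOUT = ("LysoPI a C20:5", "PS aa C42:6", "AC C16:2", "LysoPA a C15:1")

MARKER_NAMES = ("FA 2-OH C16:0", "FA C18:0", "TUDCA", "PE ae C36:4", "PE aa C38:6", "LysoPC a C20:4")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic two-cohort experiment."""

    seed: int
    n_cases: tuple[int, int] = (27, 31)
    n_controls: tuple[int, int] = (36, 53)
    n_noise_features_per_mode: int = 1400
    marker_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_EFFECTS))
    abundance_lognormal_sigma: float = 1.0
    mass_error_sd: float = 0.002
    batch_shift: float = 2.0
    dropout_labels: tuple[str, ...] = DEFAULT_DROPOUT
    cohort_names: tuple[str, str] = ("athlete", "external")

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(n <= 0 for n in (*self.n_cases, *self.n_controls)):
            raise ValueError("all group sizes must be positive")
        if self.abundance_lognormal_sigma <= 0:
            raise ValueError("abundance_lognormal_sigma must be positive")


def theoretical_auc(d: float) -> float:
    """Binormal single-feature AUC for standardized effect d: Phi(d/sqrt(2))."""
    return float(norm.cdf(d / np.sqrt(2.0)))


def _feature_means(library_names: list[str], seed: int) -> dict[str, float]:
    """Per-compound baseline log2 abundance, shared across cohorts."""
    rng = np.random.default_rng([seed, 982451653])
    return {name: float(mu) for name, mu in zip(library_names, rng.uniform(10.0, 20.0, len(library_names)))}


def simulate_cohort(
    config: SyntheticConfig,
    cohort_index: int,
    library: CompoundLibrary | None = None,
) -> FeatureTable:
    """Simulate one cohort's raw untargeted feature table.

    Every matchable library compound contributes a feature at
    ``expected_mz(M, mode) + N(0, mass_error_sd)``; noise features are
    uniform on the scan range, rejection-sampled to sit at least
    3 x 0.01 Da from any library expected m/z, so they are
    unannotatable at the default threshold by construction. Output is
    bit-reproducible for a given (seed, cohort_index).
    """
    if cohort_index not in (1, 2):
        raise ValueError("cohort_index must be 1 or 2")
    if library is None:
        library = builtin_reference_library()
    compounds = library.matchable()
    names = [c.name for c in compounds]
    for marker in config.marker_effects:
        if marker not in names:
            raise ValueError(f"marker label {marker!r} not in library")
    drop = set(config.dropout_labels) if cohort_index == 2 else set()
    compounds = [c for c in compounds if c.name not in drop]

    rng = np.random.default_rng([config.seed, cohort_index])
    means = _feature_means(names, config.seed)
    sigma = config.abundance_lognormal_sigma

    # every library compound repels noise in both adduct modes, so noise
    # features are unannotatable by construction
    expected_by_mode = {
        mode: [expected_mz(c.monoisotopic_mass, mode) for c in library.matchable()]
        for mode in ("NEG", "POS")
    }

    # compound-derived features
    features: list[FeatureRecord] = []
    mus: list[float] = []
    shifts: list[float] = []
    seen_ids: set[str] = set()
    for comp in compounds:
        mode = comp.esi_mode or "NEG"
        emz = expected_mz(comp.monoisotopic_mass, mode)
        mz = float(np.clip(emz + rng.normal(0.0, config.mass_error_sd), MZ_MIN, MZ_MAX))
        fid = feature_id_for(mz, mode)
        while fid in seen_ids:  # jitter exact id collisions
            mz = float(np.clip(mz + rng.normal(0.0, config.mass_error_sd), MZ_MIN, MZ_MAX))
            fid = feature_id_for(mz, mode)
        seen_ids.add(fid)
        features.append(FeatureRecord(fid, mz, mode))
        mus.append(means[comp.name])
        shifts.append(config.marker_effects.get(comp.name, 0.0) * sigma)

    # unannotatable noise features, per mode
    exclusion = 3 * 0.01
    for mode in ("NEG", "POS"):
        targets = np.array(expected_by_mode[mode]) if expected_by_mode[mode] else np.array([np.inf])
        made = 0
        while made < config.n_noise_features_per_mode:
            mz = float(rng.uniform(MZ_MIN, MZ_MAX))
            if np.min(np.abs(targets - mz)) < exclusion:
                continue
            fid = feature_id_for(mz, mode)
            if fid in seen_ids:
                continue
            seen_ids.add(fid)
            features.append(FeatureRecord(fid, mz, mode))
            mus.append(float(rng.uniform(10.0, 20.0)))
            shifts.append(0.0)
            made += 1

    n_cases = config.n_cases[cohort_index - 1]
    n_controls = config.n_controls[cohort_index - 1]
    cohort = config.cohort_names[cohort_index - 1]
    samples = [
        SampleRecord(f"{cohort}-case-{i+1:03d}", "case", cohort, str(cohort_index), "<=6h")
        for i in range(n_cases)
    ] + [
        SampleRecord(f"{cohort}-ctrl-{i+1:03d}", "control", cohort, str(cohort_index), "<=6h")
        for i in range(n_controls)
    ]
    is_case = np.array([1] * n_cases + [0] * n_controls, dtype=float)

    mu = np.asarray(mus)
    shift = np.asarray(shifts)
    log2_vals = (
        mu[None, :]
        + is_case[:, None] * shift[None, :]
        + rng.normal(0.0, sigma, size=(len(samples), len(features)))
    )
    if cohort_index == 2 and config.batch_shift not in (0.0, 1.0):
        log2_vals = log2_vals + np.log2(config.batch_shift)
    abundances = np.exp2(log2_vals)
    return FeatureTable.from_records(samples, features, abundances)


def simulate_two_cohorts(
    config: SyntheticConfig, library: CompoundLibrary | None = None
) -> tuple[FeatureTable, FeatureTable]:
    """Discovery and replication cohort pair (batch effect on cohort 2)."""
    if library is None:
        library = builtin_reference_library()
    return simulate_cohort(config, 1, library), simulate_cohort(config, 2, library)
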