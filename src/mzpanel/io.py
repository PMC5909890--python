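"""Feature-table data model and delimited-text I/O.

The central object is :class:`FeatureTable`: a samples x features matrix
of relative abundances plus sample metadata (group, cohort, batch,
timepoint) and feature metadata (m/z, ESI mode, optional annotation).
Samples are rows and features are columns internally, following the
statistics convention; XCMS-style exports with features as rows are
auto-detected and transposed on read.

Unannotated features are identified as ``"<mz>@<MODE>"`` strings so that
joins across pipeline stages remain stable; annotation replaces the id
with a ``Name_N`` / ``Name_P`` label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: instrument scan range in m/z, enforced on feature records
MZ_MIN, MZ_MAX = 50.0, 1200.0

ESI_MODES = ("NEG", "POS")

SAMPLE_META_COLUMNS = ("sample_id", "group", "cohort", "batch", "timepoint")

TRANSFORM_STATES = ("raw", "glog", "autoscaled")
_ALLOWED_TRANSITIONS = {("raw", "glog"), ("glog", "autoscaled")}


class FormatError(ValueError):
    """A file does not follow the expected table layout."""


class ValidationError(ValueError):
    """Table contents violate an invariant (negative abundance, duplicate ids, ...)."""


@dataclass(frozen=True)
class SampleRecord:
    """One analyzed specimen with its study metadata."""

    sample_id: str
    group: str
    cohort: str = ""
    batch: str = ""
    timepoint: str = ""

    def __post_init__(self):
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.group:
            raise ValidationError(f"sample {self.sample_id!r}: group must be non-empty")


@dataclass(frozen=True)
class FeatureRecord:
    """One detected m/z feature in a single ESI mode."""

    feature_id: str
    mz: float
    esi_mode: str
    annotation: str | None = None

    def __post_init__(self):
        if self.esi_mode not in ESI_MODES:
            raise ValidationError(
                f"feature {self.feature_id!r}: esi_mode must be one of {ESI_MODES}, "
                f"got {self.esi_mode!r}"
            )
        if not (MZ_MIN <= self.mz <= MZ_MAX):
            raise ValidationError(
                f"feature {self.feature_id!r}: m/z {self.mz} outside the "
                f"{MZ_MIN}-{MZ_MAX} instrument scan range"
            )


def feature_id_for(mz: float, esi_mode: str) -> str:
    """Canonical pre-annotation feature id, ``"<mz>@<MODE>"``."""
    return f"{mz:.4f}@{esi_mode}"


@dataclass
class FeatureTable:
    """Samples x features relative-abundance matrix with metadata.

    Parameters
    ----------
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns ``group``, ``cohort``, ``batch``,
        ``timepoint``.
    features : pandas.DataFrame
        Indexed by ``feature_id``; columns ``mz``, ``esi_mode``,
        ``annotation``.
    abundances : pandas.DataFrame
        Shape ``(n_samples, n_features)``; index/columns aligned with
        ``samples``/``features``. Raw tables must be non-negative.
    transform_state : str
        One of ``raw``, ``glog``, ``autoscaled``; transitions only
        raw -> glog -> autoscaled.
    """

    samples: pd.DataFrame
    features: pd.DataFrame
    abundances: pd.DataFrame
    transform_state: str = "raw"

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------------
    # construction helpers

    @classmethod
    def from_records(
        cls,
        samples: Sequence[SampleRecord],
        features: Sequence[FeatureRecord],
        abundances: np.ndarray | pd.DataFrame,
        transform_state: str = "raw",
    ) -> "FeatureTable":
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({x for x in sample_ids if sample_ids.count(x) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        sdf = pd.DataFrame(
            {
                "group": [s.group for s in samples],
                "cohort": [s.cohort for s in samples],
                "batch": [s.batch for s in samples],
                "timepoint": [s.timepoint for s in samples],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        fdf = pd.DataFrame(
            {
                "mz": [f.mz for f in features],
                "esi_mode": [f.esi_mode for f in features],
                "annotation": [f.annotation for f in features],
            },
            index=pd.Index([f.feature_id for f in features], name="feature_id"),
        )
        mat = pd.DataFrame(np.asarray(abundances, dtype=float), index=sdf.index, columns=fdf.index)
        return cls(samples=sdf, features=fdf, abundances=mat, transform_state=transform_state)

    # ------------------------------------------------------------------

    def validate(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"unknown transform_state {self.transform_state!r}")
        if self.samples.index.has_duplicates:
            dupes = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id(s): {dupes}")
        if (self.samples["group"].astype(str) == "").any():
            raise ValidationError("every sample needs a non-empty group label")
        if self.abundances.shape != (len(self.samples), len(self.features)):
            raise ValidationError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if not self.abundances.index.equals(self.samples.index):
            raise ValidationError("abundance rows not aligned with sample metadata")
        if not self.abundances.columns.equals(self.features.index):
            raise ValidationError("abundance columns not aligned with feature metadata")
        bad_mode = ~self.features["esi_mode"].isin(ESI_MODES)
        if bad_mode.any():
            raise ValidationError(
                f"invalid esi_mode for feature(s) {self.features.index[bad_mode].tolist()}"
            )
        if len(self.features):
            mz = self.features["mz"].to_numpy(dtype=float)
            out = (mz < MZ_MIN) | (mz > MZ_MAX)
            if out.any():
                raise ValidationError(
                    f"m/z outside {MZ_MIN}-{MZ_MAX} scan range for "
                    f"{self.features.index[out].tolist()}"
                )
        if self.transform_state == "raw":
            vals = self.abundances.to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValidationError("raw abundances must be non-negative")

    # ------------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return self.abundances.shape

    def groups(self) -> pd.Series:
        """Per-sample group labels, aligned with abundance rows."""
        return self.samples["group"]

    def with_transform_state(self, new_state: str) -> "FeatureTable":
        """Return a shallow state-transition copy; enforces raw->glog->autoscaled."""
        if (self.transform_state, new_state) not in _ALLOWED_TRANSITIONS:
            raise ValidationError(
                f"illegal transform transition {self.transform_state} -> {new_state}"
            )
        return FeatureTable(
            samples=self.samples,
            features=self.features,
            abundances=self.abundances,
            transform_state=new_state,
        )

    def with_abundances(self, abundances: pd.DataFrame, transform_state: str | None = None) -> "FeatureTable":
        return FeatureTable(
            samples=self.samples,
            features=self.features.loc[abundances.columns],
            abundances=abundances,
            transform_state=transform_state or self.transform_state,
        )

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.features.index]
        if missing:
            raise KeyError(f"feature id(s) not in table: {missing}")
        ids = list(feature_ids)
        return FeatureTable(
            samples=self.samples,
            features=self.features.loc[ids],
            abundances=self.abundances[ids],
            transform_state=self.transform_state,
        )

    def select_samples(self, mask: Sequence[bool] | pd.Series) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            samples=self.samples.loc[mask],
            features=self.features,
            abundances=self.abundances.loc[mask],
            transform_state=self.transform_state,
        )

    def equals(self, other: "FeatureTable", rtol: float = 1e-9) -> bool:
        """Label-exact, numerically tolerant equality."""
        if self.transform_state != other.transform_state:
            return False
        if not self.samples.index.equals(other.samples.index):
            return False
        if not self.features.index.equals(other.features.index):
            return False
        if not self.samples.fillna("").astype(str).equals(other.samples.fillna("").astype(str)):
            return False
        a = self.features["annotation"].fillna("")
        b = other.features["annotation"].fillna("")
        if not (a == b).all() or not (self.features["esi_mode"] == other.features["esi_mode"]).all():
            return False
        if not np.allclose(self.features["mz"], other.features["mz"], rtol=rtol):
            return False
        return np.allclose(
            self.abundances.to_numpy(), other.abundances.to_numpy(), rtol=rtol, equal_nan=True
        )


# ----------------------------------------------------------------------
# delimited I/O
#
# Canonical layout (samples as rows):
#
#   sample_id,group,cohort,batch,timepoint,<fid1>,<fid2>,...
#   #mz,,,,,<mz1>,<mz2>,...
#   #esi_mode,,,,,<mode1>,<mode2>,...
#   #annotation,,,,,<ann1>,<ann2>,...
#   S1,case,athlete,b1,<=6h,12034.1,...
#
# The three '#'-prefixed rows carry per-feature metadata and are the only
# non-sample rows. XCMS-style transposed exports (features as rows with
# 'mz' and 'esi_mode' columns followed by one column per sample) are
# detected from the header and transposed; sample metadata then defaults
# to empty cohort/batch/timepoint and group must be supplied separately.

_META_ROWS = ("#mz", "#esi_mode", "#annotation")


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    """Write a :class:`FeatureTable` to delimited text (canonical layout).

    The file round-trips through :func:`read_feature_table` to an equal
    table; floats are serialized with 10 significant digits.
    """
    path = Path(path)
    if table.n_features == 0:
        warnings.warn("writing a feature table with no features (metadata only)")
    fids = table.features.index.tolist()
    n_meta = len(SAMPLE_META_COLUMNS)
    lines = [sep.join(list(SAMPLE_META_COLUMNS) + fids)]
    pad = sep * (n_meta - 1)
    lines.append("#mz" + pad + "".join(sep + format(v, ".10g") for v in table.features["mz"]))
    lines.append("#esi_mode" + pad + "".join(sep + str(v) for v in table.features["esi_mode"]))
    ann = table.features["annotation"].fillna("")
    lines.append("#annotation" + pad + "".join(sep + str(v) for v in ann))
    meta = table.samples.fillna("").astype(str)
    mat = table.abundances.to_numpy()
    for i, sid in enumerate(table.samples.index):
        row = [str(sid)] + [meta.iloc[i][c] for c in ("group", "cohort", "batch", "timepoint")]
        row += [format(v, ".10g") for v in mat[i]]
        lines.append(sep.join(row))
    path.write_text("\n".join(lines) + "\n")


def read_feature_table(
    path: str | Path,
    format: str = "auto",
    sep: str = ",",
    transform_state: str = "raw",
) -> FeatureTable:
    """Read a delimited feature table.

    Parameters
    ----------
    path : path
        CSV/TSV file in either the canonical samples-as-rows layout or an
        XCMS-style transposed layout (feature rows; ``mz`` and
        ``esi_mode`` columns; one column per sample).
    format : {"auto", "canonical", "xcms"}
        Layout; ``auto`` sniffs the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().splitlines()
    if not text:
        raise FormatError(f"{path}: empty file")
    header = text[0].split(sep)
    if format == "auto":
        if header[: len(SAMPLE_META_COLUMNS)] == list(SAMPLE_META_COLUMNS):
            format = "canonical"
        elif "mz" in header and "esi_mode" in header:
            format = "xcms"
        else:
            raise FormatError(
                f"{path}: cannot detect layout; header must start with "
                f"{SAMPLE_META_COLUMNS} or contain 'mz' and 'esi_mode' columns"
            )
    if format == "canonical":
        return _read_canonical(path, text, sep, transform_state)
    if format == "xcms":
        return _read_xcms(path, sep, transform_state)
    raise ValueError(f"unknown format {format!r}")


def _read_canonical(path: Path, lines: list[str], sep: str, transform_state: str) -> FeatureTable:
    header = lines[0].split(sep)
    n_meta = len(SAMPLE_META_COLUMNS)
    fids = header[n_meta:]
    meta_rows: dict[str, list[str]] = {}
    sample_lines = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        cells = ln.split(sep)
        if cells[0] in _META_ROWS:
            meta_rows[cells[0]] = cells[n_meta:]
        else:
            sample_lines.append(cells)
    for required in ("#mz", "#esi_mode"):
        if required not in meta_rows:
            raise FormatError(f"{path}: missing per-feature metadata row {required!r}")
    try:
        mz = [float(v) for v in meta_rows["#mz"]]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric mz entry ({exc})") from None
    modes = meta_rows["#esi_mode"]
    anns = meta_rows.get("#annotation", [""] * len(fids))
    if not (len(mz) == len(modes) == len(anns) == len(fids)):
        raise FormatError(f"{path}: feature metadata rows do not match header width")
    features = [
        FeatureRecord(fid, m, mode, ann if ann else None)
        for fid, m, mode, ann in zip(fids, mz, modes, anns)
    ]
    samples, values = [], []
    for cells in sample_lines:
        if len(cells) != n_meta + len(fids):
            raise FormatError(f"{path}: row for {cells[0]!r} has {len(cells)} cells")
        samples.append(SampleRecord(*cells[:n_meta]))
        try:
            values.append([float(v) for v in cells[n_meta:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric abundance in row {cells[0]!r} ({exc})") from None
    return FeatureTable.from_records(samples, features, np.array(values, dtype=float).reshape(len(samples), len(fids)), transform_state)


def _read_xcms(path: Path, sep: str, transform_state: str) -> FeatureTable:
    df = pd.read_csv(path, sep=sep)
    for col in ("mz", "esi_mode"):
        if col not in df.columns:
            raise FormatError(f"{path}: XCMS layout requires a {col!r} column")
    meta_cols = [c for c in ("feature_id", "mz", "esi_mode", "annotation") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    features = []
    for _, row in df.iterrows():
        fid = str(row["feature_id"]) if "feature_id" in df.columns else feature_id_for(row["mz"], row["esi_mode"])
        ann = row.get("annotation")
        ann = None if (ann is None or (isinstance(ann, float) and np.isnan(ann)) or ann == "") else str(ann)
        features.append(FeatureRecord(fid, float(row["mz"]), str(row["esi_mode"]), ann))
    # transposed layout carries no per-sample study metadata
    samples = [SampleRecord(sid, group="unknown") for sid in sample_cols]
    values = df[sample_cols].to_numpy(dtype=float).T
    return FeatureTable.from_records(samples, features, values, transform_state)


def write_annotation_workbook(result, path: str | Path) -> None:
    """Write an annotation result as a two-sheet XLSX workbook.

    Sheet 1 lists primary annotated features (label, m/z, compound,
    monoisotopic mass, mass error, database IDs); sheet 2 lists flagged
    secondary matches — additional m/z values that fell within the
    matching threshold of an already-annotated compound. Sheet 2 is
    present (empty) even when nothing was flagged.
    """
    from openpyxl import Workbook  # deferred: only needed for workbook output

    path = Path(path)
    wb = Workbook()
    ws1 = wb.active
    ws1.title = "annotated"
    cols = [
        "label", "feature_id", "mz", "esi_mode", "compound_name",
        "monoisotopic_mass", "mass_error", "hmdb_id", "pubchem_id", "lipidmaps_id",
    ]
    ws1.append(cols)
    for m in result.primary:
        ws1.append(_match_row(m))
    ws2 = wb.create_sheet("flagged")
    ws2.append(cols)
    for m in result.flagged:
        ws2.append(_match_row(m))
    wb.save(path)


def _match_row(m) -> list:
    rec = m.compound
    return [
        m.label, m.feature_id, m.mz, m.esi_mode, m.compound_name,
        rec.monoisotopic_mass if rec is not None else None,
        m.mass_error,
        (rec.hmdb_id or "") if rec is not None else "",
        (rec.pubchem_id or "") if rec is not None else "",
        (rec.lipidmaps_id or "") if rec is not None else "",
    ]
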