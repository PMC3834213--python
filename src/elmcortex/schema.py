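"""Cortical feature schema and the tabular data model.

A subject is described by 340 features: five morphometric measures
(average cortical thickness, surface area, gray-matter volume, folding
index, intrinsic/mean curvature) on each of 68 cortical parcels (34
standard parcellation regions per hemisphere).  Features are indexed
1..340 in five contiguous measure blocks of 68; within each block the
34 left-hemisphere parcels come first, in the standard parcellation
order, followed by the 34 right-hemisphere parcels in the same order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MissingRegionError, ParseError, SchemaError, ValidationError

MEASURES = ("thickness", "surface_area", "volume", "folding_index", "curvature")

#: Short labels used in printed tables.
MEASURE_ABBREV = {
    "thickness": "CT",
    "surface_area": "SA",
    "volume": "V",
    "folding_index": "FI",
    "curvature": "IC",
}

HEMISPHERES = ("left", "right")
HEMI_ABBREV = {"left": "L", "right": "R"}

#: The 34 standard cortical parcellation regions, in the order FreeSurfer
#: prints them in per-hemisphere parcellation summary tables.
REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Gross lobe assignment for report grouping.
LOBE_OF_REGION = {
    **{r: "frontal" for r in (
        "caudalmiddlefrontal", "frontalpole", "lateralorbitofrontal",
        "medialorbitofrontal", "paracentral", "parsopercularis",
        "parsorbitalis", "parstriangularis", "precentral",
        "rostralmiddlefrontal", "superiorfrontal")},
    **{r: "parietal" for r in (
        "inferiorparietal", "postcentral", "precuneus", "superiorparietal",
        "supramarginal")},
    **{r: "temporal" for r in (
        "bankssts", "entorhinal", "fusiform", "inferiortemporal",
        "middletemporal", "parahippocampal", "superiortemporal",
        "temporalpole", "transversetemporal")},
    **{r: "occipital" for r in (
        "cuneus", "lateraloccipital", "lingual", "pericalcarine")},
    **{r: "cingulate" for r in (
        "caudalanteriorcingulate", "isthmuscingulate", "posteriorcingulate",
        "rostralanteriorcingulate")},
    "insula": "insular",
}

N_FEATURES = len(MEASURES) * len(HEMISPHERES) * len(REGIONS)  # 340


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature column: 1-based index plus (measure, hemisphere, region).

    Generic descriptors (for tables whose columns do not follow the
    standard schema) carry only ``index`` and ``name``.
    """

    index: int
    measure: Optional[str] = None
    hemisphere: Optional[str] = None
    region: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self):
        if self.measure is not None and self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")
        if self.hemisphere is not None and self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.name is None and self.measure is not None:
            object.__setattr__(self, "name", self.standard_name())

    @property
    def is_standard(self) -> bool:
        return self.measure is not None

    def standard_name(self) -> str:
        return (f"{MEASURE_ABBREV[self.measure]}_"
                f"{HEMI_ABBREV[self.hemisphere]}_{self.region}")

    def label(self) -> str:
        """Printed-table label, e.g. ``[271, FI, R-Transversetemporal]``."""
        if not self.is_standard:
            return f"[{self.index}, {self.name}]"
        return (f"[{self.index}, {MEASURE_ABBREV[self.measure]}, "
                f"{HEMI_ABBREV[self.hemisphere]}-{self.region.capitalize()}]")

    @property
    def lobe(self) -> Optional[str]:
        return LOBE_OF_REGION.get(self.region) if self.is_standard else None


@lru_cache(maxsize=1)
def _standard_schema_tuple() -> tuple[FeatureDescriptor, ...]:
    out = []
    idx = 0
    for measure in MEASURES:
        for hemi in HEMISPHERES:
            for region in REGIONS:
                idx += 1
                out.append(FeatureDescriptor(idx, measure, hemi, region))
    return tuple(out)


def standard_schema() -> list[FeatureDescriptor]:
    """Return the 340 standard feature descriptors, index order 1..340."""
    return list(_standard_schema_tuple())


def descriptor_for_index(index: int) -> FeatureDescriptor:
    """Look up the standard descriptor for a 1-based feature index."""
    if not 1 <= index <= N_FEATURES:
        raise ValidationError(f"feature index {index} outside 1..{N_FEATURES}")
    return _standard_schema_tuple()[index - 1]


_name_to_descriptor = None


def descriptor_for_name(name: str) -> Optional[FeatureDescriptor]:
    global _name_to_descriptor
    if _name_to_descriptor is None:
        _name_to_descriptor = {d.name: d for d in _standard_schema_tuple()}
    return _name_to_descriptor.get(name)


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary diagnosis labels.

    Labels are coded +1 for patients and -1 for controls throughout the
    package; this matches the single-output-node target construction of
    the ELM classifier and the threshold-0 decision rule.
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    descriptors: list[FeatureDescriptor]
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must all be finite")
        if self.labels.shape != (self.values.shape[0],):
            raise ValidationError("labels length must equal number of subjects")
        if self.labels.size and not np.all(np.isin(self.labels, (-1, 1))):
            raise ValidationError("labels must be coded +1 (patient) / -1 (control)")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValidationError("subject_ids length must equal number of subjects")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = sorted({s for s in self.subject_ids
                            if self.subject_ids.count(s) > 1})
            raise ValidationError(f"duplicate subject id(s): {', '.join(dupes)}")
        if len(self.descriptors) != self.values.shape[1]:
            raise ValidationError("descriptors length must equal number of columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_patients, n_controls)."""
        return int(np.sum(self.labels == 1)), int(np.sum(self.labels == -1))

    def columns_for(self, feature_indices: Sequence[int]) -> np.ndarray:
        """Map 1-based descriptor indices to 0-based column positions."""
        index_to_col = {d.index: j for j, d in enumerate(self.descriptors)}
        try:
            return np.array([index_to_col[i] for i in feature_indices], dtype=int)
        except KeyError as e:
            raise ValidationError(f"feature index {e.args[0]} not in table") from None

    def select_features(self, feature_indices: Sequence[int]) -> "FeatureTable":
        cols = self.columns_for(feature_indices)
        return FeatureTable(
            values=self.values[:, cols].copy(),
            labels=self.labels.copy(),
            subject_ids=list(self.subject_ids),
            descriptors=[self.descriptors[c] for c in cols],
            normalized=self.normalized,
        )

    def with_labels(self, labels: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.values.copy(), np.asarray(labels),
                            list(self.subject_ids), list(self.descriptors),
                            self.normalized)


def generic_descriptors(names: Sequence[str]) -> list[FeatureDescriptor]:
    return [FeatureDescriptor(i + 1, name=str(n)) for i, n in enumerate(names)]


_LABEL_STRINGS = {"adhd": 1, "patient": 1, "control": -1, "cs": -1, "healthy": -1}


def _parse_labels(series: pd.Series, column: str) -> np.ndarray:
    out = np.empty(len(series), dtype=int)
    for i, v in enumerate(series):
        if isinstance(v, str):
            key = v.strip().lower()
            if key in _LABEL_STRINGS:
                out[i] = _LABEL_STRINGS[key]
                continue
            try:
                v = int(v)
            except ValueError:
                raise ParseError(
                    f"unrecognized label {v!r} in column {column!r} (row {i})")
        if v in (1, -1):
            out[i] = int(v)
        else:
            raise ParseError(
                f"unrecognized label {v!r} in column {column!r} (row {i})")
    return out


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_table(path, label_column: str = "diagnosis") -> FeatureTable:
    """Read a delimited feature table (one subject per row, header row).

    The label column may be coded as integers {1, -1} or as strings
    {ADHD, control}.  A ``subject_id`` column is used when present.
    Column descriptors are attached from the standard schema when every
    feature column name matches it, else generic descriptors are used.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=object,
                     keep_default_na=False)
    if label_column not in df.columns:
        raise SchemaError(
            f"label column {label_column!r} not found in {path.name} "
            f"(columns: {', '.join(map(str, df.columns[:6]))}...)")
    labels = _parse_labels(df[label_column], label_column)
    if "subject_id" in df.columns:
        subject_ids = [str(s) for s in df["subject_id"]]
    else:
        subject_ids = [f"S{i + 1:04d}" for i in range(len(df))]
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
        raise ValidationError(
            f"duplicate subject id(s) in {path.name}: {', '.join(dupes)}")

    feature_cols = [c for c in df.columns if c not in (label_column, "subject_id")]
    n = len(df)
    values = np.empty((n, len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        try:
            # numpy's conversion is correctly rounded, so written values
            # re-read exactly
            values[:, j] = df[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, "
                f"column {col!r} of {path.name}") from None

    std = [descriptor_for_name(c) for c in feature_cols]
    if feature_cols and all(d is not None for d in std):
        descriptors = list(std)
    else:
        descriptors = generic_descriptors(feature_cols)
    return FeatureTable(values, labels, subject_ids, descriptors, normalized=False)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as delimited text; round-trips through read_feature_table."""
    path = Path(path)
    data = {"subject_id": table.subject_ids, "diagnosis": table.labels.astype(int)}
    for j, d in enumerate(table.descriptors):
        data[d.name or f"feature_{d.index}"] = table.values[:, j]
    pd.DataFrame(data).to_csv(path, sep=_delimiter_for(path), index=False)


# --- FreeSurfer parcellation summary parsing -------------------------------

#: parcellation-summary column holding each measure
_STATS_COLUMN = {
    "thickness": "ThickAvg",
    "surface_area": "SurfArea",
    "volume": "GrayVol",
    "folding_index": "FoldInd",
    "curvature": "MeanCurv",
}


def _parse_stats_file(path) -> dict[str, dict[str, float]]:
    """Parse one per-hemisphere stats table to {region: {column: value}}."""
    path = Path(path)
    colheaders = None
    rows = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*ColHeaders\s+(.*)", line)
            if m:
                colheaders = m.group(1).split()
            continue
        if colheaders is None:
            raise ParseError(
                f"{path.name}: data row before '# ColHeaders' line (line {lineno})")
        parts = line.split()
        if len(parts) != len(colheaders):
            raise ParseError(
                f"{path.name}: line {lineno} has {len(parts)} fields, "
                f"expected {len(colheaders)}")
        record = dict(zip(colheaders, parts))
        name = record.pop("StructName", None)
        if name is None:
            raise ParseError(f"{path.name}: no StructName column in header")
        try:
            rows[name.lower()] = {k: float(v) for k, v in record.items()}
        except ValueError as e:
            raise ParseError(f"{path.name}: line {lineno}: {e}")
    if colheaders is None:
        raise ParseError(f"{path.name}: no '# ColHeaders' line found")
    for measure_col in _STATS_COLUMN.values():
        if measure_col not in colheaders:
            raise ParseError(
                f"{path.name}: required column {measure_col!r} missing from header")
    return rows


def parse_freesurfer_stats(lh_path, rh_path, measures: Sequence[str] = MEASURES):
    """Assemble one subject's feature record from per-hemisphere stats tables.

    Returns an ordered mapping FeatureDescriptor -> value covering the
    requested measures, in standard schema order.  Region names are
    matched case-insensitively.
    """
    for m in measures:
        if m not in MEASURES:
            raise ValidationError(f"unknown measure {m!r}")
    per_hemi = {"left": _parse_stats_file(lh_path), "right": _parse_stats_file(rh_path)}
    for hemi, rows in per_hemi.items():
        missing = [r for r in REGIONS if r not in rows]
        if missing:
            raise MissingRegionError(missing, hemi)
    record = {}
    for d in standard_schema():
        if d.measure in measures:
            record[d] = per_hemi[d.hemisphere][d.region][_STATS_COLUMN[d.measure]]
    return record


def table_from_records(records, labels, subject_ids) -> FeatureTable:
    """Stack per-subject records (as from parse_freesurfer_stats) into a table."""
    if not records:
        raise ValidationError("no records supplied")
    descriptors = list(records[0].keys())
    values = np.array([[rec[d] for d in descriptors] for rec in records], float)
    return FeatureTable(values, np.asarray(labels), list(subject_ids),
                        descriptors, normalized=False)


def normalize_minmax(table: FeatureTable) -> FeatureTable:
    """Min-max normalize every column to [0, 1] over the whole cohort.

    Constant columns map to all-zeros (the feature is uninformative and
    keeps its F-score of zero).  The input table is not modified.
    """
    if table.n_subjects < 2:
        raise ValidationError("normalization needs at least 2 subjects")
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    values = (table.values - lo) / safe_span
    values[:, constant] = 0.0
    return FeatureTable(values, table.labels.copy(), list(table.subject_ids),
                        list(table.descriptors), normalized=True)
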