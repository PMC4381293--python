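"""Tabular input/output for the pipeline.

All on-disk formats are tab-separated UTF-8 text with ``.`` as the decimal
mark.  Peak tables are metabolite x sample matrices of non-negative peak
areas in the style of MzMatch/IDEOM exports; blank or NA cells are read as
*missing*, which is kept distinct from a literal zero throughout the
package.  Sample sheets carry the longitudinal study design: each urine
sample belongs to a subject, a time-point label (two pre-exercise
collections P1/P2 and eight post-exercise collections PT1..PT8) and a
phase group (PRE / POST1 / POST2).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class UrinormError(ValueError):
    """Base class for all validation errors raised by this package."""


class PeakTableError(UrinormError):
    pass


class SampleSheetError(UrinormError):
    pass


class AssayError(UrinormError):
    pass


#: Fixed mapping of collection labels to phase groups: the two pre-exercise
#: collections form PRE, the first three post-exercise collections (same
#: day as the exercise bout) form POST1 and the five next-day collections
#: form POST2.
PHASE_BY_LABEL: Mapping[str, str] = {
    "P1": "PRE",
    "P2": "PRE",
    "PT1": "POST1",
    "PT2": "POST1",
    "PT3": "POST1",
    "PT4": "POST2",
    "PT5": "POST2",
    "PT6": "POST2",
    "PT7": "POST2",
    "PT8": "POST2",
}

#: Chronological order of the collection labels.
TIMEPOINT_ORDER: tuple[str, ...] = (
    "P1", "P2", "PT1", "PT2", "PT3", "PT4", "PT5", "PT6", "PT7", "PT8",
)

ANNOTATION_COLUMNS = ("name", "mass", "rt")


def _check_unique(ids: Iterable[str], what: str, exc: type[UrinormError]) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise exc(f"duplicate {what}: {', '.join(str(d) for d in dups)}")


@dataclasses.dataclass
class PeakTable:
    """A metabolite x sample matrix of raw peak areas.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite id with one column per sample id.
        Values are float peak areas; ``NaN`` marks a missing measurement
        (distinct from a true zero).
    annotations
        DataFrame indexed by metabolite id with columns ``name`` (free
        text), ``mass`` (monoisotopic Da, optional) and ``rt`` (minutes,
        optional).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "metabolite ids", PeakTableError)
        _check_unique(self.values.columns, "sample ids", PeakTableError)
        self.values = self.values.astype(float)
        self.values.index.name = "metabolite_id"
        self.values.columns.name = None
        if (self.values.to_numpy() < 0).any():
            bad = np.argwhere(self.values.to_numpy() < 0)[0]
            raise PeakTableError(
                "negative peak area at metabolite "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        ann = self.annotations.copy()
        for col in ANNOTATION_COLUMNS:
            if col not in ann.columns:
                ann[col] = np.nan
        ann = ann.loc[:, list(ANNOTATION_COLUMNS)]
        try:
            ann = ann.reindex(self.values.index)
        except Exception as err:  # pragma: no cover - defensive
            raise PeakTableError(f"annotations do not align with values: {err}")
        if ann["name"].isna().any():
            ann["name"] = ann["name"].fillna(pd.Series(self.values.index, index=self.values.index))
        self.annotations = ann

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "PeakTable":
        return PeakTable(self.values.copy(), self.annotations.copy())


@dataclasses.dataclass
class SampleSheet:
    """Per-sample study-design metadata.

    ``frame`` is indexed by sample id with columns ``subject_id``,
    ``timepoint_label``, ``phase`` and ``collection_index`` (0-based
    chronological order within each subject).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "timepoint_label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SampleSheetError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(self.frame.index, "sample ids", SampleSheetError)
        frame = self.frame.copy()

        bad_labels = sorted(set(frame["timepoint_label"]) - set(PHASE_BY_LABEL))
        if bad_labels:
            raise SampleSheetError(f"unknown timepoint labels: {bad_labels}")

        pairs = frame[["subject_id", "timepoint_label"]].apply(tuple, axis=1)
        _check_unique(pairs, "(subject, timepoint) pairs", SampleSheetError)

        derived = frame["timepoint_label"].map(PHASE_BY_LABEL)
        if "phase" in frame.columns and frame["phase"].notna().any():
            given = frame["phase"].fillna(derived)
            conflicts = frame.index[given != derived]
            if len(conflicts):
                sid = conflicts[0]
                raise SampleSheetError(
                    f"phase {frame.loc[sid, 'phase']!r} for sample {sid!r} conflicts "
                    f"with the fixed mapping ({frame.loc[sid, 'timepoint_label']} -> "
                    f"{derived.loc[sid]})"
                )
        frame["phase"] = derived

        if "collection_index" not in frame.columns or frame["collection_index"].isna().all():
            order = {lab: i for i, lab in enumerate(TIMEPOINT_ORDER)}
            frame["collection_index"] = frame["timepoint_label"].map(order)
        frame["collection_index"] = frame["collection_index"].astype(int)
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def samples_of(self, subject_id: str) -> list[str]:
        """Sample ids of one subject in chronological (collection) order."""
        sub = self.frame[self.frame["subject_id"] == subject_id]
        if sub.empty:
            raise SampleSheetError(f"unknown subject {subject_id!r}")
        return list(sub.sort_values("collection_index").index)

    def sample_for(self, subject_id: str, timepoint_label: str) -> str | None:
        sub = self.frame[
            (self.frame["subject_id"] == subject_id)
            & (self.frame["timepoint_label"] == timepoint_label)
        ]
        return None if sub.empty else sub.index[0]

    def ordered_samples(self) -> list[str]:
        """All sample ids grouped by subject, chronological within subject."""
        out: list[str] = []
        for s in self.subjects:
            out.extend(self.samples_of(s))
        return out

    def check_covers(self, peaks: PeakTable) -> None:
        missing = sorted(set(peaks.sample_ids) - set(self.frame.index))
        if missing:
            raise SampleSheetError(f"samples without sheet rows: {missing}")


@dataclasses.dataclass
class CreatinineAssay:
    """Spectrophotometric creatinine concentrations, one per sample."""

    concentrations: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.concentrations.index, "assay sample ids", AssayError)
        self.concentrations = self.concentrations.astype(float)

    def check_positive(self, sample_ids: Iterable[str]) -> None:
        sample_ids = list(sample_ids)
        missing = sorted(set(sample_ids) - set(self.concentrations.index))
        if missing:
            raise AssayError(f"samples without assay values: {missing}")
        vals = self.concentrations.reindex(sample_ids)
        bad = sorted(vals.index[~(vals > 0)])
        if bad:
            raise AssayError(f"non-positive assay creatinine for samples: {bad}")


# ---------------------------------------------------------------------------
# readers


def _parse_numeric_cell(raw: str | float, row: str, col: str, path: Path) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text == "" or text.upper() in {"NA", "NAN", "N/A"}:
        return math.nan
    try:
        value = float(text)
    except ValueError:
        raise PeakTableError(
            f"{path}: unparseable value {text!r} at metabolite {row!r}, sample {col!r}"
        ) from None
    if value < 0:
        raise PeakTableError(
            f"{path}: negative value {value} at metabolite {row!r}, sample {col!r}"
        )
    return value


_IDEOM_HEADER_ALIASES = {
    "id": "id",
    "identifier": "id",
    "name": "name",
    "compound": "name",
    "mass": "mass",
    "rt": "rt",
    "retention time": "rt",
    "retention time (rt) (min)": "rt",
}


def read_peak_table(path: str | Path, dialect: str = "ideom_tsv") -> PeakTable:
    """Read a TSV peak table.

    ``dialect='ideom_tsv'`` expects annotation columns (id, name, mass, rt)
    before the sample columns, mirroring IDEOM-style exports;
    ``dialect='plain_tsv'`` expects exactly (metabolite id, then one column
    per sample) with no further annotations.
    """
    path = Path(path)
    if dialect not in {"ideom_tsv", "plain_tsv"}:
        raise PeakTableError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise PeakTableError(f"{path}: expected at least an id column and one sample column")

    if dialect == "ideom_tsv":
        ann_cols: dict[str, str] = {}
        sample_start = 0
        for col in raw.columns:
            key = _IDEOM_HEADER_ALIASES.get(col.strip().lower())
            if key is None or key in ann_cols:
                break
            ann_cols[key] = col
            sample_start += 1
        if "id" not in ann_cols:
            raise PeakTableError(
                f"{path}: ideom_tsv dialect requires a leading id column "
                "(then optional name/mass/rt) before the sample columns"
            )
        sample_cols = list(raw.columns[sample_start:])
        ids = raw[ann_cols["id"]].astype(str)
        ann = pd.DataFrame(index=ids)
        ann["name"] = raw[ann_cols["name"]].astype(str).values if "name" in ann_cols else ids.values
        for field in ("mass", "rt"):
            if field in ann_cols:
                ann[field] = pd.to_numeric(raw[ann_cols[field]].values, errors="coerce")
            else:
                ann[field] = np.nan
    else:
        sample_cols = list(raw.columns[1:])
        ids = raw.iloc[:, 0].astype(str)
        ann = pd.DataFrame({"name": ids.values, "mass": np.nan, "rt": np.nan}, index=ids)

    if not sample_cols:
        raise PeakTableError(f"{path}: no sample columns found")
    _check_unique(ids, "metabolite ids", PeakTableError)
    _check_unique(sample_cols, "sample ids", PeakTableError)

    values = pd.DataFrame(index=pd.Index(ids, name="metabolite_id"), columns=sample_cols, dtype=float)
    for col in sample_cols:
        values[col] = [
            _parse_numeric_cell(v, m, col, path) for v, m in zip(raw[col], ids)
        ]
    ann.index = values.index
    return PeakTable(values, ann)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet with columns sample_id, subject_id, timepoint_label.

    ``phase`` is derived from the fixed label mapping unless an explicit
    (and consistent) ``phase`` column is present; ``collection_index`` is
    derived from chronological label order unless provided.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "timepoint_label"}
    missing = required - set(frame.columns)
    if missing:
        raise SampleSheetError(f"{path}: missing columns {sorted(missing)}")
    _check_unique(frame["sample_id"], "sample ids", SampleSheetError)
    frame = frame.set_index("sample_id")
    if "collection_index" in frame.columns:
        frame["collection_index"] = pd.to_numeric(frame["collection_index"])
    return SampleSheet(frame)


def read_creatinine_assay(path: str | Path) -> CreatinineAssay:
    """Read a TSV table with columns sample_id, concentration."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "concentration"}
    missing = required - set(frame.columns)
    if missing:
        raise AssayError(f"{path}: missing columns {sorted(missing)}")
    conc = pd.to_numeric(frame["concentration"], errors="coerce")
    if conc.isna().any():
        bad = frame["sample_id"][conc.isna()].tolist()
        raise AssayError(f"{path}: unparseable concentrations for samples {bad}")
    return CreatinineAssay(pd.Series(conc.values, index=frame["sample_id"].values))


# ---------------------------------------------------------------------------
# writers


def write_report(table: pd.DataFrame, path: str | Path, float_digits: int = 4) -> None:
    """Write a tabular report as TSV with fixed significant digits."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def write_peak_table(peaks: PeakTable, path: str | Path, float_digits: int = 10) -> None:
    """Write a peak table in the ideom_tsv dialect (round-trips with
    :func:`read_peak_table` up to float rendering precision)."""
    path = Path(path)
    out = peaks.annotations.copy()
    out.insert(0, "id", peaks.values.index)
    out = pd.concat([out.reset_index(drop=True),
                     peaks.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.frame.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_creatinine_assay(assay: CreatinineAssay, path: str | Path,
                           float_digits: int = 10) -> None:
    out = pd.DataFrame({
        "sample_id": assay.concentrations.index,
        "concentration": assay.concentrations.values,
    })
    out.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")
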