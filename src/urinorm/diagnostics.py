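"""Metabolite stability profiling and time-profile extraction.

The relative standard deviation (RSD, percent coefficient of variation)
of each metabolite across the serial urine collections summarises how
stable its output is over the protocol; amino acids tend to sit at the
low end while exercise-responsive purines can exceed 100%.  Time profiles
pull one metabolite's normalised trajectory for one subject, in
collection order, for plotting against MS creatinine.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import PeakTable, SampleSheet, UrinormError
from .normalise import NormalisedTable


class DiagnosticsError(UrinormError):
    pass


RSD_COLUMNS = ("metabolite_id", "name", "mass", "rt", "subject_id",
               "n_samples", "rsd_percent", "flag")


def _rsd_one(values: np.ndarray) -> tuple[float, int, str]:
    values = values[np.isfinite(values)]
    n = values.size
    if n < 2:
        return np.nan, n, "insufficient_n"
    mean = values.mean()
    if mean <= 0:
        return np.nan, n, "undefined_mean"
    sd = values.std(ddof=1)
    return 100.0 * sd / mean, n, "ok"


def compute_rsd(table: PeakTable | NormalisedTable,
                scope: str = "all_samples",
                sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Per-metabolite RSD = 100 * sample SD / mean (SD with n-1 degrees
    of freedom, the QC-reporting convention).

    ``scope='all_samples'`` pools every sample (the Table-1 style report
    over all 30 collections); ``scope='per_subject'`` emits one record
    per (metabolite, subject) and requires ``sheet``.  Missing values are
    excluded and the usable count recorded.  Records with a non-positive
    mean or fewer than two usable values are flagged, never dropped.
    """
    if scope not in {"all_samples", "per_subject"}:
        raise DiagnosticsError(f"unknown scope {scope!r}")
    rows = []
    ann = table.annotations
    if scope == "all_samples":
        groups: list[tuple[str | None, list[str]]] = [(None, list(table.values.columns))]
    else:
        if sheet is None:
            raise DiagnosticsError("scope='per_subject' requires a sample sheet")
        groups = [(s, sheet.samples_of(s)) for s in sheet.subjects]
    for subject, cols in groups:
        block = table.values[cols].to_numpy(dtype=float)
        for i, mid in enumerate(table.values.index):
            rsd, n, flag = _rsd_one(block[i])
            rows.append((mid, ann.loc[mid, "name"], ann.loc[mid, "mass"],
                         ann.loc[mid, "rt"], subject, n, rsd, flag))
    return pd.DataFrame(rows, columns=RSD_COLUMNS)


@dataclasses.dataclass
class TimeProfile:
    """One metabolite's trajectory for one subject, in collection order."""

    metabolite_id: str
    subject_id: str
    timepoint_labels: list[str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.timepoint_labels)


def extract_profile(table: PeakTable | NormalisedTable, sheet: SampleSheet,
                    metabolite_id: str, subject_id: str) -> TimeProfile:
    """Values in collection order; missing stays missing, never interpolated."""
    if metabolite_id not in table.values.index:
        raise DiagnosticsError(f"unknown metabolite {metabolite_id!r}")
    samples = sheet.samples_of(subject_id)  # raises on unknown subject
    labels = [sheet.frame.loc[s, "timepoint_label"] for s in samples]
    values = table.values.loc[metabolite_id, samples].to_numpy(dtype=float)
    return TimeProfile(metabolite_id, subject_id, labels, values)


def stability_report(records: pd.DataFrame,
                     thresholds: list[float] | tuple[float, ...] = ()) -> dict:
    """Band counts plus a listing sorted by RSD ascending.

    ``thresholds`` are RSD percentages splitting the records into bands
    (<= t1, (t1, t2], ..., > tk); an empty list yields a single
    all-inclusive band.  Flagged records (undefined RSD) land in their own
    band so the counts always partition the records.
    """
    if records.empty:
        raise DiagnosticsError("no RSD records to report")
    listing = records.sort_values("rsd_percent", na_position="last", kind="mergesort")
    edges = sorted(float(t) for t in thresholds)
    labels: list[str] = []
    counts: list[int] = []
    rsd = records["rsd_percent"]
    defined = rsd.notna()
    if not edges:
        labels.append("all")
        counts.append(int(defined.sum()))
    else:
        lo = -np.inf
        for t in edges:
            labels.append(f"<={t:g}" if lo == -np.inf else f"({lo:g}, {t:g}]")
            counts.append(int(((rsd > lo) & (rsd <= t)).sum()))
            lo = t
        labels.append(f">{lo:g}")
        counts.append(int((rsd > lo).sum()))
    n_flagged = int((~defined).sum())
    if n_flagged:
        labels.append("undefined")
        counts.append(n_flagged)
    bands = pd.DataFrame({"band": labels, "count": counts})
    return {"listing": listing.reset_index(drop=True), "bands": bands}


def plot_profiles(table: PeakTable | NormalisedTable, sheet: SampleSheet,
                  metabolite_ids: list[str], out_dir, reference_id: str | None = None):
    """Write one PNG per metabolite with per-subject profiles overlaid,
    optionally with a reference metabolite (e.g. MS creatinine) dashed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for mid in metabolite_ids:
        fig, ax = plt.subplots(figsize=(7, 4))
        for subject in sheet.subjects:
            prof = extract_profile(table, sheet, mid, subject)
            ax.plot(range(len(prof)), prof.values, marker="o", label=subject)
            ax.set_xticks(range(len(prof)))
            ax.set_xticklabels(prof.timepoint_labels, rotation=45)
        if reference_id is not None and reference_id != mid:
            for subject in sheet.subjects:
                ref = extract_profile(table, sheet, reference_id, subject)
                ax.plot(range(len(ref)), ref.values, linestyle="--", alpha=0.5)
        ax.set_title(str(table.annotations.loc[mid, "name"]))
        ax.set_xlabel("collection")
        ax.set_ylabel("normalised response")
        ax.legend(fontsize="small")
        fig.tight_layout()
        target = out_dir / f"profile_{mid}.png"
        fig.savefig(target, dpi=120)
        plt.close(fig)
        written.append(target)
    return written
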