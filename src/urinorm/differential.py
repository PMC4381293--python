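"""Reference-time-point comparison tables: fold ratios and paired t-tests.

The first post-exercise collection (PT1) is taken as the reference that
best reflects the acute impact of exercise, and every other chosen
time point is compared against it.  Ratios are ratios of subject means
(reference mean / comparator mean), which stays finite when a single
subject's comparator value is near zero; p-values come from two-sided
paired t-tests across subjects, computed on the area-percentage scale
with no multiple-testing correction by default (a Benjamini-Hochberg
column is available but off).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PHASE_BY_LABEL, SampleSheet, UrinormError
from .normalise import NormalisedTable


class DifferentialError(UrinormError):
    pass


DEFAULT_COMPARATORS = ("P1", "P2", "PT2", "PT4", "PT5", "PT7")


@dataclasses.dataclass(frozen=True)
class ComparisonSpec:
    """Which time points to compare against the reference (default PT1)."""

    reference: str = "PT1"
    comparators: tuple[str, ...] = DEFAULT_COMPARATORS

    def __post_init__(self) -> None:
        labels = (self.reference, *self.comparators)
        bad = sorted(set(labels) - set(PHASE_BY_LABEL))
        if bad:
            raise DifferentialError(f"unknown timepoint labels: {bad}")
        if self.reference in self.comparators:
            raise DifferentialError(f"reference {self.reference!r} is also a comparator")
        if len(set(self.comparators)) != len(self.comparators):
            raise DifferentialError("duplicate comparator labels")


def _paired_values(table: NormalisedTable, sheet: SampleSheet, metabolite_id: str,
                   ref_label: str, comp_label: str):
    """Per-subject (reference, comparator) value pairs; subjects missing
    either value are excluded and counted."""
    if metabolite_id not in table.values.index:
        raise DifferentialError(f"unknown metabolite {metabolite_id!r}")
    ref_vals, comp_vals = [], []
    n_excluded = 0
    for subject in sheet.subjects:
        rs = sheet.sample_for(subject, ref_label)
        cs = sheet.sample_for(subject, comp_label)
        if rs is None or cs is None:
            n_excluded += 1
            continue
        r = table.values.loc[metabolite_id, rs]
        c = table.values.loc[metabolite_id, cs]
        if not (np.isfinite(r) and np.isfinite(c)):
            n_excluded += 1
            continue
        ref_vals.append(float(r))
        comp_vals.append(float(c))
    return np.asarray(ref_vals), np.asarray(comp_vals), n_excluded


@dataclasses.dataclass
class FoldResult:
    ratio: float
    n_subjects: int
    n_excluded: int
    flag: str  # ok | infinite


def fold_ratio(table: NormalisedTable, sheet: SampleSheet, metabolite_id: str,
               ref_label: str, comp_label: str) -> FoldResult:
    """Ratio of subject means: mean(reference values) / mean(comparator
    values).  A zero comparator mean yields an ``infinite`` flag rather
    than an exception."""
    ref, comp, n_excl = _paired_values(table, sheet, metabolite_id, ref_label, comp_label)
    if ref.size < 1:
        raise DifferentialError(
            f"no subject has both {ref_label} and {comp_label} for {metabolite_id!r}"
        )
    comp_mean = comp.mean()
    if comp_mean == 0:
        return FoldResult(np.inf, ref.size, n_excl, "infinite")
    return FoldResult(float(ref.mean() / comp_mean), ref.size, n_excl, "ok")


@dataclasses.dataclass
class TTestResult:
    t: float
    p: float
    df: int
    flag: str  # ok | degenerate


def paired_t(table: NormalisedTable, sheet: SampleSheet, metabolite_id: str,
             ref_label: str, comp_label: str) -> TTestResult:
    """Two-sided paired t-test across subjects on per-subject differences
    d_k = reference_k - comparator_k, with df = n_subjects - 1.

    Zero difference spread with a non-zero mean difference is flagged
    degenerate (p undefined); all differences exactly zero gives
    t = 0, p = 1.
    """
    ref, comp, _ = _paired_values(table, sheet, metabolite_id, ref_label, comp_label)
    n = ref.size
    if n < 2:
        raise DifferentialError(
            f"paired t-test needs >= 2 subjects with both {ref_label} and "
            f"{comp_label}; got {n}"
        )
    d = ref - comp
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(0.0, 1.0, n - 1, "ok")
        return TTestResult(np.inf if d.mean() > 0 else -np.inf, np.nan, n - 1, "degenerate")
    res = stats.ttest_rel(ref, comp)
    return TTestResult(float(res.statistic), float(res.pvalue), n - 1, "ok")


def build_comparison_table(table: NormalisedTable, sheet: SampleSheet,
                           spec: ComparisonSpec = ComparisonSpec(),
                           pathway_map: Mapping[str, str] | None = None,
                           alpha: float | None = None,
                           bh_correct: bool = False,
                           metabolite_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """One row per metabolite with a (ratio, p) pair per comparator.

    ``alpha`` filters rows on the reference-vs-first-comparator p-value
    (raw p, mirroring the convention of reporting uncorrected paired-t
    p-values); ``bh_correct=True`` appends Benjamini-Hochberg q-value
    columns without changing the filter.  ``pathway_map`` adds a free-text
    pathway group column and sorts rows by it.
    """
    ids = list(metabolite_ids) if metabolite_ids is not None else list(table.values.index)
    rows = []
    for mid in ids:
        row: dict = {
            "metabolite_id": mid,
            "name": table.annotations.loc[mid, "name"],
            "mass": table.annotations.loc[mid, "mass"],
            "rt": table.annotations.loc[mid, "rt"],
        }
        if pathway_map is not None:
            row["pathway"] = pathway_map.get(mid, "unassigned")
        for comp in spec.comparators:
            fr = fold_ratio(table, sheet, mid, spec.reference, comp)
            tt = paired_t(table, sheet, mid, spec.reference, comp)
            row[f"ratio_{spec.reference}_vs_{comp}"] = fr.ratio
            row[f"p_{spec.reference}_vs_{comp}"] = tt.p
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        for comp in spec.comparators:
            pcol = out[f"p_{spec.reference}_vs_{comp}"]
            q = np.full(len(pcol), np.nan)
            ok = pcol.notna().to_numpy()
            if ok.any():
                q[ok] = multipletests(pcol[ok], method="fdr_bh")[1]
            out[f"q_{spec.reference}_vs_{comp}"] = q
    if alpha is not None:
        if not 0 < alpha <= 1:
            raise DifferentialError("alpha must be in (0, 1]")
        first = f"p_{spec.reference}_vs_{spec.comparators[0]}"
        out = out[out[first] < alpha].reset_index(drop=True)
    if pathway_map is not None:
        out = out.sort_values("pathway", kind="mergesort").reset_index(drop=True)
    return out
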