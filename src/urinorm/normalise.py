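"""Normalisation strategies for urine peak tables.

Urine concentration varies strongly from void to void, so raw peak areas
confound metabolite output with hydration state.  Four strategies are
implemented:

``area_percent``
    Subject-specific area percentage (total-metabolite-output
    normalisation): each metabolite's value in a sample is divided by the
    sum of that metabolite's values across *all* of the same subject's
    serial samples and multiplied by 100.  Every metabolite time course is
    thereby expressed as percent of the subject's total output of that
    metabolite, which cancels subject x metabolite baseline differences
    exactly.
``ms_creatinine``
    Division by the creatinine peak area of the same sample (the
    mass-spectrometric creatinine response), the classical dilution
    correction.
``pooled_ms_creatinine``
    Division by a per-subject creatinine scalar (e.g. the creatinine
    response of a subject-specific pooled sample) - a constant rescaling
    within each subject.
``assay_creatinine``
    Division by a per-sample spectrophotometric creatinine concentration.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CreatinineAssay, PeakTable, SampleSheet, UrinormError

#: Monoisotopic neutral mass of creatinine (C4H7N3O), Da.
CREATININE_MASS = 113.0589

STRATEGIES = ("area_percent", "ms_creatinine", "pooled_ms_creatinine", "assay_creatinine")


class NormalisationError(UrinormError):
    pass


@dataclasses.dataclass
class NormalisedTable:
    """A peak table after one named normalisation strategy.

    Same shape and ids as the source table; ``parameters`` records the
    divisors that were applied (per-sample creatinine values or
    per-(metabolite, subject) sums) so any run can be audited.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    strategy: str
    parameters: dict

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def find_creatinine_feature(peaks: PeakTable, metabolite_id: str | None = None,
                            ppm: float = 5.0) -> str:
    """Locate the creatinine row of a peak table.

    By default rows whose annotation name contains ``creatinine``
    (case-insensitive) are candidates; when several candidates exist the
    one whose mass lies within ``ppm`` of the neutral monoisotopic mass
    113.0589 Da is preferred, falling back to the closest mass.  Pass
    ``metabolite_id`` to override detection entirely.
    """
    if metabolite_id is not None:
        if metabolite_id not in peaks.values.index:
            raise NormalisationError(f"creatinine feature {metabolite_id!r} not in table")
        return metabolite_id
    names = peaks.annotations["name"].astype(str).str.lower()
    candidates = list(peaks.values.index[names.str.contains("creatinine")])
    if not candidates:
        raise NormalisationError(
            "no metabolite with a name containing 'creatinine'; pass an explicit id"
        )
    if len(candidates) == 1:
        return candidates[0]
    masses = peaks.annotations.loc[candidates, "mass"]
    delta = (masses - CREATININE_MASS).abs() / CREATININE_MASS * 1e6
    within = delta[delta <= ppm]
    if len(within) == 1:
        return within.index[0]
    if delta.notna().any():
        best = delta.idxmin()
        warnings.warn(
            f"multiple creatinine-named features {candidates}; picked {best!r} "
            f"by closest mass ({delta.min():.1f} ppm from {CREATININE_MASS})"
        )
        return best
    raise NormalisationError(
        f"ambiguous creatinine features {candidates} with no masses to arbitrate; "
        "pass an explicit id"
    )


def normalise_area_percent(peaks: PeakTable, sheet: SampleSheet,
                           missing_policy: str = "as_zero") -> NormalisedTable:
    """Subject-specific area-percentage normalisation.

    ``out[m, s] = 100 * x[m, s] / sum over the subject's samples of x[m, .]``

    ``missing_policy='as_zero'`` lets missing cells contribute nothing to
    the subject sum (the conventional treatment when summing peak-area
    tables); ``'propagate'`` makes any missing cell poison the whole
    (metabolite, subject) block.  Metabolites whose within-subject sum is
    zero become missing for that subject and are reported in a warning.
    """
    if missing_policy not in {"as_zero", "propagate"}:
        raise NormalisationError(f"unknown missing_policy {missing_policy!r}")
    sheet.check_covers(peaks)
    out = pd.DataFrame(np.nan, index=peaks.values.index, columns=peaks.values.columns)
    sums = pd.DataFrame(index=peaks.values.index, columns=sheet.subjects, dtype=float)
    zero_sum: dict[str, list[str]] = {}
    for subject in sheet.subjects:
        cols = [c for c in sheet.samples_of(subject) if c in peaks.values.columns]
        if len(cols) < 2:
            raise NormalisationError(
                f"subject {subject!r} has {len(cols)} sample(s); area-percentage "
                "normalisation needs at least 2 serial samples per subject"
            )
        block = peaks.values[cols]
        if missing_policy == "as_zero":
            subject_sums = block.sum(axis=1, skipna=True)
        else:
            subject_sums = block.sum(axis=1, skipna=False)
        sums[subject] = subject_sums
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = 100.0 * block.div(subject_sums, axis=0)
        zero = subject_sums == 0
        scaled[zero] = np.nan
        zeros = list(peaks.values.index[zero])
        if zeros:
            zero_sum[subject] = zeros
        out[cols] = scaled
    if zero_sum:
        warnings.warn(
            "metabolites with zero within-subject sum set to missing: "
            + "; ".join(f"{s}: {m}" for s, m in zero_sum.items())
        )
    params = {"subject_sums": sums, "zero_sum": zero_sum, "missing_policy": missing_policy}
    return NormalisedTable(out, peaks.annotations.copy(), "area_percent", params)


def normalise_ms_creatinine(peaks: PeakTable,
                            creatinine_feature: str | None = None) -> NormalisedTable:
    """Divide every sample by its own MS creatinine peak area.

    The creatinine row itself becomes identically 1 and is retained so
    that the table shape stays comparable across strategies.
    """
    feature = find_creatinine_feature(peaks, creatinine_feature)
    divisors = peaks.values.loc[feature]
    bad = sorted(divisors.index[~(divisors > 0)])
    if bad:
        raise NormalisationError(
            f"creatinine feature {feature!r} is zero or missing in samples: {bad}"
        )
    out = peaks.values.div(divisors, axis=1)
    params = {"creatinine_feature": feature, "divisors": divisors.copy()}
    return NormalisedTable(out, peaks.annotations.copy(), "ms_creatinine", params)


def normalise_pooled_creatinine(peaks: PeakTable, sheet: SampleSheet,
                                pooled_creatinine: Mapping[str, float]) -> NormalisedTable:
    """Divide each subject's samples by that subject's pooled creatinine scalar."""
    sheet.check_covers(peaks)
    missing = sorted(set(sheet.subjects) - set(pooled_creatinine))
    if missing:
        raise NormalisationError(f"subjects without a pooled creatinine value: {missing}")
    bad = sorted(s for s in sheet.subjects if not pooled_creatinine[s] > 0)
    if bad:
        raise NormalisationError(f"non-positive pooled creatinine for subjects: {bad}")
    divisors = pd.Series(
        {s: float(pooled_creatinine[sheet.frame.loc[s, "subject_id"]])
         for s in peaks.values.columns}
    )
    out = peaks.values.div(divisors, axis=1)
    params = {"pooled_creatinine": dict(pooled_creatinine), "divisors": divisors}
    return NormalisedTable(out, peaks.annotations.copy(), "pooled_ms_creatinine", params)


def normalise_assay_creatinine(peaks: PeakTable, assay: CreatinineAssay) -> NormalisedTable:
    """Divide every sample by its spectrophotometric creatinine concentration."""
    assay.check_positive(peaks.sample_ids)
    divisors = assay.concentrations.reindex(peaks.values.columns)
    out = peaks.values.div(divisors, axis=1)
    params = {"divisors": divisors.copy()}
    return NormalisedTable(out, peaks.annotations.copy(), "assay_creatinine", params)


def log10_transform(table: NormalisedTable) -> NormalisedTable:
    """Optional log10 of a normalised table (off by default everywhere:
    ratios and paired t-tests are run on the percentage scale)."""
    vals = table.values.where(table.values > 0)
    dropped = int(table.values.gt(0).size - vals.notna().values.sum())
    out = np.log10(vals)
    params = dict(table.parameters)
    params["log10"] = True
    params["non_positive_set_missing"] = dropped
    return NormalisedTable(out, table.annotations.copy(), table.strategy, params)


def apply_strategy(strategy: str, peaks: PeakTable, sheet: SampleSheet,
                   assay: CreatinineAssay | None = None,
                   pooled: Mapping[str, float] | None = None,
                   creatinine_feature: str | None = None,
                   missing_policy: str = "as_zero") -> NormalisedTable:
    """Dispatch one named strategy, deriving defaults where sensible.

    ``pooled_ms_creatinine`` without explicit scalars falls back to each
    subject's mean MS creatinine response (a stand-in for the creatinine
    value of a subject-specific pooled sample); ``assay_creatinine``
    without an assay table is an error.
    """
    if strategy == "area_percent":
        return normalise_area_percent(peaks, sheet, missing_policy=missing_policy)
    if strategy == "ms_creatinine":
        return normalise_ms_creatinine(peaks, creatinine_feature)
    if strategy == "pooled_ms_creatinine":
        if pooled is None:
            feature = find_creatinine_feature(peaks, creatinine_feature)
            pooled = {
                subj: float(peaks.values.loc[feature, sheet.samples_of(subj)].mean())
                for subj in sheet.subjects
            }
        return normalise_pooled_creatinine(peaks, sheet, pooled)
    if strategy == "assay_creatinine":
        if assay is None:
            raise NormalisationError("assay_creatinine requires a creatinine assay table")
        return normalise_assay_creatinine(peaks, assay)
    raise NormalisationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
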