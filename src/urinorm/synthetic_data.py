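"""Synthetic longitudinal urine metabolome generator with ground truth.

Every observed peak area decomposes exactly as

    x[m, s] = d_s * b[m, subj(s)] * f_m(t_s) * eps[m, s]

where ``d_s`` is a per-sample dilution factor (hydration state of the
void), ``b`` a subject x metabolite baseline (personal metabotype),
``f_m`` the metabolite's temporal profile evaluated at the collection
hour, and ``eps`` multiplicative measurement noise.  All random factors
are log-normal, so peak areas stay positive and the factorisation is
exact - every normalisation strategy can be scored against known truth.

Temporal classes:

``stable``   f = 1 (constant output).
``spike``    f = 1 + A * exp(-(t - t_ex) / tau) for t >= t_ex, else 1:
             an exercise response peaking at the first post-exercise
             collection and decaying with time constant tau.
``diurnal``  f = 1 + a * sin(2*pi*(t + phi)/24): a 24-h rhythm.
``erratic``  independent log-normal draws per time point (diet-driven
             xenobiotics and the like).

A creatinine row (mass 113.050 Da, RT 10.1 min) is always generated as a
stable metabolite with its own noise level, and a spectrophotometric
assay table is emitted as ``d_s * creatinine baseline * assay noise`` so
that assay-based normalisation can be tested with a divisor that is (or
is not) proportional to the true dilution.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .differential import fold_ratio
from .io import CreatinineAssay, PeakTable, SampleSheet, UrinormError
from .normalise import NormalisedTable


class SyntheticError(UrinormError):
    pass


#: Collection labels and hours: day 1 at 08:00 (hour 0), 11:00, 14:00,
#: 17:00 and 21:00; day 2 at 08:00 (hour 24), 12:00, 14:00, 17:00, 21:00.
DEFAULT_TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("P1", 0.0), ("P2", 3.0), ("PT1", 6.0), ("PT2", 9.0), ("PT3", 13.0),
    ("PT4", 24.0), ("PT5", 28.0), ("PT6", 30.0), ("PT7", 33.0), ("PT8", 37.0),
)


@dataclasses.dataclass
class SimConfig:
    """Study-design and variance parameters of the generator.

    The defaults emulate the pilot design: 3 subjects, 10 serial
    collections over 37 h with the exercise bout at hour 4 (between the
    second pre-exercise and first post-exercise void), 80 metabolites
    split over the four temporal classes, log-normal dilution
    (sigma_dilution), subject x metabolite baseline (sigma_baseline) and
    measurement noise (sigma_noise).  Spike amplitudes are log-uniform
    between 2- and 100-fold.
    """

    n_subjects: int = 3
    timepoints: tuple[tuple[str, float], ...] = DEFAULT_TIMEPOINTS
    n_stable: int = 40
    n_spike: int = 20
    n_diurnal: int = 10
    n_erratic: int = 10
    exercise_hour: float = 4.0
    spike_amplitude: tuple[float, float] = (2.0, 100.0)   # fold increase, log-uniform
    spike_tau: tuple[float, float] = (2.0, 10.0)          # decay constant, hours
    diurnal_amplitude: tuple[float, float] = (0.2, 0.8)   # fractional amplitude
    sigma_dilution: float = 0.4     # log-SD of per-sample dilution
    sigma_baseline: float = 0.6     # log-SD of subject x metabolite baseline
    sigma_noise: float = 0.1        # log-SD of multiplicative measurement noise
    sigma_erratic: float = 0.5      # log-SD of erratic temporal draws
    creatinine_rsd_target: float = 16.3  # target raw-scale creatinine RSD, percent
    sigma_assay: float = 0.5        # log-SD of assay noise (assay-kit imprecision)
    abundance_log10_range: tuple[float, float] = (4.0, 7.0)
    mask_rate: float = 0.0          # fraction of non-creatinine cells set missing
    seed: int = 0

    def validate(self) -> None:
        sds = (self.sigma_dilution, self.sigma_baseline, self.sigma_noise,
               self.sigma_erratic, self.sigma_assay)
        if any(s < 0 for s in sds):
            raise SyntheticError("all noise SDs must be >= 0")
        labels = [lab for lab, _ in self.timepoints]
        if len(set(labels)) != len(labels):
            raise SyntheticError("duplicate timepoint labels")
        if min(self.n_stable, self.n_spike, self.n_diurnal, self.n_erratic) < 0:
            raise SyntheticError("class counts must be >= 0")
        if self.n_stable + self.n_spike + self.n_diurnal + self.n_erratic < 1:
            raise SyntheticError("at least one metabolite is required")
        if self.n_subjects < 1:
            raise SyntheticError("n_subjects must be >= 1")
        if not (self.spike_amplitude[0] > 0 and self.spike_tau[0] > 0):
            raise SyntheticError("spike amplitude and tau must be positive")
        if not 0 <= self.mask_rate < 1:
            raise SyntheticError("mask_rate must be in [0, 1)")
        if not self.creatinine_rsd_target > 0:
            raise SyntheticError("creatinine_rsd_target must be positive")


@dataclasses.dataclass
class SyntheticTruth:
    """Generator ground truth for scoring normalisation strategies."""

    dilution: pd.Series                 # per sample
    baselines: pd.DataFrame             # metabolite x subject
    profiles: pd.DataFrame              # metabolite x timepoint label, f_m(t)
    classes: pd.Series                  # per metabolite
    epsilon: pd.DataFrame               # metabolite x sample
    true_fold: pd.Series                # f(PT1-equivalent)/f(first label) per metabolite
    sigma_creatinine: float
    config: SimConfig

    def reconstruct(self, sheet: SampleSheet) -> pd.DataFrame:
        """Recompose d * b * f * eps exactly as the generator did."""
        subj = sheet.frame["subject_id"]
        label = sheet.frame["timepoint_label"]
        cols = list(self.epsilon.columns)
        b = self.baselines[[subj[s] for s in cols]].to_numpy()
        f = self.profiles[[label[s] for s in cols]].to_numpy()
        d = self.dilution[cols].to_numpy()[None, :]
        return pd.DataFrame(_compose(d, b, f, self.epsilon.to_numpy()),
                            index=self.epsilon.index, columns=cols)


def _compose(d: np.ndarray, b: np.ndarray, f: np.ndarray, eps: np.ndarray) -> np.ndarray:
    # single shared expression so reconstruction is bit-identical
    return d * b * f * eps


def _creatinine_sigma(config: SimConfig) -> float:
    """Noise log-SD for the creatinine row chosen so the raw-scale RSD
    across samples (dilution variation included) hits the configured
    target; clamped to a small floor when the dilution alone already
    exceeds the target."""
    cv = config.creatinine_rsd_target / 100.0
    total_var = math.log1p(cv ** 2)
    resid = total_var - config.sigma_dilution ** 2
    if resid <= 0:
        return 0.02
    return math.sqrt(resid)


def _profiles(config: SimConfig, classes: list[str],
              rng: np.random.Generator) -> np.ndarray:
    hours = np.array([h for _, h in config.timepoints])
    F = np.ones((len(classes), hours.size))
    for i, cls in enumerate(classes):
        if cls in ("stable", "creatinine"):
            continue
        if cls == "spike":
            lo, hi = config.spike_amplitude
            A = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            tau = rng.uniform(*config.spike_tau)
            post = hours >= config.exercise_hour
            F[i, post] = 1.0 + A * np.exp(-(hours[post] - config.exercise_hour) / tau)
        elif cls == "diurnal":
            a = rng.uniform(*config.diurnal_amplitude)
            phi = rng.uniform(0.0, 24.0)
            F[i] = 1.0 + a * np.sin(2.0 * np.pi * (hours + phi) / 24.0)
        elif cls == "erratic":
            F[i] = np.exp(rng.normal(0.0, config.sigma_erratic, hours.size))
        else:  # pragma: no cover
            raise SyntheticError(f"unknown class {cls!r}")
    return F


def generate(config: SimConfig, seed: int | None = None
             ) -> tuple[PeakTable, SampleSheet, CreatinineAssay, SyntheticTruth]:
    """Draw one dataset: peak table, sample sheet, assay table and truth.

    ``seed`` overrides ``config.seed``; the same (config, seed) pair
    yields bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    labels = [lab for lab, _ in config.timepoints]
    subjects = [f"S{k + 1}" for k in range(config.n_subjects)]
    sample_ids = [f"{subj}_{lab}" for subj in subjects for lab in labels]
    sheet = SampleSheet(pd.DataFrame({
        "subject_id": [s.split("_")[0] for s in sample_ids],
        "timepoint_label": [s.split("_", 1)[1] for s in sample_ids],
    }, index=pd.Index(sample_ids, name="sample_id")))

    classes = (["stable"] * config.n_stable + ["spike"] * config.n_spike
               + ["diurnal"] * config.n_diurnal + ["erratic"] * config.n_erratic)
    counts: dict[str, int] = {}
    met_ids, names = [], []
    for cls in classes:
        counts[cls] = counts.get(cls, 0) + 1
        met_ids.append(f"M_{cls}_{counts[cls]:03d}")
        names.append(f"{cls} metabolite {counts[cls]}")
    classes.append("creatinine")
    met_ids.append("M_creatinine")
    names.append("creatinine")
    n_mets = len(met_ids)

    mass = np.round(rng.uniform(80.0, 600.0, n_mets), 3)
    rt = np.round(rng.uniform(4.0, 27.0, n_mets), 1)
    mass[-1], rt[-1] = 113.050, 10.1
    annotations = pd.DataFrame({"name": names, "mass": mass, "rt": rt},
                               index=pd.Index(met_ids, name="metabolite_id"))

    F = _profiles(config, classes, rng)

    d = np.exp(rng.normal(0.0, config.sigma_dilution, len(sample_ids)))
    abundance = 10.0 ** rng.uniform(*config.abundance_log10_range, n_mets)
    baselines = abundance[:, None] * np.exp(
        rng.normal(0.0, config.sigma_baseline, (n_mets, config.n_subjects)))
    # creatinine output is held constant across subjects so its raw RSD is
    # governed by dilution + its own noise (see _creatinine_sigma)
    baselines[-1, :] = abundance[-1]

    sigma_cr = _creatinine_sigma(config)
    eps = np.exp(rng.normal(0.0, config.sigma_noise, (n_mets, len(sample_ids))))
    eps[-1, :] = np.exp(rng.normal(0.0, sigma_cr, len(sample_ids)))

    subj_index = np.repeat(np.arange(config.n_subjects), len(labels))
    tp_index = np.tile(np.arange(len(labels)), config.n_subjects)
    values = _compose(d[None, :], baselines[:, subj_index], F[:, tp_index], eps)

    if config.mask_rate > 0:
        # never mask the creatinine row: it must stay usable as a divisor
        maskable = rng.random((n_mets - 1, len(sample_ids))) < config.mask_rate
        values = values.copy()
        values[:-1][maskable] = np.nan

    peaks = PeakTable(
        pd.DataFrame(values, index=annotations.index, columns=sample_ids),
        annotations,
    )
    assay_vals = d * abundance[-1] * np.exp(
        rng.normal(0.0, config.sigma_assay, len(sample_ids)))
    assay = CreatinineAssay(pd.Series(assay_vals, index=sample_ids))

    ref_label = "PT1" if "PT1" in labels else labels[min(2, len(labels) - 1)]
    base_label = labels[0]
    profiles = pd.DataFrame(F, index=annotations.index, columns=labels)
    true_fold = profiles[ref_label] / profiles[base_label]
    truth = SyntheticTruth(
        dilution=pd.Series(d, index=sample_ids),
        baselines=pd.DataFrame(baselines, index=annotations.index, columns=subjects),
        profiles=profiles,
        classes=pd.Series(classes, index=annotations.index),
        epsilon=pd.DataFrame(eps, index=annotations.index, columns=sample_ids),
        true_fold=true_fold,
        sigma_creatinine=sigma_cr,
        config=config,
    )
    return peaks, sheet, assay, truth


def null_dataset(config: SimConfig, seed: int | None = None, noise: str = "multiplicative"
                 ) -> tuple[PeakTable, SampleSheet, CreatinineAssay, SyntheticTruth]:
    """A dataset with no temporal structure: every metabolite stable.

    ``noise='multiplicative'`` keeps the log-normal generative model;
    ``noise='additive'`` replaces dilution and multiplicative noise with
    relative additive Gaussian noise (d = 1, eps = 1 + N(0, sigma_noise))
    so that downstream paired t-tests on the area-percentage scale meet
    their normality assumption - the configuration used for type-I-error
    calibration.
    """
    if noise not in {"multiplicative", "additive"}:
        raise SyntheticError(f"unknown noise mode {noise!r}")
    total = config.n_stable + config.n_spike + config.n_diurnal + config.n_erratic
    null_cfg = dataclasses.replace(config, n_stable=total, n_spike=0,
                                   n_diurnal=0, n_erratic=0)
    if noise == "additive":
        null_cfg = dataclasses.replace(null_cfg, sigma_dilution=0.0)
    peaks, sheet, assay, truth = generate(null_cfg, seed=seed)
    if noise == "additive":
        rng = np.random.default_rng(
            (null_cfg.seed if seed is None else seed) + 2**20)
        eps = 1.0 + rng.normal(0.0, null_cfg.sigma_noise, truth.epsilon.shape)
        eps = np.clip(eps, 1e-6, None)
        truth.epsilon = pd.DataFrame(eps, index=truth.epsilon.index,
                                     columns=truth.epsilon.columns)
        peaks = PeakTable(truth.reconstruct(sheet), peaks.annotations)
    return peaks, sheet, assay, truth


# ---------------------------------------------------------------------------
# truth scoring


@dataclasses.dataclass
class RecoveryScore:
    """Agreement between a normalised table and the generator truth.

    ``per_subject`` holds the Pearson correlation between each
    (metabolite, subject) normalised time profile and the true temporal
    profile; ``across_subjects`` concatenates all subjects' samples per
    metabolite, so strategies that fail to remove subject baselines are
    penalised; ``folds`` reports the relative error of the estimated vs
    true reference fold for spike metabolites.
    """

    per_subject: pd.DataFrame
    across_subjects: pd.DataFrame
    folds: pd.DataFrame

    def mean_correlation(self, scope: str = "across_subjects") -> float:
        frame = getattr(self, scope)
        return float(frame["pearson_r"].mean())


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan, "insufficient_n"
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, "flat"
    return float(np.corrcoef(x, y)[0, 1]), "ok"


def truth_recovery_score(truth: SyntheticTruth, normalised: NormalisedTable,
                         sheet: SampleSheet) -> RecoveryScore:
    """Score how faithfully a normalised table recovers the true temporal
    profiles and reference folds."""
    if list(normalised.values.index) != list(truth.profiles.index):
        raise SyntheticError("normalised table and truth have different metabolites")
    per_rows, across_rows = [], []
    label_of = sheet.frame["timepoint_label"]
    for mid in truth.profiles.index:
        xs_all, ys_all = [], []
        for subject in sheet.subjects:
            samples = sheet.samples_of(subject)
            y = normalised.values.loc[mid, samples].to_numpy(dtype=float)
            x = truth.profiles.loc[mid, [label_of[s] for s in samples]].to_numpy(dtype=float)
            r, flag = _safe_corr(x, y)
            per_rows.append((mid, subject, r, flag))
            xs_all.append(x)
            ys_all.append(y)
        r, flag = _safe_corr(np.concatenate(xs_all), np.concatenate(ys_all))
        across_rows.append((mid, r, flag))
    per_subject = pd.DataFrame(per_rows,
                               columns=["metabolite_id", "subject_id", "pearson_r", "flag"])
    across = pd.DataFrame(across_rows, columns=["metabolite_id", "pearson_r", "flag"])

    fold_rows = []
    labels = list(truth.profiles.columns)
    ref_label = "PT1" if "PT1" in labels else labels[min(2, len(labels) - 1)]
    base_label = labels[0]
    for mid in truth.classes.index[truth.classes == "spike"]:
        true_f = float(truth.true_fold[mid])
        try:
            est = fold_ratio(normalised, sheet, mid, ref_label, base_label).ratio
        except UrinormError:
            est = np.nan
        rel = abs(est - true_f) / true_f if np.isfinite(est) else np.nan
        fold_rows.append((mid, true_f, est, rel))
    folds = pd.DataFrame(fold_rows,
                         columns=["metabolite_id", "true_fold", "estimated_fold",
                                  "relative_error"])
    return RecoveryScore(per_subject=per_subject, across_subjects=across, folds=folds)
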