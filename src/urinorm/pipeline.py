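"""End-to-end orchestration: read (or simulate) -> normalise -> RSD
diagnostics -> PCA strategy panel -> reference-point comparison table,
under a single YAML config with deterministic seeding and a manifest of
checksummed outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
import yaml

from . import diagnostics, differential, multivariate, normalise
from .io import (UrinormError, read_creatinine_assay, read_peak_table,
                 read_sample_sheet, write_report)
from .synthetic_data import SimConfig, generate

logger = logging.getLogger("urinorm")


class ConfigError(UrinormError):
    pass


class PipelineError(UrinormError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    peaks_path: Path | None = None
    samples_path: Path | None = None
    assay_path: Path | None = None
    peaks_dialect: str = "ideom_tsv"
    simulate: SimConfig | None = None
    strategies: tuple[str, ...] = normalise.STRATEGIES
    reference: str = "PT1"
    comparators: tuple[str, ...] = differential.DEFAULT_COMPARATORS
    alpha: float = 0.05
    n_components: int = 2
    n_folds: int = 7
    seed: int = 0
    missing_policy: str = "as_zero"
    log_level: str = "INFO"


_ACCEPTED_KEYS = {
    "out_dir", "peaks_path", "samples_path", "assay_path", "peaks_dialect",
    "simulate", "strategies", "reference", "comparators", "alpha",
    "n_components", "n_folds", "seed", "missing_policy", "log_level",
}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}


def _build_config(raw: dict, base_dir: Path) -> tuple[RunConfig | None, list[str]]:
    errors: list[str] = []
    unknown = sorted(set(raw) - _ACCEPTED_KEYS)
    if unknown:
        errors.append(f"unknown keys {unknown}; accepted keys: {sorted(_ACCEPTED_KEYS)}")

    sim = None
    if raw.get("simulate") is not None:
        sim_raw = raw["simulate"] if isinstance(raw["simulate"], dict) else {}
        if not isinstance(raw["simulate"], dict):
            errors.append("simulate must be a mapping of SimConfig fields")
        bad = sorted(set(sim_raw) - _SIM_KEYS)
        if bad:
            errors.append(f"unknown simulate keys {bad}")
        else:
            try:
                for key in ("spike_amplitude", "spike_tau", "diurnal_amplitude",
                            "abundance_log10_range"):
                    if key in sim_raw:
                        sim_raw[key] = tuple(sim_raw[key])
                if "timepoints" in sim_raw:
                    sim_raw["timepoints"] = tuple(
                        (str(l), float(h)) for l, h in sim_raw["timepoints"])
                sim = SimConfig(**sim_raw)
                sim.validate()
            except (UrinormError, TypeError, ValueError) as err:
                errors.append(f"invalid simulate config: {err}")
                sim = None

    has_inputs = raw.get("peaks_path") is not None and raw.get("samples_path") is not None
    if sim is None and not has_inputs:
        errors.append("config needs either (peaks_path and samples_path) or simulate")
    if sim is not None and has_inputs:
        errors.append("config must not give both file inputs and simulate")

    alpha = raw.get("alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha <= 1):
        errors.append("alpha must be in (0,1]")
    n_components = raw.get("n_components", 2)
    if not (isinstance(n_components, int) and n_components >= 1):
        errors.append("n_components must be a positive integer")
    n_folds = raw.get("n_folds", 7)
    if not (isinstance(n_folds, int) and n_folds >= 2):
        errors.append("n_folds must be an integer >= 2")
    strategies = tuple(raw.get("strategies", normalise.STRATEGIES))
    bad_strats = sorted(set(strategies) - set(normalise.STRATEGIES))
    if bad_strats:
        errors.append(f"unknown strategies {bad_strats}")
    missing_policy = raw.get("missing_policy", "as_zero")
    if missing_policy not in {"as_zero", "propagate"}:
        errors.append("missing_policy must be 'as_zero' or 'propagate'")
    if "out_dir" not in raw:
        errors.append("out_dir is required")

    try:
        spec = differential.ComparisonSpec(
            raw.get("reference", "PT1"),
            tuple(raw.get("comparators", differential.DEFAULT_COMPARATORS)))
    except UrinormError as err:
        errors.append(str(err))
        spec = differential.ComparisonSpec()

    if errors:
        return None, errors

    def _path(key):
        return (base_dir / raw[key]).resolve() if raw.get(key) is not None else None

    out_dir = raw["out_dir"]
    out_dir = Path(out_dir) if Path(out_dir).is_absolute() else base_dir / out_dir
    return RunConfig(
        out_dir=out_dir,
        peaks_path=_path("peaks_path"),
        samples_path=_path("samples_path"),
        assay_path=_path("assay_path"),
        peaks_dialect=raw.get("peaks_dialect", "ideom_tsv"),
        simulate=sim,
        strategies=strategies,
        reference=spec.reference,
        comparators=spec.comparators,
        alpha=float(alpha),
        n_components=n_components,
        n_folds=n_folds,
        seed=int(raw.get("seed", 0)),
        missing_policy=missing_policy,
        log_level=str(raw.get("log_level", "INFO")),
    ), []


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, reporting *all* problems at
    once rather than stopping at the first."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    config, errors = _build_config(raw, path.parent)
    if errors:
        raise ConfigError(f"{path}: " + "; ".join(errors))
    assert config is not None
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    Any stage failure aborts the run with the stage name and removes the
    partial outputs already written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> Path:
        target = out_dir / name
        writer(target)
        written.append(target)
        return target

    try:
        stage = "inputs"
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            peaks, sheet, assay, _truth = generate(sim)
            source = {"mode": "simulate", "sim_config": dataclasses.asdict(sim)}
        else:
            peaks = read_peak_table(config.peaks_path, dialect=config.peaks_dialect)
            sheet = read_sample_sheet(config.samples_path)
            assay = (read_creatinine_assay(config.assay_path)
                     if config.assay_path is not None else None)
            source = {"mode": "files",
                      "peaks_path": str(config.peaks_path),
                      "samples_path": str(config.samples_path),
                      "assay_path": str(config.assay_path) if config.assay_path else None}
        sheet.check_covers(peaks)
        strategies = tuple(s for s in config.strategies
                           if s != "assay_creatinine" or assay is not None)
        if len(strategies) < len(config.strategies):
            logger.warning("assay_creatinine skipped: no assay table provided")

        stage = "normalise"
        tables: dict[str, normalise.NormalisedTable] = {}
        for strategy in strategies:
            table = normalise.apply_strategy(
                strategy, peaks, sheet, assay=assay,
                missing_policy=config.missing_policy)
            tables[strategy] = table
            frame = table.values.copy()
            frame.insert(0, "metabolite_id", frame.index)
            emit(f"normalised_{strategy}.tsv",
                 lambda p, fr=frame: write_report(fr, p, float_digits=10))

        stage = "diagnostics"
        rsd = diagnostics.compute_rsd(peaks, scope="all_samples")
        report = diagnostics.stability_report(rsd, thresholds=(25, 50, 100))
        emit("rsd_report.tsv", lambda p: write_report(report["listing"], p))
        emit("rsd_bands.tsv", lambda p: write_report(report["bands"], p))

        stage = "multivariate"
        panel = multivariate.fit_strategy_panel(
            peaks, sheet, strategies=strategies, assay=assay,
            n_components=config.n_components, n_folds=config.n_folds,
            seed=config.seed + 1000, missing_policy=config.missing_policy)
        emit("pca_scores.tsv", lambda p: write_report(panel.scores, p, float_digits=8))
        emit("pca_model_summary.tsv", lambda p: write_report(panel.report, p, float_digits=8))

        stage = "differential"
        spec = differential.ComparisonSpec(config.reference, config.comparators)
        base = tables.get("area_percent", next(iter(tables.values())))
        comparison = differential.build_comparison_table(
            base, sheet, spec=spec, alpha=config.alpha)
        emit("comparison_table.tsv", lambda p: write_report(comparison, p, float_digits=6))

        stage = "manifest"
        manifest = {
            "source": source,
            "parameters": {
                "strategies": list(strategies),
                "reference": config.reference,
                "comparators": list(config.comparators),
                "alpha": config.alpha,
                "n_components": config.n_components,
                "n_folds": config.n_folds,
                "seed": config.seed,
                "missing_policy": config.missing_policy,
            },
            "n_metabolites": len(peaks.metabolite_ids),
            "n_samples": len(peaks.sample_ids),
            "outputs": {p.name: _sha256(p) for p in written},
        }
        target = out_dir / "manifest.json"
        target.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(target)
        return manifest
    except Exception as err:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
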