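"""End-to-end orchestration: simulate -> assign -> describe -> classify ->
summarize, driven by one structured configuration.

Every run writes delimited artifacts plus a machine-readable run manifest;
each artifact declares the hash of the configuration that produced it, so
outputs are traceable and runs with fixed seeds are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import descriptors as desc_mod
from . import dynamics as dyn
from . import ordination as ord_mod
from . import synthetic as syn
from .engine import EngineParams, IntensityMatrix, process_peaks, read_manifest, read_peaks
from .formulas import ElementConstraints, MolecularFormula

log = logging.getLogger("cryodom")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    output_dir: str = "cryodom_out"
    manifest: str | None = None        # path to sample manifest (TSV)
    peaks_dir: str | None = None       # directory of per-measurement TSVs
    design: syn.ExperimentDesign = field(default_factory=syn.ExperimentDesign)
    truth: syn.PlantedTruth = field(default_factory=syn.PlantedTruth)
    engine: EngineParams = field(default_factory=EngineParams)
    rule: dyn.MonotoneRule = field(default_factory=dyn.MonotoneRule)
    strict_transfer: bool = True
    windows: desc_mod.CategoryWindows = field(
        default_factory=desc_mod.CategoryWindows)
    ordination_seed: int = 0
    ordination_restarts: int = 50
    signal_threshold: float = 0.45

    def hash(self) -> str:
        """Hash of the scientific configuration (file-system locations are
        excluded so identical analyses hash identically)."""
        plain = _as_plain(self)
        for key in ("output_dir", "manifest", "peaks_dir"):
            plain.pop(key, None)
        blob = json.dumps(plain, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_plain(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {f.name: _as_plain(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _build(cls, data: Mapping[str, Any], **extra):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key, sub in extra.items():
        if key in kwargs:
            kwargs[key] = sub(kwargs[key])
    # YAML lists -> tuples for frozen dataclasses
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v
                for v in kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, base=Path(path).parent)


def config_from_dict(raw: Mapping[str, Any],
                     base: Path | None = None) -> PipelineConfig:
    raw = dict(raw)
    sections = {
        "design": lambda d: _build(syn.ExperimentDesign, d),
        "truth": lambda d: _build(
            syn.PlantedTruth, d,
            constraints=lambda c: _build(ElementConstraints, c)),
        "engine": lambda d: _build(
            EngineParams, d,
            constraints=lambda c: _build(ElementConstraints, c)),
        "rule": lambda d: _build(dyn.MonotoneRule, d),
        "windows": lambda d: _build(desc_mod.CategoryWindows, d),
    }
    for key, builder in sections.items():
        if key in raw and isinstance(raw[key], Mapping):
            raw[key] = builder(raw[key])
    cfg = _build(PipelineConfig, raw)
    if base is not None:
        resolved = {}
        for key in ("manifest", "peaks_dir", "output_dir"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).is_absolute():
                resolved[key] = str(base / val)
        if resolved:
            cfg = replace(cfg, **resolved)
    for key in ("manifest", "peaks_dir"):
        val = getattr(cfg, key)
        if val is not None and not Path(val).exists():
            raise FileNotFoundError(f"{key} path does not exist: {val}")
    return cfg


# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def simulate(cfg: PipelineConfig) -> Path:
    """Generate a synthetic experiment under ``output_dir``/simulated."""
    exp = syn.simulate_experiment(cfg.design, cfg.truth, cfg.seed)
    out = Path(cfg.output_dir) / "simulated"
    syn.write_experiment(exp, out)
    log.info("simulated %d measurements, %d formulae, %d blanks -> %s",
             len(exp.peaks), cfg.truth.n_formulae,
             cfg.design.n_blanks, out)
    return out


def load_inputs(cfg: PipelineConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    if cfg.manifest is None or cfg.peaks_dir is None:
        raise ValueError("config must provide 'manifest' and 'peaks_dir' "
                         "(or run the simulate stage first)")
    manifest = read_manifest(cfg.manifest)
    n_per_sample = manifest[manifest["is_blank"] != True]  # noqa: E712
    counts = n_per_sample.groupby(
        ["habitat", "pool", "condition", "time_days"])["replicate"].nunique()
    bad = counts[counts != cfg.engine.n_replicates]
    if len(bad):
        raise ValueError(
            f"manifest replicate counts disagree with configured "
            f"n_replicates={cfg.engine.n_replicates}: "
            f"{bad.head().to_dict()}")
    peaks = {}
    for sid in manifest["sample_id"]:
        path = Path(cfg.peaks_dir) / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"peak table missing for {sid}: {path}")
        peaks[sid] = read_peaks(path)
    return peaks, manifest


@dataclass
class PipelineResult:
    matrix: IntensityMatrix
    audit: pd.DataFrame
    descriptors: pd.DataFrame
    labels: pd.DataFrame
    report: dict
    ordination: "ord_mod.OrdinationResult"
    signals: dict[str, set[str]]
    output_dir: Path


def run_pipeline(cfg: PipelineConfig,
                 peaks: Mapping[str, pd.DataFrame] | None = None,
                 manifest: pd.DataFrame | None = None) -> PipelineResult:
    """Run assign -> describe -> classify -> ordinate and write artifacts."""
    cfg_hash = cfg.hash()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if peaks is None or manifest is None:
        peaks, manifest = load_inputs(cfg)

    log.info("engine: %d measurements", len(peaks))
    matrix, audit = process_peaks(peaks, manifest, cfg.engine)
    log.info("engine: %d formulae x %d merged samples "
             "(blank-removed %d, duplicate-dropped %d)",
             *matrix.data.shape, matrix.blank_removed,
             matrix.duplicate_dropped)

    formulas = [MolecularFormula.from_string(h) for h in matrix.data.index]
    desc_table = desc_mod.descriptor_table(formulas, cfg.windows)

    classifier = dyn.TrajectoryClassifier(
        matrix.data, matrix.samples, cfg.rule,
        strict_transfer=cfg.strict_transfer)
    labels = classifier.classify_all()
    counts = labels["label"].value_counts().to_dict()
    log.info("labels: %s", counts)
    report = classifier.pool_percentages(labels, cfg.windows)

    diss = ord_mod.bray_curtis(matrix.data)
    result = ord_mod.nmds(diss, matrix.data, seed=cfg.ordination_seed,
                          n_restarts=cfg.ordination_restarts)
    habs = matrix.samples.set_index("sample_id")["habitat"]
    try:
        signals = ord_mod.habitat_signal(result, habs, cfg.signal_threshold)
    except ValueError as exc:
        log.warning("habitat signal skipped: %s", exc)
        signals = {}

    # ---- artifacts -------------------------------------------------------
    _write_tsv(audit, out / "assignment_audit.tsv", cfg_hash)
    _write_tsv(matrix.data, out / "intensity_matrix.tsv", cfg_hash, index=True)
    _write_tsv(matrix.samples, out / "merged_samples.tsv", cfg_hash)
    _write_tsv(desc_table.reset_index(), out / "descriptors.tsv", cfg_hash)
    _write_tsv(labels, out / "trajectory_labels.tsv", cfg_hash)
    _write_tsv(result.coordinates.reset_index(names="sample_id"),
               out / "nmds_coordinates.tsv", cfg_hash)
    _write_tsv(result.loadings.reset_index(names="formula"),
               out / "nmds_loadings.tsv", cfg_hash)
    vk = desc_table.reset_index()[["formula", "hc", "oc",
                                   "elemental_class", "category"]]
    vk = vk.merge(labels[["formula", "habitat", "label"]], on="formula",
                  how="left")
    _write_tsv(vk, out / "van_krevelen.tsv", cfg_hash)
    with open(out / "pool_report.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, "report": _as_plain(report)},
                  fh, indent=2, default=str)
    with open(out / "habitat_signal.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, "stress": result.stress,
                   "threshold": cfg.signal_threshold,
                   "note": "threshold applied as <= -t / >= +t on NMDS1",
                   "signals": {k: sorted(v) for k, v in signals.items()}},
                  fh, indent=2)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump({
            "config_hash": cfg_hash,
            "config": _as_plain(cfg),
            "version": __version__,
            "n_measurements": len(peaks),
            "matrix_shape": list(matrix.data.shape),
            "label_counts": counts,
            "nmds_stress": result.stress,
        }, fh, indent=2)
    log.info("pipeline complete: %d formulae, stress %.4f -> %s",
             matrix.data.shape[0], result.stress, out)
    return PipelineResult(matrix=matrix, audit=audit, descriptors=desc_table,
                          labels=labels, report=report, ordination=result,
                          signals=signals, output_dir=out)


def simulate_and_run(cfg: PipelineConfig) -> PipelineResult:
    """Simulate a synthetic experiment and push it through the pipeline."""
    exp = syn.simulate_experiment(cfg.design, cfg.truth, cfg.seed)
    simdir = Path(cfg.output_dir) / "simulated"
    syn.write_experiment(exp, simdir)
    return run_pipeline(cfg, peaks=exp.peaks, manifest=exp.manifest)
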