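"""End-to-end cohort orchestration: simulate or load recordings, fit the
flow model per seizure, and write tidy result artifacts plus a manifest
sufficient to reproduce the run."""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .evaluation import summarize_cohort, EvaluationResult
from .model import PreictalFlow
from .preprocess import validate_recording
from .recording import Recording, ValidationError, load_recording, save_fixture
from .synthetic import generate_cohort

log = logging.getLogger("ieegflow")


@dataclass
class CohortSpec:
    """Synthetic-cohort parameters accepted by ``simulate`` and ``run``."""

    n_patients: int = 4
    regime_mix: dict = field(default_factory=lambda: {
        "inflow_dominant": 0.5, "outflow_dominant": 0.5})
    channels_range: tuple[int, int] = (10, 16)
    seizures_range: tuple[int, int] = (2, 3)
    coupling: float = 0.4
    noise_sd: float = 0.5
    ramp: bool = True
    base_seed: int = 0


@dataclass
class PipelineConfig:
    """Everything a run consumes, in one place."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    synthetic: CohortSpec | None = None
    recordings: list[str] = field(default_factory=list)
    periods: tuple[str, ...] = ("preictal",)

    def __post_init__(self) -> None:
        self.periods = tuple(self.periods)
        bad = set(self.periods) - {"preictal", "ictal"}
        if bad:
            raise ValidationError(f"unknown periods {bad}")
        if self.synthetic is None and not self.recordings:
            raise ValidationError(
                "config needs either a synthetic block or recording paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        analysis = AnalysisConfig.from_dict(raw.get("analysis", {}))
        synth = raw.get("synthetic")
        synthetic = None
        if synth is not None:
            known = set(CohortSpec.__dataclass_fields__)
            kwargs = {k: v for k, v in synth.items() if k in known}
            for key in ("channels_range", "seizures_range"):
                if key in kwargs:
                    kwargs[key] = tuple(kwargs[key])
            synthetic = CohortSpec(**kwargs)
        return cls(analysis=analysis, synthetic=synthetic,
                   recordings=list(raw.get("recordings", [])),
                   periods=tuple(raw.get("periods", ("preictal",))))

    def to_dict(self) -> dict:
        d = {"analysis": self.analysis.to_dict(),
             "recordings": list(self.recordings),
             "periods": list(self.periods)}
        if self.synthetic is not None:
            s = asdict(self.synthetic)
            s["channels_range"] = list(self.synthetic.channels_range)
            s["seizures_range"] = list(self.synthetic.seizures_range)
            d["synthetic"] = s
        return d


def _library_versions() -> dict:
    import numpy, scipy, pandas, sklearn
    return {"python": platform.python_version(),
            "numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__, "sklearn": sklearn.__version__}


def simulate(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Write a synthetic cohort to ``out_dir`` as npz fixtures plus a
    ground-truth JSON; returns the fixture paths."""
    if config.synthetic is None:
        raise ValidationError("config has no synthetic block")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s = config.synthetic
    cohort = generate_cohort(
        s.n_patients, s.regime_mix, base_seed=s.base_seed,
        channels_range=s.channels_range, seizures_range=s.seizures_range,
        coupling=s.coupling, noise_sd=s.noise_sd, ramp=s.ramp)
    paths, truths = [], {}
    for rec, truth in cohort:
        name = rec.meta["seizure_id"]
        path = out_dir / f"{name}.npz"
        save_fixture(path, rec)
        paths.append(path)
        truths[name] = {"regime": truth.regime,
                        "expected_measure": truth.expected_measure,
                        "soz_channels": [c for c, m in
                                         zip(rec.channel_labels,
                                             truth.soz_mask) if m]}
    (out_dir / "ground_truth.json").write_text(json.dumps(truths, indent=2))
    log.info("wrote %d synthetic recordings to %s", len(paths), out_dir)
    return paths


def _iter_recordings(config: PipelineConfig):
    if config.recordings:
        for path in config.recordings:
            yield load_recording(path)
    else:
        s = config.synthetic
        for rec, _ in generate_cohort(
                s.n_patients, s.regime_mix, base_seed=s.base_seed,
                channels_range=s.channels_range,
                seizures_range=s.seizures_range,
                coupling=s.coupling, noise_sd=s.noise_sd, ramp=s.ramp):
            yield rec


def run(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis for every recording in the config.

    Writes per-seizure flow CSVs, the pooled AUC table, regime labels with
    their test statistics, a cohort summary, and a manifest echoing the
    config, seeds, library versions and per-stage timings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis
    results: list[EvaluationResult] = []
    labels: dict[str, str] = {}
    timings: list[dict] = []
    skipped: list[dict] = []
    for i, rec in enumerate(_iter_recordings(config)):
        sid = str(rec.meta.get("seizure_id", f"rec{i:03d}"))
        outcome = validate_recording(rec, min_fs=cfg.min_fs,
                                     min_preictal_s=cfg.min_preictal_s)
        if not outcome:
            log.warning("skipping %s: %s", sid, outcome.reason)
            skipped.append({"seizure": sid, "reason": outcome.reason})
            continue
        t0 = time.perf_counter()
        try:
            res = PreictalFlow(rec, config=cfg, validate=False).fit(
                periods=config.periods)
        except Exception as err:
            raise RuntimeError(f"stage=fit seizure={sid}: {err}") from err
        timings.append({"seizure": sid,
                        "seconds": round(time.perf_counter() - t0, 3)})
        for key, flow in res.flow_series.items():
            method, measure, period = key
            flow.to_csv(out_dir / f"{sid}_{method}_{measure}_{period}.csv")
        labels[sid] = res.group_label
        results.append(res.to_evaluation_result())
        log.info("%s -> %s", sid, res.group_label)

    if not results:
        raise RuntimeError("stage=run: no recording passed validation")
    auc_table = pd.concat([r.auc_table for r in results], ignore_index=True)
    auc_table.to_csv(out_dir / "auc_table.csv", index=False)
    (out_dir / "group_labels.json").write_text(json.dumps(labels, indent=2))
    tests = pd.concat(
        [r.tests.assign(seizure=r.auc_table["seizure"].iloc[0])
         for r in results], ignore_index=True)
    tests.to_csv(out_dir / "classification_tests.csv", index=False)
    summary = summarize_cohort(results)
    summary.table.to_csv(out_dir / "cohort_summary.csv", index=False)
    meta = pd.DataFrame([
        {"seizure": r.auc_table["seizure"].iloc[0],
         "patient": r.auc_table["patient"].iloc[0], **r.meta}
        for r in results])
    meta.to_csv(out_dir / "recording_meta.csv", index=False)

    manifest = {"config": config.to_dict(),
                "master_seed": cfg.master_seed,
                "library_versions": _library_versions(),
                "timings": timings,
                "skipped": skipped,
                "n_recordings": len(results)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"auc_table": auc_table, "labels": labels,
            "summary": summary.table, "manifest": manifest}


def summarize(in_dir: str | Path, stratify_by: str | None = None
              ) -> pd.DataFrame:
    """Re-summarize a finished run directory, optionally stratified by a
    metadata column of ``recording_meta.csv``."""
    in_dir = Path(in_dir)
    auc_table = pd.read_csv(in_dir / "auc_table.csv")
    labels = json.loads((in_dir / "group_labels.json").read_text())
    meta = pd.read_csv(in_dir / "recording_meta.csv")
    results = []
    for sid, sub in auc_table.groupby("seizure"):
        row = meta[meta["seizure"] == sid]
        mrow = row.iloc[0].to_dict() if len(row) else {}
        results.append(EvaluationResult(
            auc_table=sub.reset_index(drop=True),
            group_label=labels.get(str(sid), "unclassified"),
            tests=pd.DataFrame(), meta=mrow))
    summary = summarize_cohort(results, stratify_by=stratify_by)
    out = in_dir / ("summary_stratified.csv" if stratify_by
                    else "cohort_summary.csv")
    summary.table.to_csv(out, index=False)
    if summary.strata_tests is not None and len(summary.strata_tests):
        summary.strata_tests.to_csv(in_dir / "strata_tests.csv", index=False)
    return summary.table
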