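"""End-to-end pipeline: simulate -> thresholds -> classify -> analyze -> sweep.

Every run writes plain CSV/JSON artifacts plus a manifest recording the seed,
a hash of the resolved configuration, package versions, and per-stage row
counts, so any number in the output directory can be traced to the stage that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .calibration import (
    derive_threshold_pair,
    fit_dose_response,
    resolve_thresholds,
)
from .classify import adherence_summary, classify_participants, tabulate
from .cohort import CohortParams, generate_cohort, table1_fixture, write_cohort
from .sensitivity import stability_report, sweep
from .survival import run_contrasts


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    ``threshold_source`` is exactly one of ``cosmos-default``,
    ``derive-from-calibration`` (requires ``calibration_csv``), or
    ``explicit`` (requires ``thresholds`` as [t_gvlm, t_srem]).
    """

    outdir: str = "results/run"
    seed: int = 0
    input_dir: str | None = None  # directory of 4 cohort CSVs; None -> simulate
    simulate: dict = field(default_factory=dict)  # CohortParams overrides
    use_table1_fixture: bool = False
    threshold_source: str = "cosmos-default"
    thresholds: list | None = None
    calibration_csv: str | None = None
    model_ids: list = field(default_factory=lambda: [2])
    endpoints: list = field(default_factory=lambda: ["total_cvd"])
    contrasts: list = field(default_factory=lambda: ["itt", "pp", "biomarker"])
    sweep_grid_gvlm: list | None = None
    sweep_grid_srem: list | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = pathlib.Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def validate(self) -> None:
        if self.threshold_source not in ("cosmos-default", "derive-from-calibration", "explicit"):
            raise ValueError(f"unknown threshold_source {self.threshold_source!r}")
        if self.threshold_source == "explicit" and not self.thresholds:
            raise ValueError("threshold_source=explicit requires thresholds=[t_gvlm, t_srem]")
        if self.threshold_source == "derive-from-calibration" and not self.calibration_csv:
            raise ValueError("threshold_source=derive-from-calibration requires calibration_csv")

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_cohort(cfg: PipelineConfig):
    if cfg.use_table1_fixture:
        participants, samples, reports = table1_fixture()
        return participants, samples, reports, None
    if cfg.input_dir:
        d = pathlib.Path(cfg.input_dir)
        participants = pd.read_csv(d / "participants.csv")
        samples = pd.read_csv(d / "urine_samples.csv")
        reports = pd.read_csv(d / "self_reports.csv")
        ev_path = d / "events.csv"
        events = pd.read_csv(ev_path) if ev_path.exists() else None
        return participants, samples, reports, events
    params = CohortParams(seed=cfg.seed, **cfg.simulate)
    participants, samples, reports, events, _ = generate_cohort(params)
    return participants, samples, reports, events


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline stages in order; returns the manifest.

    A stage failure is recorded in the manifest (``stages[*].status``) and
    downstream stages are skipped; the manifest is always written.
    """
    config.validate()
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "stages": {},
    }

    def record(stage, status, **info):
        manifest["stages"][stage] = {"status": status, **info}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        participants, samples, reports, events = _load_cohort(config)
        write_cohort(out / "cohort", participants, samples, reports, events)
        record(
            "simulate", "ok",
            n_participants=len(participants), n_samples=len(samples),
            n_reports=len(reports), n_events=0 if events is None else len(events),
        )
    except Exception as exc:
        record("simulate", f"failed: {exc}")
        return manifest

    try:
        if config.threshold_source == "derive-from-calibration":
            calib = pd.read_csv(config.calibration_csv)
            fits = {
                bm: fit_dose_response(calib, biomarker=bm)
                for bm in calib["biomarker"].unique()
            }
            thresholds = derive_threshold_pair(fits)
        elif config.threshold_source == "explicit":
            thresholds = resolve_thresholds(tuple(config.thresholds))
        else:
            thresholds = resolve_thresholds("cosmos")
        (out / "thresholds.json").write_text(
            json.dumps({"t_gvlm": thresholds.t_gvlm, "t_srem": thresholds.t_srem}, indent=2)
        )
        record("thresholds", "ok", t_gvlm=thresholds.t_gvlm, t_srem=thresholds.t_srem)
    except Exception as exc:
        record("thresholds", f"failed: {exc}")
        return manifest

    try:
        cls = classify_participants(participants, samples, thresholds)
        table1 = tabulate(cls, participants, samples)
        table1["adherence"] = adherence_summary(cls, reports)
        cls.to_csv(out / "classifications.csv", index=False)
        (out / "table1.json").write_text(json.dumps(table1, indent=2))
        record("classify", "ok", n_classified=len(cls), analysis_n=table1["analysis_n"])
    except Exception as exc:
        record("classify", f"failed: {exc}")
        return manifest

    if events is not None:
        try:
            table2, _ = run_contrasts(
                participants, events, self_reports=reports, classifications=cls,
                model_ids=config.model_ids, endpoints=config.endpoints,
                contrasts=config.contrasts,
            )
            table2.to_csv(out / "contrasts.csv", index=False)
            record("analyze", "ok", n_cells=len(table2),
                   n_estimable=int(table2["hr"].notna().sum()))
        except Exception as exc:
            record("analyze", f"failed: {exc}")
            return manifest
    else:
        record("analyze", "skipped: no events table")

    if events is not None and config.sweep_grid_gvlm and config.sweep_grid_srem:
        try:
            surface = sweep(
                participants, samples, events,
                config.sweep_grid_gvlm, config.sweep_grid_srem,
                endpoints=config.endpoints,
            )
            surface.to_frame().to_csv(out / "sweep.csv", index=False)
            try:
                stab = stability_report(surface, thresholds)
                (out / "stability.json").write_text(
                    json.dumps({k: asdict(v) for k, v in stab.items()}, indent=2)
                )
            except ValueError:
                pass  # reference cell outside grid or not estimable
            record("sweep", "ok", n_cells=int(surface.n_active.size))
        except Exception as exc:
            record("sweep", f"failed: {exc}")
            return manifest
    else:
        record("sweep", "skipped: no grid configured")

    return manifest
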