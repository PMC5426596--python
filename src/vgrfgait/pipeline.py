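"""One-command orchestration: (simulate | load) → preprocess → features →
selection → leave-one-subject-out evaluation → report bundle.

Outputs written to the run directory:

* ``features.csv`` — the per-subject 13-feature table with labels,
* ``selection.json`` — the selected subset and per-step diagnostics,
* ``metrics.csv`` — one row per classifier spec (accuracy, sensitivity,
  specificity, AUC, confusion counts),
* ``predictions.csv`` — pooled out-of-fold predictions and scores,
* ``run_log.json`` — config hash, package version, seed,
* ``MANIFEST`` — the stage reached, for post-mortem of partial runs.

The selection wrapper and the final comparison use the same LOO
evaluator and the same subjects; the metrics are therefore wrapper-
optimistic in the same way the original protocol is.  The report keeps
wrapper and final metrics clearly separated so the caveat stays visible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import compare_classifiers, default_specs, metrics_frame
from .features import FeatureConfig, feature_table, split_matrix
from .io import default_layout, load_layout, read_manifest, load_cohort
from .selection import mi_rank, mrmr_select, sequential_forward_select
from .synthetic import CohortConfig, simulate_cohort

STAGES = ("input", "features", "selection", "evaluation", "report")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    manifest: str | None = None        # load mode: path to a cohort manifest
    layout: str | None = None          # optional layout YAML override
    sampling_rate: float = 100.0
    simulate: dict = field(default_factory=dict)  # simulate mode: CohortConfig kwargs
    side: str = "left"
    feature_config: dict = field(default_factory=dict)  # FeatureConfig kwargs
    selection_method: str = "sfs"      # sfs | mrmr | mi | none
    selection_k: int = 10
    mrmr_criterion: str = "MID"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline failed at stage {stage!r}: {message}")
        self.stage = stage


def _write_manifest_file(out: Path, stage: str) -> None:
    (out / "MANIFEST").write_text(
        "".join(f"{s}: {'done' if STAGES.index(s) <= STAGES.index(stage) else 'pending'}\n"
                for s in STAGES))


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict.

    Deterministic given (config, seed): re-running with the same config
    produces byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        layout = load_layout(config.layout) if config.layout else default_layout()
        if config.manifest:
            manifest = read_manifest(config.manifest)
            records = load_cohort(manifest, layout=layout,
                                  sampling_rate=config.sampling_rate,
                                  base_dir=Path(config.manifest).parent)
        else:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("rng_seed", config.seed)
            cohort = simulate_cohort(CohortConfig(**sim_kwargs), layout=layout)
            records = cohort.records
        _write_manifest_file(out, stage)

        stage = "features"
        fconfig = FeatureConfig(**config.feature_config)
        table = feature_table(records, side=config.side, layout=layout, config=fconfig)
        if len(table) < 3:
            raise PipelineError(stage, f"only {len(table)} usable subjects")
        table.to_csv(out / "features.csv", index=False, float_format="%.10g")
        X, y, names = split_matrix(table)
        _write_manifest_file(out, stage)

        stage = "selection"
        frame = table[list(names)]
        if config.selection_method == "sfs":
            sel = sequential_forward_select(frame, y)
        elif config.selection_method == "mrmr":
            sel = mrmr_select(frame, y, k=config.selection_k,
                              criterion=config.mrmr_criterion)
        elif config.selection_method == "mi":
            sel = mi_rank(frame, y)
            sel.selected = sel.selected[:config.selection_k]
        elif config.selection_method == "none":
            sel = None
        else:
            raise PipelineError(stage, f"unknown selection method "
                                       f"{config.selection_method!r}")
        if sel is not None:
            with open(out / "selection.json", "w") as fh:
                json.dump(sel.to_dict(), fh, indent=1, sort_keys=True)
            keep = [n for n in names if n in sel.selected]
        else:
            keep = list(names)
        _write_manifest_file(out, stage)

        stage = "evaluation"
        Xsel = table[keep].to_numpy(dtype=float)
        results = compare_classifiers(Xsel, y, default_specs(), seed=config.seed)
        metrics = metrics_frame(results)
        metrics.insert(1, "features_used", ",".join(keep))
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        preds = []
        for name, res in results.items():
            for sid, yt, yp, sc in zip(table["subject_id"], res.y_true,
                                       res.y_pred, res.scores):
                preds.append({"classifier": name, "subject_id": sid,
                              "y_true": yt, "y_pred": yp, "score": sc})
        pd.DataFrame(preds).to_csv(out / "predictions.csv", index=False,
                                   float_format="%.10g")
        _write_manifest_file(out, stage)

        stage = "report"
        log = {"package_version": __version__, "seed": config.seed,
               "config_digest": config.digest(), "config": asdict(config),
               "n_subjects": int(len(table)), "features_used": keep}
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
        _write_manifest_file(out, stage)
        return {"out_dir": str(out), "n_subjects": len(table),
                "selected": keep, "metrics": metrics}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
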