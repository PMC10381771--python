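"""End-to-end orchestration: validate -> key-build -> score -> fit ->
diagnostics -> cull -> DIF, with a consolidated report bundle.

The stage order follows the construction logic of the instrument: stimuli
are normed and selected first, confusion-driven keys are built from the
norming data, responses are scored into graded categories, each modality
is calibrated as its own unidimensional GRM, items are diagnosed and
culled, and measurement equivalence is checked last.  Each stage's outputs
are the next stage's inputs; a stage failure halts downstream stages and
leaves an error manifest beside the completed outputs.

The report bundle is a directory of CSV/JSON files (diff-able, no binary
archives); every file embeds the config hash and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import GradedMatrix, write_item_bank, write_responses
from .diagnostics import (
    CullThresholds,
    compute_diagnostics,
    cull_items,
    reliability,
    test_information,
    tif_area,
)
from .dif import all_pairs, dif_report
from .grm import FitControls, default_quadrature, fit_grm, write_grm_fit
from .scoring import build_graded_matrix, category_frequencies
from .simulate import SimulationSpec, simulate_study
from .validation import (
    SelectionCriteria,
    StimulusStats,
    confusion_matrix,
    select_stimuli,
    stimulus_pi,
    summarize_ratings,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized into the output directory."""

    out_dir: str = "results/pipeline"
    seed: int = 20230719
    n_per_cell: int = 50
    stages: dict = field(
        default_factory=lambda: {
            "validate": True,
            "score": True,
            "fit": True,
            "diagnostics": True,
            "dif": True,
        }
    )
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    cull_rule: str = "two_of_three"
    cull_thresholds: CullThresholds = field(default_factory=CullThresholds)
    dif_factor: str = "race"
    fit_min_n: int = 100
    em_tol: float = 1e-3
    em_max_cycles: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if k == "criteria":
                cfg.criteria = SelectionCriteria(**v)
            elif k == "cull_thresholds":
                cfg.cull_thresholds = CullThresholds(**v)
            elif hasattr(cfg, k):
                setattr(cfg, k, v)
            else:
                raise ValueError(f"unknown config key {k!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        # hash the analysis-relevant settings only: where outputs land and
        # how loudly we log must not change what they contain
        d = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.content_hash(), "package_version": __version__}


def _write_json(path: Path, payload: dict, cfg: PipelineConfig) -> None:
    payload = {**_stamp(cfg), **payload}
    path.write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_csv(path: Path, df: pd.DataFrame, cfg: PipelineConfig) -> None:
    stamp = _stamp(cfg)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={stamp['config_hash']} version={stamp['package_version']}\n")
        df.to_csv(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the staged flow on a seeded synthetic study; return a manifest.

    Fully deterministic given (config, seed): identical reruns produce
    byte-identical outputs (no timestamps enter file contents).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages_completed": [], "error": None}
    (out / "config.json").write_text(
        json.dumps({**_stamp(config), **config.to_dict()}, indent=1, default=_jsonify)
    )
    try:
        # --- simulate inputs -------------------------------------------------
        spec = SimulationSpec(n_per_cell=config.n_per_cell, seed=config.seed)
        study = simulate_study(spec)
        write_responses(study.table, out / "responses.csv")
        write_item_bank(study.bank, out / "bank.json")
        manifest["stages_completed"].append("simulate")

        modalities = sorted({s.modality for s in study.bank.stimuli.values()})

        # --- validate --------------------------------------------------------
        if config.stages.get("validate", True):
            ratings = summarize_ratings(study.table)
            _write_csv(out / "ratings_per_stimulus.csv", ratings.per_stimulus, config)
            stats = []
            for sid, stim in sorted(study.bank.stimuli.items()):
                per = ratings.per_stimulus
                mi = float(per.loc[sid, "intensity_mean"]) if sid in per.index else None
                mb = float(per.loc[sid, "believability_mean"]) if sid in per.index else None
                stats.append(
                    StimulusStats(
                        stimulus_id=sid, modality=stim.modality,
                        pi=stimulus_pi(study.table, sid, n_options=study.bank.keys[sid].n_options),
                        mean_intensity=mi, mean_believability=mb,
                    )
                )
            sel = select_stimuli(stats, config.criteria)
            _write_json(
                out / "stimulus_selection.json",
                {"accepted": sel.accepted, "rejected": sel.rejected, "reasons": sel.reasons},
                config,
            )
            for mod in modalities:
                cm = confusion_matrix(study.table, mod)
                _write_csv(out / f"confusion_{mod}_pi.csv", cm.pi_frame(), config)
            manifest["stages_completed"].append("validate")

        # --- score -----------------------------------------------------------
        matrix = build_graded_matrix(study.table, study.bank)
        _write_csv(out / "graded_matrix.csv", matrix.to_frame(), config)
        _write_csv(out / "category_frequencies.csv", category_frequencies(matrix), config)
        manifest["stages_completed"].append("score")

        # --- fit / diagnostics / cull per modality ---------------------------
        fits = {}
        controls = FitControls(
            min_n=config.fit_min_n, tol=config.em_tol, max_cycles=config.em_max_cycles
        )
        if config.stages.get("fit", True):
            quad = default_quadrature()
            for mod in modalities:
                sub = matrix.subset_items(study.bank.by_modality(mod))
                sub.group_labels = matrix.group_labels
                fit = fit_grm(sub, quad, controls)
                fits[mod] = (sub, fit)
                write_grm_fit(fit, out / f"fit_{mod}.json")
            manifest["stages_completed"].append("fit")

        if config.stages.get("diagnostics", True) and fits:
            for mod, (sub, fit) in fits.items():
                diags = compute_diagnostics(sub, fit)
                df = pd.DataFrame(
                    [
                        {
                            "Item Name": d.item_id,
                            "Item Information": d.scalar_information,
                            "Factor Loadings": d.loading,
                            "chisq": d.fit_chisq,
                            "d.f.": d.fit_df,
                            "p": d.fit_p,
                            "chisq/d.f.": d.chisq_df_ratio,
                        }
                        for d in diags
                    ]
                ).set_index("Item Name")
                _write_csv(out / f"diagnostics_{mod}.csv", df, config)
                cull = cull_items(diags, config.cull_thresholds, config.cull_rule)
                rel = reliability(sub, fit)
                _write_json(
                    out / f"summary_{mod}.json",
                    {
                        "retained": cull.retained,
                        "culled": cull.culled,
                        "reasons": cull.reasons,
                        "alpha": rel.alpha,
                        "omega": rel.omega,
                        "tif_area_-3_3": tif_area(fit),
                    },
                    config,
                )
                grid = np.linspace(-3, 3, 61)
                _write_csv(
                    out / f"tif_{mod}.csv",
                    pd.DataFrame({"theta": grid, "information": test_information(grid, fit)}).set_index("theta"),
                    config,
                )
            manifest["stages_completed"].append("diagnostics")

        # --- DIF -------------------------------------------------------------
        if config.stages.get("dif", True) and fits:
            for mod, (sub, fit) in fits.items():
                levels = sorted(sub.group_labels[config.dif_factor].unique())
                reports = dif_report(
                    sub, config.dif_factor, all_pairs(levels), controls=controls
                )
                rows = []
                detail = []
                for rep in reports:
                    rows.append({"comparison": rep.comparison, "mean_d_dif": rep.mean_d_dif})
                    for r in rep.results:
                        detail.append(
                            {
                                "comparison": rep.comparison,
                                "item_id": r.item_id,
                                "d_dif": r.d_dif,
                                "classification": r.classification,
                            }
                        )
                _write_csv(out / f"dif_{mod}.csv", pd.DataFrame(rows).set_index("comparison"), config)
                _write_csv(out / f"dif_{mod}_items.csv", pd.DataFrame(detail).set_index("item_id"), config)
            manifest["stages_completed"].append("dif")
    except Exception as err:  # stage failure: record and halt downstream
        manifest["error"] = {"stage": _next_stage(manifest), "message": str(err)}
        (out / "error_manifest.json").write_text(
            json.dumps({**manifest, "traceback": traceback.format_exc()}, indent=1)
        )
        raise
    (out / "manifest.json").write_text(json.dumps({**_stamp(config), **manifest}, indent=1))
    return manifest


def _next_stage(manifest: dict) -> str:
    order = ["simulate", "validate", "score", "fit", "diagnostics", "dif"]
    done = set(manifest["stages_completed"])
    for s in order:
        if s not in done:
            return s
    return "unknown"
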