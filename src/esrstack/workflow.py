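"""End-to-end orchestration: simulate -> extract -> evaluate -> compare -> report.

A run directory holds one CSV/JSON artifact per stage plus a manifest that
records the configuration, every derived seed and a checksum per output file,
so any stage can be re-run in isolation and two runs with the same master
seed produce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from esrstack import synth
from esrstack.basemodels import ArchitectureSpec, TrainConfig, make_windows
from esrstack.compare import bland_altman, full_comparison
from esrstack.ensemble import fit_stacking, save_manifest
from esrstack.evaluate import (
    EvalModel,
    default_roster,
    proportional_split_sizes,
    repeated_eval,
    split_cohort,
)
from esrstack.synth import ParamPriors, RenderSpec

logger = logging.getLogger("esrstack")

STAGES = ("simulate", "extract", "evaluate", "compare", "report")

#: windows shorter than this produce unusable forecasts; require an override
MIN_SEQUENCE_MIN = 5.0


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message} (re-run with: esrstack {stage} --out <run dir>)")
        self.stage = stage


@dataclass
class RunConfig:
    """Operating point of a full pipeline run.

    Defaults follow the reference protocol: 304 normal + 6 patient subjects,
    194/50/60 split, 15-min input window, N_B = 8 bootstrap bases, all four
    meta-models on LSTM and GRU bases, D = 30 repetitions, alpha = 0.05.
    """

    n_normal: int = 304
    n_patient: int = 6
    noise_sd: float = 0.004
    render: bool = False             # False: tabular curves only; True: image round trip
    split_sizes: tuple[int, int, int] | None = None  # None -> proportional 194/50/60
    length_min: float = 15.0
    n_base: int = 8
    D: int = 30
    alpha: float = 0.05
    seed: int = 0
    max_epochs: int = 300
    patience: int = 15
    allow_short_window: bool = False
    column_height_px: int = 290
    pixel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.split_sizes is not None:
            self.split_sizes = tuple(int(s) for s in self.split_sizes)
            if sum(self.split_sizes) != self.n_normal:
                raise ValueError(
                    f"split sizes {self.split_sizes} must sum to n_normal={self.n_normal}"
                )
        if abs(self.length_min / synth.TIME_STEP_MIN - round(self.length_min / synth.TIME_STEP_MIN)) > 1e-9:
            raise ValueError("length_min must lie on the 0.5-min grid")
        if self.length_min < MIN_SEQUENCE_MIN and not self.allow_short_window:
            raise ValueError(
                f"input windows below {MIN_SEQUENCE_MIN} min give extremely poor "
                "forecasts; set allow_short_window to override"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if d["split_sizes"] is not None:
            d["split_sizes"] = list(d["split_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("split_sizes") is not None:
            d["split_sizes"] = tuple(d["split_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(4) % (2**31 - 1)
        return {
            "simulate": int(state[0]),
            "extract": int(state[1]),
            "evaluate": int(state[2]),
            "compare": int(state[3]),
        }

    def train_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(max_epochs=self.max_epochs, patience=self.patience, seed=seed)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: str, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": config.stage_seeds(),
        "package_version": __import__("esrstack").__version__,
        "checksums": {},
    }
    if extra:
        manifest.update(extra)
    for name in sorted(os.listdir(out_dir)):
        if name == "manifest.json" or not name.endswith((".csv", ".json", ".md", ".yaml")):
            continue
        manifest["checksums"][name] = _sha256(os.path.join(out_dir, name))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    seed = config.stage_seeds()["simulate"]
    logger.info("simulate: n_normal=%d n_patient=%d seed=%d", config.n_normal, config.n_patient, seed)
    priors = ParamPriors(noise_sd=config.noise_sd)
    curves = synth.generate_dataset(config.n_normal, config.n_patient, seed=seed, priors=priors)
    synth.save_curves(curves, os.path.join(out_dir, "curves_true.csv"))
    config.to_yaml(os.path.join(out_dir, "config.yaml"))


def stage_extract(config: RunConfig, out_dir: str) -> None:
    from esrstack.imaging import extract_series

    path = os.path.join(out_dir, "curves_true.csv")
    if not os.path.exists(path):
        raise StageError("extract", "missing curves_true.csv; run simulate first")
    curves = synth.load_curves(path)
    seed = config.stage_seeds()["extract"]
    if not config.render:
        logger.info("extract: curves-only mode, passing ground-truth curves through")
        synth.save_curves(curves, os.path.join(out_dir, "curves_measured.csv"))
        return
    logger.info("extract: rendering %d image stacks (seed=%d)", len(curves), seed)
    spec = RenderSpec(
        column_height_px=config.column_height_px, pixel_noise_sd=config.pixel_noise_sd
    )
    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=max(len(curves), 1))
    measured = []
    for curve, sub in zip(curves, sub_seeds):
        frames = synth.render_frames(curve, spec, seed=int(sub))
        measured.append(
            extract_series(frames, curve.times, sample_id=curve.sample_id, group=curve.group)
        )
    synth.save_curves(measured, os.path.join(out_dir, "curves_measured.csv"))


def stage_evaluate(config: RunConfig, out_dir: str) -> None:
    path = os.path.join(out_dir, "curves_measured.csv")
    if not os.path.exists(path):
        raise StageError("evaluate", "missing curves_measured.csv; run extract first")
    curves = [c for c in synth.load_curves(path) if c.group == "normal"]
    seed = config.stage_seeds()["evaluate"]
    roster = default_roster(config.n_base)
    logger.info("evaluate: %d models, D=%d, L=%.1f min, seed=%d",
                len(roster), config.D, config.length_min, seed)
    records = repeated_eval(
        curves, roster,
        length_min=config.length_min, D=config.D, master_seed=seed,
        split_sizes=config.split_sizes, config=config.train_config(),
    )
    records.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)


def stage_compare(config: RunConfig, out_dir: str) -> None:
    metrics_path = os.path.join(out_dir, "metrics.csv")
    if not os.path.exists(metrics_path):
        raise StageError("compare", "missing metrics.csv; run evaluate first")
    records = pd.read_csv(metrics_path)
    report = full_comparison(records, alpha=config.alpha)
    report.to_frame().to_csv(os.path.join(out_dir, "comparison.csv"), index=False)
    summary = {
        "alpha": config.alpha,
        "k": report.k,
        "D": report.D,
        "metrics": {
            m: {
                "friedman_statistic": mc.statistic,
                "friedman_p": mc.p_value,
                "cd": mc.cd,
                "mean_ranks": {str(i): float(v) for i, v in mc.mean_ranks.items()},
                "groups": mc.groups,
                "posthoc_run": mc.cd is not None,
            }
            for m, mc in report.metrics.items()
        },
    }
    with open(os.path.join(out_dir, "comparison.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _patient_agreement(config, out_dir)


def _patient_agreement(config: RunConfig, out_dir: str) -> None:
    """Train the headline GRU-PLSR ensemble and Bland-Altman it on patients."""
    curves = synth.load_curves(os.path.join(out_dir, "curves_measured.csv"))
    normal = [c for c in curves if c.group == "normal"]
    patient = [c for c in curves if c.group != "normal"]
    if not patient:
        logger.info("compare: no patient group; skipping Bland-Altman")
        return
    seed = config.stage_seeds()["compare"]
    tr_c, va_c, te_c = split_cohort(normal, config.split_sizes, seed=seed)
    L = config.length_min
    train = make_windows(tr_c, L, allow_any_length=True)
    val = make_windows(va_c, L, allow_any_length=True)
    pat = make_windows(patient, L, allow_any_length=True)
    ensemble, _ = fit_stacking(
        ArchitectureSpec("GRU"), config.n_base, "plsr",
        train, val, pat, config=config.train_config(), rng=seed,
    )
    pred = ensemble.predict(pat)
    ba = bland_altman(pat.y, pred)
    out = {
        "model": "GRU-PLSR",
        "n": int(pat.n),
        "bias": ba.bias,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
        "sd_diff": ba.sd_diff,
        "coverage": ba.coverage,
        "pairs": [[float(m), float(d)] for m, d in zip(ba.means, ba.differences)],
    }
    with open(os.path.join(out_dir, "bland_altman.json"), "w") as fh:
        json.dump(out, fh, indent=1)
    save_manifest(ensemble, os.path.join(out_dir, "ensemble_manifest.json"))


def stage_report(config: RunConfig, out_dir: str) -> None:
    metrics_path = os.path.join(out_dir, "metrics.csv")
    comparison_path = os.path.join(out_dir, "comparison.json")
    if not (os.path.exists(metrics_path) and os.path.exists(comparison_path)):
        raise StageError("report", "missing metrics.csv/comparison.json; run earlier stages")
    records = pd.read_csv(metrics_path)
    with open(comparison_path) as fh:
        comparison = json.load(fh)
    lines = [
        "# ESR prediction run report",
        "",
        f"- cohort: {config.n_normal} normal + {config.n_patient} patient subjects",
        f"- input window: {config.length_min} min; ensemble size N_B = {config.n_base}",
        f"- repetitions D = {comparison['D']}; models k = {comparison['k']}; "
        f"alpha = {comparison['alpha']}",
        "",
        "## Mean errors over repetitions (test split)",
        "",
        "| model | mean MAPE (%) | SD | mean RMSE | SD |",
        "|---|---|---|---|---|",
    ]
    summary = (
        records.groupby("model_id")
        .agg(
            mean_mape=("mape", "mean"), sd_mape=("mape", lambda s: s.std(ddof=1)),
            mean_rmse=("rmse", "mean"), sd_rmse=("rmse", lambda s: s.std(ddof=1)),
        )
        .sort_values("mean_mape")
    )
    for model_id, row in summary.iterrows():
        lines.append(
            f"| {model_id} | {row.mean_mape:.3f} | {row.sd_mape:.3f} "
            f"| {row.mean_rmse:.4f} | {row.sd_rmse:.4f} |"
        )
    for metric, mc in comparison["metrics"].items():
        lines += [
            "",
            f"## Friedman/Nemenyi on {metric.upper()}",
            "",
            f"- Friedman statistic {mc['friedman_statistic']:.3f}, p = {mc['friedman_p']:.3g}",
            f"- critical distance CD = {mc['cd']:.3f}" if mc["cd"] is not None
            else "- post-hoc skipped (Friedman not significant)",
            "- mean ranks (best first): "
            + ", ".join(f"{m} {r:.2f}" for m, r in sorted(mc["mean_ranks"].items(), key=lambda t: t[1])),
        ]
    ba_path = os.path.join(out_dir, "bland_altman.json")
    if os.path.exists(ba_path):
        with open(ba_path) as fh:
            ba = json.load(fh)
        lines += [
            "",
            "## Bland-Altman agreement on the patient group",
            "",
            f"- model: {ba['model']} on n = {ba['n']} patient samples",
            f"- bias {ba['bias']:+.4f}, 95% limits of agreement "
            f"[{ba['loa_low']:+.4f}, {ba['loa_high']:+.4f}]",
        ]
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "evaluate": stage_evaluate,
    "compare": stage_compare,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, out_dir: str, stages: tuple[str, ...] = STAGES) -> str:
    """Run the requested stages in order; returns the run directory."""
    os.makedirs(out_dir, exist_ok=True)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage %s starting", stage)
        try:
            _STAGE_FUNCS[stage](config, out_dir)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
    _write_manifest(out_dir, config)
    return out_dir
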