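"""Synthetic sedimentation curves and rendered syringe image stacks.

Real sedimentation data consist of one grayscale frame of the blood column
every 0.5 min for 60 min; after normalization each subject yields a curve
H_E/H_T(t) that starts at 1, falls along a three-phase (lag / fast
sedimentation / packing) trajectory and ends at the ESR value, which for
normal subjects at 35% hematocrit spans roughly 0.35-0.86.  This module
emulates that structure so the measurement and modelling stages can be
exercised without access to a clinical cohort.

The noiseless curve is a rescaled logistic,

    h(t) = 1 - (1 - esr_final) * (F(t) - F(0)) / (F(60) - F(0)),

with F the logistic CDF with midpoint ``t_mid`` and steepness ``rate``.  The
rescaling pins h(0) = 1 and h(60) = esr_final exactly, and the sedimentation
velocity -dh/dt peaks at ``t_mid``, reproducing the acceleration-then-decay
velocity profile seen in real columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

TIME_STEP_MIN = 0.5
TOTAL_TIME_MIN = 60.0
#: the fixed measurement grid: 0, 0.5, ..., 60 min (121 points)
TIME_GRID = np.round(np.arange(0.0, TOTAL_TIME_MIN + TIME_STEP_MIN / 2, TIME_STEP_MIN), 4)

GROUPS = ("normal", "periodontitis")


class ConfigError(ValueError):
    """Invalid generator configuration (priors, render spec, ...)."""


@dataclass(frozen=True)
class CurveParams:
    """Free parameters of one synthetic sedimentation curve.

    esr_final : normalized column height at 60 min, in (0, 1).
    t_mid     : minutes; sigmoid midpoint == sedimentation-velocity peak time.
    rate      : 1/min; sigmoid steepness.
    noise_sd  : additive Gaussian measurement noise on h_ratio.
    group     : "normal" or "periodontitis".
    """

    esr_final: float
    t_mid: float
    rate: float
    noise_sd: float = 0.0
    group: str = "normal"

    def __post_init__(self) -> None:
        if not 0.0 < self.esr_final < 1.0:
            raise ValueError(f"esr_final must be in (0, 1), got {self.esr_final}")
        if self.t_mid <= 0:
            raise ValueError(f"t_mid must be positive, got {self.t_mid}")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class SedimentationCurve:
    """One subject's normalized column-height series on the fixed 0.5-min grid."""

    sample_id: str
    times: np.ndarray
    h_ratio: np.ndarray
    group: str = "normal"
    params: CurveParams | None = None  # generating parameters, if synthetic
    seed: int | None = None  # per-curve sub-seed, for provenance

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.h_ratio = np.asarray(self.h_ratio, dtype=float)
        if self.times.shape != self.h_ratio.shape:
            raise ValueError("times and h_ratio must have the same length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def esr(self) -> float:
        """H_E/H_T at the final time point (the ESR value for a 60-min curve)."""
        return float(self.h_ratio[-1])

    def monotone_projected(self) -> "SedimentationCurve":
        """Cumulative-minimum projection onto non-increasing curves."""
        return SedimentationCurve(
            sample_id=self.sample_id,
            times=self.times.copy(),
            h_ratio=np.minimum.accumulate(self.h_ratio),
            group=self.group,
            params=self.params,
            seed=self.seed,
        )


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and photometry of the rendered syringe column."""

    column_height_px: int = 290
    column_width_px: int = 12
    erythrocyte_gray: int = 60
    plasma_gray: int = 200
    pixel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.column_height_px <= 0 or self.column_width_px <= 0:
            raise ConfigError("column dimensions must be positive")
        if not (0 <= self.erythrocyte_gray <= 255 and 0 <= self.plasma_gray <= 255):
            raise ConfigError("gray levels must be in 0..255")
        if self.erythrocyte_gray >= self.plasma_gray:
            raise ConfigError("erythrocyte column must be darker than plasma")
        if self.pixel_noise_sd < 0:
            raise ConfigError("pixel_noise_sd must be >= 0")


@dataclass(frozen=True)
class ParamPriors:
    """Uniform priors over CurveParams, one set per group.

    Defaults emulate a normal cohort whose 60-min ESR spans 0.35-0.86 with
    velocity peaks in the 10-20 min window, and a faster-sedimenting
    periodontitis-like group (lower endpoint, velocity peak ~4 min earlier).
    """

    esr_final_normal: tuple[float, float] = (0.35, 0.86)
    esr_final_patient: tuple[float, float] = (0.35, 0.55)
    t_mid_normal: tuple[float, float] = (10.0, 20.0)
    t_mid_patient: tuple[float, float] = (6.0, 16.0)
    rate: tuple[float, float] = (0.18, 0.40)
    noise_sd: float = 0.004

    def __post_init__(self) -> None:
        for name in ("esr_final_normal", "esr_final_patient"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi < 1.0):
                raise ConfigError(f"{name} bounds must satisfy 0 < lo <= hi < 1")
        for name in ("t_mid_normal", "t_mid_patient", "rate"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ConfigError(f"{name} bounds must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def draw(self, group: str, rng: np.random.Generator) -> CurveParams:
        if group == "normal":
            esr = rng.uniform(*self.esr_final_normal)
            t_mid = rng.uniform(*self.t_mid_normal)
        elif group == "periodontitis":
            esr = rng.uniform(*self.esr_final_patient)
            t_mid = rng.uniform(*self.t_mid_patient)
        else:
            raise ConfigError(f"unknown group {group!r}")
        rate = rng.uniform(*self.rate)
        return CurveParams(esr_final=esr, t_mid=t_mid, rate=rate, noise_sd=self.noise_sd, group=group)


def _logistic(t: np.ndarray, t_mid: float, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - t_mid)))


def curve_model(params: CurveParams, t):
    """Noiseless normalized column height h(t) at time(s) ``t`` in minutes.

    h(0) = 1 and h(60) = esr_final exactly; -dh/dt is maximal at t_mid.
    Raises ValueError for t outside [0, 60].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > TOTAL_TIME_MIN):
        raise ValueError("t must lie in [0, 60] minutes")
    f = _logistic(t_arr, params.t_mid, params.rate)
    f0 = _logistic(np.array(0.0), params.t_mid, params.rate)
    f1 = _logistic(np.array(TOTAL_TIME_MIN), params.t_mid, params.rate)
    amplitude = 1.0 - params.esr_final
    h = 1.0 - amplitude * (f - f0) / (f1 - f0)
    return h if h.ndim else float(h)


def make_curve(
    params: CurveParams,
    sample_id: str,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    monotone: bool = False,
) -> SedimentationCurve:
    """One curve on the 121-point grid, with optional noise and projection."""
    h = np.asarray(curve_model(params, TIME_GRID), dtype=float)
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        h = h + rng.normal(0.0, params.noise_sd, size=h.shape)
    h = np.clip(h, 1e-6, 1.05)
    curve = SedimentationCurve(
        sample_id=sample_id, times=TIME_GRID.copy(), h_ratio=h,
        group=params.group, params=params, seed=seed,
    )
    return curve.monotone_projected() if monotone else curve


def generate_dataset(
    n_normal: int,
    n_patient: int = 0,
    seed: int = 0,
    priors: ParamPriors | None = None,
    monotone: bool = False,
) -> list[SedimentationCurve]:
    """Reproducible synthetic cohort: ``n_normal`` + ``n_patient`` curves.

    All randomness flows from ``seed`` via spawned per-curve sub-seeds, so the
    i-th curve is independent of cohort size ordering and the whole cohort is
    bitwise reproducible.
    """
    if n_normal < 0 or n_patient < 0:
        raise ValueError("counts must be >= 0")
    priors = priors or ParamPriors()
    n_total = n_normal + n_patient
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=max(n_total, 1))
    curves: list[SedimentationCurve] = []
    for i in range(n_total):
        group = "normal" if i < n_normal else "periodontitis"
        idx = i if group == "normal" else i - n_normal
        sub = int(sub_seeds[i])
        rng = np.random.default_rng(sub)
        params = priors.draw(group, rng)
        curves.append(
            make_curve(params, f"{group}_{idx:04d}", rng=rng, seed=sub, monotone=monotone)
        )
    return curves


# ---------------------------------------------------------------------------
# image rendering

def render_frames(
    curve: SedimentationCurve, spec: RenderSpec, seed: int = 0
) -> np.ndarray:
    """Render the curve as a (n_times, H, W) uint8 grayscale stack.

    At each time the top fraction 1 - h_ratio of rows is plasma-bright and the
    bottom fraction h_ratio is erythrocyte-dark; the interface sits at row
    round((1 - h_ratio) * column_height_px), counting from the top.
    """
    rng = np.random.default_rng(seed)
    n_t = curve.times.size
    h_px, w_px = spec.column_height_px, spec.column_width_px
    rows = np.arange(h_px)[None, :]  # (1, H)
    iface = np.rint((1.0 - np.clip(curve.h_ratio, 0.0, 1.0)) * h_px)[:, None]  # (T, 1)
    frames = np.where(rows < iface, float(spec.plasma_gray), float(spec.erythrocyte_gray))
    frames = np.repeat(frames[:, :, None], w_px, axis=2)  # (T, H, W)
    if spec.pixel_noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.pixel_noise_sd, size=frames.shape)
    return np.clip(np.rint(frames), 0, 255).astype(np.uint8)


def save_frames(frames: np.ndarray, times: np.ndarray, sample_id: str, out_dir: str) -> list[str]:
    """Write one 8-bit PNG per frame as ``<sample_id>_t<minutes*10>.png``."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for frame, t in zip(frames, times):
        path = os.path.join(out_dir, f"{sample_id}_t{int(round(t * 10))}.png")
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def load_frames(paths: list[str]) -> np.ndarray:
    import imageio.v3 as iio

    return np.stack([iio.imread(p) for p in paths])


# ---------------------------------------------------------------------------
# tabular I/O (long CSV: sample_id, group, time_min, h_ratio)

def curves_to_frame(curves: list[SedimentationCurve]) -> pd.DataFrame:
    records = []
    for c in curves:
        records.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "group": c.group,
                    "time_min": c.times,
                    "h_ratio": c.h_ratio,
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=["sample_id", "group", "time_min", "h_ratio"])
    return pd.concat(records, ignore_index=True)


def save_curves(curves: list[SedimentationCurve], path: str) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def load_curves(path_or_frame) -> list[SedimentationCurve]:
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame)
    curves = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("time_min")
        group = str(sub["group"].iloc[0]) if "group" in sub else "normal"
        curves.append(
            SedimentationCurve(
                sample_id=str(sample_id),
                times=sub["time_min"].to_numpy(float),
                h_ratio=sub["h_ratio"].to_numpy(float),
                group=group,
            )
        )
    return curves
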