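"""Measurement pipeline: frame -> binary -> row profile -> interface -> curve.

Each grayscale frame of the (already-cropped) blood column is binarized with
Otsu's method, averaged across rows to a 1-D intensity profile, and the
erythrocyte/plasma interface is located as the single least-squares
changepoint of that profile.  Row 0 is the TOP of the column (plasma side);
with the interface at row c of n rows, the normalized erythrocyte-column
height is H_E/H_T = 1 - c/n.  Repeating over all frames yields the
sedimentation curve; differentiating it yields the sedimentation velocity
V_E = -dH/dt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from esrstack.synth import SedimentationCurve

#: frames whose two Otsu classes differ by less than this many gray levels are
#: treated as uniform (all-plasma or all-erythrocyte) rather than changepointed
MIN_CONTRAST_GRAY = 20.0


class DegenerateImageError(ValueError):
    """Image lacks the structure the operation requires (e.g. constant)."""


def _as_uint8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.dtype == np.uint8:
        return image
    if np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() > 255:
            raise ValueError("integer images must have values in 0..255")
        return image.astype(np.uint8)
    raise ValueError("images must be 8-bit grayscale (integer 0..255)")


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold over the 256-bin histogram.

    Returns the gray level T maximizing the between-class variance
    w0*w1*(mu0-mu1)^2 of the split {<=T} / {>T}; ties go to the smallest T.
    """
    image = _as_uint8(image)
    hist = np.bincount(image.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("Otsu requires at least 2 distinct gray levels")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)                      # pixels at level <= T
    total = w0[-1]
    sum0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu0 = np.divide(sum0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros(256), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[w1 == 0] = -np.inf  # a split must leave both classes nonempty
    return int(np.argmax(between))


def otsu_binarize(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Binarize with Otsu's method; pixels above the threshold map to 1 (plasma)."""
    image = _as_uint8(image)
    threshold = otsu_threshold(image)
    return (image > threshold).astype(np.uint8), threshold


def horizontal_profile(binary: np.ndarray) -> np.ndarray:
    """Row-wise mean of a binary image (top row first)."""
    binary = np.asarray(binary, dtype=float)
    if binary.ndim != 2 or binary.size == 0:
        raise ValueError("expected a nonempty 2-D image")
    return binary.mean(axis=1)


def detect_interface(profile: np.ndarray) -> int:
    """Single least-squares changepoint of a 1-D profile.

    Returns the cut index c (1 <= c <= n-1) minimizing the total squared
    deviation of segments [0, c) and [c, n) from their own means; ties break
    to the smallest c.  This is the classical one-changepoint, squared-error
    criterion (the statistic behind MATLAB's findchangepts default).
    """
    x = np.asarray(profile, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("profile must have at least 2 points")
    # SSE(a, b) = sum(x^2) - (sum x)^2 / m for each segment; prefix sums give
    # every cut in O(n).
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    m_left = np.arange(1, n)                  # cut c -> left has c points
    left_sse = s2[:-1] - s1[:-1] ** 2 / m_left
    sum_r = s1[-1] - s1[:-1]
    sumsq_r = s2[-1] - s2[:-1]
    right_sse = sumsq_r - sum_r**2 / (n - m_left)
    total = left_sse + right_sse
    return int(np.argmin(total)) + 1


@dataclass
class FrameAudit:
    """Per-frame measurement provenance for the JSON sidecar."""

    index: int
    threshold: int | None
    changepoint: int | None
    degenerate: bool
    polarity_flipped: bool = False


def _global_threshold(frames: np.ndarray) -> float:
    """Otsu threshold of the pooled histogram; mid-gray if the stack is constant."""
    try:
        return float(otsu_threshold(frames.reshape(-1, 1)))
    except DegenerateImageError:
        return 127.5


def _measure_frame(
    frame: np.ndarray, global_thr: float, index: int
) -> tuple[float, FrameAudit]:
    frame = _as_uint8(frame)
    n_rows = frame.shape[0]
    try:
        binary, thr = otsu_binarize(frame)
    except DegenerateImageError:
        # constant frame: dark => full erythrocyte column, light => empty
        h = 1.0 if frame.flat[0] <= global_thr else 0.0
        return h, FrameAudit(index, None, None, degenerate=True)
    class_hi = frame[binary == 1]
    class_lo = frame[binary == 0]
    if class_hi.mean() - class_lo.mean() < MIN_CONTRAST_GRAY:
        # near-uniform frame (e.g. t=0 plus pixel noise): Otsu is splitting
        # noise, not an interface; classify against the stack-global threshold
        h = 1.0 if frame.mean() <= global_thr else 0.0
        return h, FrameAudit(index, int(thr), None, degenerate=True)
    cut = detect_interface(horizontal_profile(binary))
    flipped = False
    upper_mean = binary[:cut].mean()
    if upper_mean < binary[cut:].mean():
        # plasma must be the brighter (=1) class on top; flip polarity
        warnings.warn(f"frame {index}: binarization polarity flipped", stacklevel=3)
        flipped = True
    h = 1.0 - cut / n_rows
    return h, FrameAudit(index, int(thr), int(cut), degenerate=False, polarity_flipped=flipped)


def extract_series(
    frames: np.ndarray | list[np.ndarray],
    times: np.ndarray,
    sample_id: str = "sample",
    group: str = "normal",
    return_audit: bool = False,
):
    """Assemble the H_E/H_T curve from an ordered image stack.

    One frame per time point; per-frame failures are re-raised with the frame
    index attached.  Degenerate (uniform) frames map to h=1 (dark) or h=0
    (light) instead of failing, since the t=0 frame is legitimately all-dark.
    """
    frames = np.asarray(frames)
    times = np.asarray(times, dtype=float)
    if frames.size == 0:
        raise ValueError("empty frame stack")
    if frames.shape[0] != times.size:
        raise ValueError(f"{frames.shape[0]} frames but {times.size} time points")
    global_thr = _global_threshold(frames)
    h_ratio = np.empty(times.size)
    audits: list[FrameAudit] = []
    for i in range(frames.shape[0]):
        try:
            h_ratio[i], audit = _measure_frame(frames[i], global_thr, i)
        except (ValueError, DegenerateImageError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        audits.append(audit)
    curve = SedimentationCurve(sample_id=sample_id, times=times, h_ratio=h_ratio, group=group)
    return (curve, audits) if return_audit else curve


def velocity(curve: SedimentationCurve, total_height_mm: float | None = None):
    """Sedimentation velocity V_E = -dH/dt by finite differences.

    Central differences on interior points, one-sided at the ends; positive
    while the column settles.  With ``total_height_mm`` the result is scaled
    from 1/min to mm/min (the study column is ~53 mm for 1 mL).
    """
    if curve.times.size < 3:
        raise ValueError("velocity needs at least 3 points")
    steps = np.diff(curve.times)
    if not np.allclose(steps, steps[0]):
        raise ValueError("velocity requires a uniform time grid")
    v = -np.gradient(curve.h_ratio, curve.times)
    if total_height_mm is not None:
        v = v * total_height_mm
    return curve.times.copy(), v
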