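"""Core calcium-imaging pipeline: raw ROI fluorescence → ΔF/F → stimulus-locked
average → responder flag and peak response.

Processing steps, in order:

1. :func:`register_frames` — translation-only frame alignment (integer-pixel
   cross-correlation to a reference).
2. :func:`extract_roi_trace` — ROI pixel mean minus background mean per frame.
3. :func:`fit_bleach` — photobleaching baseline F0(t) as a sum of two
   exponentials (plus an optional additive offset), fitted over all frames or
   over the last 25% of each gray interleave.
4. :func:`compute_dff` — ΔF/F = (F(t) − F0(t)) / F0(t).
5. :func:`stimulus_locked_average` — sample times reassigned relative to each
   stimulus transition, then a simple moving average with a 25 ms window and
   8.33 ms shift (an effective resampling from 38.9 Hz to ~120 Hz with 3-point
   boxcar smoothing).
6. :func:`identify_responder`, :func:`peak_response`, :func:`normalize_peaks`
   — response detection and peak statistics normalized to the no-Flp control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from flpstop_pipeline.stimulus import StimulusLog, TransitionType, gray_periods

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cell_body", "M1", "M5", "M8", "M10", "Lo1", "Lo4")
GENOTYPES = ("experimental", "no_flp_control", "het_control")

DEFAULT_WINDOW_S = 0.025
DEFAULT_SHIFT_S = 0.00833  # printed stimulus-frame duration; 1/0.00833 ≈ 120 Hz


@dataclass
class RoiTrace:
    """One ROI's background-subtracted fluorescence time series."""

    roi_id: str
    times_s: np.ndarray
    F: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times_s.shape != self.F.shape:
            raise ValueError("times_s and F must have the same length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence values must be finite")


@dataclass
class BleachFit:
    """Two-exponential photobleaching baseline F0(t).

    F0(t) = a1·exp(−t/tau1_s) + a2·exp(−t/tau2_s) + offset, with components
    ordered so tau1_s ≤ tau2_s.
    """

    a1: float
    tau1_s: float
    a2: float
    tau2_s: float
    offset: float
    window_rule: Literal["all_frames", "last_25pct_gray"]
    mask: np.ndarray
    f0: np.ndarray

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.a1 * np.exp(-t / self.tau1_s)
            + self.a2 * np.exp(-t / self.tau2_s)
            + self.offset
        )


@dataclass
class DffTrace:
    times_s: np.ndarray
    dff: np.ndarray


@dataclass
class StimLockedAverage:
    """Stimulus-locked mean ΔF/F on a regular grid of reassigned times.

    ``grid_s[k]`` is the centre of the k-th averaging window; spacing is
    exactly ``shift_s``. ``n_per_bin`` counts pooled samples (all trials of
    all matching transitions); empty bins are dropped.
    """

    grid_s: np.ndarray
    mean_dff: np.ndarray
    sem_dff: np.ndarray
    n_per_bin: np.ndarray
    window_s: float
    shift_s: float
    transition_type: TransitionType

    @property
    def effective_rate_hz(self) -> float:
        return 1.0 / self.shift_s


@dataclass
class PeakResponse:
    """Peak ΔF/F of a stimulus-locked average in the expected direction."""

    value: float
    time_s: float
    expected_direction: Literal["increase", "decrease"] = "increase"
    normalized_value: float | None = None


# ---------------------------------------------------------------------------
# registration and extraction


def register_frames(
    stack: np.ndarray,
    max_shift: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-only registration of a movie to its own early-frame mean.

    Each frame is shifted by the integer displacement maximizing its circular
    cross-correlation with the reference (the mean of the first 10 frames).
    Displacements are restricted to ±``max_shift`` pixels; a frame whose
    correlation peak lies outside that range is clamped and a warning logged.

    Returns (aligned stack, shifts) where ``shifts[i] = (dy, dx)`` is the
    shift applied to frame i.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be a (n_frames, h, w) array with >= 2 frames")
    n, h, w = stack.shape
    ref = stack[: min(10, n)].mean(axis=0)
    ref_f = np.fft.rfft2(ref - ref.mean())

    # allowed circular shifts: dy in [-max_shift, max_shift], same for dx
    dy_ok = np.zeros(h, dtype=bool)
    dx_ok = np.zeros(w, dtype=bool)
    idx_y = np.arange(h)
    idx_x = np.arange(w)
    wrap_y = np.where(idx_y <= h // 2, idx_y, idx_y - h)
    wrap_x = np.where(idx_x <= w // 2, idx_x, idx_x - w)
    dy_ok[np.abs(wrap_y) <= max_shift] = True
    dx_ok[np.abs(wrap_x) <= max_shift] = True
    allowed = np.outer(dy_ok, dx_ok)

    shifts = np.zeros((n, 2), dtype=int)
    aligned = np.empty_like(stack)
    clamped = 0
    for i in range(n):
        frame = stack[i]
        corr = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(frame - frame.mean())), s=(h, w))
        best_all = np.unravel_index(np.argmax(corr), corr.shape)
        masked = np.where(allowed, corr, -np.inf)
        best = np.unravel_index(np.argmax(masked), corr.shape)
        if best_all != best:
            clamped += 1
        dy = int(wrap_y[best[0]])
        dx = int(wrap_x[best[1]])
        shifts[i] = (dy, dx)
        aligned[i] = np.roll(frame, (dy, dx), axis=(0, 1))
    if clamped:
        logger.warning(
            "register_frames: %d/%d frames had correlation peaks beyond max_shift=%d; "
            "shifts were clamped", clamped, n, max_shift,
        )
    return aligned, shifts


def extract_roi_trace(
    stack: np.ndarray,
    roi_mask: np.ndarray,
    background_mask: np.ndarray,
    roi_id: str = "roi",
    frame_rate_hz: float = 38.9,
    meta: dict | None = None,
) -> RoiTrace:
    """Mean ROI intensity minus mean background intensity, per frame."""
    stack = np.asarray(stack, dtype=float)
    roi_mask = np.asarray(roi_mask).astype(bool)
    background_mask = np.asarray(background_mask).astype(bool)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, h, w)")
    if roi_mask.shape != stack.shape[1:] or background_mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must match frame shape")
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("masks must be nonempty")
    if (roi_mask & background_mask).any():
        raise ValueError("roi_mask and background_mask must be disjoint")
    F = stack[:, roi_mask].mean(axis=1) - stack[:, background_mask].mean(axis=1)
    times = np.arange(stack.shape[0]) / frame_rate_hz
    return RoiTrace(roi_id=roi_id, times_s=times, F=F, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# bleach correction and ΔF/F


def _bleach_model(t, a1, tau1, a2, tau2, offset):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + offset


def _fit_bleach_ls(t, y, p0, with_offset):
    """Least-squares fit of the two-exponential baseline.

    Internally log-parameterized (q = ln of amplitudes, taus, offset), which
    enforces positivity — the baseline is decaying fluorescence, so F0 > 0
    everywhere — and roughly equalizes parameter scales for the
    Levenberg–Marquardt solver.
    """
    from scipy.optimize import least_squares

    tiny = 1e-9 * max(abs(y).max(), 1.0)
    q0 = np.log(np.maximum(np.asarray(p0, dtype=float), tiny))
    if not with_offset:
        q0 = q0[:4]

    def unpack(q):
        a1, tau1, a2, tau2 = np.exp(q[:4])
        offset = np.exp(q[4]) if with_offset else 0.0
        return a1, tau1, a2, tau2, offset

    def resid(q):
        return _bleach_model(t, *unpack(q)) - y

    def jac(q):
        a1, tau1, a2, tau2, offset = unpack(q)
        e1 = np.exp(-t / tau1)
        e2 = np.exp(-t / tau2)
        cols = [a1 * e1, a1 * (t / tau1) * e1, a2 * e2, a2 * (t / tau2) * e2]
        if with_offset:
            cols.append(np.full_like(t, offset))
        return np.stack(cols, axis=1)

    sol = least_squares(resid, q0, jac=jac, method="lm", xtol=1e-10, ftol=1e-10,
                        max_nfev=400)
    # status 0 = evaluation cap reached: on noise-limited data LM plateaus long
    # before the cap, so the iterate is a usable optimum, not a failure
    if not np.all(np.isfinite(sol.x)):
        raise RuntimeError(f"bleach fit diverged: {sol.message}")
    popt = np.array([*unpack(sol.x)])
    return popt, float(np.sum(sol.fun**2))


def fitting_mask(
    trace: RoiTrace,
    window_rule: Literal["all_frames", "last_25pct_gray"],
    log: StimulusLog | None = None,
    gray_fraction: float = 0.25,
) -> np.ndarray:
    """Boolean mask of frames used for the bleaching fit.

    ``last_25pct_gray`` selects frames whose time falls in the final
    ``gray_fraction`` of any gray interleave (375 ms of a 1500 ms gray),
    placing ΔF/F = 0 at the baseline the cell returns to between flashes.
    """
    if window_rule == "all_frames":
        return np.ones_like(trace.times_s, dtype=bool)
    if window_rule != "last_25pct_gray":
        raise ValueError(f"unknown window_rule {window_rule!r}")
    if log is None:
        raise ValueError("last_25pct_gray requires a stimulus log")
    mask = np.zeros_like(trace.times_s, dtype=bool)
    for start, end in gray_periods(log):
        lo = end - gray_fraction * (end - start)
        mask |= (trace.times_s >= lo) & (trace.times_s < end)
    return mask


def fit_bleach(
    trace: RoiTrace,
    window_rule: Literal["all_frames", "last_25pct_gray"] = "all_frames",
    log: StimulusLog | None = None,
    with_offset: bool = True,
    max_restarts: int = 5,
    restart_seed: int = 0,
) -> BleachFit:
    """Fit the photobleaching baseline F ≈ a1·e^(−t/τ1) + a2·e^(−t/τ2) (+ offset).

    Least squares over the masked frames; the fitted curve evaluated at every
    frame becomes F0 for the ΔF/F computation.  τ's are initialized at 10%
    and 100% of the trace duration, amplitudes from the first/last masked
    values; on failure up to ``max_restarts`` seeded multi-starts are tried
    and the lowest-SSE success wins.  Output components are ordered
    τ1 ≤ τ2.
    """
    mask = fitting_mask(trace, window_rule, log)
    n_params = 5 if with_offset else 4
    if mask.sum() < n_params + 1:
        raise ValueError(
            f"fitting mask selects {int(mask.sum())} frames; need at least {n_params + 1}"
        )
    t = trace.times_s[mask]
    y = trace.F[mask]
    T = trace.times_s[-1] - trace.times_s[0]

    # degenerate: (near-)constant trace collapses to the offset
    y_span = y.max() - y.min()
    if y_span <= 1e-12 * max(1.0, abs(y.mean())):
        c = float(y.mean())
        return BleachFit(
            a1=0.0, tau1_s=0.1 * T, a2=0.0, tau2_s=T, offset=c,
            window_rule=window_rule, mask=mask,
            f0=np.full_like(trace.F, c),
        )

    offset0 = max(float(y[-1]), 0.0) if with_offset else 0.0
    amp0 = max(float(y[0]) - offset0, 0.1 * max(y_span, 1e-12))

    def inits(rng: np.random.Generator | None):
        if rng is None:
            tau1, tau2 = 0.1 * T, 1.0 * T
            return [amp0 / 2, tau1, amp0 / 2, tau2, offset0]
        tau1 = float(np.exp(rng.uniform(np.log(0.01 * T), np.log(T))))
        tau2 = float(np.exp(rng.uniform(np.log(0.1 * T), np.log(10 * T))))
        return [amp0 / 2, min(tau1, tau2), amp0 / 2, max(tau1, tau2), offset0]

    def try_fit(p0):
        return _fit_bleach_ls(t, y, p0, with_offset)

    # multi-starts are a fallback: the deterministic init is used alone when it
    # converges; on failure up to max_restarts seeded inits compete by SSE
    best = None
    errors = []
    for attempt in range(max_restarts + 1):
        rng = None if attempt == 0 else np.random.default_rng(restart_seed + attempt)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, sse = try_fit(inits(rng))
        except (RuntimeError, ValueError) as exc:
            errors.append(exc)
            continue
        if best is None or sse < best[1]:
            best = (popt, sse)
        if attempt == 0:
            break
    if best is None:
        raise RuntimeError(f"bleach fit failed after {max_restarts + 1} attempts: {errors[-1]}")

    a1, tau1, a2, tau2, offset = best[0]
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    fit = BleachFit(
        a1=float(a1), tau1_s=float(tau1), a2=float(a2), tau2_s=float(tau2),
        offset=float(offset), window_rule=window_rule, mask=mask,
        f0=np.empty(0),
    )
    fit.f0 = fit.evaluate(trace.times_s)
    return fit


def compute_dff(trace: RoiTrace, fit: BleachFit) -> DffTrace:
    """ΔF/F = (F(t) − F0(t)) / F0(t); F0 must be positive at every frame."""
    if np.any(fit.f0 <= 0):
        raise ValueError("fitted baseline F0 must be positive at every frame")
    return DffTrace(times_s=trace.times_s, dff=(trace.F - fit.f0) / fit.f0)


# ---------------------------------------------------------------------------
# stimulus-locked averaging


def stimulus_locked_average(
    dff: DffTrace,
    log: StimulusLog,
    transition_type: TransitionType,
    window_s: float = DEFAULT_WINDOW_S,
    shift_s: float = DEFAULT_SHIFT_S,
    pre_s: float = 0.5,
    post_s: float = 1.0,
) -> StimLockedAverage:
    """Pooled moving-window average of ΔF/F around stimulus transitions.

    Every sample's time is reassigned relative to each matching transition
    (pooling over all transitions of the requested type), and the output at
    grid point t_k = −pre_s + k·shift_s is the unweighted mean of all samples
    with reassigned time in [t_k − window_s/2, t_k + window_s/2).  With a
    25 ms window and an 8.33 ms shift this resamples 38.9 Hz data to ~120 Hz
    with 3-point boxcar smoothing.  Windows are centred on the grid point so
    peak timing is preserved.  Bins with no samples are dropped.
    """
    if window_s < shift_s:
        raise ValueError("window_s must be >= shift_s")
    trans = log.times(transition_type)
    if trans.size == 0:
        raise ValueError(f"no transitions of type {transition_type!r} in log")

    # reassigned sample times pooled over transitions
    rel = (dff.times_s[None, :] - trans[:, None]).ravel()
    vals = np.broadcast_to(dff.dff, (trans.size, dff.dff.size)).ravel()
    keep = (rel >= -pre_s - window_s) & (rel <= post_s + window_s)
    rel, vals = rel[keep], vals[keep]
    if rel.size == 0:
        raise ValueError("no samples fall near any matching transition")

    order = np.argsort(rel, kind="stable")
    rel, vals = rel[order], vals[order]

    n_bins = int(np.floor((post_s + pre_s) / shift_s + 1e-9)) + 1
    full_grid = -pre_s + shift_s * np.arange(n_bins)
    lo_idx = np.searchsorted(rel, full_grid - window_s / 2, side="left")
    hi_idx = np.searchsorted(rel, full_grid + window_s / 2, side="left")
    n = hi_idx - lo_idx
    nonempty = n > 0
    grid, lo_idx, hi_idx, n = (
        full_grid[nonempty], lo_idx[nonempty], hi_idx[nonempty], n[nonempty]
    )
    mean = np.empty(len(grid))
    sem = np.zeros(len(grid))
    for k in range(len(grid)):
        window = vals[lo_idx[k]:hi_idx[k]]
        mean[k] = window.mean()
        if n[k] > 1:
            sem[k] = window.std(ddof=1) / np.sqrt(n[k])
    return StimLockedAverage(
        grid_s=grid, mean_dff=mean, sem_dff=sem, n_per_bin=n,
        window_s=window_s, shift_s=shift_s, transition_type=transition_type,
    )


def identify_responder(
    search_avg: StimLockedAverage,
    k_sigma: float = 3.0,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    response_window: tuple[float, float] = (0.0, 1.0),
) -> bool:
    """Flag a ROI as responding to the search stimulus.

    True iff the largest |mean ΔF/F| inside the response window exceeds
    ``k_sigma`` times the SD of the mean trace in the pre-stimulus baseline
    window.  The criterion is a configurable interpretation: response
    detection against baseline variability at k·σ (default k = 3).
    """
    t = search_avg.grid_s
    base = (t >= baseline_window[0]) & (t < baseline_window[1])
    resp = (t >= response_window[0]) & (t < response_window[1])
    if base.sum() < 2:
        raise ValueError("baseline window must contain at least 2 grid points")
    if not resp.any():
        raise ValueError("response window contains no grid points")
    sigma = float(np.std(search_avg.mean_dff[base], ddof=1))
    peak = float(np.max(np.abs(search_avg.mean_dff[resp])))
    if sigma == 0.0:
        return peak > 0.0
    return peak > k_sigma * sigma


def peak_response(
    avg: StimLockedAverage,
    direction: Literal["increase", "decrease"] = "increase",
    response_window_s: tuple[float, float] = (0.0, 0.5),
) -> PeakResponse:
    """Peak ΔF/F: the value farthest from zero in the expected direction.

    For ``increase`` (the initial calcium response to a light flash) this is
    the maximum of the averaged trace inside the response window; for
    ``decrease`` the minimum.
    """
    sel = (avg.grid_s >= response_window_s[0]) & (avg.grid_s <= response_window_s[1])
    if not sel.any():
        raise ValueError("response window contains no grid points")
    vals = avg.mean_dff[sel]
    times = avg.grid_s[sel]
    i = int(np.argmax(vals)) if direction == "increase" else int(np.argmin(vals))
    return PeakResponse(value=float(vals[i]), time_s=float(times[i]), expected_direction=direction)


def normalize_peaks(
    peaks: pd.DataFrame,
    control: str = "no_flp_control",
    value_col: str = "peak",
    group_col: str = "genotype",
) -> pd.DataFrame:
    """Normalize each ROI's peak ΔF/F to the mean peak of the control group.

    Returns a copy with a ``normalized_peak`` column; by construction the
    control group's mean normalized value is exactly 1.
    """
    if group_col not in peaks.columns or value_col not in peaks.columns:
        raise ValueError(f"peak table must have columns {group_col!r} and {value_col!r}")
    ctrl = peaks.loc[peaks[group_col] == control, value_col]
    if ctrl.empty:
        raise ValueError(f"control group {control!r} is empty")
    m = ctrl.mean()
    if m == 0:
        raise ValueError("control group mean is zero; cannot normalize")
    out = peaks.copy()
    out["normalized_peak"] = out[value_col] / m
    return out
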