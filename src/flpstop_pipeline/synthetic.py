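"""Seeded synthetic data with the statistical structure the analysis assumes.

Every generator records its ground truth, so downstream parameter-recovery
tests can compare what the pipeline estimates against what was programmed.

The ROI-trace generator follows the signal model the processing pipeline
inverts:

    F(t) = B(t) · (1 + Σ_trials m · k(t − t_onset)) + ε(t)

with a two-exponential bleaching envelope
B(t) = baseline_F · (a1·e^(−t/τ1) + a2·e^(−t/τ2) + offset), a fast-indicator
transient kernel k (difference of exponentials, unit peak), a per-condition
amplitude multiplier m from the effect map, and i.i.d. Gaussian noise ε.
Physical stimulus onsets lag the nominal command times by a delay uniform
within one stimulus frame whose mean equals the measured rig delay, so
mean-delay compensation leaves sub-frame residual jitter — as in the real
acquisition.

Random streams are named substreams of the root seed: per-ROI parameters are
drawn on a stream independent of the noise stream, so the same ROI keeps its
identity (bleach parameters, amplitude) across different stimulus protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Literal

import numpy as np
import pandas as pd

from flpstop_pipeline._rng import substream
from flpstop_pipeline.stimulus import StimulusLog, StimulusSpec, build_stimulus_log
from flpstop_pipeline.stats import CrossSpec, surviving_class_probabilities
from flpstop_pipeline.traces import RoiTrace


def default_effect_map() -> dict[str, dict[str, float]]:
    """Genotype × compartment amplitude multipliers.

    The experimental genotype loses part of its response in the cell body
    and the lobula arbors, is unchanged in M1/M8/M10, and over-responds in
    M5; both controls are flat.  Fully configurable — these defaults only
    set the qualitative pattern the pipeline should resolve.
    """
    flat = {c: 1.0 for c in ("cell_body", "M1", "M5", "M8", "M10", "Lo1", "Lo4")}
    experimental = dict(flat)
    experimental.update({"cell_body": 0.5, "Lo1": 0.5, "Lo4": 0.5, "M5": 3.0})
    return {
        "experimental": experimental,
        "no_flp_control": dict(flat),
        "het_control": dict(flat),
    }


@dataclass
class SimConfig:
    """Free parameters of the synthetic two-photon acquisition.

    ``amp`` is the base peak ΔF/F of a single flash response; the effect map
    multiplies it per (genotype, compartment).  ``noise_sd`` is the additive
    Gaussian SD on raw fluorescence (a.u.); with ``baseline_F = 1000`` and
    ``amp = 0.5``, ``noise_sd = 100`` corresponds to a per-frame peak-signal
    SNR of 5.
    """

    seed: int = 0
    frame_rate: float = 38.9
    stim_spec: StimulusSpec = field(default_factory=StimulusSpec.flash_off_gray)
    bleach: dict = field(default_factory=lambda: {
        "a1": 0.4, "tau1_s": 20.0, "a2": 0.3, "tau2_s": 200.0, "offset": 0.3,
    })
    kernel: dict = field(default_factory=lambda: {"rise_s": 0.05, "decay_s": 0.4})
    baseline_F: float = 1000.0
    noise_sd: float = 100.0
    amp: float = 0.5
    effect_map: dict[str, dict[str, float]] = field(default_factory=default_effect_map)
    conditions: list[tuple[str, str]] = field(default_factory=lambda: [
        ("experimental", "M5"), ("no_flp_control", "M5"), ("het_control", "M5"),
    ])
    n_rois: int = 10
    n_trials: int = 25          # light flashes; cycles alternate light/dark
    bleach_jitter_cv: float = 0.1
    dark_response_frac: float = 0.0
    tail_s: float = 1.0
    noise_model: Literal["gaussian", "poisson"] = "gaussian"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.bleach["tau1_s"] <= 0 or self.bleach["tau2_s"] <= 0:
            raise ValueError("bleach time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.kernel["rise_s"] <= 0 or self.kernel["decay_s"] <= self.kernel["rise_s"]:
            raise ValueError("kernel requires 0 < rise_s < decay_s")
        for g, comps in self.effect_map.items():
            if any(v < 0 for v in comps.values()):
                raise ValueError("amplitude multipliers must be nonnegative")
        if self.n_rois < 1 or self.n_trials < 1:
            raise ValueError("n_rois and n_trials must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually used, keyed by record id."""

    roi_bleach: dict[str, dict] = field(default_factory=dict)
    roi_peak_dff: dict[str, float] = field(default_factory=dict)
    true_onsets_s: dict[str, list[float]] = field(default_factory=dict)
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)
    true_fraction: float | None = None
    class_probabilities: dict[str, float] | None = None

    def to_json_dict(self) -> dict:
        return {
            "roi_bleach": self.roi_bleach,
            "roi_peak_dff": self.roi_peak_dff,
            "true_onsets_s": self.true_onsets_s,
            "matched_pairs": [list(p) for p in self.matched_pairs],
            "true_fraction": self.true_fraction,
            "class_probabilities": self.class_probabilities,
        }


# ---------------------------------------------------------------------------
# transient kernel


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Time of the difference-of-exponentials peak."""
    return np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Fast-indicator response kernel, unit peak, zero for t < 0.

    k(t) = (e^(−t/decay) − e^(−t/rise)) / k_max — GCaMP6f-scale dynamics with
    the default 50 ms rise and 400 ms decay.
    """
    t = np.asarray(t, dtype=float)
    tp = kernel_peak_time(rise_s, decay_s)
    peak = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    tc = np.maximum(t, 0.0)  # k(0) = 0, so clamping negative times is exact
    return np.where(t >= 0, np.exp(-tc / decay_s) - np.exp(-tc / rise_s), 0.0) / peak


def bleach_envelope(t: np.ndarray, baseline_F: float, bleach: dict) -> np.ndarray:
    return baseline_F * (
        bleach["a1"] * np.exp(-t / bleach["tau1_s"])
        + bleach["a2"] * np.exp(-t / bleach["tau2_s"])
        + bleach["offset"]
    )


# ---------------------------------------------------------------------------
# ROI traces


def _true_onsets(log: StimulusLog, rng: np.random.Generator) -> dict[float, float]:
    """Map nominal transition time -> true physical onset.

    True onset = nominal + (delay − frame/2) + U[0, frame): the lag varies
    within one stimulus frame and its mean equals the measured delay.
    """
    spec = log.spec
    frame_s = spec.stimulus_frame_ms / 1000.0
    base = spec.delay_ms / 1000.0 - frame_s / 2.0
    out = {}
    for tr in log.transitions:
        if tr.type in ("to_light", "to_dark"):
            out[tr.t_s] = tr.t_s + base + rng.uniform(0.0, frame_s)
    return out


def generate_roi_traces(
    cfg: SimConfig,
    stim_spec: StimulusSpec | None = None,
) -> tuple[list[RoiTrace], StimulusLog, GroundTruth]:
    """Generate synthetic ROI fluorescence traces for every configured condition.

    Returns the traces, the *nominal* stimulus log (what the experimenter
    knows; true onsets live in the ground truth), and the ground truth.
    ``stim_spec`` overrides the configured stimulus (e.g. to generate the
    search acquisition for the same ROIs); per-ROI parameters are drawn on a
    stream that does not depend on the stimulus, so ROI identity is stable
    across protocols.
    """
    spec = stim_spec if stim_spec is not None else cfg.stim_spec
    if spec.kind == "flash_off_gray":
        n_cycles = 2 * cfg.n_trials  # light/dark alternation -> n_trials light flashes
    else:
        n_cycles = 2 * cfg.n_trials
    log = build_stimulus_log(spec, n_cycles=n_cycles)
    duration = log.duration_s + cfg.tail_s
    n_frames = int(np.ceil(duration * cfg.frame_rate))
    times = np.arange(n_frames) / cfg.frame_rate

    truth = GroundTruth()
    traces: list[RoiTrace] = []
    for genotype, compartment in cfg.conditions:
        if genotype not in cfg.effect_map or not cfg.effect_map[genotype]:
            raise KeyError(f"effect_map has no entries for genotype {genotype!r}")
        if compartment not in cfg.effect_map[genotype]:
            raise KeyError(
                f"effect_map[{genotype!r}] has no multiplier for {compartment!r}"
            )
        mult = cfg.effect_map[genotype][compartment]
        for i in range(cfg.n_rois):
            roi_id = f"{genotype}/{compartment}/roi{i:03d}"
            rng_params = substream(cfg.seed, f"roi_params/{roi_id}")
            rng_noise = substream(cfg.seed, f"noise/{spec.kind}/{roi_id}")

            bleach = dict(cfg.bleach)
            if cfg.bleach_jitter_cv > 0:
                for key in ("a1", "a2", "offset"):
                    bleach[key] *= float(
                        np.exp(rng_params.normal(0.0, cfg.bleach_jitter_cv))
                    )
                for key in ("tau1_s", "tau2_s"):
                    bleach[key] *= float(
                        np.exp(rng_params.normal(0.0, cfg.bleach_jitter_cv))
                    )
            m = cfg.amp * mult

            onset_map = _true_onsets(log, rng_noise)
            signal = np.zeros_like(times)
            for tr in log.transitions:
                if tr.type == "to_light":
                    amp_tr = m
                elif tr.type == "to_dark":
                    amp_tr = m * cfg.dark_response_frac
                else:
                    continue
                if amp_tr == 0.0:
                    continue
                onset = onset_map[tr.t_s]
                signal += amp_tr * transient_kernel(
                    times - onset, cfg.kernel["rise_s"], cfg.kernel["decay_s"]
                )

            B = bleach_envelope(times, cfg.baseline_F, bleach)
            F = B * (1.0 + signal)
            if cfg.noise_sd > 0:
                if cfg.noise_model == "poisson":
                    # variance scaled to noise_sd at the mean baseline
                    scale = cfg.noise_sd**2 / max(F.mean(), 1e-12)
                    F = rng_noise.poisson(np.maximum(F / scale, 0.0)) * scale
                else:
                    F = F + rng_noise.normal(0.0, cfg.noise_sd, size=F.shape)

            traces.append(RoiTrace(
                roi_id=roi_id, times_s=times, F=F,
                meta={"fly_id": f"fly{i % 3}", "compartment": compartment,
                      "genotype": genotype},
            ))
            truth.roi_bleach[roi_id] = {
                "baseline_F": cfg.baseline_F, **bleach,
            }
            truth.roi_peak_dff[roi_id] = m
            truth.true_onsets_s[roi_id] = [onset_map[k] for k in sorted(onset_map)]
    return traces, log, truth


# ---------------------------------------------------------------------------
# rendered movie


def generate_movie(
    cfg: SimConfig,
    frame_shape: tuple[int, int] = (64, 64),
    blob_centers: list[tuple[int, int]] | None = None,
    blob_radius: int = 4,
    background_level: float = 100.0,
    pixel_noise_sd: float = 0.0,
) -> tuple[np.ndarray, dict[str, np.ndarray], GroundTruth]:
    """Render ROI traces into a 16-bit movie with masks.

    Each ROI is a uniform-intensity disk at ``background_level + F_i(t)`` on
    a flat background, so the ROI-mask mean minus the background-mask mean
    reproduces the generating trace within quantization (±0.5 grey levels,
    plus pixel noise if enabled).  Masks: one boolean mask per ROI plus a
    ``background`` mask in a cell-free corner.
    """
    traces, log, truth = generate_roi_traces(cfg)
    h, w = frame_shape
    n_rois = len(traces)
    if blob_centers is None:
        cols = int(np.ceil(np.sqrt(n_rois)))
        spacing_x = w // (cols + 1)
        spacing_y = h // (cols + 1)
        blob_centers = [
            ((i // cols + 1) * spacing_y, (i % cols + 1) * spacing_x)
            for i in range(n_rois)
        ]
    if len(blob_centers) != n_rois:
        raise ValueError("need one blob center per ROI")

    yy, xx = np.mgrid[0:h, 0:w]
    masks: dict[str, np.ndarray] = {}
    for (cy, cx), tr in zip(blob_centers, traces):
        if not (blob_radius <= cy < h - blob_radius and blob_radius <= cx < w - blob_radius):
            raise ValueError(f"blob at ({cy}, {cx}) extends outside the {h}x{w} frame")
        masks[tr.roi_id] = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_radius**2

    bg_mask = np.zeros((h, w), dtype=bool)
    bg_mask[:max(2, h // 8), :max(2, w // 8)] = True
    for m in masks.values():
        if (bg_mask & m).any():
            raise ValueError("background corner overlaps a blob; move blob_centers")
    masks["background"] = bg_mask

    n_frames = len(traces[0].times_s)
    stack = np.full((n_frames, h, w), background_level, dtype=float)
    for tr in traces:
        stack[:, masks[tr.roi_id]] = background_level + tr.F[:, None]
    if pixel_noise_sd > 0:
        rng = substream(cfg.seed, "movie_pixel_noise")
        stack += rng.normal(0.0, pixel_noise_sd, size=stack.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    return stack, masks, truth


# ---------------------------------------------------------------------------
# 3D cell clouds


def generate_cell_cloud(
    n_a: int,
    coloc_fraction: float,
    jitter_um: float,
    decoys: int,
    volume_um3: float = 50.0**3,
    seed: int = 0,
    channel_a: str = "GFP",
    channel_b: str = "tdTomato",
):
    """Two 3D point clouds with a planted double-labeled fraction.

    Exactly ``round(coloc_fraction · n_a)`` A-spots receive a B-partner
    displaced by at most ``jitter_um`` (uniform in the ball); ``decoys``
    additional B-spots are placed uniformly in the volume.
    """
    from flpstop_pipeline.coloc import SpotSet

    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must be in [0, 1]")
    if jitter_um < 0:
        raise ValueError("jitter_um must be nonnegative")
    if n_a < 1:
        raise ValueError("n_a must be >= 1")
    rng = substream(seed, "cell_cloud")
    side = volume_um3 ** (1.0 / 3.0)
    a_pts = rng.uniform(0.0, side, size=(n_a, 3))

    k = int(round(coloc_fraction * n_a))
    partner_a = rng.choice(n_a, size=k, replace=False)
    if jitter_um > 0:
        direction = rng.normal(size=(k, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = jitter_um * rng.uniform(0.0, 1.0, size=(k, 1)) ** (1.0 / 3.0)
        partners = a_pts[partner_a] + direction * radius
    else:
        partners = a_pts[partner_a].copy()
    decoy_pts = rng.uniform(0.0, side, size=(decoys, 3))

    b_pts = np.vstack([partners, decoy_pts])
    perm = rng.permutation(len(b_pts))
    b_pts = b_pts[perm]
    inv = np.argsort(perm)
    truth = GroundTruth(
        true_fraction=coloc_fraction,
        matched_pairs=[(int(a_i), int(inv[j])) for j, a_i in enumerate(partner_a)],
    )
    return SpotSet(a_pts, channel=channel_a), SpotSet(b_pts, channel=channel_b), truth


# ---------------------------------------------------------------------------
# Ct tables and cross counts


def generate_ct_table(
    true_fraction: float,
    replicate_sd: float,
    n_bio: int,
    n_tech: int = 4,
    seed: int = 0,
    base_target_ct: float = 20.0,
    base_reference_ct: float = 15.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthetic qPCR Ct table for a disruption experiment.

    The disrupting genotype's target-gene Ct is offset by −log2(true_fraction)
    cycles relative to the non-disrupting genotype (half the transcript costs
    one extra cycle); the reference gene shares one base Ct across genotypes.
    Gaussian noise with SD ``replicate_sd`` is applied per technical read.
    """
    if true_fraction <= 0:
        raise ValueError("true_fraction must be positive")
    if replicate_sd < 0 or n_bio < 1 or n_tech < 1:
        raise ValueError("invalid replicate structure")
    rng = substream(seed, "ct_table")
    offset = -np.log2(true_fraction)
    rows = []
    for genotype, target_base in (("ND", base_target_ct), ("D", base_target_ct + offset)):
        for bio in range(1, n_bio + 1):
            for gene, base in (("target", target_base), ("reference", base_reference_ct)):
                for tech in range(1, n_tech + 1):
                    ct = base + (rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0)
                    rows.append({
                        "genotype": genotype, "gene": gene,
                        "biological_replicate": bio, "technical_replicate": tech,
                        "ct": float(ct),
                    })
    truth = GroundTruth(true_fraction=true_fraction)
    return pd.DataFrame(rows), truth


def generate_cross_counts(
    cross: CrossSpec,
    n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multinomial progeny counts over the surviving genotype classes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = surviving_class_probabilities(cross)  # raises if all lethal
    all_classes = sorted(set(cross.zygote_classes()))
    survivors = sorted(probs)
    p = np.array([probs[c] for c in survivors])
    rng = substream(seed, "cross_counts")
    counts = dict(zip(survivors, rng.multinomial(n, p)))
    df = pd.DataFrame({
        "genotype_class": ["/".join(c) for c in all_classes],
        "count": [int(counts.get(c, 0)) for c in all_classes],
    })
    truth = GroundTruth(
        class_probabilities={"/".join(c): float(probs[c]) for c in survivors}
    )
    return df, truth
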