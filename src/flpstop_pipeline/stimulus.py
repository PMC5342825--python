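"""Visual-stimulus timing: epoch protocols, delay compensation, contrast.

Two protocols are modelled, matching the in-vivo imaging experiments:

``search_2s``
    Alternating full-contrast light and dark flashes, 2 s each, no gray
    interleave.  Used to find responding ROIs.

``flash_off_gray``
    25 ms flashes off a 1500 ms gray interleave, polarity alternating
    light/dark, Michelson contrast 0.5 relative to the gray.  Used for the
    peak-response analysis.

Physical stimulus onset lags the nominal command by a delay that varies
within one stimulus frame (8.33 ms); the measured mean lag (6.25 ms) is
compensated once by :func:`compensate_delay`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

TransitionType = Literal["to_light", "to_dark", "to_gray"]

#: epoch conventions: times in seconds, durations in ms in the spec objects.
STIMULUS_FRAME_MS = 8.33
MEASURED_DELAY_MS = 6.25


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one stimulus protocol.

    Durations are in milliseconds; ``screen_span_deg`` is metadata only.
    """

    kind: Literal["search_2s", "flash_off_gray"] = "flash_off_gray"
    flash_ms: float = 25.0
    gray_ms: float = 1500.0
    contrast: float = 0.5
    stimulus_frame_ms: float = STIMULUS_FRAME_MS
    delay_ms: float = MEASURED_DELAY_MS
    screen_span_deg: tuple[float, float] = (80.0, 50.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        for name in ("flash_ms", "gray_ms", "stimulus_frame_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind not in ("search_2s", "flash_off_gray"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    @classmethod
    def search_2s(cls, **kw) -> "StimulusSpec":
        kw.setdefault("flash_ms", 2000.0)
        return cls(kind="search_2s", **kw)

    @classmethod
    def flash_off_gray(cls, **kw) -> "StimulusSpec":
        return cls(kind="flash_off_gray", **kw)

    @property
    def cycle_s(self) -> float:
        """Duration of one flash presentation cycle in seconds."""
        if self.kind == "flash_off_gray":
            return (self.gray_ms + self.flash_ms) / 1000.0
        return self.flash_ms / 1000.0


@dataclass(frozen=True)
class Transition:
    t_s: float
    type: TransitionType


@dataclass(frozen=True)
class StimulusLog:
    """Ordered stimulus transitions with their nominal (command) times."""

    spec: StimulusSpec
    transitions: tuple[Transition, ...]
    delay_compensated: bool = False

    def __post_init__(self) -> None:
        times = [tr.t_s for tr in self.transitions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("transition times must be strictly increasing")

    def times(self, transition_type: TransitionType | None = None) -> np.ndarray:
        if transition_type is None:
            return np.array([tr.t_s for tr in self.transitions])
        return np.array([tr.t_s for tr in self.transitions if tr.type == transition_type])

    @property
    def duration_s(self) -> float:
        """End of the protocol: last transition plus its epoch duration."""
        last = self.transitions[-1]
        tail = self.spec.gray_ms if last.type == "to_gray" else self.spec.flash_ms
        return last.t_s + tail / 1000.0


def build_stimulus_log(
    spec: StimulusSpec,
    n_cycles: int,
    jitter_seed: int | None = None,
) -> StimulusLog:
    """Build the transition sequence for ``n_cycles`` presentations.

    For ``flash_off_gray`` each cycle is gray(1500 ms) followed by a flash
    (25 ms), flash polarity alternating light/dark starting with light; the
    leading gray period precedes the first flash.  For ``search_2s`` the
    protocol alternates 2 s light and dark epochs with no gray.

    If ``jitter_seed`` is given, each flash event is shifted by an
    independent u ~ U[0, stimulus_frame_ms), emulating stimulus onsets that
    vary within one stimulus frame.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    flash_s = spec.flash_ms / 1000.0
    gray_s = spec.gray_ms / 1000.0
    transitions: list[Transition] = []
    if spec.kind == "flash_off_gray":
        for i in range(n_cycles):
            onset = (i + 1) * gray_s + i * flash_s
            polarity: TransitionType = "to_light" if i % 2 == 0 else "to_dark"
            transitions.append(Transition(onset, polarity))
            transitions.append(Transition(onset + flash_s, "to_gray"))
    elif spec.kind == "search_2s":
        for i in range(n_cycles):
            polarity = "to_light" if i % 2 == 0 else "to_dark"
            transitions.append(Transition(i * flash_s, polarity))
    else:  # pragma: no cover - guarded in StimulusSpec
        raise ValueError(f"unknown stimulus kind {spec.kind!r}")

    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        jittered: list[Transition] = []
        frame_s = spec.stimulus_frame_ms / 1000.0
        if spec.kind == "flash_off_gray":
            # one draw per flash event; the flash onset and its gray return
            # move together (the projector delays the whole frame).
            for k in range(0, len(transitions), 2):
                u = rng.uniform(0.0, frame_s)
                jittered.append(replace(transitions[k], t_s=transitions[k].t_s + u))
                jittered.append(replace(transitions[k + 1], t_s=transitions[k + 1].t_s + u))
        else:
            for tr in transitions:
                jittered.append(replace(tr, t_s=tr.t_s + rng.uniform(0.0, frame_s)))
        transitions = jittered

    return StimulusLog(spec=spec, transitions=tuple(transitions))


def compensate_delay(log: StimulusLog, delay_ms: float | None = None) -> StimulusLog:
    """Shift every transition by the measured projector delay (once).

    Corrected onset = nominal + delay.  Applying the compensation twice is
    an error: the delay is a fixed property of the rig, not a per-stage
    adjustment.
    """
    if log.delay_compensated:
        raise ValueError("stimulus log is already delay-compensated")
    delay_s = (log.spec.delay_ms if delay_ms is None else delay_ms) / 1000.0
    shifted = tuple(replace(tr, t_s=tr.t_s + delay_s) for tr in log.transitions)
    return StimulusLog(spec=log.spec, transitions=shifted, delay_compensated=True)


def michelson_contrast(flash_lum: float, gray_lum: float) -> float:
    """Michelson contrast |L_flash − L_gray| / (L_flash + L_gray)."""
    if flash_lum < 0 or gray_lum < 0:
        raise ValueError("luminances must be nonnegative")
    if flash_lum == 0 and gray_lum == 0:
        raise ValueError("luminances must not both be zero")
    return abs(flash_lum - gray_lum) / (flash_lum + gray_lum)


def flash_luminances(gray_lum: float, contrast: float) -> tuple[float, float]:
    """Light- and dark-flash luminances giving the requested Michelson contrast.

    Solves (L − G)/(L + G) = c for the light flash and (G − D)/(G + D) = c
    for the dark flash, so both polarities have the same contrast relative
    to the gray and light > gray > dark for 0 < c < 1.
    """
    if gray_lum <= 0:
        raise ValueError("gray luminance must be positive")
    if not (0.0 <= contrast < 1.0):
        raise ValueError("contrast must be in [0, 1) for finite luminances")
    light = gray_lum * (1.0 + contrast) / (1.0 - contrast)
    dark = gray_lum * (1.0 - contrast) / (1.0 + contrast)
    return light, dark


def gray_periods(log: StimulusLog) -> list[tuple[float, float]]:
    """(start, end) of every gray period, including the leading gray.

    A gray period runs from a ``to_gray`` transition (or t=0 for the leading
    interleave of a flash_off_gray protocol) to the next flash onset.
    """
    if log.spec.kind != "flash_off_gray":
        return []
    periods: list[tuple[float, float]] = []
    start = 0.0
    for tr in log.transitions:
        if tr.type == "to_gray":
            start = tr.t_s
        else:
            periods.append((start, tr.t_s))
    if log.transitions and log.transitions[-1].type == "to_gray":
        # trailing gray: full interleave duration
        periods.append((start, start + log.spec.gray_ms / 1000.0))
    return periods
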