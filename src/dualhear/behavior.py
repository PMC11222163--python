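"""Playback triggering, startle detection and directional-bias statistics.

Trajectories are overhead-camera centroid tracks at 120 frames/s.  A
playback may be triggered when the fish is inside the central trigger
zone, oriented within 45 degrees of the y axis, and a refractory delay of
5 s plus a per-trial exponential draw (mean 5 s) has elapsed.  Startles
are detected as trials whose mean speed inside a 25-ms window centred on
the post-trigger speed peak exceeds 17 cm/s, and classified left/right by
the sign of the x displacement over the first 50 ms after startle onset.
Directional bias is the fraction of startles in a reference direction,
with an exact two-sided binomial p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .configs import active_side as _active_side
from .configs import config_kind

log = logging.getLogger(__name__)

FRAME_RATE = 120.0
SPEED_THRESHOLD = 0.17        # m/s, startle classification
DETECTION_WINDOW = 0.025      # s, averaging window around the speed peak
SEARCH_WINDOW = 0.2           # s after trigger searched for the speed peak
DISPLACEMENT_WINDOW = 0.05    # s after onset used for left/right readout
MIN_DELAY = 5.0               # s, refractory minimum between playbacks
MEAN_EXTRA_DELAY = 5.0        # s, mean of the exponential extra delay
TRIGGER_ZONE = (0.015, 0.03)  # m, (x extent, y extent) of the central zone
MAX_HEADING_DEV = np.pi / 4   # rad from the y axis


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Centroid track of one fish (overhead camera, tank-centred metres)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray          # rad, relative to +y
    fish_id: str = "fish0"
    arena: tuple = (-0.05, 0.05, -0.05, 0.05)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        if not (self.times.size == self.x.size == self.y.size == self.heading.size):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def speed(self) -> np.ndarray:
        """Centroid speed (m/s) by central differences, no smoothing."""
        vx = np.gradient(self.x, self.times)
        vy = np.gradient(self.y, self.times)
        return np.hypot(vx, vy)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.times, "x_m": self.x, "y_m": self.y,
                      "heading_rad": self.heading,
                      "fish_id": self.fish_id}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        fish = str(df["fish_id"].iloc[0]) if "fish_id" in df else "fish0"
        return cls(df["t_s"].to_numpy(), df["x_m"].to_numpy(),
                   df["y_m"].to_numpy(), df["heading_rad"].to_numpy(), fish)


@dataclass(frozen=True)
class PlaybackTrial:
    trigger_time: float
    config: str
    fish_id: str = "fish0"
    position: tuple = (0.0, 0.0)
    heading: float = 0.0


@dataclass
class StartleEvent:
    trial: PlaybackTrial
    onset_time: float
    peak_speed: float
    window_mean_speed: float
    x_displacement: float = float("nan")   # m over the first 50 ms
    direction: str | None = None           # 'left' | 'right'
    escape: bool | None = None             # vs the active speaker side

    @property
    def fish_id(self) -> str:
        return self.trial.fish_id

    @property
    def config(self) -> str:
        return self.trial.config


@dataclass(frozen=True)
class BiasResult:
    """Directional bias of n trials with k in the reference direction."""

    n: int
    k: int
    fraction: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")


# ---------------------------------------------------------------------------
# Trigger logic
# ---------------------------------------------------------------------------

def heading_deviation_from_y(heading: float) -> float:
    """Smallest angle (rad) between the heading axis and the y axis."""
    a = np.mod(heading, np.pi)
    return float(min(a, np.pi - a))


def draw_trigger_delay(rng: np.random.Generator,
                       min_delay: float = MIN_DELAY,
                       mean_extra: float = MEAN_EXTRA_DELAY) -> float:
    """Per-trial required delay: 5 s plus an exponential draw of mean 5 s."""
    return min_delay + float(rng.exponential(mean_extra))


def should_trigger(x: float, y: float, heading: float,
                   elapsed: float, required_delay: float,
                   zone: tuple = TRIGGER_ZONE,
                   max_deviation: float = MAX_HEADING_DEV) -> bool:
    """Pure trigger predicate.

    True iff the centroid lies inside the central ``zone`` (x extent by
    y extent, centred on the tank), the heading axis deviates from the y
    axis by at most ``max_deviation``, and at least ``required_delay``
    seconds have elapsed since the last playback.
    """
    in_zone = (abs(x) <= zone[0] / 2) and (abs(y) <= zone[1] / 2)
    aligned = heading_deviation_from_y(heading) <= max_deviation
    return bool(in_zone and aligned and elapsed >= required_delay)


# ---------------------------------------------------------------------------
# Startle detection and classification
# ---------------------------------------------------------------------------

def detect_startles(traj: Trajectory, trials: list[PlaybackTrial],
                    threshold: float = SPEED_THRESHOLD,
                    window: float = DETECTION_WINDOW,
                    search: float = SEARCH_WINDOW) -> list[StartleEvent]:
    """Classify each trial as startle / non-startle by windowed mean speed.

    Per trial the post-trigger speed peak is located inside ``search``
    seconds; the speed is averaged over a ``window`` centred on the peak,
    and the trial is a startle iff that mean strictly exceeds
    ``threshold``.  Onset is the first frame in the window whose speed
    exceeds the threshold.  Trials whose trajectory coverage has gaps in
    the search window are dropped with a log entry rather than classified.
    """
    speed = traj.speed()
    dt = 1.0 / traj.frame_rate
    events = []
    for trial in trials:
        t0 = trial.trigger_time
        sel = np.flatnonzero((traj.times > t0) & (traj.times <= t0 + search))
        if sel.size == 0 or traj.times[sel[-1]] < t0 + search - 2 * dt or \
                np.any(np.diff(traj.times[sel]) > 1.5 * dt) or \
                not np.all(np.isfinite(speed[sel])):
            log.warning("trial at t=%.3f s unusable: trajectory gap", t0)
            continue
        i_peak = sel[np.argmax(speed[sel])]
        half = window / 2
        win = np.flatnonzero((traj.times >= traj.times[i_peak] - half)
                             & (traj.times <= traj.times[i_peak] + half))
        mean_speed = float(np.mean(speed[win]))
        if mean_speed <= threshold:
            continue
        above = win[speed[win] > threshold]
        onset_idx = int(above[0]) if above.size else int(i_peak)
        events.append(StartleEvent(
            trial=trial,
            onset_time=float(traj.times[onset_idx]),
            peak_speed=float(speed[i_peak]),
            window_mean_speed=mean_speed,
        ))
    return events


def classify_direction(event: StartleEvent, traj: Trajectory,
                       active_side: str | None = None) -> StartleEvent:
    """Left/right classification by x displacement over the first 50 ms.

    ``direction`` is the sign of the x displacement between startle onset
    and onset + 50 ms; ``escape`` is True iff that direction is opposite
    the active speaker side (None for standing-wave stimuli).  Events with
    exactly zero displacement are left unclassified with a log entry.
    """
    t1 = event.onset_time + DISPLACEMENT_WINDOW
    if t1 > traj.times[-1]:
        log.warning("startle at t=%.3f s lacks 50 ms of frames", event.onset_time)
        return event
    x0 = float(np.interp(event.onset_time, traj.times, traj.x))
    x1 = float(np.interp(t1, traj.times, traj.x))
    dx = x1 - x0
    event.x_displacement = dx
    if dx == 0.0:
        log.warning("startle at t=%.3f s has zero x displacement; "
                    "unclassifiable", event.onset_time)
        return event
    event.direction = "right" if dx > 0 else "left"
    if active_side is not None:
        away = "right" if active_side == "L" else "left"
        event.escape = event.direction == away
    return event


def classify_events(traj: Trajectory, events: list[StartleEvent]) -> list[StartleEvent]:
    """Classify all events, inferring the active side from the config label."""
    return [classify_direction(e, traj, _active_side(e.config)) for e in events]


def events_to_frame(events: list[StartleEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "fish_id": e.fish_id, "config": e.config,
        "trigger_time_s": e.trial.trigger_time, "onset_time_s": e.onset_time,
        "peak_speed_ms": e.peak_speed, "mean_speed_ms": e.window_mean_speed,
        "x_displacement_m": e.x_displacement, "direction": e.direction,
        "escape": e.escape,
    } for e in events])


# ---------------------------------------------------------------------------
# Bias statistics
# ---------------------------------------------------------------------------

def binomial_p_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (sum of outcomes no more likely
    than the observed one, the 'minlike' convention)."""
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def directional_bias(k: int, n: int) -> BiasResult:
    """Fraction of startles in the reference direction with exact p-value."""
    if n < 1:
        raise ValueError("directional bias needs at least one trial")
    return BiasResult(n=n, k=k, fraction=k / n,
                      p_value=binomial_p_two_sided(k, n))


def escape_bias(events: list[StartleEvent]) -> BiasResult:
    """Pooled escape bias over classified events with a known active side."""
    flags = [e.escape for e in events if e.escape is not None]
    return directional_bias(sum(flags), len(flags))


def per_fish_bias(events: list[StartleEvent], min_startles: int = 10
                  ) -> pd.DataFrame:
    """Per-fish escape fractions, filtered for well-sampled fish.

    Only fish with at least ``min_startles`` classified startles in both
    the single-speaker condition (pooled over its 4 stimuli) and the trick
    condition (pooled over its 4 stimuli) are included; excluded fish are
    reported with a reason.
    """
    rows = []
    df = events_to_frame([e for e in events if e.escape is not None])
    if df.empty:
        return pd.DataFrame(columns=["fish_id", "included", "reason",
                                     "n_single", "n_trick",
                                     "single_escape_fraction",
                                     "trick_escape_fraction"])
    df["kind"] = df["config"].map(config_kind)
    for fish, sub in df.groupby("fish_id"):
        single = sub[sub["kind"] == "single"]
        trick = sub[sub["kind"] == "trick"]
        ok = len(single) >= min_startles and len(trick) >= min_startles
        rows.append({
            "fish_id": fish,
            "included": ok,
            "reason": "" if ok else (
                f"single={len(single)}, trick={len(trick)} "
                f"(need >= {min_startles} in both)"),
            "n_single": len(single), "n_trick": len(trick),
            "single_escape_fraction": single["escape"].mean() if len(single) else np.nan,
            "trick_escape_fraction": trick["escape"].mean() if len(trick) else np.nan,
        })
    return pd.DataFrame(rows)


__all__ = [
    "Trajectory", "PlaybackTrial", "StartleEvent", "BiasResult",
    "heading_deviation_from_y", "draw_trigger_delay", "should_trigger",
    "detect_startles", "classify_direction", "classify_events",
    "events_to_frame", "binomial_p_two_sided", "directional_bias",
    "escape_bias", "per_fish_bias",
    "FRAME_RATE", "SPEED_THRESHOLD", "DETECTION_WINDOW", "SEARCH_WINDOW",
    "DISPLACEMENT_WINDOW", "MIN_DELAY", "MEAN_EXTRA_DELAY", "TRIGGER_ZONE",
]
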