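"""Candidate directional-hearing algorithms and the consistency table.

Seven hypotheses map the local sound field at the fish to a predicted
startle direction:

1. P-ILD -- two pressure sensors compare pressure levels,
2. M-ILD -- two particle-motion sensors compare motion levels,
3. P-ITD -- two pressure sensors compare arrival times,
4. M-ITD -- two particle-motion sensors compare arrival times,
5/6. M-polarity(+/-) -- a single motion sensor interprets the initial
   motion polarity as directed away from (towards) the source,
7. Schuijf -- the relative phase of pressure and directed particle
   velocity, realized quantitatively as the sign of the time-averaged
   product <p(t) v_x(t)> (the x component of active acoustic intensity).

Each predictor emits 'left', 'right' or 'undirected'; a direction is
emitted only when the hypothesis's input cue exceeds a floor of 5% of its
single-speaker reference value, encoding the absence of a significant
bias for cues that the stimulus nulls.  Comparing predictions with the
observed outcomes across the stimulus battery (single-speaker, pressure-
only, motion-only and trick configurations, both polarities) yields the
consistency matrix; adding the anatomical constraint that the fish has a
single pressure sensor leaves phase comparison (Schuijf) as the only
surviving mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend

from .acoustics import (WATER, CueEstimate, Medium, Waveform, estimate_cues,
                        pressure_to_acceleration, propagate_pressure)
from .configs import ALL_CONFIGS, active_side, config_kind, polarity

HYPOTHESES = ("P-ILD", "M-ILD", "P-ITD", "M-ITD",
              "M-polarity+", "M-polarity-", "Schuijf")

#: Qualitative startle outcomes of the playback battery: escapes away from
#: the active speaker for single-speaker sounds of either polarity, no
#: directional bias for pure-pressure / pure-motion standing waves, and
#: approaches towards the active speaker in the trick configuration.
DEFAULT_OBSERVED_OUTCOMES = {
    label: {"single": "escape", "trick": "approach",
            "pressure": "undirected", "motion": "undirected"}[config_kind(label)]
    for label in ALL_CONFIGS
}


class IncompleteCueError(ValueError):
    """Raised when a hypothesis's required field components are missing."""


# ---------------------------------------------------------------------------
# Stimulus cues
# ---------------------------------------------------------------------------

def velocity_from_acceleration(ax: Waveform) -> Waveform:
    """Particle velocity by cumulative trapezoidal integration of the
    acceleration, linearly detrended to enforce zero mean drift."""
    v = cumulative_trapezoid(ax.samples, dx=1.0 / ax.sample_rate, initial=0.0)
    return Waveform(detrend(v, type="linear"), ax.sample_rate, "velocity")


@dataclass
class StimulusCues:
    """Everything the seven predictors read, for one configuration."""

    label: str
    p: Waveform                  # pressure at the fish centre
    ax: Waveform                 # x particle acceleration at the centre
    vx: Waveform                 # x particle velocity (integrated from ax)
    cues: CueEstimate            # binaural cues at the two ear positions
    p_ear_peak: float            # max over the two ears of peak |p|
    ax_ear_peak: float           # max over the two ears of peak |ax|

    def initial_motion_polarity(self) -> int:
        """Sign of the x acceleration at its first significant deflection.

        The first crossing of a quarter of the peak magnitude: low enough
        to catch the onset lobe rather than the later absolute peak, high
        enough to ignore filter pre-ringing.  0 for a silent component.
        """
        peak = self.ax.peak()
        if peak == 0:
            return 0
        i = int(np.argmax(np.abs(self.ax.samples) >= 0.25 * peak))
        return int(np.sign(self.ax.samples[i]))

    def active_intensity_x(self) -> float:
        """Time-averaged p(t) * v_x(t), the x active-intensity component."""
        return float(np.mean(self.p.samples * self.vx.samples))


def _speaker_drives(label: str) -> dict[tuple[float, float], float]:
    """Drive coefficient (units of the template) per speaker position.

    Speakers sit on the +-x and +-y axes at the source distance; the
    standing-wave pairs split the template between opposing speakers, and
    the trick configuration adds the in-phase orthogonal pair that
    contributes -2x the centre pressure of the held speaker.
    """
    kind = config_kind(label)
    pol = float(polarity(label))
    L, R, F, B = (-1.0, 0.0), (+1.0, 0.0), (0.0, +1.0), (0.0, -1.0)
    if kind == "single":
        return {L if active_side(label) == "L" else R: pol}
    if kind == "pressure":
        return {L: pol / 2, R: pol / 2}
    if kind == "motion":
        return {L: pol / 2, R: -pol / 2}
    held = L if active_side(label) == "L" else R
    return {held: pol, F: -pol, B: -pol}


def _field_at(point: np.ndarray, drives: dict, template: Waveform,
              source_distance: float, medium: Medium
              ) -> tuple[Waveform, Waveform]:
    """(pressure, x-acceleration) superposition of monopole sources."""
    p_sum = np.zeros(len(template))
    a_sum = np.zeros(len(template))
    for unit_pos, coeff in drives.items():
        src = np.asarray(unit_pos) * source_distance
        delta = point - src
        r = float(np.hypot(*delta))
        ux = delta[0] / r
        p_here = propagate_pressure(template, source_distance, r, medium)
        a_rad = pressure_to_acceleration(p_here, r, medium)
        p_sum += coeff * p_here.samples
        a_sum += coeff * ux * a_rad.samples
    return (Waveform(p_sum, template.sample_rate, "pressure"),
            Waveform(a_sum, template.sample_rate, "acceleration"))


def synthesize_config_cues(label: str, template: Waveform,
                           source_distance: float = 0.03,
                           ear_separation: float = 0.6e-3,
                           medium: Medium = WATER) -> StimulusCues:
    """Simulate the local sound field of a configuration and extract cues.

    The field is a superposition of monopoles at the speaker positions
    (source_distance from the tank centre on the x and y axes); cues are
    estimated between the two ear positions +-ear_separation/2 along x,
    with no inter-ear rescaling (the points already are the ears).
    """
    drives = _speaker_drives(label)
    centre = np.zeros(2)
    left_ear = np.array([-ear_separation / 2, 0.0])
    right_ear = np.array([+ear_separation / 2, 0.0])
    p_c, a_c = _field_at(centre, drives, template, source_distance, medium)
    p_l, a_l = _field_at(left_ear, drives, template, source_distance, medium)
    p_r, a_r = _field_at(right_ear, drives, template, source_distance, medium)
    try:
        cues = estimate_cues((p_l, a_l), (p_r, a_r), spacing=ear_separation,
                             ear_scale_factor=1.0)
    except Exception:
        cues = CueEstimate(0.0, 0.0, 0.0, 0.0, ear_separation, 1.0,
                           p_itd_defined=False, m_itd_defined=False)
    return StimulusCues(
        label=label, p=p_c, ax=a_c, vx=velocity_from_acceleration(a_c),
        cues=cues, p_ear_peak=max(p_l.peak(), p_r.peak()),
        ax_ear_peak=max(a_l.peak(), a_r.peak()))


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    hypothesis: str
    direction: str               # 'left' | 'right' | 'undirected'
    anatomical_support: bool = True
    cue_value: float = float("nan")


def _direction_from_sign(sign: float) -> str:
    return "right" if sign > 0 else "left"


def predict(hypothesis: str, cues: StimulusCues,
            reference: StimulusCues | None = None,
            floor_fraction: float = 0.05) -> Prediction:
    """Predicted startle direction of one hypothesis for one stimulus.

    The inferred source side translates into a startle *away* from it.  A
    positive binaural cue (larger / earlier on the left) puts the source
    left, hence a startle to the right.  Cue magnitudes (and the relevant
    signal amplitude at the sensors) must exceed ``floor_fraction`` of
    their single-speaker ``reference`` values for a direction to be
    emitted; otherwise the prediction is 'undirected'.
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    ref = reference if reference is not None else cues

    def floor(value: float) -> float:
        return floor_fraction * abs(value)

    if hypothesis in ("P-ILD", "P-ITD"):
        amp_ok = cues.p_ear_peak > floor(ref.p_ear_peak)
        if hypothesis == "P-ILD":
            value = cues.cues.p_ild
            ok = amp_ok and abs(value) > floor(ref.cues.p_ild)
        else:
            value = cues.cues.p_itd
            ok = (amp_ok and cues.cues.p_itd_defined
                  and abs(value) > floor(ref.cues.p_itd))
        return Prediction(hypothesis,
                          _direction_from_sign(value) if ok else "undirected",
                          cue_value=value)

    if hypothesis in ("M-ILD", "M-ITD"):
        amp_ok = cues.ax_ear_peak > floor(ref.ax_ear_peak)
        if hypothesis == "M-ILD":
            value = cues.cues.m_ild
            ok = amp_ok and abs(value) > floor(ref.cues.m_ild)
        else:
            value = cues.cues.m_itd
            ok = (amp_ok and cues.cues.m_itd_defined
                  and abs(value) > floor(ref.cues.m_itd))
        return Prediction(hypothesis,
                          _direction_from_sign(value) if ok else "undirected",
                          cue_value=value)

    if hypothesis in ("M-polarity+", "M-polarity-"):
        if cues.ax.peak() <= floor(ref.ax.peak()):
            return Prediction(hypothesis, "undirected", cue_value=0.0)
        pol = cues.initial_motion_polarity()
        if pol == 0:
            return Prediction(hypothesis, "undirected", cue_value=0.0)
        # '+' reads initial motion as directed away from the source, so the
        # startle goes along the initial motion; '-' assumes the opposite.
        sign = pol if hypothesis == "M-polarity+" else -pol
        return Prediction(hypothesis, _direction_from_sign(sign),
                          cue_value=float(pol))

    # Schuijf: active intensity flows away from the source, so a positive
    # x intensity means the source is on the left and the fish flees right.
    value = cues.active_intensity_x()
    ok = abs(value) > floor(ref.active_intensity_x())
    return Prediction(hypothesis,
                      _direction_from_sign(value) if ok else "undirected",
                      cue_value=value)


# ---------------------------------------------------------------------------
# Consistency table
# ---------------------------------------------------------------------------

#: Hypotheses that require two spatially separated pressure sensors, which
#: the anatomy (single swim-bladder pressure pathway) does not provide.
TWO_PRESSURE_SENSOR_HYPOTHESES = ("P-ILD", "P-ITD")


def outcome_of(prediction: Prediction, config: str) -> str:
    """Map a predicted direction to {escape, approach, undirected, directed}."""
    if prediction.direction == "undirected":
        return "undirected"
    side = active_side(config)
    if side is None:
        return "directed"      # a directional prediction for a symmetric stimulus
    away = "right" if side == "L" else "left"
    return "escape" if prediction.direction == away else "approach"


def decision_table(template: Waveform,
                   configs=ALL_CONFIGS,
                   observed: dict[str, str] | None = None,
                   source_distance: float = 0.03,
                   ear_separation: float = 0.6e-3,
                   medium: Medium = WATER) -> pd.DataFrame:
    """Consistency of every hypothesis with every observed outcome.

    Rows are hypotheses, columns configurations; entries are True
    (prediction matches the observed outcome), False, or pd.NA where the
    observed outcome is missing.  Use :func:`survivors` to reduce to the
    surviving hypothesis set.
    """
    observed = DEFAULT_OBSERVED_OUTCOMES if observed is None else observed
    all_cues = {c: synthesize_config_cues(c, template, source_distance,
                                          ear_separation, medium)
                for c in configs}
    reference = all_cues.get("single_L_pos") or next(iter(all_cues.values()))
    table = pd.DataFrame(index=list(HYPOTHESES), columns=list(configs),
                         dtype=object)
    for config in configs:
        obs = observed.get(config)
        for hyp in HYPOTHESES:
            if obs is None:
                table.loc[hyp, config] = pd.NA
                continue
            pred = predict(hyp, all_cues[config], reference)
            table.loc[hyp, config] = outcome_of(pred, config) == obs
    return table


def survivors(table: pd.DataFrame,
              single_pressure_sensor: bool = False) -> set[str]:
    """Hypotheses consistent with every observed outcome.

    With ``single_pressure_sensor`` the anatomical constraint is applied:
    mechanisms needing two pressure sensors are eliminated regardless of
    behavioural consistency.
    """
    alive = set()
    for hyp in table.index:
        row = table.loc[hyp]
        if all(bool(v) for v in row if v is not pd.NA):
            alive.add(hyp)
    if single_pressure_sensor:
        alive -= set(TWO_PRESSURE_SENSOR_HYPOTHESES)
    return alive


__all__ = [
    "HYPOTHESES", "DEFAULT_OBSERVED_OUTCOMES", "IncompleteCueError",
    "StimulusCues", "Prediction", "velocity_from_acceleration",
    "synthesize_config_cues", "predict", "outcome_of", "decision_table",
    "survivors", "TWO_PRESSURE_SENSOR_HYPOTHESES",
]
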