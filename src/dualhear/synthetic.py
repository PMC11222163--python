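"""Synthetic-data generators emulating the study's measurements.

Everything the analysis modules consume can be generated here with known
ground truth: the transient pressure template (a damped oscillation with
a ~780 Hz centre frequency and ~0.66 ms rise time at 167 dB re 1 uPa
peak), per-speaker tank impulse responses on the calibration grid (image-
source echoes plus a speaker band-pass response), swimming sessions with
triggered startles of configurable directional bias, and stroboscopic
phase stacks of textured structures oscillating with known amplitude and
phase.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.signal import butter, sosfiltfilt, sosfreqz

from . import behavior as bhv
from .acoustics import Medium, Waveform
from .configs import ALL_CONFIGS, active_side, config_kind
from .field_control import ImpulseResponseGrid
from .vibrometry import PhaseStack, ScanPlan

# ---------------------------------------------------------------------------
# Stimulus template
# ---------------------------------------------------------------------------

DEFAULT_SR = 51_200.0
DEFAULT_PEAK_SPL_DB = 167.0     # dB re 1 uPa


def rise_time_10_90(w: Waveform) -> float:
    """10%-to-90% absolute-amplitude rise time (s), with sub-sample
    interpolation of the threshold crossings."""
    amp = np.abs(w.samples)
    peak = amp.max()

    def crossing(th: float) -> float:
        i = int(np.argmax(amp >= th * peak))
        if i == 0:
            return 0.0
        lo, hi = amp[i - 1], amp[i]
        return (i - 1 + (th * peak - lo) / (hi - lo)) / w.sample_rate

    return crossing(0.9) - crossing(0.1)


def spectral_peak_frequency(w: Waveform, zero_pad: int = 16) -> float:
    """Frequency of the power-spectrum maximum (Hz), zero-padded DFT."""
    n = zero_pad * len(w)
    power = np.abs(np.fft.rfft(w.samples, n=n)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / w.sample_rate)
    return float(freqs[np.argmax(power)])


def make_template(sr: float = DEFAULT_SR, duration: float = 0.012,
                  centre_frequency: float = 780.0, rise: float = 0.664e-3,
                  peak_spl_db: float = DEFAULT_PEAK_SPL_DB,
                  onset_time: float | None = None,
                  decay_tau: float = 3.0e-3,
                  carrier_phase: float = np.pi / 4,
                  highpass_hz: float = 100.0) -> Waveform:
    """Transient pressure waveform template.

    A sinusoidal carrier under a half-cosine onset and exponential decay,
    high-pass filtered at ``highpass_hz`` and rescaled so the peak equals
    ``10^(peak_spl_db/20)`` uPa.  The generated waveform's measured
    10-90% rise time and spectral peak are validated against the
    requested ``rise`` and ``centre_frequency`` (within 10%); parameter
    combinations that cannot meet them raise with a diagnosis.
    """
    if sr <= 2 * centre_frequency:
        raise ValueError("sample rate must exceed twice the centre frequency")
    onset = 1.5 * rise if onset_time is None else onset_time
    t = np.arange(int(round(sr * duration))) / sr
    env = np.where(t < onset, 0.5 * (1 - np.cos(np.pi * t / np.maximum(onset, 1e-12))),
                   1.0) * np.exp(-t / decay_tau)
    x = env * np.sin(2 * np.pi * centre_frequency * t + carrier_phase)
    sos = butter(2, highpass_hz, "highpass", fs=sr, output="sos")
    x = sosfiltfilt(sos, x)
    peak_pa = 10.0 ** (peak_spl_db / 20.0) * 1e-6
    x = x / np.max(np.abs(x)) * peak_pa
    w = Waveform(x, sr, "pressure")
    measured_rise = rise_time_10_90(w)
    measured_fc = spectral_peak_frequency(w)
    if abs(measured_rise - rise) > 0.1 * rise:
        raise ValueError(
            f"template rise time {measured_rise * 1e3:.3f} ms deviates more "
            f"than 10% from the requested {rise * 1e3:.3f} ms; adjust "
            "onset_time/decay_tau/carrier_phase")
    if abs(measured_fc - centre_frequency) > 0.1 * centre_frequency:
        raise ValueError(
            f"template spectral peak {measured_fc:.0f} Hz deviates more than "
            f"10% from the requested {centre_frequency:.0f} Hz")
    return w


# ---------------------------------------------------------------------------
# Tank impulse responses (image-source model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TankModel:
    """Rectangular test tank with four speakers on the x/y axes.

    The fish swims in an acoustically transparent inner tank; echoes come
    from the outer boundary, modelled by image sources with a
    frequency-independent reflection coefficient.  Speakers carry a
    band-pass response (Butterworth parameters).
    """

    inner_size: tuple = (0.10, 0.10)
    outer_size: tuple = (0.30, 0.30)
    water_height: float = 0.10
    speaker_distance: float = 0.08
    wall_reflection: float = 0.5
    speaker_band: tuple = (150.0, 1800.0)
    speaker_order: int = 2
    medium: Medium = dataclass_field(default_factory=Medium)

    def __post_init__(self) -> None:
        if self.speaker_distance <= max(self.inner_size) / 2:
            raise ValueError("speakers must sit outside the inner tank")
        if abs(self.wall_reflection) > 1:
            raise ValueError("|wall_reflection| must not exceed 1")

    @property
    def speaker_positions(self) -> np.ndarray:
        d = self.speaker_distance
        return np.array([[-d, 0.0], [+d, 0.0], [0.0, +d], [0.0, -d]])


def image_sources(tank: TankModel, source, order: int
                  ) -> list[tuple[np.ndarray, float]]:
    """Image-source positions and gains over the rectangular outer boundary.

    Returns (position, reflection-gain) pairs for all images with at most
    ``order`` wall reflections (|n_x| + |n_y| <= order).
    """
    if order < 0:
        raise ValueError("echo order must be >= 0")
    lx, ly = tank.outer_size
    sx = float(source[0]) + lx / 2   # shift into [0, L] coordinates
    sy = float(source[1]) + ly / 2
    out = []
    for nx in range(-order, order + 1):
        for ny in range(-order, order + 1):
            refl = abs(nx) + abs(ny)
            if refl > order:
                continue
            ix = nx * lx + (sx if nx % 2 == 0 else lx - sx)
            iy = ny * ly + (sy if ny % 2 == 0 else ly - sy)
            pos = np.array([ix - lx / 2, iy - ly / 2])
            out.append((pos, tank.wall_reflection ** refl))
    return out


def grid_positions(n: int = 5, spacing: float = 0.015) -> np.ndarray:
    """Tank-centred calibration grid, n x n nodes at the given spacing."""
    axis = (np.arange(n) - (n - 1) / 2) * spacing
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def make_tank_irs(tank: TankModel, grid_n: int = 5, spacing: float = 0.015,
                  echo_order: int = 2, sr: float = DEFAULT_SR,
                  duration: float = 0.05,
                  gain_reference: float = 0.03) -> ImpulseResponseGrid:
    """Per-speaker impulse-response kernels on the calibration grid.

    Pressure kernels are the speaker band-pass response convolved with the
    image-source arrival train (delay r/c, gain ``gain_reference/r`` times
    the reflection-coefficient product); acceleration kernels apply the
    monopole pressure-acceleration relation per arrival, projected onto
    the x and y axes.  Built in the frequency domain so fractional delays
    are exact.
    """
    rho, c = tank.medium.density, tank.medium.sound_speed
    positions = grid_positions(grid_n, spacing)
    n = int(round(sr * duration))
    freqs = np.fft.rfftfreq(n, 1.0 / sr)
    k = 2.0 * np.pi * freqs / c
    sos = butter(tank.speaker_order, tank.speaker_band, "bandpass",
                 fs=sr, output="sos")
    _, speaker_resp = sosfreqz(sos, worN=freqs, fs=sr)

    speakers = tank.speaker_positions
    kernels = np.zeros((len(speakers), len(positions), 3, n))
    for i, spk in enumerate(speakers):
        images = image_sources(tank, spk, echo_order)
        for g, pos in enumerate(positions):
            spec = np.zeros((3, freqs.size), dtype=complex)
            for img_pos, refl_gain in images:
                delta = pos - img_pos
                r = float(np.hypot(*delta))
                if r == 0:
                    raise ValueError("image source coincides with a grid node")
                ux, uy = delta / r
                phase = np.exp(-2j * np.pi * freqs * (r / c))
                p_term = (gain_reference / r) * refl_gain * phase
                # +ik on positive-frequency bins: see acoustics._acceleration_factor
                a_term = p_term * (1.0 / r + 1j * k) / rho
                spec[0] += p_term
                spec[1] += a_term * ux
                spec[2] += a_term * uy
            spec *= speaker_resp[None, :]
            kernels[i, g] = np.fft.irfft(spec, n=n, axis=-1)
    return ImpulseResponseGrid(kernels, positions, speakers, sr)


# ---------------------------------------------------------------------------
# Behavioural sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic behavioural session (one fish)."""

    fish_id: str = "fish0"
    duration: float = 600.0              # s
    frame_rate: float = 120.0
    startle_probability: float = 0.37    # playbacks answered with a startle
    escape_probabilities: dict = dataclass_field(default_factory=lambda: {
        "single": 0.80, "trick": 0.33, "pressure": 0.50, "motion": 0.50})
    displacement_mean: float = 0.010     # m of |x| displacement over 50 ms
    displacement_sd: float = 0.004
    displacement_min: float = 0.002
    burst_speed_mean: float = 0.38       # m/s mean speed in the burst window
    burst_speed_sd: float = 0.06
    burst_speed_min: float = 0.28
    max_latency_frames: int = 2
    cruise_speed: float = 0.045          # m/s baseline swimming speed
    arena_half: float = 0.05             # m

    def __post_init__(self) -> None:
        for p in [self.startle_probability, *self.escape_probabilities.values()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _cruise_trajectory(spec: SessionSpec, rng: np.random.Generator):
    """Wall-following swim: y oscillation between the white walls with an
    Ornstein-Uhlenbeck heading wobble and a weakly confined x position."""
    dt = 1.0 / spec.frame_rate
    n = int(round(spec.duration * spec.frame_rate))
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    wobble = 0.0
    tau_w, sd_w = 0.6, 0.65          # s, rad: heading wobble dynamics
    xp, yp = rng.uniform(-0.01, 0.01, size=2)
    direction = 1.0                   # +1 toward +y, -1 toward -y
    turn_margin = 0.038
    noise = rng.standard_normal(n)
    for i in range(n):
        wobble += (-wobble / tau_w) * dt + sd_w * np.sqrt(2 * dt / tau_w) * noise[i]
        if direction > 0 and yp > turn_margin:
            direction = -1.0
        elif direction < 0 and yp < -turn_margin:
            direction = 1.0
        phi = (0.0 if direction > 0 else np.pi) + wobble
        vx = spec.cruise_speed * np.sin(phi) - 0.8 * xp  # soft x centring
        vy = spec.cruise_speed * np.cos(phi)
        xp = float(np.clip(xp + vx * dt, -spec.arena_half, spec.arena_half))
        yp = float(np.clip(yp + vy * dt, -spec.arena_half, spec.arena_half))
        x[i], y[i], heading[i] = xp, yp, phi
    times = np.arange(n) * dt
    return times, x, y, heading


#: Fraction of the startle x displacement completed after each frame
#: (50 ms = 6 frames at 120 fps); most of it happens in the first 25 ms.
_STARTLE_X_PROFILE = np.array([0.25, 0.25, 0.20, 0.15, 0.10, 0.05])


def _inject_startle(x, y, onset_idx, dx_total, burst_speed, y_sign, dt,
                    relax_tau: float = 1.5):
    """Superimpose a startle displacement starting at ``onset_idx``.

    The x displacement follows the startle profile; extra y motion keeps
    the frame-to-frame speed at ``burst_speed`` during the first three
    frames (the burst phase) so the event carries a realistic C-start
    speed signature.  After the 50-ms displacement phase the offset
    relaxes back to the cruise path with time constant ``relax_tau`` (the
    fish resumes wall-following), so repeated startles do not accumulate
    a net drift out of the arena.
    """
    n = len(x)
    steps_x = dx_total * _STARTLE_X_PROFILE
    steps_y = np.zeros_like(steps_x)
    for j in range(3):
        need = burst_speed * dt
        steps_y[j] = y_sign * np.sqrt(max(need ** 2 - steps_x[j] ** 2, 0.0))
    offs_x = np.concatenate([[0.0], np.cumsum(steps_x)])
    offs_y = np.concatenate([[0.0], np.cumsum(steps_y)])
    off_x = np.zeros(n)
    off_y = np.zeros(n)
    for j, (ox, oy) in enumerate(zip(offs_x, offs_y)):
        if onset_idx + j < n:
            off_x[onset_idx + j] = ox
            off_y[onset_idx + j] = oy
    tail = onset_idx + offs_x.size
    if tail < n:
        decay = np.exp(-np.arange(n - tail) * dt / relax_tau)
        off_x[tail:] = offs_x[-1] * decay
        off_y[tail:] = offs_y[-1] * decay
    x += off_x
    y += off_y


def make_session(spec: SessionSpec, configs=ALL_CONFIGS,
                 rng: np.random.Generator | int | None = 0):
    """One synthetic session: trajectory, triggered trials, truth labels.

    Playbacks are triggered through :func:`dualhear.behavior.should_trigger`
    (central zone, y-aligned heading, 5 s + Exp(5 s) refractory); a
    configurable fraction of playbacks receives an injected startle with
    latency of at most 2 frames, an x displacement of 1 cm +- 0.4 cm over
    50 ms, and a left/right direction drawn from the per-configuration
    escape probability.  Returns ``(Trajectory, [PlaybackTrial], labels)``
    where ``labels`` is a DataFrame with one row per trial carrying the
    injected ground truth.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dt = 1.0 / spec.frame_rate
    times, x, y, heading = _cruise_trajectory(spec, rng)

    in_zone = (np.abs(x) <= bhv.TRIGGER_ZONE[0] / 2) & \
              (np.abs(y) <= bhv.TRIGGER_ZONE[1] / 2)
    dev = np.mod(heading, np.pi)
    aligned = np.minimum(dev, np.pi - dev) <= bhv.MAX_HEADING_DEV

    trials: list[bhv.PlaybackTrial] = []
    rows = []
    last_time = -np.inf
    required = bhv.draw_trigger_delay(rng)
    candidates = np.flatnonzero(in_zone & aligned)
    for i in candidates:
        t = times[i]
        if not bhv.should_trigger(x[i], y[i], heading[i], t - last_time, required):
            continue
        last_time = t
        required = bhv.draw_trigger_delay(rng)
        config = str(rng.choice(configs))
        trial = bhv.PlaybackTrial(trigger_time=float(t), config=config,
                                  fish_id=spec.fish_id,
                                  position=(float(x[i]), float(y[i])),
                                  heading=float(heading[i]))
        trials.append(trial)
        startle = rng.random() < spec.startle_probability
        row = {"fish_id": spec.fish_id, "trigger_time_s": float(t),
               "config": config, "startle": startle, "direction": None,
               "escape": None, "onset_time_s": np.nan, "dx_m": np.nan}
        if startle:
            latency = int(rng.integers(1, spec.max_latency_frames + 1))
            onset_idx = i + latency
            side = active_side(config)
            p_escape = spec.escape_probabilities[config_kind(config)]
            escapes = bool(rng.random() < p_escape)
            if side is None:
                direction = "right" if rng.random() < 0.5 else "left"
                escape_label = None
            else:
                away = "right" if side == "L" else "left"
                direction = away if escapes else ("left" if away == "right" else "right")
                escape_label = escapes
            mag = max(rng.normal(spec.displacement_mean, spec.displacement_sd),
                      spec.displacement_min)
            dx_total = mag if direction == "right" else -mag
            burst = max(rng.normal(spec.burst_speed_mean, spec.burst_speed_sd),
                        spec.burst_speed_min)
            _inject_startle(x, y, onset_idx, dx_total, burst,
                            float(rng.choice([-1.0, 1.0])), dt)
            row.update({"direction": direction, "escape": escape_label,
                        "onset_time_s": float(times[min(onset_idx, len(times) - 1)]),
                        "dx_m": dx_total})
        rows.append(row)

    half = spec.arena_half
    traj = bhv.Trajectory(times, x, y, heading, fish_id=spec.fish_id,
                          arena=(-half, half, -half, half))
    labels = pd.DataFrame(rows)
    return traj, trials, labels


def make_experiment(n_fish: int, spec: SessionSpec = SessionSpec(),
                    configs=ALL_CONFIGS, seed: int = 0):
    """Independent sessions for ``n_fish`` fish with per-fish sub-seeds."""
    sessions = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_fish)):
        fish_spec = SessionSpec(**{**spec.__dict__, "fish_id": f"fish{i:03d}"})
        sessions.append(make_session(fish_spec, configs,
                                     np.random.default_rng(child)))
    return sessions


# ---------------------------------------------------------------------------
# Vibrometry phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillatingStructure:
    """A textured region oscillating along x with fixed amplitude/phase."""

    mask: np.ndarray
    amplitude_um: float
    phase: float

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be non-negative")


def make_vibro_stack(structures: list[OscillatingStructure], plan: ScanPlan,
                     pixel_size_um: float = 0.5,
                     rng: np.random.Generator | int | None = 0,
                     noise_sigma: float = 0.0,
                     texture_scale_px: float = 1.5) -> PhaseStack:
    """Stroboscopic phase stack of oscillating textured structures.

    Each pixel of phase step j is sampled at stimulus phase
    ``2 pi j / n_step + 2 pi f_stim t_pixel x`` (the exact stroboscopic
    timing: repeats of a line start at phase offsets of 2 pi / n_step and
    the phase advances along the line by the pixel period).  The scene
    texture is a smooth reflectance speckle; structure pixels displace by
    ``A sin(phase + phi)`` along x.  Ground truth is embedded in the
    stack metadata.  Structure masks must not overlap.
    """
    ny, nx = plan.shape
    total = np.zeros((ny, nx), dtype=int)
    for s in structures:
        if s.mask.shape != (ny, nx):
            raise ValueError("structure mask shape must match the scan plan")
        total += s.mask.astype(int)
    if np.any(total > 1):
        raise ValueError("structure masks overlap")

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    texture = gaussian_filter(rng.standard_normal((ny, nx)), texture_scale_px)
    texture = (texture - texture.min()) / np.ptp(texture)
    texture = 2000.0 + 50000.0 * texture          # 16-bit-ish counts

    col_phase = plan.column_phase(np.arange(nx))[None, :]
    amp_px = np.zeros((ny, nx))
    phase_map = np.zeros((ny, nx))
    for s in structures:
        amp_px[s.mask] = s.amplitude_um / pixel_size_um
        phase_map[s.mask] = s.phase

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    data = np.empty((ny, nx, plan.n_step))
    for j in range(plan.n_step):
        theta = 2.0 * np.pi * j / plan.n_step
        disp = amp_px * np.sin(theta + col_phase + phase_map)
        frame = map_coordinates(texture, [yy, xx - disp], order=3,
                                mode="reflect")
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma * np.sqrt(frame))
            frame = np.clip(np.round(frame), 0, 2 ** 16 - 1)
        data[:, :, j] = frame
    truth = {"structures": [
        {"amplitude_um": s.amplitude_um, "phase": s.phase,
         "n_pixels": int(s.mask.sum())} for s in structures],
        "pixel_size_um": pixel_size_um}
    return PhaseStack(data, plan, ground_truth=truth)


def otolith_phantom_masks(shape=(128, 128)) -> dict[str, np.ndarray]:
    """Two well-separated rectangular regions: surrounding tissue and an
    otolith (lapillus) block, for the relative-motion worked example."""
    ny, nx = shape
    tissue = np.zeros(shape, dtype=bool)
    lapillus = np.zeros(shape, dtype=bool)
    tissue[ny // 8: ny // 2 - 8, nx // 8: 7 * nx // 8] = True
    lapillus[ny // 2 + 8: 7 * ny // 8, nx // 8: 7 * nx // 8] = True
    return {"tissue": tissue, "lapillus": lapillus}


__all__ = [
    "DEFAULT_SR", "DEFAULT_PEAK_SPL_DB", "rise_time_10_90",
    "spectral_peak_frequency", "make_template", "TankModel", "image_sources",
    "grid_positions", "make_tank_irs", "SessionSpec", "make_session",
    "make_experiment", "OscillatingStructure", "make_vibro_stack",
    "otolith_phantom_masks",
]
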