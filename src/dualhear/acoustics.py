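"""Monopole sound-field theory and binaural-cue estimation.

Complex pressure / particle-velocity / particle-acceleration fields of an
underwater point source (monopole), waveform-level conversion of pressure to
radial particle acceleration via the DFT, pressure-gradient acceleration
estimation, and the four binaural cues (P-ILD, M-ILD, P-ITD, M-ITD) between
two closely spaced sensing points.

Conventions (used consistently across the package):

* time dependence ``e^{-i omega t}``; forward DFT with negative exponent
  (numpy's default), inverse with positive exponent,
* the x axis runs from the left (-) to the right (+) speaker; a *positive*
  cue means the signal is larger, or arrives earlier, at the left point
  ``x0``,
* all phases are reported in ``(-pi, pi]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile as _wavfile


class SilentFieldError(ValueError):
    """Raised when a cue is requested from an all-zero (silent) field."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """Acoustic medium, by default fresh water at tank conditions.

    Parameters
    ----------
    density:
        Mass density ``rho`` in kg m^-3.
    sound_speed:
        Speed of sound ``c`` in m s^-1.
    """

    density: float = 1000.0
    sound_speed: float = 1500.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sound_speed <= 0:
            raise ValueError("density and sound_speed must be positive")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance ``rho * c`` (Pa s m^-1)."""
        return self.density * self.sound_speed


WATER = Medium()

#: Units attached to each waveform quantity tag.
QUANTITY_UNITS = {
    "pressure": "Pa",
    "velocity": "m s^-1",
    "acceleration": "m s^-2",
    "voltage": "V",
}


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled real time series of one acoustic quantity."""

    samples: np.ndarray
    sample_rate: float
    quantity: str = "pressure"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-d array with >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.quantity not in QUANTITY_UNITS:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def unit(self) -> str:
        return QUANTITY_UNITS[self.quantity]

    def with_samples(self, samples: np.ndarray, quantity: str | None = None) -> "Waveform":
        return Waveform(samples, self.sample_rate, quantity or self.quantity)

    def peak(self) -> float:
        """Peak absolute amplitude ``max_t |x(t)|``."""
        return float(np.max(np.abs(self.samples)))

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples ** 2)))

    # -- I/O ---------------------------------------------------------------

    def to_wav(self, path: str | Path) -> None:
        """Write as float-PCM WAV plus a JSON sidecar with quantity/units."""
        path = Path(path)
        _wavfile.write(path, int(round(self.sample_rate)), self.samples.astype(np.float32))
        sidecar = {"quantity": self.quantity, "unit": self.unit,
                   "sample_rate_hz": self.sample_rate}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_wav(cls, path: str | Path, quantity: str | None = None) -> "Waveform":
        path = Path(path)
        sr, data = _wavfile.read(path)
        if quantity is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            quantity = (json.loads(sidecar.read_text())["quantity"]
                        if sidecar.exists() else "pressure")
        return cls(np.asarray(data, dtype=float), float(sr), quantity)

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV ``t_s,value``."""
        np.savetxt(path, np.column_stack([self.times, self.samples]),
                   delimiter=",", header=f"t_s,value_{self.unit.replace(' ', '')}",
                   comments="")

    @classmethod
    def from_csv(cls, path: str | Path, quantity: str = "pressure") -> "Waveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, x = data[:, 0], data[:, 1]
        sr = 1.0 / float(np.mean(np.diff(t)))
        return cls(x, sr, quantity)


@dataclass(frozen=True)
class Spectrum:
    """One-sided DFT of a real waveform with per-bin wavenumbers."""

    coefficients: np.ndarray      # complex, rfft layout
    frequencies: np.ndarray       # Hz
    wavenumbers: np.ndarray       # rad m^-1
    n_samples: int
    sample_rate: float

    @classmethod
    def from_waveform(cls, w: Waveform, medium: Medium = WATER) -> "Spectrum":
        coeff = np.fft.rfft(w.samples)
        freqs = np.fft.rfftfreq(len(w), d=1.0 / w.sample_rate)
        return cls(coeff, freqs, 2.0 * np.pi * freqs / medium.sound_speed,
                   len(w), w.sample_rate)

    def centroid(self) -> float:
        """Power-weighted spectral centroid frequency (Hz)."""
        power = np.abs(self.coefficients) ** 2
        power[0] = 0.0  # DC carries no frequency information
        total = power.sum()
        if total == 0:
            raise SilentFieldError("spectral centroid of a silent waveform")
        return float(np.sum(self.frequencies * power) / total)


@dataclass(frozen=True)
class MonopoleSpec:
    """Monopole source: pressure amplitude ``p0`` at reference distance ``r0``."""

    amplitude: float
    reference_distance: float
    medium: Medium = field(default_factory=Medium)

    def __post_init__(self) -> None:
        if self.reference_distance <= 0:
            raise ValueError("reference_distance must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class CueEstimate:
    """Binaural cues between two points separated by ``sample_spacing``.

    Level differences are measured across ``sample_spacing`` and divided by
    ``ear_scale_factor`` to refer them to the inter-ear axis (default 50,
    i.e. a 3 cm sensor spacing scaled to the 0.6 mm ear separation).
    Positive values mean larger / earlier at the left point ``x0``.
    """

    p_ild: float            # Pa
    m_ild: float            # m s^-2
    p_itd: float            # s
    m_itd: float            # s
    sample_spacing: float   # m
    ear_scale_factor: float = 50.0
    p_itd_defined: bool = True
    m_itd_defined: bool = True

    def __post_init__(self) -> None:
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be positive")
        if self.ear_scale_factor <= 0:
            raise ValueError("ear_scale_factor must be positive")


# ---------------------------------------------------------------------------
# Monopole fields
# ---------------------------------------------------------------------------

def _check_rf(r, f) -> None:
    if np.any(np.asarray(r) <= 0):
        raise ValueError("distance r must be positive")
    if np.any(np.asarray(f) <= 0):
        raise ValueError("frequency f must be positive")


def monopole_pressure(spec: MonopoleSpec, r, f, t=0.0):
    """Complex pressure ``p0 * (r0 e^{ikr} / r) e^{-i omega t}``.

    The pressure magnitude decays as 1/r at every frequency.  Accepts
    scalars or broadcastable arrays for ``r``, ``f`` and ``t``.
    """
    _check_rf(r, f)
    r = np.asarray(r, dtype=float)
    f = np.asarray(f, dtype=float)
    omega = 2.0 * np.pi * f
    k = omega / spec.medium.sound_speed
    return (spec.amplitude * spec.reference_distance / r
            * np.exp(1j * k * r) * np.exp(-1j * omega * np.asarray(t)))


def monopole_velocity(spec: MonopoleSpec, r, f, t=0.0):
    """Complex radial particle velocity ``(1/(rho c)) (1 + i/(kr)) p``.

    Far from the source (kr >> 1) this tends to the plane-wave relation
    ``v = p / (rho c)``; in the near field (kr << 1) the 1/(kr) term
    dominates and the magnitude decays as 1/r^2.
    """
    _check_rf(r, f)
    k = 2.0 * np.pi * np.asarray(f, dtype=float) / spec.medium.sound_speed
    p = monopole_pressure(spec, r, f, t)
    return (1.0 + 1j / (k * np.asarray(r, dtype=float))) * p / spec.medium.impedance


def monopole_acceleration(spec: MonopoleSpec, r, f, t=0.0):
    """Complex radial particle acceleration ``(1/rho)(1/r - ik) p``.

    Equals ``-i omega`` times :func:`monopole_velocity`; the magnitude
    decays as 1/r^2 for r much smaller than a wavelength, independent of
    frequency.
    """
    _check_rf(r, f)
    k = 2.0 * np.pi * np.asarray(f, dtype=float) / spec.medium.sound_speed
    p = monopole_pressure(spec, r, f, t)
    return (1.0 / np.asarray(r, dtype=float) - 1j * k) * p / spec.medium.density


def pressure_level_drop(r_near: float, r_far: float) -> float:
    """Fractional monopole pressure-level drop from ``r_near`` to ``r_far``.

    Frequency independent: ``1 - r_near / r_far`` by the 1/r law.
    """
    if r_near <= 0 or r_far <= 0:
        raise ValueError("distances must be positive")
    return 1.0 - r_near / r_far


def velocity_level_drop(r_near: float, r_far: float, f: float,
                        medium: Medium = WATER) -> float:
    """Fractional particle-velocity level drop from ``r_near`` to ``r_far``.

    Frequency dependent: approaches the quadratic-decay value
    ``1 - (r_near/r_far)^2`` at low frequency (kr << 1) and the pressure
    drop ``1 - r_near/r_far`` in the far field.  Exposed as a curve so the
    transition frequency can be inspected rather than hard-coded.
    """
    spec = MonopoleSpec(1.0, r_near, medium)
    v_near = np.abs(monopole_velocity(spec, r_near, f))
    v_far = np.abs(monopole_velocity(spec, r_far, f))
    return float(1.0 - v_far / v_near)


# ---------------------------------------------------------------------------
# Waveform-level conversions
# ---------------------------------------------------------------------------

def _acceleration_factor(r0: float, wavenumbers: np.ndarray, medium: Medium) -> np.ndarray:
    # Physics phasors (e^{-i omega t} convention) obey a = (1/rho)(1/r - ik) p;
    # the positive-frequency DFT bins of a real signal carry e^{+i omega t}
    # and therefore take the conjugate factor.  Time domain: a = p/(rho r) +
    # p'/(rho c), the in-phase geometric near-field term plus the far-field
    # derivative term.  The DC bin (k = 0) gets the purely geometric factor
    # 1/(rho r0); templates are high-pass filtered so DC energy is negligible.
    return (1.0 / r0 + 1j * wavenumbers) / medium.density


def _real_bin_safe(factor: np.ndarray, n: int) -> np.ndarray:
    # For even n the Nyquist bin of a real signal is necessarily real; keep
    # only the real part of the factor there so the conversion is a
    # bijection on real waveforms (the quadrature Nyquist component cannot
    # be represented and band-limited stimuli carry no energy there).
    if n % 2 == 0:
        factor = factor.copy()
        factor[-1] = factor[-1].real
    return factor


def pressure_to_acceleration(p: Waveform, r0: float,
                             medium: Medium = WATER) -> Waveform:
    """Radial particle acceleration of a monopole field from its pressure.

    Applies ``A_l = (1/rho) (1/r0 - i k_l) P_l`` per Fourier component and
    inverts the DFT, i.e. the acceleration that would be observed at
    distance ``r0`` from a monopole whose pressure waveform at ``r0`` is
    ``p``.  Output has the same length and sample rate as the input.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if p.quantity != "pressure":
        raise ValueError("input waveform must be tagged 'pressure'")
    spec = Spectrum.from_waveform(p, medium)
    factor = _real_bin_safe(_acceleration_factor(r0, spec.wavenumbers, medium), len(p))
    a_coeff = factor * spec.coefficients
    a = np.fft.irfft(a_coeff, n=len(p))
    return Waveform(a, p.sample_rate, "acceleration")


def acceleration_to_pressure(a: Waveform, r0: float,
                             medium: Medium = WATER) -> Waveform:
    """Inverse of :func:`pressure_to_acceleration` (per-bin factor inverted)."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    spec = Spectrum.from_waveform(a, medium)
    factor = _real_bin_safe(_acceleration_factor(r0, spec.wavenumbers, medium), len(a))
    p_coeff = spec.coefficients / factor
    p = np.fft.irfft(p_coeff, n=len(a))
    return Waveform(p, a.sample_rate, "pressure")


def propagate_pressure(p: Waveform, r_ref: float, r: float,
                       medium: Medium = WATER) -> Waveform:
    """Monopole pressure waveform at distance ``r`` given it at ``r_ref``.

    Per Fourier component the spherical spreading factor
    ``(r_ref / r) e^{ik(r - r_ref)}`` is applied, i.e. a 1/r amplitude
    rescaling and the propagation delay ``(r - r_ref)/c``.
    """
    if r_ref <= 0 or r <= 0:
        raise ValueError("distances must be positive")
    spec = Spectrum.from_waveform(p, medium)
    delay = (r - r_ref) / medium.sound_speed
    coeff = spec.coefficients * (r_ref / r) * np.exp(
        -2j * np.pi * spec.frequencies * delay)
    return p.with_samples(np.fft.irfft(coeff, n=len(p)))


def gradient_acceleration(p_left: Waveform, p_right: Waveform, dx: float,
                          medium: Medium = WATER) -> Waveform:
    """Particle acceleration from the finite-difference pressure gradient.

    Newton's second law for a fluid parcel, ``a = -grad(p) / rho``,
    discretised as ``a_x = -(p(x2) - p(x1)) / (rho (x2 - x1))``; valid for
    frequencies far below c/dx (~100 kHz at 1.5 cm spacing in water).
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if len(p_left) != len(p_right) or p_left.sample_rate != p_right.sample_rate:
        raise ValueError("waveforms must share length and sample rate")
    a = -(p_right.samples - p_left.samples) / (medium.density * dx)
    return Waveform(a, p_left.sample_rate, "acceleration")


# ---------------------------------------------------------------------------
# Binaural cues
# ---------------------------------------------------------------------------

def geometric_itd(r0: float, r1: float, c: float = WATER.sound_speed) -> float:
    """Propagation-delay ITD for source distances ``r0``/``r1`` to each ear.

    Positive when the left point ``x0`` is nearer (earlier).  The maximal
    value for a sensor separation d is ``d / c`` (source on the sensor
    axis), e.g. 0.4 us for d = 0.6 mm in water.
    """
    if r0 <= 0 or r1 <= 0:
        raise ValueError("distances must be positive")
    return (r1 - r0) / c


def cross_correlation_delay(a: Waveform, b: Waveform) -> float:
    """Delay of ``b`` relative to ``a`` (s) from the cross-correlation peak.

    Positive when ``a`` leads (arrives earlier).  Sub-sample refinement by
    parabolic interpolation around the integer-lag peak.
    """
    if len(a) != len(b) or a.sample_rate != b.sample_rate:
        raise ValueError("waveforms must share length and sample rate")
    from scipy.signal import correlate
    xc = correlate(b.samples, a.samples, mode="full")
    lags = np.arange(-(len(a) - 1), len(a))
    i = int(np.argmax(xc))
    if 0 < i < xc.size - 1:
        denom = xc[i - 1] - 2.0 * xc[i] + xc[i + 1]
        frac = 0.5 * (xc[i - 1] - xc[i + 1]) / denom if denom != 0 else 0.0
    else:
        frac = 0.0
    return float((lags[i] + frac) / a.sample_rate)


def _phase_delay(a: Waveform, b: Waveform) -> float:
    """Signed delay of b vs a from the cross-spectrum phase at the centroid."""
    sa = Spectrum.from_waveform(a)
    sb = Spectrum.from_waveform(b)
    cross = sa.coefficients * np.conj(sb.coefficients)
    weight = np.abs(cross)
    weight[0] = 0.0
    if weight.sum() == 0:
        raise SilentFieldError("phase delay of silent waveforms")
    fc = float(np.sum(sa.frequencies * weight) / weight.sum())
    idx = int(np.argmin(np.abs(sa.frequencies - fc)))
    phase = float(np.angle(cross[idx]))
    return phase / (2.0 * np.pi * sa.frequencies[idx])


def estimate_cues(left: tuple[Waveform, Waveform],
                  right: tuple[Waveform, Waveform],
                  spacing: float,
                  ear_scale_factor: float = 50.0) -> CueEstimate:
    """Binaural cues from (pressure, x-acceleration) pairs at two points.

    ILDs are differences of peak absolute amplitudes,
    ``max_t |q(x0,t)| - max_t |q(x1,t)|``, divided by ``ear_scale_factor``
    to refer the sensor spacing to the inter-ear axis.  ITDs are the signed
    propagation delays of the right-point signal relative to the left-point
    signal, estimated from the cross-spectrum phase at the spectral-centroid
    frequency (cross-correlation is available as an independent check via
    :func:`cross_correlation_delay`).

    Raises :class:`SilentFieldError` if all four inputs are silent; an ITD
    of an identical (or silent) pair is flagged undefined rather than
    reported as a directional zero.
    """
    p0, a0 = left
    p1, a1 = right
    for w, q in ((p0, "pressure"), (p1, "pressure"),
                 (a0, "acceleration"), (a1, "acceleration")):
        if w.quantity != q:
            raise ValueError(f"expected a {q} waveform, got {w.quantity!r}")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if all(np.all(w.samples == 0) for w in (p0, p1, a0, a1)):
        raise SilentFieldError("cannot estimate cues from silent fields")

    p_ild = (p0.peak() - p1.peak()) / ear_scale_factor
    m_ild = (a0.peak() - a1.peak()) / ear_scale_factor

    def itd(w0: Waveform, w1: Waveform) -> tuple[float, bool]:
        silent = np.all(w0.samples == 0) or np.all(w1.samples == 0)
        identical = np.array_equal(w0.samples, w1.samples)
        if silent or identical:
            return 0.0, False
        return _phase_delay(w0, w1), True

    p_itd, p_ok = itd(p0, p1)
    m_itd, m_ok = itd(a0, a1)
    return CueEstimate(p_ild=p_ild, m_ild=m_ild, p_itd=p_itd, m_itd=m_itd,
                       sample_spacing=spacing, ear_scale_factor=ear_scale_factor,
                       p_itd_defined=p_ok, m_itd_defined=m_ok)


def cue_table(estimates: dict[str, CueEstimate]) -> "pandas.DataFrame":
    """Cue estimates as a table with one row per stimulus configuration."""
    import pandas as pd
    rows = [{"config_id": cid, "p_ild_pa": e.p_ild, "m_ild_ms2": e.m_ild,
             "p_itd_s": e.p_itd, "m_itd_s": e.m_itd}
            for cid, e in estimates.items()]
    return pd.DataFrame(rows)


__all__ = [
    "Medium", "WATER", "Waveform", "Spectrum", "MonopoleSpec", "CueEstimate",
    "SilentFieldError", "monopole_pressure", "monopole_velocity",
    "monopole_acceleration", "pressure_level_drop", "velocity_level_drop",
    "pressure_to_acceleration", "acceleration_to_pressure", "propagate_pressure",
    "gradient_acceleration", "geometric_itd", "cross_correlation_delay",
    "estimate_cues", "cue_table",
]
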