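"""Impulse-response-based multi-speaker stimulus conditioning.

Given measured (or simulated) per-speaker impulse-response kernels for
pressure and x/y particle acceleration on a spatial grid, this module
solves for speaker drive signals that deliver a target (p, a_x, a_y)
triple at any grid position while cancelling reverberation.  It realizes
the standing-wave (pressure-only / motion-only) and "trick" (pressure
selectively inverted) configurations and interpolates solved programs
between grid nodes.

The per-bin system ``K_l S_l = (P_l, A_{x,l}, A_{y,l})^T`` is solved with
a bounded least-squares solver after stacking real and imaginary parts,
with box bounds ``|S_{i,l}| <= B_{i,l} = alpha_i * gamma * |P_l|`` applied
to both parts (a documented approximation of the modulus bound).  Solved
signals are restricted to the conditioning pass band, 200-1200 Hz by
default, chosen to stay above the lateral-line sensitivity range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile as _wavfile
from scipy.optimize import lsq_linear
from scipy.signal import fftconvolve

from .acoustics import Waveform

QUANTITIES = ("pressure", "ax", "ay")
DEFAULT_BAND = (200.0, 1200.0)


class ConditioningError(RuntimeError):
    """Raised when a speaker program cannot meet its postconditions."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImpulseResponseGrid:
    """Per-speaker, per-quantity impulse responses at grid positions.

    ``kernels`` has shape (M, G, 3, N): M speakers, G grid positions, the
    three quantities (pressure, a_x, a_y) and N kernel samples.  Positions
    are tank-centred metres.  ``speaker_positions`` (M, 2) is metadata used
    to identify opposing pairs and orthogonal axes.
    """

    kernels: np.ndarray
    positions: np.ndarray
    speaker_positions: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.speaker_positions = np.asarray(self.speaker_positions, dtype=float)
        if self.kernels.ndim != 4 or self.kernels.shape[2] != 3:
            raise ValueError("kernels must have shape (M, G, 3, N)")
        if self.positions.shape != (self.kernels.shape[1], 2):
            raise ValueError("positions must have shape (G, 2)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_speakers(self) -> int:
        return self.kernels.shape[0]

    @property
    def n_positions(self) -> int:
        return self.kernels.shape[1]

    @property
    def kernel_length(self) -> int:
        return self.kernels.shape[3]

    def position_index(self, xy) -> int:
        d = np.hypot(*(self.positions - np.asarray(xy, dtype=float)).T)
        i = int(np.argmin(d))
        if d[i] > 1e-9:
            raise ValueError(f"{xy} is not a grid node")
        return i

    def kernel(self, speaker: int, position: int, quantity: str) -> Waveform:
        q = QUANTITIES.index(quantity)
        tag = "pressure" if quantity == "pressure" else "acceleration"
        return Waveform(self.kernels[speaker, position, q], self.sample_rate, tag)

    # -- I/O ---------------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kernels", data=self.kernels)
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("speaker_positions", data=self.speaker_positions)
            f.attrs["sample_rate"] = self.sample_rate

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ImpulseResponseGrid":
        with h5py.File(path, "r") as f:
            return cls(f["kernels"][()], f["positions"][()],
                       f["speaker_positions"][()], float(f.attrs["sample_rate"]))

    def export_kernel_csv(self, path: str | Path, speaker: int, position: int,
                          quantity: str) -> None:
        self.kernel(speaker, position, quantity).to_csv(path)


@dataclass
class TargetField:
    """Target (pressure, x-acceleration, y-acceleration) triple.

    ``bound_reference`` is the pressure waveform whose magnitude spectrum
    sets the solver bounds ``B_{i,l}``; it defaults to the pressure target
    and must be supplied for motion-only targets (whose pressure is zero).
    """

    p: Waveform
    ax: Waveform
    ay: Waveform
    label: str = ""
    bound_reference: Waveform | None = None

    def __post_init__(self) -> None:
        n, sr = len(self.p), self.p.sample_rate
        for w in (self.ax, self.ay):
            if len(w) != n or w.sample_rate != sr:
                raise ValueError("target components must share length and rate")

    @property
    def n_samples(self) -> int:
        return len(self.p)

    @property
    def sample_rate(self) -> float:
        return self.p.sample_rate

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.p.samples, self.ax.samples, self.ay.samples

    @classmethod
    def from_template(cls, template: Waveform, label: str, r0: float = 0.03,
                      n_samples: int | None = None, band=DEFAULT_BAND,
                      onset_delay: float = 0.005, medium=None) -> "TargetField":
        """Build a configuration target from the pressure template.

        The template is delayed by ``onset_delay`` seconds (a modelling
        delay so the inverse-filtered speaker drives, which must lead the
        field by the propagation and speaker-response delay, stay causal)
        and zero-padded to ``n_samples`` to leave room for reverberation
        decay inside the conditioning window.  Its particle acceleration
        is derived for a monopole at distance ``r0`` and both components
        are band-limited to the conditioning band so the target is
        realizable by band-limited speaker signals.
        """
        from .acoustics import WATER, pressure_to_acceleration
        from .configs import component_signs
        medium = medium or WATER
        lead = int(round(onset_delay * template.sample_rate))
        n = n_samples or (len(template) + lead)
        if n < len(template) + lead:
            raise ValueError("n_samples must cover the delayed template")
        p_pad = Waveform(np.pad(template.samples,
                                (lead, n - len(template) - lead)),
                         template.sample_rate, "pressure")
        p_bl = band_limit(p_pad, band)
        a_bl = band_limit(pressure_to_acceleration(p_bl, r0, medium), band)
        p_sign, a_sign = component_signs(label)
        zero = Waveform(np.zeros(n), template.sample_rate, "acceleration")
        return cls(
            p=p_bl.with_samples(p_sign * p_bl.samples),
            ax=a_bl.with_samples(a_sign * a_bl.samples) if a_sign else zero,
            ay=zero,
            label=label,
            bound_reference=p_bl,
        )


@dataclass
class SpeakerProgram:
    """Solved per-speaker drive signals with their conditioning metadata."""

    signals: np.ndarray          # (M, N), arbitrary voltage units
    sample_rate: float
    alpha: np.ndarray            # (M,) per-speaker bound scale
    gamma: float = 1.0           # pressure-to-voltage scale
    band: tuple[float, float] = DEFAULT_BAND
    label: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must have shape (M, N)")

    @property
    def n_speakers(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def to_wav(self, path: str | Path) -> None:
        """Multichannel float WAV plus JSON sidecar (alpha, gamma, band, label)."""
        path = Path(path)
        _wavfile.write(path, int(round(self.sample_rate)),
                       self.signals.T.astype(np.float32))
        meta = {"alpha": self.alpha.tolist(), "gamma": self.gamma,
                "band_hz": list(self.band), "label": self.label}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_wav(cls, path: str | Path) -> "SpeakerProgram":
        path = Path(path)
        sr, data = _wavfile.read(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(np.asarray(data, dtype=float).T, float(sr),
                   np.asarray(meta["alpha"]), meta["gamma"],
                   tuple(meta["band_hz"]), meta["label"])


# ---------------------------------------------------------------------------
# Band handling
# ---------------------------------------------------------------------------

def band_limit(w: Waveform, band=DEFAULT_BAND) -> Waveform:
    """Restrict a waveform to [band[0], band[1]] Hz by zeroing DFT bins.

    A sharp spectral gate keeps band limitation idempotent, which makes the
    conditioning loop (solve in-band, zero out-of-band) exactly consistent
    with the band-limited target.
    """
    coeff = np.fft.rfft(w.samples)
    f = np.fft.rfftfreq(len(w), 1.0 / w.sample_rate)
    coeff[(f < band[0]) | (f > band[1])] = 0.0
    return w.with_samples(np.fft.irfft(coeff, n=len(w)))


def out_of_band_energy_fraction(w: Waveform, band=DEFAULT_BAND) -> float:
    """Fraction of signal energy outside the pass band (DFT-bin energy)."""
    power = np.abs(np.fft.rfft(w.samples)) ** 2
    f = np.fft.rfftfreq(len(w), 1.0 / w.sample_rate)
    total = power.sum()
    if total == 0:
        return 0.0
    return float(power[(f < band[0]) | (f > band[1])].sum() / total)


# ---------------------------------------------------------------------------
# Field prediction
# ---------------------------------------------------------------------------

def predict_field(grid: ImpulseResponseGrid, program: SpeakerProgram,
                  position) -> TargetField:
    """Field produced by a program at a grid position.

    ``q(t) = sum_i (k_{i,q} * s_i)(t)`` by linear (zero-padded) convolution,
    truncated to the program length.
    """
    if program.sample_rate != grid.sample_rate:
        raise ValueError("program and grid sample rates differ")
    g = position if isinstance(position, (int, np.integer)) else grid.position_index(position)
    n = program.n_samples
    out = np.zeros((3, n))
    for q in range(3):
        acc = fftconvolve(grid.kernels[:, g, q, :], program.signals, axes=1)
        out[q] = acc.sum(axis=0)[:n]
    sr = grid.sample_rate
    return TargetField(Waveform(out[0], sr, "pressure"),
                       Waveform(out[1], sr, "acceleration"),
                       Waveform(out[2], sr, "acceleration"),
                       label=program.label)


# ---------------------------------------------------------------------------
# Conditioning (bounded per-bin least squares)
# ---------------------------------------------------------------------------

def _stack_real(K: np.ndarray, b: np.ndarray):
    """Complex (3, M) system -> real (6, 2M) system [Re | -Im; Im | Re]."""
    A = np.block([[K.real, -K.imag], [K.imag, K.real]])
    rhs = np.concatenate([b.real, b.imag])
    return A, rhs


DEFAULT_ALPHA = 10.0


def solve_program(grid: ImpulseResponseGrid, target: TargetField, position,
                  alpha=None, gamma: float | None = None, band=DEFAULT_BAND,
                  cond_max: float = 1e6, fixed_signals: dict | None = None,
                  fixed_tol: float = 0.01,
                  accel_weight: float | None = None) -> SpeakerProgram:
    """Solve per-speaker drive signals delivering ``target`` at ``position``.

    Per retained Fourier bin, minimizes ``||K_l S_l - (P_l, Ax_l, Ay_l)||_2``
    subject to ``|Re S|, |Im S| <= B_{i,l} = alpha_i gamma |P_l|`` where
    ``|P_l|`` is the magnitude spectrum of the target's bound-reference
    pressure.  Bins outside the pass band are zeroed; bins whose kernel
    matrix has condition number above ``cond_max`` are skipped and recorded
    in the diagnostics.

    ``gamma`` converts pressure (Pa) to drive units; when None it is set
    to the inverse of the median in-band pressure-kernel magnitude, so a
    bound of ``alpha_i = 1`` roughly allows each speaker to produce the
    target pressure on its own.  The default ``alpha`` leaves headroom for
    near-field acceleration targets and echo cancellation.
    ``accel_weight`` (default ``rho * 0.03`` m) converts the acceleration
    rows to pressure-equivalent units so the least-squares trade-off is
    balanced between components.

    ``fixed_signals`` maps speaker index -> time-domain signal (length
    ``target.n_samples``) to be held (within ``fixed_tol`` relative bounds)
    at a previously solved value; used by the two-step trick conditioning.
    """
    M = grid.n_speakers
    if M < 3:
        raise ConditioningError("need at least 3 speakers to condition "
                                "(p, ax, ay) independently")
    if target.sample_rate != grid.sample_rate:
        raise ValueError("target and grid sample rates differ")
    g = position if isinstance(position, (int, np.integer)) else grid.position_index(position)
    alpha = (np.full(M, DEFAULT_ALPHA) if alpha is None
             else np.broadcast_to(np.asarray(alpha, dtype=float), (M,)))

    n = target.n_samples
    nfft = n  # targets are pre-padded; the DFT length is the program length
    freqs = np.fft.rfftfreq(nfft, 1.0 / grid.sample_rate)
    Kf = np.fft.rfft(grid.kernels[:, g, :, :], n=nfft, axis=-1)  # (M, 3, L)
    P, Ax, Ay = (np.fft.rfft(c, n=nfft) for c in target.components())
    ref = target.bound_reference if target.bound_reference is not None else target.p
    Bmag = np.abs(np.fft.rfft(ref.samples, n=nfft))

    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if gamma is None:
        typical = np.median(np.abs(Kf[:, 0, in_band]))
        gamma = 1.0 / typical if typical > 0 else 1.0
    if accel_weight is None:
        accel_weight = 30.0   # rho * r0 for water and a 3 cm source distance
    weights = np.array([1.0, accel_weight, accel_weight])

    fixed_spectra = {}
    if fixed_signals:
        for i, sig in fixed_signals.items():
            fixed_spectra[int(i)] = np.fft.rfft(np.asarray(sig, dtype=float), n=nfft)

    S = np.zeros((M, freqs.size), dtype=complex)
    skipped, residuals = [], []
    targets_w = np.abs(np.array([P, Ax, Ay])) * weights[:, None]
    scale = max(float(targets_w.max()), 1e-30)

    for l in np.flatnonzero(in_band):
        K = Kf[:, :, l].T * weights[:, None]  # (3, M), unit-balanced rows
        if not np.all(np.isfinite(K)) or np.linalg.cond(K) > cond_max:
            skipped.append(int(l))
            continue
        b = np.array([P[l], Ax[l], Ay[l]]) * weights
        A, rhs = _stack_real(K, b)
        lb = np.empty(2 * M)
        ub = np.empty(2 * M)
        for i in range(M):
            if i in fixed_spectra:
                centre = fixed_spectra[i][l]
                half = fixed_tol * (abs(centre) + 1e-6 * max(Bmag[l], 1e-30))
                lb[i], ub[i] = centre.real - half, centre.real + half
                lb[M + i], ub[M + i] = centre.imag - half, centre.imag + half
            else:
                B = alpha[i] * gamma * Bmag[l]
                lb[i] = lb[M + i] = -B
                ub[i] = ub[M + i] = B
        res = lsq_linear(A, rhs, bounds=(lb, ub), tol=1e-12)
        S[:, l] = res.x[:M] + 1j * res.x[M:]
        residuals.append(float(np.linalg.norm(A @ res.x - rhs) / scale))

    signals = np.fft.irfft(S, n=nfft, axis=1)
    diagnostics = {
        "skipped_bins": skipped,
        "n_bins_solved": int(in_band.sum()) - len(skipped),
        "max_bin_residual": max(residuals) if residuals else 0.0,
        "position_index": int(g),
    }
    return SpeakerProgram(signals, grid.sample_rate, alpha, gamma, tuple(band),
                          target.label, diagnostics)


def relative_rms_error(predicted: Waveform, target: Waveform) -> float:
    """RMS of (predicted - target) relative to the target RMS."""
    err = np.sqrt(np.mean((predicted.samples - target.samples) ** 2))
    ref = np.sqrt(np.mean(target.samples ** 2))
    return float(err / ref) if ref > 0 else float(np.inf if err > 0 else 0.0)


def _pressure_scale(target: TargetField) -> float:
    ref = target.bound_reference if target.bound_reference is not None else target.p
    return ref.rms()


def _accel_scale(target: TargetField) -> float:
    """Acceleration RMS a monopole at 3 cm would pair with the pressure target."""
    from .acoustics import pressure_to_acceleration
    ref = target.bound_reference if target.bound_reference is not None else target.p
    if ref.rms() == 0:
        return 0.0
    return pressure_to_acceleration(ref, 0.03).rms()


def field_errors(grid: ImpulseResponseGrid, program: SpeakerProgram,
                 position, target: TargetField) -> dict:
    """Per-component relative RMS error / leakage of a program's field.

    Non-zero target components report relative RMS error.  Zero components
    report leakage: predicted RMS divided by the natural scale of that
    component (the bound-reference pressure for p, the monopole-equivalent
    acceleration of the bound reference for ax/ay).
    """
    pred = predict_field(grid, program, position)
    out = {}
    for name, p_w, t_w in (("p", pred.p, target.p), ("ax", pred.ax, target.ax),
                           ("ay", pred.ay, target.ay)):
        if t_w.rms() > 0:
            out[name] = relative_rms_error(p_w, t_w)
        else:
            base = _pressure_scale(target) if name == "p" else _accel_scale(target)
            out[name] = float(p_w.rms() / base) if base > 0 else 0.0
    return out


def make_standing_wave_program(grid: ImpulseResponseGrid, template: Waveform,
                               mode: str, position, r0: float = 0.03,
                               n_samples: int | None = None, alpha=None,
                               gamma: float = 1.0, band=DEFAULT_BAND,
                               leakage_tol: float = 0.05) -> SpeakerProgram:
    """Pressure-only or motion-only standing-wave program.

    Pressure-only targets (p = template, ax = 0, ay = 0); motion-only
    targets (p = 0, ax = monopole acceleration of the template at ``r0``,
    ay = 0).  Raises :class:`ConditioningError` if the predicted off-target
    component exceeds ``leakage_tol`` of the on-target RMS.
    """
    if mode not in ("pressure_only", "motion_only"):
        raise ValueError("mode must be 'pressure_only' or 'motion_only'")
    label = "pressure_pos" if mode == "pressure_only" else "motion_pos"
    target = TargetField.from_template(template, label, r0=r0,
                                       n_samples=n_samples, band=band)
    program = solve_program(grid, target, position, alpha=alpha, gamma=gamma,
                            band=band)
    pred = predict_field(grid, program, position)
    if mode == "pressure_only":
        leak = pred.ax.rms() / _accel_scale(target)
    else:
        leak = pred.p.rms() / target.bound_reference.rms()
    program.diagnostics["off_target_leakage"] = float(leak)
    if leak > leakage_tol:
        raise ConditioningError(
            f"standing-wave leakage {leak:.3f} exceeds {leakage_tol}")
    return program


def orthogonal_speakers(grid: ImpulseResponseGrid, speaker: int) -> list[int]:
    """Speakers on the axis orthogonal to the given speaker's axis."""
    pos = grid.speaker_positions
    axis = int(np.argmax(np.abs(pos[speaker])))  # 0 = x axis, 1 = y axis
    other = 1 - axis
    return [i for i in range(grid.n_speakers)
            if abs(pos[i, other]) > abs(pos[i, axis])]


def make_trick_program(grid: ImpulseResponseGrid,
                       single_program: SpeakerProgram,
                       position, single_target: TargetField,
                       alpha=None, gamma: float = 1.0, band=DEFAULT_BAND,
                       fixed_tol: float = 0.01,
                       corr_tol: float = 0.99) -> SpeakerProgram:
    """Two-step trick conditioning: invert pressure, keep particle motion.

    The speakers already active in ``single_program`` are held at their
    solved signals (within ``fixed_tol`` relative bounds) and only the two
    speakers along the orthogonal axis are conditioned, targeting the
    single-speaker field with its pressure sign flipped.  The postcondition
    is verified through :func:`predict_field`: the trick pressure must
    anticorrelate (r <= -``corr_tol``) and the x acceleration correlate
    (r >= ``corr_tol``) with the single-speaker field.
    """
    energy = np.sum(single_program.signals ** 2, axis=1)
    held_speaker = int(np.argmax(energy))
    free = orthogonal_speakers(grid, held_speaker)
    if len(free) < 2:
        raise ConditioningError("need two speakers on the orthogonal axis")
    g = position if isinstance(position, (int, np.integer)) else grid.position_index(position)
    for i in free:
        if np.max(np.abs(grid.kernels[i, g, 0, :])) == 0:
            raise ConditioningError(
                f"orthogonal speaker {i} has no pressure response at the "
                "target position; pressure inversion is unreachable")

    trick_label = single_target.label.replace("single", "trick")
    target = TargetField(
        p=single_target.p.with_samples(-single_target.p.samples),
        ax=single_target.ax, ay=single_target.ay,
        label=trick_label, bound_reference=single_target.bound_reference)
    fixed = {i: single_program.signals[i] for i in range(grid.n_speakers)
             if i not in free}
    program = solve_program(grid, target, position, alpha=alpha, gamma=gamma,
                            band=band, fixed_signals=fixed, fixed_tol=fixed_tol)

    pred_single = predict_field(grid, single_program, position)
    pred_trick = predict_field(grid, program, position)
    corr_p = float(np.corrcoef(pred_trick.p.samples, pred_single.p.samples)[0, 1])
    corr_ax = float(np.corrcoef(pred_trick.ax.samples, pred_single.ax.samples)[0, 1])
    program.diagnostics["pressure_correlation"] = corr_p
    program.diagnostics["ax_correlation"] = corr_ax
    if corr_p > -corr_tol or corr_ax < corr_tol:
        raise ConditioningError(
            f"trick postcondition failed: corr(p) = {corr_p:.3f}, "
            f"corr(ax) = {corr_ax:.3f}")
    return program


def interpolate_program(grid: ImpulseResponseGrid,
                        programs: dict[int, SpeakerProgram],
                        query) -> SpeakerProgram:
    """Bilinear interpolation of node programs at a query position.

    ``programs`` maps grid position indices to solved programs at those
    nodes; the query must lie inside the grid hull.  At a node the node
    program is returned exactly; at the midpoint of two nodes the signals
    are the arithmetic mean.
    """
    xs = np.unique(grid.positions[:, 0])
    ys = np.unique(grid.positions[:, 1])
    qx, qy = float(query[0]), float(query[1])
    if not (xs[0] <= qx <= xs[-1] and ys[0] <= qy <= ys[-1]):
        raise ValueError(f"query {query} outside the grid hull")
    # a query on a solved node is returned exactly (interpolation identity)
    d = np.hypot(*(grid.positions - [qx, qy]).T)
    nearest = int(np.argmin(d))
    if d[nearest] < 1e-12 and nearest in programs:
        return programs[nearest]
    ix = int(np.clip(np.searchsorted(xs, qx, side="right") - 1, 0, xs.size - 2))
    iy = int(np.clip(np.searchsorted(ys, qy, side="right") - 1, 0, ys.size - 2))
    x0, x1 = xs[ix], xs[ix + 1]
    y0, y1 = ys[iy], ys[iy + 1]
    tx = (qx - x0) / (x1 - x0)
    ty = (qy - y0) / (y1 - y0)

    def node(ax_, ay_):
        xy = (xs[ax_], ys[ay_])
        idx = grid.position_index(xy)
        if idx not in programs:
            raise ValueError(f"no program solved at grid node {xy}")
        return programs[idx]

    corners = [(node(ix, iy), (1 - tx) * (1 - ty)),
               (node(ix + 1, iy), tx * (1 - ty)),
               (node(ix, iy + 1), (1 - tx) * ty),
               (node(ix + 1, iy + 1), tx * ty)]
    signals = sum(w * p.signals for p, w in corners)
    base = corners[0][0]
    return SpeakerProgram(signals, base.sample_rate, base.alpha, base.gamma,
                          base.band, base.label,
                          {"interpolated_at": [qx, qy]})


__all__ = [
    "ImpulseResponseGrid", "TargetField", "SpeakerProgram",
    "ConditioningError", "band_limit", "out_of_band_energy_fraction",
    "predict_field", "solve_program", "relative_rms_error", "field_errors",
    "make_standing_wave_program", "make_trick_program", "orthogonal_speakers",
    "interpolate_program", "QUANTITIES", "DEFAULT_BAND",
]
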