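"""Stroboscopic laser-scanning vibrometry reconstruction.

A continuous sinusoidal sound stimulus at ``f_stim`` is locked to the
line rate ``f_scan`` of a scanning microscope so that each line, scanned
``n_step`` times in a row, samples the oscillation at phase offsets of
exactly ``2 pi / n_step``:

    f_stim = (N + 1/n_step) * f_scan,   N = floor(f_stim / f_scan)

Reshaping the repeats yields an (Ny, Nx, n_step) phase stack.  Frame-to-
frame displacements are estimated by multi-pass block matching with
sub-pixel cross-correlation peaks; the first Fourier coefficient over the
phase steps gives per-pixel oscillation amplitude and phase, which is
then corrected for the acoustic phase accumulating along the scan (x)
direction at ``2 pi f_stim t_pixel`` per pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.interpolate import RegularGridInterpolator, griddata
from scipy.ndimage import median_filter
from scipy.signal import fftconvolve
from skimage import exposure


# ---------------------------------------------------------------------------
# Scan planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanPlan:
    """Stroboscopic timing of one vibrometry acquisition."""

    f_scan: float                 # line rate, Hz
    f_stim: float                 # admissible stimulation frequency, Hz
    n_step: int                   # phase steps per line
    n_cycles: int                 # integer N in the rate relation
    pixel_period: float           # s per pixel along the line
    shape: tuple = (128, 128)     # (Ny, Nx)
    planes: int = 1

    def __post_init__(self) -> None:
        if self.n_step < 3:
            raise ValueError(
                "n_step must be >= 3: each pixel must be sampled at more "
                "than two phases to reconstruct amplitude and phase")
        expected = (self.n_cycles + 1.0 / self.n_step) * self.f_scan
        if abs(self.f_stim - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("f_stim must equal (N + 1/n_step) * f_scan")
        if self.pixel_period * self.shape[1] > 1.0 / self.f_scan + 1e-12:
            raise ValueError("a line of pixels must fit into one line period")

    @property
    def phase_offsets(self) -> np.ndarray:
        """Stimulus phase sampled by repeat j at the start of each line."""
        return 2.0 * np.pi * np.arange(self.n_step) / self.n_step

    def column_phase(self, columns) -> np.ndarray:
        """Acoustic phase accumulated by pixel column along the scan."""
        return 2.0 * np.pi * self.f_stim * self.pixel_period * np.asarray(columns)


def plan_scan(f_scan: float, n_step: int, requested_f_stim: float,
              shape: tuple = (128, 128), planes: int = 1,
              pixel_period: float | None = None,
              line_pixels: int = 512) -> ScanPlan:
    """Nearest admissible stimulation frequency at or below the request.

    ``N = floor(requested / f_scan)`` maximizes the line rate relative to
    the stimulus; the admissible frequency is ``(N + 1/n_step) f_scan``.
    The default pixel period assumes a full scan line of ``line_pixels``
    pixels at an 80% duty cycle (the imaged field may be a crop of the
    line), keeping the per-pixel acoustic phase step small compared with
    the block-matching windows.
    """
    if f_scan <= 0:
        raise ValueError("f_scan must be positive")
    if n_step < 3:
        raise ValueError("n_step must be >= 3 (phase Nyquist requirement)")
    if requested_f_stim < f_scan / n_step:
        raise ValueError("requested stimulation frequency below the smallest "
                         "admissible value f_scan / n_step")
    n_cycles = int(np.floor(requested_f_stim / f_scan))
    f_stim = (n_cycles + 1.0 / n_step) * f_scan
    if pixel_period is None:
        pixel_period = 0.8 / (f_scan * max(line_pixels, shape[1]))
    return ScanPlan(f_scan=f_scan, f_stim=f_stim, n_step=n_step,
                    n_cycles=n_cycles, pixel_period=pixel_period,
                    shape=tuple(shape), planes=planes)


# ---------------------------------------------------------------------------
# Phase stacks
# ---------------------------------------------------------------------------

@dataclass
class PhaseStack:
    """Reflectance images at ``n_step`` stimulus phases (optionally z planes).

    ``data`` has shape (Ny, Nx, n_step) or (Ny, Nx, n_step, planes) with
    non-negative intensities.
    """

    data: np.ndarray
    plan: ScanPlan
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError("data must be (Ny, Nx, n_step[, planes])")
        if self.data.shape[2] != self.plan.n_step:
            raise ValueError("phase-step axis does not match the scan plan")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def n_planes(self) -> int:
        return self.data.shape[3]

    def to_tiff(self, path: str | Path) -> None:
        """Multi-page TIFF (pages = planes x steps) + JSON scan metadata."""
        path = Path(path)
        ny, nx, ns, npl = self.data.shape
        pages = np.moveaxis(self.data, (3, 2), (0, 1)).reshape(npl * ns, ny, nx)
        tifffile.imwrite(path, pages.astype(np.float32),
                         photometric="minisblack")
        meta = {"f_scan": self.plan.f_scan, "f_stim": self.plan.f_stim,
                "n_step": self.plan.n_step, "n_cycles": self.plan.n_cycles,
                "pixel_period": self.plan.pixel_period,
                "shape": list(self.plan.shape), "planes": npl,
                "ground_truth": self.ground_truth}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "PhaseStack":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        pages = tifffile.imread(path)
        npl, ns = meta["planes"], meta["n_step"]
        data = np.moveaxis(pages.reshape(npl, ns, *pages.shape[-2:]), (0, 1), (3, 2))
        plan = ScanPlan(meta["f_scan"], meta["f_stim"], ns, meta["n_cycles"],
                        meta["pixel_period"], tuple(meta["shape"]), npl)
        return cls(data, plan, meta.get("ground_truth", {}))


# ---------------------------------------------------------------------------
# Block-matching displacement estimation
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Displacement vectors on a window-centre grid (pixels)."""

    dx: np.ndarray
    dy: np.ndarray
    rows: np.ndarray            # window-centre y coordinates
    cols: np.ndarray            # window-centre x coordinates
    valid: np.ndarray           # False where featureless / weak peak / outlier

    def to_dense(self, shape) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear upsampling of (dx, dy) onto the full pixel grid."""
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
        out = []
        for comp in (self.dx, self.dy):
            itp = RegularGridInterpolator((self.rows, self.cols), comp,
                                          bounds_error=False, fill_value=None)
            out.append(itp(pts).reshape(shape))
        return out[0], out[1]


def _subpixel_offset(c: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Three-point Gaussian (fallback parabolic) peak interpolation."""
    def axis_offset(m1, c0, p1):
        if m1 > 0 and c0 > 0 and p1 > 0:
            denom = np.log(m1) + np.log(p1) - 2.0 * np.log(c0)
            if denom < 0:
                return 0.5 * (np.log(m1) - np.log(p1)) / denom
        denom = m1 + p1 - 2.0 * c0
        return 0.5 * (m1 - p1) / denom if denom != 0 else 0.0
    dy = axis_offset(c[i - 1, j], c[i, j], c[i + 1, j]) if 0 < i < c.shape[0] - 1 else 0.0
    dx = axis_offset(c[i, j - 1], c[i, j], c[i, j + 1]) if 0 < j < c.shape[1] - 1 else 0.0
    return float(dy), float(dx)


def _match_window(a: np.ndarray, b: np.ndarray, max_shift: int
                  ) -> tuple[float, float, float]:
    """Cross-correlate two equal windows; return (dy, dx, peak NCC)."""
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0, 0.0, 0.0
    corr = fftconvolve(b, a[::-1, ::-1], mode="full") / (a.size * sa * sb)
    centre = np.array(a.shape) - 1
    lo = centre - max_shift
    hi = centre + max_shift + 1
    sub = corr[lo[0]:hi[0], lo[1]:hi[1]]
    # unbiased normalization: the zero-padded correlation shrinks linearly
    # with the per-lag overlap, which would drag broad peaks toward zero lag
    lags = np.arange(-max_shift, max_shift + 1)
    tent_y = 1.0 - np.abs(lags) / a.shape[0]
    tent_x = 1.0 - np.abs(lags) / a.shape[1]
    sub = sub / np.outer(tent_y, tent_x)
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    peak = float(sub[i, j])
    oy, ox = _subpixel_offset(sub, i, j)
    return float(i - max_shift + oy), float(j - max_shift + ox), peak


def enhance_contrast(img: np.ndarray) -> np.ndarray:
    """Adaptive histogram equalization of a reflectance image."""
    lo, hi = np.min(img), np.max(img)
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    norm = (img - lo) / (hi - lo)
    return exposure.equalize_adapthist(norm, clip_limit=0.02)


def estimate_displacement(img_a: np.ndarray, img_b: np.ndarray,
                          windows: tuple = (64, 32, 16),
                          overlap: float = 0.5,
                          min_peak: float = 0.3,
                          outlier_px: float = 2.0,
                          enhance: bool = True) -> DisplacementField:
    """Displacement of ``img_b`` relative to ``img_a`` by block matching.

    Multi-pass coarse-to-fine cross-correlation of interrogation windows
    (``windows`` sizes, ``overlap`` fraction), with sub-pixel peak
    interpolation.  Windows with no texture or a weak correlation peak are
    masked invalid; vectors deviating more than ``outlier_px`` from their
    3x3 local median are masked as outliers; gaps are filled by linear
    interpolation from the valid vectors.
    """
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError("images must have equal shapes")
    if min(windows) < 8:
        raise ValueError("interrogation windows must be at least 8 px")
    if enhance:
        img_a = enhance_contrast(img_a)
        img_b = enhance_contrast(img_b)

    shape = img_a.shape
    prev: DisplacementField | None = None
    for w in windows:
        step = max(1, int(round(w * (1.0 - overlap))))
        half = w // 2
        rows = np.arange(half, shape[0] - half + 1, step)
        cols = np.arange(half, shape[1] - half + 1, step)
        dx = np.zeros((rows.size, cols.size))
        dy = np.zeros((rows.size, cols.size))
        valid = np.ones((rows.size, cols.size), dtype=bool)
        if prev is not None:
            gy, gx = np.meshgrid(rows, cols, indexing="ij")
            pts = np.stack([gy.ravel(), gx.ravel()], axis=1)
            for arr, comp in ((dx, prev.dx), (dy, prev.dy)):
                itp = RegularGridInterpolator((prev.rows, prev.cols), comp,
                                              bounds_error=False, fill_value=None)
                arr[...] = itp(pts).reshape(arr.shape)
        max_shift = max(2, w // 4)
        for iy, r in enumerate(rows):
            for ix, c in enumerate(cols):
                sy = int(round(dy[iy, ix]))
                sx = int(round(dx[iy, ix]))
                ra, ca = r - half, c - half
                rb, cb = ra + sy, ca + sx
                if rb < 0 or cb < 0 or rb + w > shape[0] or cb + w > shape[1]:
                    sy = sx = 0
                    rb, cb = ra, ca
                a = img_a[ra:ra + w, ca:ca + w]
                b = img_b[rb:rb + w, cb:cb + w]
                oy, ox, peak = _match_window(a, b, max_shift)
                if peak < min_peak:
                    valid[iy, ix] = False
                    dy[iy, ix] = sy
                    dx[iy, ix] = sx
                else:
                    dy[iy, ix] = sy + oy
                    dx[iy, ix] = sx + ox
        prev = DisplacementField(dx, dy, rows.astype(float), cols.astype(float), valid)

    return _postprocess(prev, outlier_px)


def _postprocess(fld: DisplacementField, outlier_px: float) -> DisplacementField:
    """Local-median outlier rejection and gap interpolation."""
    valid = fld.valid.copy()
    for comp in (fld.dx, fld.dy):
        med = median_filter(comp, size=3, mode="nearest")
        valid &= np.abs(comp - med) <= outlier_px
    dx, dy = fld.dx.copy(), fld.dy.copy()
    if valid.any() and not valid.all():
        gy, gx = np.meshgrid(fld.rows, fld.cols, indexing="ij")
        pts_ok = np.stack([gy[valid], gx[valid]], axis=1)
        pts_bad = np.stack([gy[~valid], gx[~valid]], axis=1)
        for comp in (dx, dy):
            fill = griddata(pts_ok, comp[valid], pts_bad, method="linear")
            nearest = griddata(pts_ok, comp[valid], pts_bad, method="nearest")
            fill = np.where(np.isfinite(fill), fill, nearest)
            comp[~valid] = fill
    elif not valid.any():
        dx[...] = 0.0
        dy[...] = 0.0
    return DisplacementField(dx, dy, fld.rows, fld.cols, valid)


# ---------------------------------------------------------------------------
# Motion reconstruction
# ---------------------------------------------------------------------------

@dataclass
class MotionMap:
    """Per-pixel complex displacement (micrometres) for x and y motion."""

    dx: np.ndarray               # complex, amplitude um / phase rad
    dy: np.ndarray
    valid: np.ndarray
    pixel_size_um: float
    plan: ScanPlan

    def amplitude(self, component: str = "x") -> np.ndarray:
        return np.abs(self.dx if component == "x" else self.dy)

    def phase(self, component: str = "x") -> np.ndarray:
        return np.angle(self.dx if component == "x" else self.dy)

    def to_tiff(self, path_prefix: str | Path, component: str = "x") -> None:
        """Amplitude/phase TIFF pair."""
        prefix = Path(path_prefix)
        tifffile.imwrite(prefix.with_name(prefix.name + "_amplitude.tif"),
                         self.amplitude(component).astype(np.float32))
        tifffile.imwrite(prefix.with_name(prefix.name + "_phase.tif"),
                         self.phase(component).astype(np.float32))


def _first_fourier(displacements: list[np.ndarray], n_step: int) -> np.ndarray:
    """Complex motion from displacements relative to phase step 0.

    For d_j = A sin(2 pi j/n + psi) - A sin(psi) the first Fourier
    coefficient (2/n) sum_j d_j e^{-2 pi i j/n} equals -i A e^{i psi}; the
    constant offset only affects the DC term.  Multiplying by i returns
    A e^{i psi} directly.
    """
    acc = np.zeros_like(displacements[0], dtype=complex)
    for j, d in enumerate(displacements):
        acc += d * np.exp(-2j * np.pi * j / n_step)
    return 1j * acc * (2.0 / n_step)


def reconstruct_motion(stack: PhaseStack, windows: tuple = (64, 32, 16),
                       pixel_size_um: float = 1.0,
                       min_valid_fraction: float = 0.0,
                       **piv_kwargs) -> MotionMap:
    """Per-pixel oscillation amplitude and phase from a phase stack.

    Displacement fields between phase step j and step 0 are estimated by
    block matching, the first Fourier coefficient over the steps gives the
    complex motion, and the phase is corrected per pixel column for the
    acoustic phase accumulated along the scan direction.  Multi-plane
    stacks are reduced by a per-pixel maximum-amplitude projection.
    """
    plan = stack.plan
    if stack.data.shape[:2] != tuple(plan.shape):
        raise ValueError("stack image shape does not match the scan plan")
    ny, nx = stack.data.shape[:2]
    per_plane = []
    for pl in range(stack.n_planes):
        ref = stack.data[:, :, 0, pl]
        dxs, dys, masks = [np.zeros((ny, nx))], [np.zeros((ny, nx))], []
        for j in range(1, plan.n_step):
            fld = estimate_displacement(ref, stack.data[:, :, j, pl],
                                        windows=windows, **piv_kwargs)
            ddx, ddy = fld.to_dense((ny, nx))
            dxs.append(ddx)
            dys.append(ddy)
            mask_itp = RegularGridInterpolator(
                (fld.rows, fld.cols), fld.valid.astype(float),
                method="nearest", bounds_error=False, fill_value=0.0)
            yy, xx = np.mgrid[0:ny, 0:nx]
            masks.append(mask_itp(np.stack([yy.ravel(), xx.ravel()], axis=1))
                         .reshape(ny, nx) > 0.5)
        cx = _first_fourier(dxs, plan.n_step) * pixel_size_um
        cy = _first_fourier(dys, plan.n_step) * pixel_size_um
        correction = np.exp(-1j * plan.column_phase(np.arange(nx)))[None, :]
        per_plane.append((cx * correction, cy * correction,
                          np.logical_and.reduce(masks)))
    if len(per_plane) == 1:
        cx, cy, valid = per_plane[0]
    else:
        amps = np.stack([np.abs(p[0]) + np.abs(p[1]) for p in per_plane])
        best = np.argmax(amps, axis=0)
        cx = np.choose(best, [p[0] for p in per_plane])
        cy = np.choose(best, [p[1] for p in per_plane])
        valid = np.choose(best, [p[2] for p in per_plane])
    return MotionMap(cx, cy, valid, pixel_size_um, plan)


# ---------------------------------------------------------------------------
# Region statistics and relative motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMotion:
    """Motion statistics over a region of interest."""

    amplitude_mean: float        # um
    amplitude_sd: float
    phase_mean: float            # rad, circular mean in (-pi, pi]
    phase_sd: float              # rad, circular standard deviation
    n_pixels: int
    amplitude_median: float = float("nan")


def circular_mean_sd(phases: np.ndarray) -> tuple[float, float]:
    z = np.mean(np.exp(1j * np.asarray(phases)))
    r = min(abs(z), 1.0)
    sd = float(np.sqrt(-2.0 * np.log(r))) if r > 0 else float("inf")
    return float(np.angle(z)), sd


def region_stats(motion: MotionMap, mask: np.ndarray,
                 component: str = "x", use_valid: bool = True) -> RegionMotion:
    mask = np.asarray(mask, dtype=bool)
    if use_valid:
        mask = mask & motion.valid
    if not mask.any():
        raise ValueError("empty (or fully invalid) region")
    amp = motion.amplitude(component)[mask]
    ph = motion.phase(component)[mask]
    mean_ph, sd_ph = circular_mean_sd(ph)
    return RegionMotion(float(amp.mean()), float(amp.std()),
                        mean_ph, sd_ph, int(mask.sum()),
                        amplitude_median=float(np.median(amp)))


@dataclass(frozen=True)
class RelativeMotion:
    """Relative motion of region B with respect to region A."""

    amplitude_ratio: float           # A_B / A_A, ratio of region means
    phase_difference: float          # rad in (-pi, pi]
    max_relative_displacement: float  # um, peak of the difference oscillation
    amplitude_ratio_median: float = float("nan")  # ratio of region medians


def max_relative_displacement(amp_a: float, amp_b: float,
                              phase_difference: float) -> float:
    """Peak of the difference of two same-frequency sinusoids.

    ``|A_a - A_b e^{i dphi}| = sqrt(A_a^2 + A_b^2 - 2 A_a A_b cos dphi)``.
    """
    return float(np.sqrt(amp_a ** 2 + amp_b ** 2
                         - 2.0 * amp_a * amp_b * np.cos(phase_difference)))


def relative_motion(region_a: RegionMotion, region_b: RegionMotion
                    ) -> RelativeMotion:
    """Amplitude ratio, circular phase lag and peak relative displacement."""
    if region_a.n_pixels == 0 or region_b.n_pixels == 0:
        raise ValueError("regions must be non-empty")
    dphi = float(np.angle(np.exp(1j * (region_b.phase_mean - region_a.phase_mean))))
    med = (region_b.amplitude_median / region_a.amplitude_median
           if region_a.amplitude_median and np.isfinite(region_a.amplitude_median)
           else float("nan"))
    return RelativeMotion(
        amplitude_ratio=region_b.amplitude_mean / region_a.amplitude_mean,
        phase_difference=dphi,
        max_relative_displacement=max_relative_displacement(
            region_a.amplitude_mean, region_b.amplitude_mean, dphi),
        amplitude_ratio_median=med,
    )


__all__ = [
    "ScanPlan", "plan_scan", "PhaseStack", "DisplacementField",
    "estimate_displacement", "enhance_contrast", "MotionMap",
    "reconstruct_motion", "RegionMotion", "region_stats", "circular_mean_sd",
    "RelativeMotion", "relative_motion", "max_relative_displacement",
]
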