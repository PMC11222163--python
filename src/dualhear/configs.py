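"""Stimulus-configuration vocabulary shared across modules.

Twelve playback configurations: four single-speaker sounds
(left/right x positive/negative polarity), two pressure-only and two
motion-only standing-wave sounds (positive/negative polarity), and four
trick sounds that match the single-speaker targets but invert the pressure
component via the orthogonal speaker pair.
"""

from __future__ import annotations

SIDES = ("L", "R")
POLARITIES = ("pos", "neg")

SINGLE_CONFIGS = tuple(f"single_{s}_{p}" for s in SIDES for p in POLARITIES)
TRICK_CONFIGS = tuple(f"trick_{s}_{p}" for s in SIDES for p in POLARITIES)
PRESSURE_CONFIGS = tuple(f"pressure_{p}" for p in POLARITIES)
MOTION_CONFIGS = tuple(f"motion_{p}" for p in POLARITIES)

ALL_CONFIGS = SINGLE_CONFIGS + PRESSURE_CONFIGS + MOTION_CONFIGS + TRICK_CONFIGS


def config_kind(label: str) -> str:
    """One of {'single', 'pressure', 'motion', 'trick'}."""
    kind = label.split("_")[0]
    if kind not in ("single", "pressure", "motion", "trick"):
        raise ValueError(f"unknown configuration label {label!r}")
    return kind


def active_side(label: str) -> str | None:
    """'L' or 'R' for lateralized configurations, None for standing waves."""
    if config_kind(label) in ("single", "trick"):
        return label.split("_")[1]
    return None


def polarity(label: str) -> int:
    """+1 for positive template polarity, -1 for negative."""
    return +1 if label.endswith("pos") else -1


def component_signs(label: str) -> tuple[int, int]:
    """Signs (p_sign, ax_sign) of the target (pressure, x-acceleration).

    The x axis runs left(-) to right(+).  A monopole on the left produces
    x acceleration of the same sign as its pressure (motion directed away
    from the source, towards +x); a monopole on the right produces the
    opposite sign.  The trick configuration inverts the pressure sign of
    the matching single-speaker target while keeping the acceleration.
    """
    kind = config_kind(label)
    pol = polarity(label)
    if kind == "pressure":
        return pol, 0
    if kind == "motion":
        return 0, pol
    side = active_side(label)
    ax_sign = pol if side == "L" else -pol
    p_sign = pol if kind == "single" else -pol
    return p_sign, ax_sign


def mirror(label: str) -> str:
    """Reflect a configuration about the y axis (swap left and right).

    Lateralized configurations swap sides; the motion-only standing wave
    is antisymmetric in x, so its reflection is the opposite polarity; the
    pressure-only standing wave is symmetric and maps to itself.
    """
    kind = config_kind(label)
    if kind in ("single", "trick"):
        kind, side, pol = label.split("_")
        return f"{kind}_{'R' if side == 'L' else 'L'}_{pol}"
    if kind == "motion":
        return f"motion_{'neg' if label.endswith('pos') else 'pos'}"
    return label


__all__ = [
    "SIDES", "POLARITIES", "SINGLE_CONFIGS", "TRICK_CONFIGS",
    "PRESSURE_CONFIGS", "MOTION_CONFIGS", "ALL_CONFIGS",
    "config_kind", "active_side", "polarity", "component_signs", "mirror",
]
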