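"""Oscillation windowing, cosine fitting, and storage/loss modulus extraction.

The dynamic moduli follow from the amplitudes F0, h0 of the oscillatory
load and depth and the phase lag delta between them.  With contact area
A = pi*a^2 the spherical-contact relations are

    E'(w)  = (1 - nu^2) * (F0/h0) * cos(delta) / (2*a)
    E''(w) = (1 - nu^2) * (F0/h0) * sin(delta) / (2*a)

so E''/E' = tan(delta) identically.  The contact radius a is evaluated
from the window-mean corrected indentation depth: during an oscillatory
ramp the contact grows, hence fits are done per 5-cycle block with the
block-averaged depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import IndentationRecord, ProtocolSpec

__all__ = [
    "CosineFit",
    "fit_cosine",
    "Window",
    "segment_windows",
    "find_trigger_time",
    "moduli_from_fit",
    "shear_from_storage",
    "wrap_phase",
]

OR_CYCLES_PER_WINDOW = 5


def wrap_phase(phi: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    phi = math.fmod(phi, 2.0 * math.pi)
    if phi > math.pi:
        phi -= 2.0 * math.pi
    elif phi <= -math.pi:
        phi += 2.0 * math.pi
    return phi


@dataclass(frozen=True)
class CosineFit:
    """Least-squares fit of y = A*cos(2*pi*f*t + phi) + b [+ m*t]."""

    amplitude: float
    phase: float          # rad, wrapped to (-pi, pi]
    offset: float
    linear_slope: float   # 0 when detrending disabled
    r2: float


def fit_cosine(t: np.ndarray, y: np.ndarray, freq: float, detrend: bool = False) -> CosineFit:
    """Fit a fixed-frequency cosine by linear least squares.

    The model is linear in (A*cos(phi), A*sin(phi), offset[, slope]), so the
    fit is a single lstsq solve — deterministic and free of starting-value
    issues.  ``detrend=True`` adds a linear term, used for oscillatory-ramp
    windows where the ramp advances during the block.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need >= 4 matching samples")
    if freq <= 0:
        raise ValueError("frequency must be positive")
    w = 2.0 * math.pi * freq
    # reference time at window start improves conditioning of the t column
    tref = t - t[0]
    cols = [np.cos(w * t), np.sin(w * t), np.ones_like(t)]
    if detrend:
        cols.append(tref)
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular cosine design matrix (degenerate time base)")
    a, b = beta[0], beta[1]
    amplitude = math.hypot(a, b)
    phase = wrap_phase(math.atan2(-b, a))
    resid = y - X @ beta
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    slope = float(beta[3]) if detrend else 0.0
    return CosineFit(amplitude, phase, float(beta[2]), slope, min(r2, 1.0))


@dataclass(frozen=True)
class Window:
    """One oscillation analysis window within a record."""

    start: float       # s
    end: float         # s
    frequency: float   # Hz, drive frequency
    index: int
    label: str         # "or" or "fs"


def find_trigger_time(record: IndentationRecord, trigger_load: float | None = None) -> float:
    """Time of the first crossing of the trigger load (feedback engagement)."""
    if trigger_load is None:
        trigger_load = record.protocol.trigger_load
    above = np.nonzero(record.load >= trigger_load)[0]
    if not above.size:
        raise ValueError("record never reaches the trigger load")
    return float(record.time[above[0]])


def protocol_windows(protocol: ProtocolSpec, t_start: float, t_end: float) -> list[Window]:
    """Oscillation windows for a protocol whose controlled phase starts at t_start.

    OR: consecutive non-overlapping 5-cycle windows over the ramp; a trailing
    partial window is dropped.  FS: one window per frequency, skipping the
    loading and relaxation segments and the first (settling) cycle of each
    frequency block.
    """
    wins: list[Window] = []
    if protocol.kind == "oscillatory_ramp":
        f = protocol.or_frequency
        dur = OR_CYCLES_PER_WINDOW / f
        k = 0
        while t_start + (k + 1) * dur <= t_end + 1e-12:
            wins.append(Window(t_start + k * dur, t_start + (k + 1) * dur, f, k, "or"))
            k += 1
        return wins
    # frequency sweep
    t = t_start + protocol.fs_load_depth / protocol.fs_load_speed + protocol.fs_relax_time
    for k, f in enumerate(protocol.fs_frequencies):
        block = protocol.fs_cycles / f
        # trigger-detection jitter can leave the record marginally shorter
        # than the nominal profile; trim the window to the record end and
        # keep it as long as no more than one cycle is missing
        end_w = min(t + block, t_end)
        if end_w - (t + 1.0 / f) >= (protocol.fs_cycles - 2) / f - 1e-9:
            wins.append(Window(t + 1.0 / f, end_w, f, k, "fs"))
        t += block
    return wins


def segment_windows(record: IndentationRecord, trigger_time: float | None = None) -> list[Window]:
    """Segment a record into oscillation windows from its protocol timing.

    The controlled phase begins one settling interval after the trigger
    crossing; window placement is then fully determined by the protocol.
    """
    if trigger_time is None:
        trigger_time = find_trigger_time(record)
    t0 = trigger_time + record.protocol.settle_time
    return protocol_windows(record.protocol, t0, float(record.time[-1]))


def moduli_from_fit(F0: float, h0: float, delta: float, a: float, nu: float = 0.5) -> tuple[float, float]:
    """Convert oscillation amplitudes and phase lag into (E', E'') in Pa.

    delta is the phase of the load oscillation minus the phase of the depth
    oscillation, wrapped into (-pi, pi].
    """
    if a <= 0:
        raise ValueError("zero contact area")
    if F0 < 0 or h0 <= 0:
        raise ValueError("amplitudes must be positive")
    factor = (1.0 - nu**2) * F0 / (2.0 * a * h0)
    return factor * math.cos(delta), factor * math.sin(delta)


def shear_from_storage(E_storage: float, nu: float = 0.5) -> float:
    """Shear storage modulus G' = E' / (2*(1+nu)); E'/3 for nu = 0.5."""
    if E_storage < 0:
        raise ValueError("storage modulus must be non-negative")
    return E_storage / (2.0 * (1.0 + nu))
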