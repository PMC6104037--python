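"""Hertzian spherical contact mechanics and surface detection.

For a rigid sphere of radius R indenting an incompressible half-space to
depth h, the Hertz load is F = (4/3) * E/(1-nu^2) * sqrt(R) * h^(3/2); the
contact radius in the small-depth regime is a = sqrt(h*R) and the
indentation strain is eps = 0.2 * a/R.  The true surface position is not
known a priori (the depth channel is piezo-referenced), so it is recovered
by fitting F = c * (h_raw - offset)^(3/2) to the initial loading segment
below the trigger threshold; the fitted offset corrects the depth channel
and the prefactor yields an apparent quasi-static modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .records import IndentationRecord

__all__ = [
    "hertz_force",
    "contact_radius",
    "contact_area",
    "indentation_strain",
    "hertz_contact_stiffness",
    "ContactFit",
    "detect_surface",
    "BaselineCheck",
    "started_in_contact",
    "InsufficientLoadingDataError",
]


class InsufficientLoadingDataError(ValueError):
    """Raised when too few samples lie below the fit threshold."""


def hertz_force(E, nu, R, h):
    """Hertz load F = (4/3) * E/(1-nu^2) * sqrt(R) * h^(3/2) (SI units).

    Accepts scalars or arrays in ``h``. Negative depths are a caller error:
    pre-contact samples must be clipped to zero force by the caller.
    """
    if np.any(np.asarray(R) <= 0):
        raise ValueError("tip radius must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    out = (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * h**1.5
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def hertz_contact_stiffness(E, nu, R, h):
    """Tangent stiffness dF/dh = 2*a*E/(1-nu^2) with a = sqrt(h*R)."""
    a = contact_radius(h, R)
    return 2.0 * a * E / (1.0 - nu**2)


def contact_radius(h, R):
    """Contact radius a = sqrt(h*R) for spherical indentation."""
    if np.any(np.asarray(R) <= 0):
        raise ValueError("tip radius must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    out = np.sqrt(h * R)
    return float(out) if out.ndim == 0 else out


def contact_area(h, R):
    """Contact area A = pi * a^2 = pi * h * R."""
    a = contact_radius(h, R)
    return math.pi * np.asarray(a) ** 2 if np.ndim(a) else math.pi * a * a


def indentation_strain(h, R):
    """Indentation strain eps = 0.2 * a / R = 0.2 * sqrt(h/R)."""
    a = contact_radius(h, R)
    return a * (0.2 / R)


@dataclass
class ContactFit:
    """Result of the surface-detection Hertz fit.

    ``converged=False`` marks a flagged failure (rendered as a gap in the
    maps); it never raises, so a single bad curve cannot abort a grid run.
    """

    surface_offset: float          # m, piezo coordinate of the true surface
    hertz_modulus: float           # Pa, apparent quasi-static E from the fit
    fit_r2: float
    fit_range: tuple[int, int]     # [start, end) sample indices used
    corrected_depth: np.ndarray    # m, h = raw - offset, clipped at 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not -1e-12 <= self.fit_r2 <= 1.0 + 1e-12:
            raise ValueError("fit_r2 must lie in [0, 1] for a converged fit")


def detect_surface(
    record: IndentationRecord,
    threshold_load: float | None = None,
    min_samples: int = 10,
    max_iterations: int = 200,
) -> ContactFit:
    """Locate the sample surface by Hertz-fitting the initial loading data.

    Samples from the start of the record up to the first crossing of
    ``threshold_load`` (default: the protocol's trigger load) are fit with
    F = c * max(h_raw - offset, 0)^(3/2) by bounded least squares.
    Pre-contact samples contribute zero model force, which anchors the
    offset; the apparent modulus is E = 3*c*(1-nu^2) / (4*sqrt(R)).
    """
    if threshold_load is None:
        threshold_load = record.protocol.trigger_load
    load = record.load
    depth = record.depth

    above = np.nonzero(load >= threshold_load)[0]
    end = int(above[0]) + 1 if above.size else load.size
    if end < min_samples:
        raise InsufficientLoadingDataError(
            f"insufficient loading data: {end} samples below threshold, need {min_samples}"
        )
    t_seg = slice(0, end)
    h_seg = depth[t_seg]
    f_seg = load[t_seg]

    R = record.probe.tip_radius
    nu = record.probe.poisson_ratio

    # Profile out the Hertz prefactor: for a fixed offset, the best c in
    # F = c*max(h-offset,0)^(3/2) is a closed-form linear LSQ solution, so
    # the fit reduces to a 1-D search over the offset.  Pre-contact samples
    # contribute zero model force, which anchors the offset near contact.
    def profiled_ss(offset: float) -> tuple[float, float]:
        w = np.clip(h_seg - offset, 0.0, None) ** 1.5
        ww = float(np.dot(w, w))
        if ww <= 0.0:
            return float(np.dot(f_seg, f_seg)), 0.0
        c = float(np.dot(w, f_seg)) / ww
        r = c * w - f_seg
        return float(np.dot(r, r)), c

    lo = float(np.min(h_seg))
    hi = float(np.max(h_seg))
    grid = np.linspace(lo, hi, 256)
    ss_grid = np.array([profiled_ss(o)[0] for o in grid])
    k = int(np.argmin(ss_grid))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, grid.size - 1)]
    sol = minimize_scalar(
        lambda o: profiled_ss(o)[0],
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": 1e-13, "maxiter": max_iterations},
    )
    offset = float(sol.x)
    ss_res, c = profiled_ss(offset)
    converged = bool(sol.success) and c > 0.0
    e_apparent = 3.0 * c * (1.0 - nu**2) / (4.0 * math.sqrt(R)) if c > 0 else float("nan")

    ss_tot = float(np.sum((f_seg - np.mean(f_seg)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    corrected = np.clip(depth - offset, 0.0, None)
    return ContactFit(offset, e_apparent, min(max(r2, 0.0), 1.0), (0, end),
                      corrected, converged=converged)


@dataclass(frozen=True)
class BaselineCheck:
    """Decision on whether a record started already in contact."""

    in_contact: bool
    zscore: float          # mean pre-trigger load in units of baseline sigma
    n_baseline: int


def started_in_contact(
    record: IndentationRecord,
    k_sigma: float = 5.0,
    noise_sigma: float | None = None,
    min_baseline_samples: int = 10,
) -> BaselineCheck:
    """Flag records whose approach segment lacks a zero-load baseline.

    A well-formed record shows near-zero load during the free approach
    before the trigger.  If the mean pre-trigger load exceeds
    ``k_sigma`` baseline standard deviations the probe was already
    touching the sample when acquisition started; such records are
    rejected downstream.  Degenerate approach segments (fewer than
    ``min_baseline_samples`` samples) are conservatively flagged.
    """
    trigger = record.protocol.trigger_load
    above = np.nonzero(record.load >= trigger)[0]
    end = int(above[0]) if above.size else record.load.size
    # baseline = first half of the pre-trigger segment, away from contact
    n_base = end // 2
    if n_base < min_baseline_samples:
        return BaselineCheck(True, math.inf, n_base)
    seg = record.load[:n_base]
    if noise_sigma is not None:
        sigma = noise_sigma
    else:
        # detrended residual std estimates the noise floor even when the
        # baseline carries a slow ramp (drift or creeping contact)
        t = record.time[:n_base]
        coeffs = np.polyfit(t, seg, 1)
        sigma = float(np.std(seg - np.polyval(coeffs, t)))
    sigma = max(sigma, 1e-12)
    z = abs(float(np.mean(seg))) / sigma
    return BaselineCheck(z > k_sigma, z, n_base)
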