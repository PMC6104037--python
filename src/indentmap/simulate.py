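"""Forward simulation of depth-controlled ferrule-top indentation.

The simulator emulates the instrument's behaviour on a spatially
heterogeneous viscoelastic phantom: a constant-speed approach until the
load crosses the trigger threshold, an uncontrolled 1-3 um initial
penetration while the depth feedback engages, and then one of two
depth-controlled protocols (oscillatory ramp or equilibrium frequency
sweep).  The depth channel is treated as perfectly feedback-controlled;
measurement noise is additive white Gaussian on the load channel (the
interferometric readout), with optional linear drift.

Every record carries the ground truth used to generate it, so each
downstream analysis stage can be verified by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

from .contact import contact_radius, hertz_contact_stiffness, hertz_force, indentation_strain
from .oscillation import OR_CYCLES_PER_WINDOW
from .records import IndentationRecord, ProbeSpec, ProtocolSpec
from .rheology import RheologyModel

__all__ = ["TissuePhantom", "GridSpec", "simulate_record", "simulate_grid", "synthetic_nuclei_mask"]

UNCONTROLLED_DEPTH_RANGE = (1e-6, 3e-6)   # m, initial penetration at trigger


@dataclass
class TissuePhantom:
    """Spatial layout of rheologically distinct regions in a slice.

    ``regions`` is an ordered list of (label, polygon in um slice
    coordinates, rheology model); a query point takes the first listed
    polygon that covers it (boundary included), falling back to
    ``background``.  ``surface_offset`` is the piezo coordinate of the
    true sample surface (m), either a constant or a callable of (x, y).
    """

    regions: list[tuple[str, Polygon, RheologyModel]] = field(default_factory=list)
    background: RheologyModel = field(default_factory=lambda: RheologyModel("elastic", 1500.0))
    surface_offset: float = 20e-6

    def __post_init__(self) -> None:
        for label, poly, _ in self.regions:
            if not poly.is_valid:
                raise ValueError(f"region {label!r} polygon is invalid (self-intersecting?)")

    def model_at(self, x: float, y: float) -> tuple[str, RheologyModel]:
        p = Point(x, y)
        for label, poly, model in self.regions:
            if poly.covers(p):
                return label, model
        return "background", self.background

    def offset_at(self, x: float, y: float) -> float:
        if callable(self.surface_offset):
            return float(self.surface_offset(x, y))
        return float(self.surface_offset)


def _trigger_depth(model: RheologyModel, probe: ProbeSpec, omega: float, trigger_load: float) -> float:
    """Depth at which the quasi-static Hertz load reaches the trigger."""
    R, nu = probe.tip_radius, probe.poisson_ratio

    def f(h):
        eps = indentation_strain(h, R)
        E = model.complex_modulus(omega, eps)[0]
        return hertz_force(E, nu, R, h) - trigger_load

    return brentq(f, 1e-12, 50e-6)


def simulate_record(
    phantom: TissuePhantom,
    probe: ProbeSpec,
    protocol: ProtocolSpec,
    location: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    noise_sigma: float = 0.5e-9,
    drift: float = 0.0,
    slice_id: str = "slice0",
    animal_id: str = "animal0",
    record_id: str | None = None,
) -> IndentationRecord:
    """Simulate one indentation record at a grid location.

    Parameters
    ----------
    noise_sigma : float
        Std of the additive Gaussian load noise in N (default 0.5 nN).
    drift : float
        Linear load drift in N/s added to the load channel.

    Notes
    -----
    Within each oscillatory-ramp 5-cycle block the quasi-static load is
    linearized about the block-mean depth using the exact Hertz tangent
    stiffness 2*a*E'/(1-nu^2); the oscillatory response is synthesized as
    (2*a*h0/(1-nu^2)) * (E'*cos(wt) - E''*sin(wt)).  Generator and
    analyzer therefore share one quasi-static approximation, which makes
    noise-free round trips exact.
    """
    rate = protocol.effective_sample_rate
    if rate < 10.0 * protocol.max_frequency:
        raise ValueError(
            f"sample rate {rate:g} Hz < 10x oscillation frequency "
            f"{protocol.max_frequency:g} Hz: cosine fits would alias"
        )
    rng = np.random.default_rng(seed)
    h_init = rng.uniform(*UNCONTROLLED_DEPTH_RANGE)

    label, model = phantom.model_at(*location)
    offset = phantom.offset_at(*location)
    R, nu = probe.tip_radius, probe.poisson_ratio
    h0 = protocol.osc_amplitude
    dt = 1.0 / rate

    if protocol.kind == "oscillatory_ramp":
        omega_drive = 2.0 * math.pi * protocol.or_frequency
    else:
        omega_drive = 2.0 * math.pi * protocol.fs_frequencies[0]

    def qs_load(h):
        """Quasi-static Hertz load at depth h (clipped below contact)."""
        h = max(h, 0.0)
        if h == 0.0:
            return 0.0
        eps = indentation_strain(h, R)
        E = model.complex_modulus(omega_drive, eps)[0]
        return hertz_force(E, nu, R, h)

    # --- approach: free travel then Hertzian loading up to the trigger ---
    h_trig = _trigger_depth(model, probe, omega_drive, protocol.trigger_load)
    t_trig_exact = (offset + h_trig) / protocol.approach_speed
    n_before = int(math.ceil(t_trig_exact / dt - 1e-9))
    t_trigger = n_before * dt     # first grid sample at/after the crossing

    t0 = t_trigger + protocol.settle_time   # controlled phase begins here

    # depth at the end of settling joins the protocol trajectory continuously
    if protocol.kind == "oscillatory_ramp":
        eps_init = indentation_strain(h_init, R)
        ramp_dur = (protocol.or_final_strain - eps_init) / protocol.or_strain_rate
        if ramp_dur <= 0:
            raise ValueError("or_final_strain below the initial uncontrolled strain")
        t_end = t0 + ramp_dur
        h_settle_target = h_init + h0
    else:
        load_dur = protocol.fs_load_depth / protocol.fs_load_speed
        osc_dur = sum(protocol.fs_cycles / f for f in protocol.fs_frequencies)
        t_end = t0 + load_dur + protocol.fs_relax_time + osc_dur
        h_settle_target = h_init

    n_total = int(math.ceil(t_end / dt - 1e-9)) + 1   # last sample at/after t_end
    time = np.arange(n_total) * dt
    depth = np.empty(n_total)
    load = np.empty(n_total)

    # approach samples (t <= t_trigger): depth moves at the approach speed
    app = time <= t_trigger + 1e-12
    z_app = protocol.approach_speed * time[app]
    depth[app] = z_app
    load[app] = [qs_load(z - offset) for z in z_app]

    # settling (t_trigger, t0]: linear dive to the uncontrolled depth
    z_trig = protocol.approach_speed * t_trigger
    settle = (~app) & (time <= t0 + 1e-12)
    frac = (time[settle] - t_trigger) / protocol.settle_time
    depth[settle] = z_trig + frac * (offset + h_settle_target - z_trig)
    load[settle] = [qs_load(z - offset) for z in depth[settle]]

    ctrl = time > t0 + 1e-12
    tau = time[ctrl] - t0

    if protocol.kind == "oscillatory_ramp":
        eps_ramp = eps_init + protocol.or_strain_rate * tau
        h_ramp = R * (eps_ramp / 0.2) ** 2
        h_ctrl = h_ramp + h0 * np.cos(2.0 * math.pi * protocol.or_frequency * tau)
        f_ctrl = np.empty_like(h_ctrl)
        dur = OR_CYCLES_PER_WINDOW / protocol.or_frequency
        n_blocks = int(math.ceil(tau[-1] / dur))
        omega = 2.0 * math.pi * protocol.or_frequency
        for k in range(n_blocks):
            sel = (tau >= k * dur) & (tau < (k + 1) * dur)
            if not np.any(sel):
                continue
            h_bar = float(np.mean(h_ctrl[sel]))       # block-mean measured depth
            eps_bar = indentation_strain(h_bar, R)
            e1, e2 = model.complex_modulus(omega, eps_bar)
            a = contact_radius(h_bar, R)
            k_c = hertz_contact_stiffness(e1, nu, R, h_bar)
            f_qs = hertz_force(e1, nu, R, h_bar) + k_c * (h_ramp[sel] - h_bar)
            osc = (2.0 * a * h0 / (1.0 - nu**2)) * (
                e1 * np.cos(omega * tau[sel]) - e2 * np.sin(omega * tau[sel])
            )
            f_ctrl[sel] = f_qs + osc
    else:
        load_dur = protocol.fs_load_depth / protocol.fs_load_speed
        h_op = protocol.fs_load_depth
        h_ctrl = np.empty_like(tau)
        f_ctrl = np.empty_like(tau)
        loading = tau <= load_dur + 1e-12
        h_ctrl[loading] = np.minimum(h_init + protocol.fs_load_speed * tau[loading], h_op)
        f_ctrl[loading] = [qs_load(h) for h in h_ctrl[loading]]
        relax = (~loading) & (tau <= load_dur + protocol.fs_relax_time + 1e-12)
        h_ctrl[relax] = h_op
        f_ctrl[relax] = qs_load(h_op)
        t_block = load_dur + protocol.fs_relax_time
        eps_op = indentation_strain(h_op, R)
        a = contact_radius(h_op, R)
        f_static = qs_load(h_op)
        for j, f_k in enumerate(protocol.fs_frequencies):
            block = protocol.fs_cycles / f_k
            last = j == len(protocol.fs_frequencies) - 1
            sel = (tau > t_block + 1e-12)
            if not last:
                sel &= tau <= t_block + block + 1e-12
            theta = 2.0 * math.pi * f_k * (tau[sel] - t_block)
            e1, e2 = model.complex_modulus(2.0 * math.pi * f_k, eps_op)
            h_ctrl[sel] = h_op + h0 * np.cos(theta)
            f_ctrl[sel] = f_static + (2.0 * a * h0 / (1.0 - nu**2)) * (
                e1 * np.cos(theta) - e2 * np.sin(theta)
            )
            t_block += block

    depth[ctrl] = offset + h_ctrl
    load[ctrl] = f_ctrl

    if noise_sigma > 0:
        load = load + rng.normal(0.0, noise_sigma, n_total)
    if drift != 0.0:
        load = load + drift * time

    return IndentationRecord(
        time=time,
        depth=depth,
        load=load,
        probe=probe,
        protocol=protocol,
        location=tuple(location),
        slice_id=slice_id,
        animal_id=animal_id,
        record_id=record_id or f"{slice_id}_x{location[0]:.0f}_y{location[1]:.0f}",
        noise_seed=seed,
        truth={
            "region": label,
            "model": model,
            "surface_offset": offset,
            "h_init": h_init,
            "trigger_time": t_trigger,
            "protocol_start": t0,
        },
    )


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid of indentation locations in um slice coordinates."""

    origin: tuple[float, float] = (0.0, 0.0)
    spacing: float = 50.0          # um, >= 50 so deformed areas do not overlap
    nx: int = 3
    ny: int = 3

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("empty grid")
        if self.spacing < 50.0:
            raise ValueError("grid spacing below 50 um: deformed areas would overlap")

    def locations(self) -> list[tuple[float, float]]:
        x0, y0 = self.origin
        return [
            (x0 + i * self.spacing, y0 + j * self.spacing)
            for j in range(self.ny)
            for i in range(self.nx)
        ]


def simulate_grid(
    phantom: TissuePhantom,
    probe: ProbeSpec,
    protocol: ProtocolSpec,
    grid: GridSpec,
    seed: int = 0,
    noise_sigma: float = 0.5e-9,
    drift: float = 0.0,
    slice_id: str = "slice0",
    animal_id: str = "animal0",
) -> list[IndentationRecord]:
    """Simulate one record per grid point with per-point seeds derived
    deterministically from the master seed."""
    locs = grid.locations()
    children = np.random.SeedSequence(seed).spawn(len(locs))
    out = []
    for i, (loc, child) in enumerate(zip(locs, children)):
        point_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            simulate_record(
                phantom, probe, protocol, loc,
                seed=point_seed, noise_sigma=noise_sigma, drift=drift,
                slice_id=slice_id, animal_id=animal_id,
                record_id=f"{slice_id}_p{i:04d}",
            )
        )
    return out


def synthetic_nuclei_mask(
    shape: tuple[int, int],
    coverage_by_region: list[tuple[Polygon, float]],
    pixel_size: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    nucleus_radius_px: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Binary nuclei mask with a target area coverage per region.

    Synthetic stand-in for a thresholded fluorescence nuclei channel: disks
    of ``nucleus_radius_px`` are dropped at random inside each polygon until
    the covered fraction of that region reaches its target.  Used to test
    the relative-nuclear-area computation and the density grouping; it does
    not emulate nucleus shape, clustering, or out-of-plane blur.
    """
    import shapely
    from skimage.draw import disk

    ny, nx = shape
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    xs = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    for poly, target in coverage_by_region:
        if not 0.0 <= target <= 1.0:
            raise ValueError("coverage target must lie in [0, 1]")
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(shape)
        n_inside = int(inside.sum())
        if n_inside == 0:
            raise ValueError("region polygon does not intersect the raster")
        xmin, ymin, xmax, ymax = poly.bounds
        guard = 0
        while (mask & inside).sum() / n_inside < target:
            guard += 1
            if guard > 100000:
                raise RuntimeError("mask generation did not reach target coverage")
            cx = rng.uniform(xmin, xmax)
            cy = rng.uniform(ymin, ymax)
            col = int((cx - origin[0]) / pixel_size)
            row = int((cy - origin[1]) / pixel_size)
            rr, cc = disk((row, col), nucleus_radius_px, shape=shape)
            keep = inside[rr, cc]
            mask[rr[keep], cc[keep]] = True
    return mask
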