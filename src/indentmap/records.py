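"""Domain types for one indentation measurement.

All in-memory quantities are strict SI (m, N, Pa, s).  File I/O (see
:mod:`indentmap.io`) converts to the field-conventional um / nN with
unit-suffixed column headers; keeping one canonical unit system internally
avoids factor-of-1e6 mistakes when mixing contact-radius and oscillation
scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ProbeSpec", "ProtocolSpec", "IndentationRecord"]


@dataclass(frozen=True)
class ProbeSpec:
    """Ferrule-top probe: cantilever spring constant and spherical tip.

    Typical instruments use 0.2-0.5 N/m cantilevers with 60-105 um bead
    radius; Poisson's ratio of the sample is carried here because it enters
    every contact formula (0.5 = incompressible, the standard assumption
    for brain tissue).
    """

    stiffness: float = 0.3        # N/m
    tip_radius: float = 60e-6     # m
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("cantilever stiffness must be positive")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass(frozen=True)
class ProtocolSpec:
    """Depth-controlled indentation profile.

    Two kinds are supported:

    ``oscillatory_ramp`` (OR)
        Small oscillations (default 0.2 um at 5.62 Hz) superimposed on a
        loading ramp at constant indentation strain rate (default 0.01 /s),
        up to ``or_final_strain``.
    ``frequency_sweep`` (FS)
        Load to ``fs_load_depth`` at ``fs_load_speed``, hold for
        ``fs_relax_time`` of stress relaxation, then oscillate at each of
        ``fs_frequencies`` in turn (``fs_cycles`` cycles per frequency).

    Both start with an approach at ``approach_speed`` until the load
    crosses ``trigger_load``, after which the depth feedback engages with
    an uncontrolled 1-3 um initial penetration (settling over
    ``settle_time``) that post-processing must correct for.
    """

    kind: str = "oscillatory_ramp"
    osc_amplitude: float = 0.2e-6        # m, h0
    or_frequency: float = 5.62           # Hz
    or_strain_rate: float = 0.01         # 1/s
    or_final_strain: float = 0.10
    fs_load_depth: float = 10e-6         # m
    fs_load_speed: float = 10e-6         # m/s
    fs_relax_time: float = 30.0          # s
    fs_frequencies: tuple[float, ...] = (1.0, 1.78, 3.2, 5.62, 10.0)
    fs_cycles: int = 10
    approach_speed: float = 30e-6        # m/s
    trigger_load: float = 15e-9          # N
    settle_time: float = 0.05            # s, uncontrolled penetration after trigger
    sample_rate: float | None = None     # Hz; default >= 50x max oscillation frequency

    def __post_init__(self) -> None:
        if self.kind not in ("oscillatory_ramp", "frequency_sweep"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        for name in ("osc_amplitude", "or_frequency", "or_strain_rate", "or_final_strain",
                     "fs_load_depth", "fs_load_speed", "fs_relax_time",
                     "approach_speed", "trigger_load", "settle_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fs_cycles < 2:
            raise ValueError("fs_cycles must be at least 2 (first cycle is discarded as settling)")
        freqs = tuple(float(f) for f in self.fs_frequencies)
        if any(f <= 0 for f in freqs):
            raise ValueError("fs_frequencies must be positive")
        if list(freqs) != sorted(freqs):
            raise ValueError("fs_frequencies must be sorted ascending")
        object.__setattr__(self, "fs_frequencies", freqs)
        if self.sample_rate is not None and self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def max_frequency(self) -> float:
        if self.kind == "oscillatory_ramp":
            return self.or_frequency
        return max(self.fs_frequencies)

    @property
    def effective_sample_rate(self) -> float:
        """Acquisition rate; defaults to 50x the highest oscillation frequency."""
        if self.sample_rate is not None:
            return self.sample_rate
        return 50.0 * self.max_frequency


@dataclass
class IndentationRecord:
    """One indentation measurement: time, piezo-referenced depth, load.

    ``depth`` includes the unknown surface offset (the piezo coordinate at
    which the tip touches the sample); surface detection recovers that
    offset so downstream analysis can work with true indentation depth.
    """

    time: np.ndarray            # s
    depth: np.ndarray           # m, piezo-referenced
    load: np.ndarray            # N
    probe: ProbeSpec
    protocol: ProtocolSpec
    location: tuple[float, float] = (0.0, 0.0)   # um, slice coordinates
    slice_id: str = "slice0"
    animal_id: str = "animal0"
    record_id: str = "rec0"
    noise_seed: int | None = None
    truth: dict = field(default_factory=dict)    # simulator ground truth (tests only)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if not (self.time.shape == self.depth.shape == self.load.shape):
            raise ValueError("time, depth and load must have identical shapes")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("record must contain a 1-D time series with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def with_arrays(self, **arrays: np.ndarray) -> "IndentationRecord":
        return replace(self, **arrays)
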