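"""Model/Results surface for single-record dynamic indentation analysis.

:class:`DynamicIndentationModel` wraps one indentation record together
with the analysis configuration; :meth:`~DynamicIndentationModel.fit`
runs surface detection, baseline QC, window segmentation, per-window
cosine fits, and the amplitude/phase -> (E', E'') conversion, returning a
:class:`DynamicIndentationResults` that carries the per-window moduli
estimates, their diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import (
    BaselineCheck,
    ContactFit,
    InsufficientLoadingDataError,
    contact_radius,
    detect_surface,
    indentation_strain,
    started_in_contact,
)
from .oscillation import (
    CosineFit,
    Window,
    fit_cosine,
    moduli_from_fit,
    segment_windows,
    shear_from_storage,
    wrap_phase,
)
from .records import IndentationRecord, ProbeSpec

__all__ = ["ModuliPoint", "DynamicIndentationModel", "DynamicIndentationResults", "analyze_record"]

R2_MIN_DEFAULT = 0.7          # cosine fits at or below this are rejected
DELTA_MIN_DEFAULT = -0.1      # rad; more negative phase lags are unphysical


@dataclass
class ModuliPoint:
    """One (E', E'') estimate from a single oscillation window."""

    E_storage: float        # Pa
    E_loss: float           # Pa
    phase_lag: float        # rad, load phase minus depth phase
    frequency: float        # Hz
    strain: float
    mean_depth: float       # m, window-mean corrected indentation depth
    contact_radius: float   # m
    r2_depth: float
    r2_load: float
    qc_pass: bool
    qc_reason: str = ""
    window_index: int = 0
    protocol_kind: str = "oscillatory_ramp"
    location: tuple[float, float] = (0.0, 0.0)
    slice_id: str = ""
    record_id: str = ""

    @property
    def loss_tangent(self) -> float:
        return math.tan(self.phase_lag)

    @property
    def G_storage(self) -> float:
        """Shear storage modulus G' = E'/3 for an incompressible sample."""
        return shear_from_storage(max(self.E_storage, 0.0))


class DynamicIndentationModel:
    """Per-record analysis model.

    Parameters
    ----------
    record : IndentationRecord
    probe : ProbeSpec, optional
        Overrides the probe stored on the record.
    r2_min : float
        QC threshold: a window passes only if the cosine fits of *both*
        channels exceed this R^2.
    threshold_load : float, optional
        Upper load bound of the surface-detection Hertz fit window
        (default: the protocol trigger load).
    delta_min : float
        Phase lags below this (rad) are flagged unphysical.
    """

    def __init__(
        self,
        record: IndentationRecord,
        probe: ProbeSpec | None = None,
        r2_min: float = R2_MIN_DEFAULT,
        threshold_load: float | None = None,
        delta_min: float = DELTA_MIN_DEFAULT,
    ) -> None:
        if not 0.0 < r2_min < 1.0:
            raise ValueError("r2_min must lie in (0, 1)")
        self.record = record
        self.probe = probe or record.probe
        self.r2_min = r2_min
        self.threshold_load = threshold_load
        self.delta_min = delta_min

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, probe: ProbeSpec, protocol, **kwargs):
        """Build from a tidy frame with columns time_s, depth_um, load_nN."""
        rec = IndentationRecord(
            time=frame["time_s"].to_numpy(),
            depth=frame["depth_um"].to_numpy() * 1e-6,
            load=frame["load_nN"].to_numpy() * 1e-9,
            probe=probe,
            protocol=protocol,
            **{k: v for k, v in kwargs.items() if k in
               ("location", "slice_id", "animal_id", "record_id")},
        )
        model_kwargs = {k: v for k, v in kwargs.items() if k in ("r2_min", "threshold_load", "delta_min")}
        return cls(rec, probe=probe, **model_kwargs)

    def fit(self) -> "DynamicIndentationResults":
        rec = self.record
        baseline = started_in_contact(rec)
        try:
            contact = detect_surface(rec, threshold_load=self.threshold_load)
        except InsufficientLoadingDataError:
            if not baseline.in_contact:
                raise
            # no usable free-approach data: the record is rejected anyway,
            # but we still emit flagged points so maps show the gap
            contact = ContactFit(
                surface_offset=0.0,
                hertz_modulus=float("nan"),
                fit_r2=0.0,
                fit_range=(0, 0),
                corrected_depth=np.clip(rec.depth, 0.0, None),
                converged=False,
            )
        windows = segment_windows(rec)

        record_reason = ""
        if baseline.in_contact:
            record_reason = "started_in_contact"
        elif not contact.converged:
            record_reason = "contact_fit_failed"

        points: list[ModuliPoint] = []
        t = rec.time
        h_corr = contact.corrected_depth
        for win in windows:
            sel = (t >= win.start - 1e-12) & (t < win.end - 1e-12)
            if np.count_nonzero(sel) < 8:
                continue
            detrend = win.label == "or"
            try:
                fit_h = fit_cosine(t[sel], rec.depth[sel], win.frequency, detrend=detrend)
                fit_f = fit_cosine(t[sel], rec.load[sel], win.frequency, detrend=detrend)
            except ValueError:
                continue
            h_bar = float(np.mean(h_corr[sel]))
            a = contact_radius(max(h_bar, 0.0), self.probe.tip_radius)
            delta = wrap_phase(fit_f.phase - fit_h.phase)
            if a > 0 and fit_h.amplitude > 0:
                e1, e2 = moduli_from_fit(
                    fit_f.amplitude, fit_h.amplitude, delta, a, self.probe.poisson_ratio
                )
            else:
                e1, e2 = float("nan"), float("nan")

            reason = record_reason
            if not reason:
                if fit_h.r2 <= self.r2_min:
                    reason = "r2_depth"
                elif fit_f.r2 <= self.r2_min:
                    reason = "r2_load"
                elif delta < self.delta_min:
                    reason = "unphysical_phase"
                elif not (e1 > 0):
                    reason = "nonpositive_storage"
            points.append(
                ModuliPoint(
                    E_storage=e1,
                    E_loss=e2,
                    phase_lag=delta,
                    frequency=win.frequency,
                    strain=indentation_strain(max(h_bar, 0.0), self.probe.tip_radius),
                    mean_depth=h_bar,
                    contact_radius=a,
                    r2_depth=fit_h.r2,
                    r2_load=fit_f.r2,
                    qc_pass=reason == "",
                    qc_reason=reason,
                    window_index=win.index,
                    protocol_kind=rec.protocol.kind,
                    location=rec.location,
                    slice_id=rec.slice_id,
                    record_id=rec.record_id,
                )
            )
        return DynamicIndentationResults(self, contact, baseline, points)


@dataclass
class DynamicIndentationResults:
    """Fit results for one record: contact fit, QC, and per-window moduli."""

    model: DynamicIndentationModel
    contact: ContactFit
    baseline: BaselineCheck
    points: list[ModuliPoint]

    @property
    def n_windows(self) -> int:
        return len(self.points)

    @property
    def n_passed(self) -> int:
        return sum(p.qc_pass for p in self.points)

    @property
    def n_rejected(self) -> int:
        return self.n_windows - self.n_passed

    def frame(self) -> pd.DataFrame:
        """Tidy table, one row per moduli point (um / nN / Pa units)."""
        rows = []
        for p in self.points:
            rows.append(
                {
                    "record_id": p.record_id,
                    "slice_id": p.slice_id,
                    "x_um": p.location[0],
                    "y_um": p.location[1],
                    "protocol": p.protocol_kind,
                    "window": p.window_index,
                    "freq_hz": p.frequency,
                    "strain": p.strain,
                    "mean_depth_um": p.mean_depth * 1e6,
                    "contact_radius_um": p.contact_radius * 1e6,
                    "E_storage_Pa": p.E_storage,
                    "E_loss_Pa": p.E_loss,
                    "delta_rad": p.phase_lag,
                    "r2_depth": p.r2_depth,
                    "r2_load": p.r2_load,
                    "qc_pass": p.qc_pass,
                    "qc_reason": p.qc_reason,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        rec = self.model.record
        lines = [
            "Dynamic indentation fit",
            "=" * 60,
            f"record            {rec.record_id}  ({rec.protocol.kind})",
            f"location          ({rec.location[0]:.0f}, {rec.location[1]:.0f}) um, slice {rec.slice_id}",
            f"surface offset    {self.contact.surface_offset * 1e6:.3f} um  "
            f"(Hertz fit R2 = {self.contact.fit_r2:.4f})",
            f"apparent modulus  {self.contact.hertz_modulus:.1f} Pa (quasi-static Hertz)",
            f"started in contact: {self.baseline.in_contact}  (|z| = {self.baseline.zscore:.2f})",
            f"windows           {self.n_windows} total, {self.n_passed} passed QC, "
            f"{self.n_rejected} rejected",
            "-" * 60,
            "win   f_Hz  strain     E'_Pa     E\"_Pa   delta   R2_h   R2_F   QC",
        ]
        for p in self.points:
            lines.append(
                f"{p.window_index:>3} {p.frequency:>6.2f} {p.strain:>7.4f} "
                f"{p.E_storage:>9.1f} {p.E_loss:>9.1f} {p.phase_lag:>7.4f} "
                f"{p.r2_depth:>6.3f} {p.r2_load:>6.3f} {'ok' if p.qc_pass else p.qc_reason:>4}"
            )
        return "\n".join(lines)


def analyze_record(
    record: IndentationRecord,
    probe: ProbeSpec | None = None,
    r2_min: float = R2_MIN_DEFAULT,
    threshold_load: float | None = None,
) -> list[ModuliPoint]:
    """Functional entry point: fit one record and return its moduli points."""
    return DynamicIndentationModel(
        record, probe=probe, r2_min=r2_min, threshold_load=threshold_load
    ).fit().points
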