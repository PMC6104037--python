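"""End-to-end orchestration: simulate -> analyze -> aggregate -> map -> stats.

A run is driven by one configuration mapping (YAML/JSON on disk, plain
dict in memory) and a master seed; everything derived from them is
deterministic, and the run manifest lists every artifact with a content
hash plus the QC outcome of every record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as imio
from .contact import InsufficientLoadingDataError
from .model import DynamicIndentationModel
from .records import ProbeSpec, ProtocolSpec
from .regions import RegionGeometry, reconstruct_map, region_summaries, slice_region_stats
from .simulate import GridSpec, simulate_grid
from .stats import region_reports

__all__ = ["RunConfig", "run_pipeline", "default_demo_config"]

log = logging.getLogger("indentmap")


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (lengths in um at this boundary)."""

    output_dir: str = "indentmap_run"
    seed: int = 0
    phantom: dict = dataclasses.field(default_factory=dict)
    probe: dict = dataclasses.field(default_factory=dict)
    protocols: tuple[str, ...] = ("oscillatory_ramp", "frequency_sweep")
    protocol_overrides: dict = dataclasses.field(default_factory=dict)
    grid: dict = dataclasses.field(default_factory=dict)
    n_slices: int = 1
    noise_sigma_nN: float = 0.5
    drift_nN_per_s: float = 0.0
    r2_min: float = 0.7
    strain_center: float = 0.073
    strain_halfwidth: float = 0.005
    comparison_frequency: float = 5.62
    alpha: float = 0.05
    weighting: str = "points"
    map_resolution_um: float = 10.0
    write_records: bool = False
    records_dir: str | None = None     # analyze existing records instead of simulating

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_min < 1.0:
            raise ValueError("r2_min must lie in (0, 1)")
        if not 0.0 < self.strain_center < 0.08:
            raise ValueError("strain bin center must lie in the small-strain range (0, 0.08)")
        if self.strain_center + self.strain_halfwidth >= 0.08 + 1e-12:
            raise ValueError("strain bin must stay below the 8% small-strain limit")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out = cls(**cfg)
        out.protocols = tuple(out.protocols)
        return out


def _probe_from_cfg(cfg: dict) -> ProbeSpec:
    return ProbeSpec(
        stiffness=float(cfg.get("stiffness_N_per_m", 0.3)),
        tip_radius=float(cfg.get("tip_radius_um", 60.0)) * 1e-6,
        poisson_ratio=float(cfg.get("poisson_ratio", 0.5)),
    )


def _protocol(kind: str, overrides: dict) -> ProtocolSpec:
    return ProtocolSpec(kind=kind, **overrides.get(kind, {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_demo_config() -> dict:
    """Two-region demo phantom: a soft dense layer in a stiffer background."""
    return {
        "output_dir": "indentmap_demo",
        "seed": 1,
        "phantom": {
            "background": {"kind": "kelvin_voigt", "E0": 1800.0, "eta": 20.0},
            "surface_offset_um": 20.0,
            "regions": [
                {
                    "label": "GCL",
                    "polygon": [[0, 0], [175, 0], [175, 400], [0, 400]],
                    "rheology": {"kind": "kelvin_voigt", "E0": 900.0, "eta": 15.0},
                },
                {
                    "label": "ML",
                    "polygon": [[175, 0], [400, 0], [400, 400], [175, 400]],
                    "rheology": {"kind": "kelvin_voigt", "E0": 1800.0, "eta": 20.0},
                },
            ],
        },
        "grid": {"origin": [25.0, 25.0], "spacing": 50.0, "nx": 7, "ny": 3},
        "protocols": ["oscillatory_ramp"],
        "n_slices": 2,
        "noise_sigma_nN": 0.5,
    }


def run_pipeline(config: dict | RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full chain and return the run manifest.

    The manifest records configuration, per-record QC status (passed /
    rejected / failed), and every output artifact with its sha256.  Failed
    records (e.g. surface fit without enough loading data) are logged and
    skipped, never fatal.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(dict(config))
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    probe = _probe_from_cfg(cfg.probe)
    phantom = imio.phantom_from_dict(cfg.phantom)
    geometry = RegionGeometry([(lab, poly) for lab, poly, _ in phantom.regions])

    # ---- gather records ----------------------------------------------------
    records = []
    if cfg.records_dir:
        for path in sorted(Path(cfg.records_dir).glob("*.csv")):
            records.append(imio.read_record(path))
    else:
        grid = GridSpec(
            origin=tuple(cfg.grid.get("origin", (0.0, 0.0))),
            spacing=float(cfg.grid.get("spacing", 50.0)),
            nx=int(cfg.grid.get("nx", 3)),
            ny=int(cfg.grid.get("ny", 3)),
        )
        slice_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_slices)
        for s, child in enumerate(slice_seeds):
            for kind in cfg.protocols:
                protocol = _protocol(kind, cfg.protocol_overrides)
                recs = simulate_grid(
                    phantom, probe, protocol, grid,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    noise_sigma=cfg.noise_sigma_nN * 1e-9,
                    drift=cfg.drift_nN_per_s * 1e-9,
                    slice_id=f"slice{s}", animal_id=f"animal{s}",
                )
                for r in recs:
                    r.record_id = f"{r.record_id}_{'or' if kind == 'oscillatory_ramp' else 'fs'}"
                records.extend(recs)
        if cfg.write_records:
            rec_dir = out / "records"
            for r in records:
                imio.write_record(r, rec_dir)

    # ---- per-record analysis ----------------------------------------------
    frames, contact_rows, statuses = [], [], {}
    for rec in records:
        try:
            res = DynamicIndentationModel(rec, probe=rec.probe, r2_min=cfg.r2_min).fit()
        except (InsufficientLoadingDataError, ValueError) as exc:
            log.warning("record %s failed: %s", rec.record_id, exc)
            statuses[rec.record_id] = {"status": "failed", "reason": str(exc)}
            continue
        frames.append(res.frame())
        contact_rows.append(
            {
                "record_id": rec.record_id,
                "offset_um": res.contact.surface_offset * 1e6,
                "hertz_E_Pa": res.contact.hertz_modulus,
                "r2": res.contact.fit_r2,
                "started_in_contact": res.baseline.in_contact,
                "converged": res.contact.converged,
            }
        )
        if res.baseline.in_contact or not res.contact.converged:
            status = "rejected"
            reason = "started_in_contact" if res.baseline.in_contact else "contact_fit_failed"
        elif res.n_passed == 0:
            status, reason = "rejected", "no_windows_passed_qc"
        else:
            status, reason = "passed", ""
        statuses[rec.record_id] = {
            "status": status,
            "reason": reason,
            "windows_total": res.n_windows,
            "windows_passed": res.n_passed,
            "windows_rejected": res.n_rejected,
        }

    artifacts: dict[str, str] = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.9g")
        artifacts[name] = _sha256(path)

    moduli = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(moduli):
        from .regions import assign_region

        moduli["region"] = [
            assign_region((x, y), geometry) for x, y in zip(moduli["x_um"], moduli["y_um"])
        ]
    save_csv(moduli, "moduli.csv")
    save_csv(pd.DataFrame(contact_rows), "contact.csv")

    # ---- aggregation, maps, statistics -------------------------------------
    stats_df = (
        slice_region_stats(
            moduli,
            geometry,
            strain_center=cfg.strain_center,
            strain_halfwidth=cfg.strain_halfwidth,
            frequency=cfg.comparison_frequency,
        )
        if len(moduli)
        else pd.DataFrame()
    )
    save_csv(stats_df, "slice_region_stats.csv")
    summaries = region_summaries(stats_df, weighting=cfg.weighting) if len(stats_df) else pd.DataFrame()
    save_csv(summaries, "region_summaries.csv")

    if len(summaries):
        from .plotting import plot_modulus_raster

        for kind in sorted(summaries["protocol"].unique()):
            raster, extent = reconstruct_map(
                geometry, summaries, protocol=kind, resolution=cfg.map_resolution_um
            )
            tag = "or" if kind == "oscillatory_ramp" else "fs"
            grid_path = out / f"map_{tag}.txt"
            np.savetxt(grid_path, raster, fmt="%.6g", header=f"extent_um {extent}")
            artifacts[grid_path.name] = _sha256(grid_path)
            ax = plot_modulus_raster(raster, extent, title=f"E' weighted means ({kind})")
            fig_path = out / f"map_{tag}.png"
            ax.figure.savefig(fig_path, dpi=120)
            artifacts[fig_path.name] = _sha256(fig_path)

    reports = region_reports(moduli, alpha=cfg.alpha) if len(moduli) else []
    stat_path = out / "stat_reports.json"
    stat_path.write_text(json.dumps([r.to_dict() for r in reports], indent=2))
    artifacts[stat_path.name] = _sha256(stat_path)
    (out / "stat_reports.txt").write_text("\n\n".join(r.summary() for r in reports))

    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_records": len(records),
        "records": statuses,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
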