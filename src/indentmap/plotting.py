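"""Map rendering: regional rasters and per-point modulus scatter maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_modulus_raster", "plot_point_map"]


def plot_modulus_raster(raster, extent, title="Storage modulus E' (Pa)", ax=None):
    """Render a reconstructed modulus raster; NaN (unmeasured) shows gray."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.6")
    xmin, ymin, xmax, ymax = extent
    im = ax.imshow(
        raster,
        origin="upper",
        extent=(xmin, xmax, ymax, ymin),   # image convention: y down
        cmap=cmap,
        interpolation="nearest",
    )
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label="Pa")
    return ax


def plot_point_map(moduli: pd.DataFrame, value="E_storage_Pa", ax=None):
    """Scatter of grid points colored by modulus; QC failures in gray."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    passed = moduli[moduli["qc_pass"].astype(bool)]
    failed = moduli[~moduli["qc_pass"].astype(bool)]
    if len(failed):
        ax.scatter(failed["x_um"], failed["y_um"], c="0.6", marker="s", s=40, label="failed QC")
    sc = ax.scatter(
        passed["x_um"], passed["y_um"], c=passed[value], cmap="viridis", marker="s", s=40
    )
    ax.invert_yaxis()
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    plt.colorbar(sc, ax=ax, label=f"{value}")
    if len(failed):
        ax.legend(loc="best", fontsize=8)
    return ax
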