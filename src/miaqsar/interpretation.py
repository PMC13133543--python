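"""Folding model vectors back into image space: VIP and coefficient maps.

These are the study's interpretation artifacts — heat maps showing which
image regions (hence which substituents) the latent-variable model leans on
(VIP) and in which direction they push the predicted activity (regression
coefficients b).  Raw values are the artifact of record; the rendered PNG is
presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mia_encoder import Canvas

__all__ = ["MIAMap", "fold_map", "export_heatmap"]


@dataclass(frozen=True)
class MIAMap:
    """A canvas-shaped map of a model vector; dropped columns are exactly 0."""

    grid: np.ndarray  # (height, width)
    kind: str  # "vip" or "coefficient"
    vmin: float
    vmax: float


def fold_map(
    vector: np.ndarray,
    column_mask: np.ndarray,
    canvas: Canvas,
    kind: str | None = None,
) -> MIAMap:
    """Place a retained-column vector back at its pixel positions.

    ``vector`` has one entry per retained column; all other pixels are 0.
    ``kind`` defaults to "coefficient" when the vector is signed, else "vip".
    """
    vector = np.asarray(vector, dtype=float).ravel()
    column_mask = np.asarray(column_mask, dtype=bool).ravel()
    if column_mask.size != canvas.n_pixels:
        raise ValueError("column mask does not match the canvas")
    if vector.size != int(column_mask.sum()):
        raise ValueError(
            f"vector length {vector.size} != retained columns {int(column_mask.sum())}"
        )
    full = np.zeros(canvas.n_pixels)
    full[column_mask] = vector
    grid = full.reshape(canvas.height, canvas.width)
    if kind is None:
        kind = "coefficient" if vector.size and vector.min() < 0 else "vip"
    return MIAMap(grid, kind, float(grid.min()), float(grid.max()))


def export_heatmap(mia_map: MIAMap, path: str | Path) -> tuple[Path, Path]:
    """Write the map as a PNG plus a sidecar CSV of the raw grid.

    Coefficient maps use a diverging scale centered at 0; VIP maps a
    sequential scale from 0.  Returns (png_path, csv_path).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    png = path if path.suffix == ".png" else path.with_suffix(".png")
    csv = png.with_suffix(".csv")

    fig, ax = plt.subplots(figsize=(5, 5.8))
    if mia_map.kind == "coefficient":
        bound = max(abs(mia_map.vmin), abs(mia_map.vmax)) or 1.0
        im = ax.imshow(mia_map.grid, cmap="RdBu_r", vmin=-bound, vmax=bound)
    else:
        im = ax.imshow(mia_map.grid, cmap="viridis", vmin=0.0)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(mia_map.kind)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)

    np.savetxt(csv, mia_map.grid, delimiter=",", fmt="%.10g")
    return png, csv
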