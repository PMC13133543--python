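"""Property-coded rasterization of aligned 2D structures and matrix unfolding.

Each compound is painted on a fixed canvas as filled disks (one per atom,
radius proportional to the element's van der Waals radius) whose pixel value
is an atomic property — Pauling electronegativity or the van der Waals
radius itself.  Background pixels are exactly 0, which is safe because every
coded property is >= 0.7.  Row-major unfolding of the n aligned images gives
the descriptor matrix X (n x width*height); columns that are constant across
the series (background and shared scaffold pixels) carry no information and
are recorded in a column mask.

All pixel geometry is integer and the draw order is fixed (decreasing disk
radius, so small atoms such as H and F stay visible on top), making the
matrix byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_model import (
    ELEMENTS,
    Molecule2D,
    TemplateLibrary,
    CompoundSpec,
    assemble_molecule,
    element_property,
)

__all__ = [
    "Canvas",
    "PropertyImage",
    "DescriptorMatrix",
    "default_canvas",
    "rasterize",
    "unfold",
    "fold",
    "build_descriptor_matrix",
    "image_to_png",
]

#: disk radius as a fraction of the full van der Waals radius
#: (ball-and-stick convention: balls well below space-filling size)
DEFAULT_BALL_FRACTION = 0.25


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class Canvas:
    """Raster frame: size in pixels, scale (px per angstrom) and the pixel
    position of the template-frame origin (column, row)."""

    width: int = 300
    height: int = 348
    scale: float = 16.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """Map template coordinates (angstrom, y up) to (row, col)."""
        col = int(_round_half_up(self.origin[0] + x * self.scale))
        row = int(_round_half_up(self.origin[1] - y * self.scale))
        return row, col


def _library_extent(lib: TemplateLibrary, ball_fraction: float):
    """Union bounding box (angstrom) over every compound the library can
    produce, each atom padded by its disk radius."""
    pts: list[tuple[float, float, float]] = []  # (x, y, pad)

    def pad(el: str) -> float:
        return ball_fraction * element_property(el, "vdw_radius")

    for el, x, y in lib.scaffold_atoms:
        pts.append((x, y, pad(el)))
    from .chem_model import _rotate

    for name in ("X", "Y"):
        slot = lib.slots[name]
        px, py = slot["position"]
        for code in slot["allowed"]:
            el = "C" if code in ("CH", "C") else code
            pts.append((px, py, pad(el)))
        hx, hy = slot["h_direction"]
        pts.append((px + 1.09 * hx, py + 1.09 * hy, pad("H")))
    for name in ("R1", "R2_3", "R2_5"):
        slot = lib.slots[name]
        if "attach_scaffold" in slot:
            ax, ay = lib.scaffold_atoms[slot["attach_scaffold"]][1:3]
        else:
            ax, ay = lib.slots[slot["attach_slot"]]["position"]
        for code in slot["allowed"]:
            for el, x, y in lib.substituents[code]["atoms"]:
                rx, ry = _rotate(slot["direction"], (x, y))
                pts.append((ax + rx, ay + ry, pad(el)))
    xs_lo = min(x - p for x, y, p in pts)
    xs_hi = max(x + p for x, y, p in pts)
    ys_lo = min(y - p for x, y, p in pts)
    ys_hi = max(y + p for x, y, p in pts)
    return xs_lo, xs_hi, ys_lo, ys_hi


def default_canvas(
    lib: TemplateLibrary,
    width: int = 300,
    height: int = 348,
    scale: float | None = None,
    ball_fraction: float = DEFAULT_BALL_FRACTION,
    margin: float = 0.9,
) -> Canvas:
    """Canvas sized to the study default (300 x 348) with the whole series
    centered; if ``scale`` is not given, the largest half-pixel multiple
    keeping every possible compound within ``margin`` of both dimensions is
    used (deterministic in the library alone)."""
    x_lo, x_hi, y_lo, y_hi = _library_extent(lib, ball_fraction)
    if scale is None:
        sx = margin * (width - 1) / (x_hi - x_lo)
        sy = margin * (height - 1) / (y_hi - y_lo)
        scale = float(np.floor(2 * min(sx, sy)) / 2.0)
        if scale <= 0:
            raise ValueError("canvas too small for the template library")
    ox = (width - 1) / 2.0 - scale * (x_lo + x_hi) / 2.0
    oy = (height - 1) / 2.0 + scale * (y_lo + y_hi) / 2.0
    return Canvas(
        width=width, height=height, scale=scale,
        origin=(float(round(ox, 3)), float(round(oy, 3))),
    )


@dataclass(frozen=True)
class PropertyImage:
    """A property-coded raster: background 0, foreground = element property."""

    values: np.ndarray  # (height, width) float64
    property_kind: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rasterize(
    mol: Molecule2D,
    property_kind: str,
    canvas: Canvas,
    ball_fraction: float = DEFAULT_BALL_FRACTION,
    paint_bonds: bool = False,
) -> PropertyImage:
    """Paint ``mol`` as property-valued disks on the canvas.

    Disks are painted in order of decreasing pixel radius (ties by atom
    index), so smaller atoms remain visible on top of larger neighbours.
    An atom whose disk would leave the canvas raises — never silent clipping.
    With ``paint_bonds`` set, 1-px stick lines valued at carbon's property are
    painted underneath the disks.
    """
    img = np.zeros((canvas.height, canvas.width), dtype=np.float64)
    n = len(mol.atoms)
    if n == 0:
        return PropertyImage(img, property_kind)

    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    radii = np.empty(n, dtype=int)
    values = np.empty(n, dtype=float)
    for i, (el, x, y) in enumerate(mol.atoms):
        rows[i], cols[i] = canvas.to_pixel(x, y)
        radii[i] = int(
            _round_half_up(ball_fraction * element_property(el, "vdw_radius") * canvas.scale)
        )
        values[i] = element_property(el, property_kind)
        if (
            rows[i] - radii[i] < 0
            or rows[i] + radii[i] >= canvas.height
            or cols[i] - radii[i] < 0
            or cols[i] + radii[i] >= canvas.width
        ):
            raise ValueError(
                f"atom {i} ({el}) at ({x:.2f}, {y:.2f}) angstrom -> pixel "
                f"({rows[i]}, {cols[i]}) radius {radii[i]} px falls outside "
                f"the {canvas.width}x{canvas.height} canvas"
            )

    if paint_bonds:
        c_val = element_property("C", property_kind)
        for i, j, _ in mol.bonds:
            npts = max(abs(rows[j] - rows[i]), abs(cols[j] - cols[i])) + 1
            rr = _round_half_up(np.linspace(rows[i], rows[j], npts))
            cc = _round_half_up(np.linspace(cols[i], cols[j], npts))
            img[rr, cc] = c_val

    order = np.argsort(-radii, kind="stable")
    for i in order:
        r = radii[i]
        dr, dc = np.ogrid[-r : r + 1, -r : r + 1]
        disk = dr * dr + dc * dc <= r * r
        patch = img[rows[i] - r : rows[i] + r + 1, cols[i] - r : cols[i] + r + 1]
        patch[disk] = values[i]
    return PropertyImage(img, property_kind)


def unfold(img: PropertyImage) -> np.ndarray:
    """Row-major flattening of the image into a 1 x (width*height) vector."""
    return img.values.reshape(-1).copy()


def fold(vector: np.ndarray, canvas: Canvas, property_kind: str = "") -> PropertyImage:
    """Inverse of :func:`unfold` for a full-length vector."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != canvas.n_pixels:
        raise ValueError(
            f"vector length {vector.size} != canvas pixels {canvas.n_pixels}"
        )
    return PropertyImage(vector.reshape(canvas.height, canvas.width).copy(), property_kind)


@dataclass
class DescriptorMatrix:
    """Unfolded descriptor block: X is n_compounds x (width*height), rows in
    input order; ``column_mask`` marks columns retained for modeling (those
    that vary across the series)."""

    X: np.ndarray
    ids: list[str]
    column_mask: np.ndarray
    canvas: Canvas
    property_kind: str

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def p_total(self) -> int:
        return self.X.shape[1]

    @property
    def p_retained(self) -> int:
        return int(self.column_mask.sum())

    def masked(self) -> np.ndarray:
        return self.X[:, self.column_mask]


def build_descriptor_matrix(
    specs: list[CompoundSpec],
    property_kind: str,
    canvas: Canvas,
    templates: TemplateLibrary,
    ball_fraction: float = DEFAULT_BALL_FRACTION,
    paint_bonds: bool = False,
) -> DescriptorMatrix:
    """Encode a series: assemble, rasterize and unfold every compound.

    Constant columns (background and scaffold pixels identical across rows)
    are excluded from the retained-column mask.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 compounds")
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes}")
    X = np.empty((len(specs), canvas.n_pixels), dtype=np.float64)
    for k, spec in enumerate(specs):
        mol = assemble_molecule(spec, templates)
        X[k] = unfold(rasterize(mol, property_kind, canvas, ball_fraction, paint_bonds))
    variable = X.max(axis=0) != X.min(axis=0)
    return DescriptorMatrix(X, ids, variable, canvas, property_kind)


def image_to_png(img: PropertyImage, path) -> None:
    """Write an 8-bit visualization (property rescaled to [0, 255])."""
    import matplotlib.image

    v = img.values
    hi = v.max()
    scaled = (v / hi * 255).astype(np.uint8) if hi > 0 else v.astype(np.uint8)
    matplotlib.image.imsave(path, scaled, cmap="gray", vmin=0, vmax=255)
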