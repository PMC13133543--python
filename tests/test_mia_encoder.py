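"""Rasterization, unfolding and descriptor-matrix construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miaqsar.chem_model import CompoundSpec, Molecule2D, assemble_molecule
from miaqsar.mia_encoder import (
    Canvas,
    PropertyImage,
    build_descriptor_matrix,
    fold,
    rasterize,
    unfold,
)

SMALL = Canvas(width=60, height=60, scale=10.0, origin=(30.0, 30.0))


def test_empty_molecule_gives_zero_image():
    mol = Molecule2D((), (), ())
    img = rasterize(mol, "electronegativity", SMALL)
    assert img.values.shape == (60, 60)
    assert not img.values.any()


def test_single_atom_disk_value_and_pixel_count():
    mol = Molecule2D((("C", 0.0, 0.0),), (), (False,))
    img = rasterize(mol, "electronegativity", SMALL)
    fg = img.values[img.values > 0]
    assert set(np.unique(fg)) == {2.55}
    # brute-force enumeration of the discrete disk
    r = int(np.floor(0.25 * 1.70 * 10 + 0.5))
    count = sum(
        1
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    )
    assert fg.size == count
    # centered at the mapped pixel
    rows, cols = np.nonzero(img.values)
    assert rows.mean() == 30 and cols.mean() == 30


def test_smaller_atom_painted_on_top():
    # H overlapping the larger C keeps its own property value at its center
    mol = Molecule2D((("C", 0.0, 0.0), ("H", 0.15, 0.0)), (), (False, False))
    img = rasterize(mol, "electronegativity", SMALL)
    assert img.values[30, 32] == 2.20  # H center pixel ~ (30, 31.5) -> col 32


def test_atom_outside_canvas_raises():
    mol = Molecule2D((("C", 50.0, 0.0),), (), (False,))
    with pytest.raises(ValueError, match="outside"):
        rasterize(mol, "electronegativity", SMALL)


@settings(max_examples=20, database=None, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_unfold_fold_inverse(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 4, size=(12, 9))
    img = PropertyImage(values, "electronegativity")
    cv = Canvas(width=9, height=12, scale=1.0, origin=(0, 0))
    back = fold(unfold(img), cv, "electronegativity")
    assert np.array_equal(back.values, values)


def test_unfold_is_row_major():
    values = np.arange(12, dtype=float).reshape(3, 4)
    img = PropertyImage(values, "vdw_radius")
    assert np.array_equal(unfold(img), np.arange(12.0))


def test_fold_shape_mismatch():
    with pytest.raises(ValueError, match="length"):
        fold(np.zeros(10), Canvas(width=4, height=4, scale=1, origin=(0, 0)))


def test_descriptor_matrix_shapes_and_mask(series_specs, canvas, library, dm_vdw):
    assert dm_vdw.X.shape == (33, canvas.n_pixels)
    assert dm_vdw.ids == [s.id for s in series_specs]
    # background never covered by any atom is masked out
    assert dm_vdw.p_retained < canvas.n_pixels
    retained = dm_vdw.masked()
    assert (retained.max(axis=0) > retained.min(axis=0)).all()


def test_descriptor_matrix_deterministic(series_specs, canvas, library, dm_vdw):
    again = build_descriptor_matrix(series_specs[:5], "vdw_radius", canvas, library)
    assert np.array_equal(again.X, dm_vdw.X[:5])


def test_duplicate_ids_rejected(series_specs, canvas, library):
    dup = [series_specs[0], series_specs[0]]
    with pytest.raises(ValueError, match="duplicate"):
        build_descriptor_matrix(dup, "vdw_radius", canvas, library)


def test_identical_compounds_identical_rows(canvas, library):
    a = CompoundSpec(id="a", X="S", Y="CH", R1="F", R2="H")
    b = CompoundSpec(id="b", X="S", Y="CH", R1="F", R2="H")
    dm = build_descriptor_matrix([a, b], "vdw_radius", canvas, library)
    assert np.array_equal(dm.X[0], dm.X[1])
    assert dm.p_retained == 0  # nothing varies


def test_substituent_swap_changes_only_local_pixels(series_specs, canvas, library):
    """Images of R1=H vs R1=Br compounds differ only inside the union of the
    disks of the atoms that differ."""
    by_id = {s.id: s for s in series_specs}
    imgs = {}
    mols = {}
    for cid in ("1", "22"):
        mols[cid] = assemble_molecule(by_id[cid], library)
        imgs[cid] = rasterize(mols[cid], "vdw_radius", canvas).values
    diff = imgs["1"] != imgs["22"]
    common = set(mols["1"].atoms) & set(mols["22"].atoms)
    allowed = np.zeros_like(diff)
    for mol in mols.values():
        for el, x, y in set(mol.atoms) - common:
            from miaqsar.chem_model import element_property

            row, col = canvas.to_pixel(x, y)
            r = int(np.floor(0.25 * element_property(el, "vdw_radius") * canvas.scale + 0.5))
            rr, cc = np.ogrid[: canvas.height, : canvas.width]
            allowed |= (rr - row) ** 2 + (cc - col) ** 2 <= r * r
    assert not (diff & ~allowed).any()
    assert diff.any()


def test_scaffold_pixels_identical_across_series(series_specs, canvas, library):
    """Scaffold-atom disks render identically for every compound (alignment)."""
    from miaqsar.chem_model import element_property

    mols = [assemble_molecule(s, library) for s in series_specs[:6]]
    core = np.zeros((canvas.height, canvas.width), dtype=bool)
    sub = np.zeros_like(core)
    for mol in mols:
        for (el, x, y), is_core in zip(mol.atoms, mol.scaffold_mask):
            row, col = canvas.to_pixel(x, y)
            r = int(np.floor(0.25 * element_property(el, "vdw_radius") * canvas.scale + 0.5))
            rr, cc = np.ogrid[: canvas.height, : canvas.width]
            disk = (rr - row) ** 2 + (cc - col) ** 2 <= r * r
            (core if is_core else sub)[disk] = True
    interior = core & ~sub  # scaffold pixels no slot atom of these compounds shadows
    imgs = [rasterize(mol, "vdw_radius", canvas).values for mol in mols]
    for img in imgs[1:]:
        assert np.array_equal(img[interior], imgs[0][interior])


def test_bond_painting_optional(series_specs, canvas, library):
    mol = assemble_molecule(series_specs[0], library)
    plain = rasterize(mol, "electronegativity", canvas)
    sticks = rasterize(mol, "electronegativity", canvas, paint_bonds=True)
    extra = (sticks.values > 0) & (plain.values == 0)
    assert extra.any()
    assert set(np.unique(sticks.values[extra])) == {2.55}  # carbon-valued lines
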