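"""Loaders for the packaged compound tables (modeled series and proposals)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem_model import CompoundSpec

__all__ = ["load_compound_table", "load_series", "load_proposals"]

COLUMNS = ["id", "X", "Y", "R1", "R2", "ic50_mg_per_L", "pic50"]


def load_compound_table(path: str | None = None, name: str = "phenyltriazolinones.csv") -> pd.DataFrame:
    """Read a compound CSV (columns id,X,Y,R1,R2,ic50_mg_per_L,pic50)."""
    if path is None:
        with resources.files("miaqsar.data").joinpath(name).open() as fh:
            df = pd.read_csv(fh, dtype={"id": str})
    else:
        df = pd.read_csv(path, dtype={"id": str})
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    return df


def specs_from_table(df: pd.DataFrame) -> list[CompoundSpec]:
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            CompoundSpec(
                id=str(row.id),
                X=row.X,
                Y=row.Y,
                R1=row.R1,
                R2=row.R2,
                ic50_mg_per_L=None if pd.isna(row.ic50_mg_per_L) else float(row.ic50_mg_per_L),
                pic50=None if pd.isna(row.pic50) else float(row.pic50),
            )
        )
    return specs


def load_series(path: str | None = None) -> list[CompoundSpec]:
    """The 33 measured phenyltriazolinones (packaged fixture by default)."""
    return specs_from_table(load_compound_table(path))


def load_proposals(path: str | None = None) -> list[CompoundSpec]:
    """The eight proposed analogs used as prediction queries."""
    return specs_from_table(load_compound_table(path, name="proposals.csv"))
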