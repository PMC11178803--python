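"""Reaction-table CSV input/output and descriptor-table loading.

The on-disk schema is one row per reaction with one SMILES column per role
plus a numeric yield column (RFC-4180 CSV, UTF-8).  The synthetic generator
emits exactly this schema, so synthetic and real tables are interchangeable
throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import DEFAULT_ROLES, Reaction

__all__ = ["TableSchema", "read_reaction_csv", "write_reaction_csv", "read_descriptor_csv", "write_manifest"]


@dataclass(frozen=True)
class TableSchema:
    """Column mapping for a reaction table."""

    role_columns: dict = field(
        default_factory=lambda: {role: role for role in DEFAULT_ROLES}
    )
    yield_column: str = "yield"
    id_column: str | None = "id"

    @property
    def roles(self) -> tuple:
        return tuple(self.role_columns)


def read_reaction_csv(path, schema: TableSchema = TableSchema(), allow_missing_yield: bool = False):
    """Load reactions from CSV, validating schema and every SMILES.

    Rows with a missing yield are admitted only with
    ``allow_missing_yield=True`` (pure prediction inputs).  Errors name the
    offending column or 1-based data row.
    """
    df = pd.read_csv(path)
    needed = list(schema.role_columns.values()) + [schema.yield_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"schema error: columns {missing} not in {list(df.columns)}")
    has_id = schema.id_column is not None and schema.id_column in df.columns
    reactions = []
    for i, rowd in enumerate(df.to_dict(orient="records"), start=1):
        components = {}
        for role, col in schema.role_columns.items():
            smiles = str(rowd[col])
            if Chem.MolFromSmiles(smiles) is None:
                raise ValueError(f"row {i}: unparseable SMILES {smiles!r} in column {col!r}")
            components[role] = smiles
        y = rowd[schema.yield_column]
        if pd.isna(y):
            if not allow_missing_yield:
                raise ValueError(f"row {i}: missing yield")
            y = None
        else:
            y = float(y)
        rid = str(rowd[schema.id_column]) if has_id else f"row-{i}"
        reactions.append(Reaction(components=components, yield_=y, id=rid))
    return reactions


def write_reaction_csv(path, reactions, schema: TableSchema = TableSchema()) -> None:
    rows = []
    for r in reactions:
        row = {schema.id_column or "id": r.id}
        for role, col in schema.role_columns.items():
            row[col] = r.components[role]
        row[schema.yield_column] = r.yield_
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_descriptor_csv(path, id_column: str) -> dict:
    """Component-id → descriptor-vector map from a CSV descriptor table."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not in {list(df.columns)}")
    value_cols = [c for c in df.columns if c != id_column]
    table = {}
    for _, row in df.iterrows():
        vec = row[value_cols].to_numpy(dtype=np.float64)
        if not np.isfinite(vec).all():
            raise ValueError(f"non-finite descriptors for component {row[id_column]!r}")
        table[str(row[id_column])] = vec
    return table


def write_manifest(path, config: dict) -> None:
    """Drop a JSON manifest (config + seeds + package version) beside outputs."""
    from . import __version__

    manifest = {"package_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
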