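"""Delimited-text readers/writers shared by all modules.

Labeled data lives in UTF-8 comma-delimited tables with a ``smiles``
column followed by the M objective columns (and optional auxiliary
columns); candidate pools are plain SMILES line files (one string per
line, ``#`` comments and blank lines ignored).  Floats are serialized at
17 significant digits so that write→read round-trips are lossless and a
run can be replayed bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .pareto import MinMaxSpec

logger = logging.getLogger(__name__)

__all__ = [
    "read_labeled_table",
    "write_labeled_table",
    "read_smiles_pool",
    "write_smiles_pool",
]

_FLOAT_FMT = "%.17g"


def read_labeled_table(
    path,
    objective_names: list[str] | None = None,
    minmax: MinMaxSpec | None = None,
) -> pd.DataFrame:
    """Read and validate a labeled molecule table.

    Requires a ``smiles`` column with unique entries and finite objective
    values.  When ``objective_names`` is given the named columns must all
    be present; otherwise every non-smiles numeric column is treated as an
    objective.  When ``minmax`` is given, minimized objectives are negated
    on load (internal maximization orientation).
    """
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: missing required 'smiles' column")
    if objective_names is None:
        objective_names = [c for c in df.columns if c not in ("smiles", "iteration")]
    missing = [c for c in objective_names if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing objective columns {missing}")
    dup = df["smiles"][df["smiles"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate molecules: {sorted(set(dup))}")
    vals = df[objective_names].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(vals).all(axis=1))[0]
    if len(bad):
        raise ValueError(
            f"{path}: non-finite objective values at rows {[int(b) + 2 for b in bad]}"
        )
    if minmax is not None:
        df = df.copy()
        df[objective_names] = minmax.apply(vals)
    return df


def write_labeled_table(df: pd.DataFrame, path, minmax: MinMaxSpec | None = None) -> None:
    """Write a labeled table; when ``minmax`` is given, restore raw orientation."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if minmax is not None:
        df = df.copy()
        cols = [c for c in df.columns if c not in ("smiles", "iteration")]
        df[cols] = minmax.restore(df[cols].to_numpy(dtype=float))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_smiles_pool(path) -> list[str]:
    """Read a SMILES line file: canonicalized, deduplicated, invalids dropped.

    Invalid strings are dropped with a logged count; a file with zero valid
    lines is an error.
    """
    from rdkit import Chem

    seen: dict[str, None] = {}
    n_bad = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                n_bad += 1
                continue
            seen.setdefault(Chem.MolToSmiles(mol))
    if n_bad:
        logger.warning("%s: dropped %d invalid SMILES line(s)", path, n_bad)
    if not seen:
        raise ValueError(f"{path}: no valid SMILES lines")
    return list(seen)


def write_smiles_pool(smiles_list, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for s in smiles_list:
            fh.write(s + "\n")
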