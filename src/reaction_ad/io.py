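"""Reaction dataset container and delimited-text IO.

A dataset is one row per reaction: atom-mapped reaction SMILES, a
real-valued property (e.g. log k), a solvent (by name, or as 15 explicit
``solv_*`` columns), a temperature in Kelvin and an optional organic
solvent molar ratio in percent (100 for a pure solvent).
"""

from __future__ import annotations

from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import condition_vector
from .reaction_graph import CGR, Reaction, build_cgr, parse_reaction
from .solvents import SolventTable

__all__ = ["ReactionDataset", "load_dataset"]

REQUIRED_COLUMNS = ("reaction", "property", "temperature_K")


class ReactionDataset:
    """Table of reactions with lazily parsed graphs and condition vectors."""

    def __init__(self, table: pd.DataFrame, solvent_table: SolventTable | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        explicit = [c for c in table.columns if c.startswith("solv_")]
        if "solvent" not in table.columns and len(explicit) != 15:
            raise ValueError("dataset needs a 'solvent' column or 15 explicit solv_* columns")
        self.table = table.reset_index(drop=True)
        self.solvent_table = solvent_table or SolventTable.bundled()
        self._explicit_solvent_cols = explicit if "solvent" not in table.columns else []

    def __len__(self) -> int:
        return len(self.table)

    @property
    def y(self) -> np.ndarray:
        return self.table["property"].to_numpy(dtype=float)

    @cached_property
    def reactions(self) -> list[Reaction]:
        return [parse_reaction(s) for s in self.table["reaction"]]

    @cached_property
    def cgrs(self) -> list[CGR]:
        return [build_cgr(r) for r in self.reactions]

    @cached_property
    def conditions(self) -> list[np.ndarray]:
        out = []
        for _, row in self.table.iterrows():
            ratio = float(row.get("molar_ratio", 100.0)) if "molar_ratio" in self.table.columns else 100.0
            if self._explicit_solvent_cols:
                solvent = [float(row[c]) for c in self._explicit_solvent_cols]
            else:
                solvent = row["solvent"]
            out.append(
                condition_vector(solvent, float(row["temperature_K"]), ratio,
                                 solvent_table=self.solvent_table)
            )
        return out

    def subset(self, indices: np.ndarray) -> "ReactionDataset":
        sub = ReactionDataset(self.table.iloc[indices].reset_index(drop=True),
                              self.solvent_table)
        # reuse parsed graphs: parsing dominates repeated CV splitting cost
        idx = list(np.asarray(indices))
        sub.__dict__["reactions"] = [self.reactions[i] for i in idx]
        sub.__dict__["cgrs"] = [self.cgrs[i] for i in idx]
        sub.__dict__["conditions"] = [self.conditions[i] for i in idx]
        return sub

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_dataset(path: str | Path, solvent_table: SolventTable | None = None,
                 sep: str | None = None) -> ReactionDataset:
    """Load a CSV/TSV dataset (delimiter sniffed from the extension by default)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return ReactionDataset(pd.read_csv(path, sep=sep), solvent_table)
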