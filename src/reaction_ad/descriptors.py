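"""Fragment and condition descriptors for Condensed Graphs of Reaction.

Structural descriptors are counts of linear atom-bond paths of 2-4 atoms
enumerated on the CGR (ISIDA-style sequence fragments).  Fragment atom
tokens carry the chemical element; bond tokens carry the bond order before
and after the transformation, so fragments crossing dynamic bonds encode
the transformation while a CGR without dynamic bonds (e.g. a
zwitterion-neutral tautomerization) produces only ordinary molecular
fragments.  Condition descriptors are the 15 solvent values, the inverse
absolute temperature 1/T and the organic-solvent molar ratio in percent.
Descriptor matrices are standardized to zero mean and unit variance on the
training block (population standard deviation; constant columns map to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reaction_graph import BOND_TOKENS, CGR
from .solvents import SOLVENT_DESCRIPTOR_NAMES, SolventTable

__all__ = [
    "CONDITION_NAMES",
    "enumerate_fragments",
    "condition_vector",
    "DescriptorMatrix",
    "ReactionFeaturizer",
]

#: fixed order of the 17 condition descriptor columns
CONDITION_NAMES = ["solv_" + n for n in SOLVENT_DESCRIPTOR_NAMES] + ["inv_T", "molar_ratio"]


def _path_string(cgr: CGR, path: tuple[int, ...]) -> str:
    parts = [cgr.atoms[path[0]].element]
    for a, b in zip(path, path[1:]):
        bond = cgr.bonds[(min(a, b), max(a, b))]
        parts.append(f"[{BOND_TOKENS[bond.order_before]}>>{BOND_TOKENS[bond.order_after]}]")
        parts.append(cgr.atoms[b].element)
    return "".join(parts)


def enumerate_fragments(cgr: CGR, min_atoms: int = 2, max_atoms: int = 4) -> dict[str, int]:
    """Count simple linear paths of ``min_atoms``..``max_atoms`` atoms on a CGR.

    Paths are unordered (a path and its reverse are one occurrence) and
    keyed by the lexicographic minimum of the forward and reversed
    serializations.
    """
    if not (max_atoms >= min_atoms >= 2):
        raise ValueError("need max_atoms >= min_atoms >= 2")
    adj = cgr.adjacency()
    directed: dict[str, int] = {}

    def extend(path: list[int]) -> None:
        if len(path) >= min_atoms:
            fwd = _path_string(cgr, tuple(path))
            rev = _path_string(cgr, tuple(reversed(path)))
            key = min(fwd, rev)
            directed[key] = directed.get(key, 0) + 1
        if len(path) == max_atoms:
            return
        for nb in adj[path[-1]]:
            if nb not in path:
                path.append(nb)
                extend(path)
                path.pop()

    for start in cgr.atoms:
        extend([start])
    # every unordered path was found twice, once from each end
    return {k: v // 2 for k, v in directed.items()}


def condition_vector(
    solvent: str | list[float],
    temperature_K: float,
    molar_ratio_pct: float = 100.0,
    solvent_table: SolventTable | None = None,
) -> np.ndarray:
    """17 condition descriptors: 15 solvent values, 1/T and molar ratio."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    if isinstance(solvent, str):
        table = solvent_table or SolventTable.bundled()
        values = table.lookup(solvent)
    else:
        values = list(solvent)
        if len(values) != 15:
            raise ValueError("explicit solvent descriptors must have 15 values")
    return np.asarray(values + [1.0 / temperature_K, float(molar_ratio_pct)], dtype=float)


@dataclass
class DescriptorMatrix:
    """Descriptor block with column metadata and standardization parameters."""

    row_ids: list
    columns: list[str]
    values: np.ndarray
    n_fragment_columns: int
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def standardized(self) -> np.ndarray:
        if self.means is None:
            raise RuntimeError("standardization parameters not fitted")
        return apply_standardization(self.values, self.means, self.sds)


def fit_standardization(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and population standard deviation of a training block."""
    means = block.mean(axis=0)
    sds = block.std(axis=0)  # population (1/N) convention
    return means, sds


def apply_standardization(block: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    out = block - means
    nonzero = sds > 0
    out[:, nonzero] = out[:, nonzero] / sds[nonzero]
    out[:, ~nonzero] = 0.0
    return out


class ReactionFeaturizer:
    """Fits a fragment vocabulary plus condition block on a training set.

    The fragment columns are the union of the fragments seen in the fitted
    CGRs, ordered lexicographically, followed by the 17 condition columns
    in fixed order.  ``transform`` restricts test reactions to the fitted
    columns and reports, per row, the set of fragments present in the test
    CGR but absent from the vocabulary (consumed by Fragment Control).
    """

    def __init__(self, min_atoms: int = 2, max_atoms: int = 4,
                 solvent_table: SolventTable | None = None):
        self.min_atoms = min_atoms
        self.max_atoms = max_atoms
        self.solvent_table = solvent_table or SolventTable.bundled()
        self.columns_: list[str] | None = None
        self.fragment_columns_: list[str] | None = None
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    # -- internal ----------------------------------------------------------
    def _row(self, counts: dict[str, int], conditions: np.ndarray,
             col_index: dict[str, int], n_cols: int) -> np.ndarray:
        row = np.zeros(n_cols)
        for frag, c in counts.items():
            idx = col_index.get(frag)
            if idx is not None:
                row[idx] = c
        row[-len(CONDITION_NAMES):] = conditions
        return row

    def fit(self, cgrs: list[CGR], conditions: list[np.ndarray],
            row_ids: list | None = None) -> DescriptorMatrix:
        if not cgrs:
            raise ValueError("empty training set")
        counts_per_row = [enumerate_fragments(g, self.min_atoms, self.max_atoms) for g in cgrs]
        vocab = sorted(set().union(*[set(c) for c in counts_per_row]))
        self.fragment_columns_ = vocab
        self.columns_ = vocab + CONDITION_NAMES
        col_index = {f: i for i, f in enumerate(vocab)}
        n_cols = len(self.columns_)
        block = np.vstack([
            self._row(c, cond, col_index, n_cols)
            for c, cond in zip(counts_per_row, conditions)
        ])
        self.means_, self.sds_ = fit_standardization(block)
        return DescriptorMatrix(
            row_ids=list(row_ids) if row_ids is not None else list(range(len(cgrs))),
            columns=list(self.columns_),
            values=block,
            n_fragment_columns=len(vocab),
            means=self.means_,
            sds=self.sds_,
        )

    def transform(self, cgrs: list[CGR], conditions: list[np.ndarray]
                  ) -> tuple[np.ndarray, list[frozenset[str]]]:
        if self.columns_ is None:
            raise RuntimeError("featurizer not fitted")
        col_index = {f: i for i, f in enumerate(self.fragment_columns_)}
        n_cols = len(self.columns_)
        rows, unseen = [], []
        for g, cond in zip(cgrs, conditions):
            counts = enumerate_fragments(g, self.min_atoms, self.max_atoms)
            rows.append(self._row(counts, cond, col_index, n_cols))
            unseen.append(frozenset(f for f in counts if f not in col_index))
        block = np.vstack(rows) if rows else np.zeros((0, n_cols))
        return block, unseen

    def transform_standardized(self, cgrs: list[CGR], conditions: list[np.ndarray]
                               ) -> tuple[np.ndarray, list[frozenset[str]]]:
        block, unseen = self.transform(cgrs, conditions)
        return apply_standardization(block, self.means_, self.sds_), unseen
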