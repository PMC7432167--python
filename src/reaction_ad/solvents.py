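"""Solvent descriptor table.

Each solvent is described by 15 numbers reflecting polarity, polarizability,
hydrogen-bond acidity and basicity: the Catalan SPP, SA and SB scales, the
Kamlet-Taft alpha, beta and pi* parameters, four functions of the static
dielectric constant, three functions of the refractive index, and two
user-definable reserved slots (zero by default; the published descriptor
scheme counts 15 slots while naming 13, so the last two are left to the
user).  The bundled table stores the raw physical constants for common
solvents and expands them to the 15-vector; user tables supply the 15
values explicitly.
"""

from __future__ import annotations

import csv
from pathlib import Path

__all__ = ["SOLVENT_DESCRIPTOR_NAMES", "SolventTable", "SolventLookupError"]

SOLVENT_DESCRIPTOR_NAMES = [
    "spp",
    "sa",
    "sb",
    "kt_alpha",
    "kt_beta",
    "kt_pistar",
    "eps",
    "f_eps_clausius",   # (eps-1)/(eps+2)
    "f_eps_kirkwood",   # (eps-1)/(2*eps+1)
    "f_eps_block",      # (eps-1)/(eps+1)
    "n_squared",
    "f_n_clausius",     # (n^2-1)/(n^2+2)
    "f_n_kirkwood",     # (n^2-1)/(2*n^2+1)
    "reserved_1",
    "reserved_2",
]

# name: SPP, SA, SB, alpha, beta, pi*, dielectric constant, refractive index
_RAW_CONSTANTS: dict[str, tuple[float, ...]] = {
    "water":          (0.962, 1.062, 0.025, 1.17, 0.47, 1.09, 78.36, 1.333),
    "methanol":       (0.857, 0.605, 0.545, 0.98, 0.66, 0.60, 32.66, 1.328),
    "ethanol":        (0.853, 0.400, 0.658, 0.86, 0.75, 0.54, 24.55, 1.361),
    "acetonitrile":   (0.895, 0.044, 0.286, 0.19, 0.40, 0.75, 35.94, 1.344),
    "acetone":        (0.881, 0.000, 0.475, 0.08, 0.43, 0.71, 20.56, 1.359),
    "dmso":           (1.000, 0.072, 0.647, 0.00, 0.76, 1.00, 46.45, 1.479),
    "dmf":            (0.954, 0.031, 0.613, 0.00, 0.69, 0.88, 36.71, 1.430),
    "thf":            (0.838, 0.000, 0.591, 0.00, 0.55, 0.58, 7.58, 1.407),
    "dichloromethane": (0.876, 0.040, 0.178, 0.13, 0.10, 0.82, 8.93, 1.424),
    "chloroform":     (0.786, 0.047, 0.071, 0.20, 0.10, 0.58, 4.81, 1.446),
    "toluene":        (0.655, 0.000, 0.128, 0.00, 0.11, 0.54, 2.38, 1.497),
    "benzene":        (0.667, 0.000, 0.124, 0.00, 0.10, 0.59, 2.27, 1.501),
    "diethyl ether":  (0.694, 0.000, 0.562, 0.00, 0.47, 0.27, 4.20, 1.352),
}


class SolventLookupError(KeyError):
    """Unknown solvent name; message lists the registered names."""


def _expand(raw: tuple[float, ...]) -> list[float]:
    spp, sa, sb, alpha, beta, pistar, eps, n = raw
    n2 = n * n
    return [
        spp, sa, sb, alpha, beta, pistar,
        eps,
        (eps - 1.0) / (eps + 2.0),
        (eps - 1.0) / (2.0 * eps + 1.0),
        (eps - 1.0) / (eps + 1.0),
        n2,
        (n2 - 1.0) / (n2 + 2.0),
        (n2 - 1.0) / (2.0 * n2 + 1.0),
        0.0,
        0.0,
    ]


class SolventTable:
    """Mapping solvent name -> 15-descriptor vector, user-extensible."""

    def __init__(self, table: dict[str, list[float]] | None = None):
        if table is None:
            table = {name: _expand(raw) for name, raw in _RAW_CONSTANTS.items()}
        for name, values in table.items():
            if len(values) != 15:
                raise ValueError(f"solvent {name!r} must have 15 descriptor values")
        self._table = dict(table)

    @classmethod
    def bundled(cls) -> "SolventTable":
        return cls()

    @classmethod
    def from_csv(cls, path: str | Path, extend_bundled: bool = True) -> "SolventTable":
        """Load a CSV of ``name`` plus 15 descriptor values per row."""
        table = {name: _expand(raw) for name, raw in _RAW_CONSTANTS.items()} if extend_bundled else {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if len(header) != 16:
                raise ValueError("solvent table CSV needs a name column plus 15 values")
            for row in reader:
                if not row:
                    continue
                table[row[0].strip().lower()] = [float(v) for v in row[1:16]]
        return cls(table)

    @property
    def names(self) -> list[str]:
        return sorted(self._table)

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._table

    def lookup(self, name: str) -> list[float]:
        key = name.strip().lower()
        if key not in self._table:
            raise SolventLookupError(
                f"unknown solvent {name!r}; known solvents: {', '.join(self.names)}"
            )
        return list(self._table[key])
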