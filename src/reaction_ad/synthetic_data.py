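"""Seeded synthetic reaction datasets with controlled reaction types.

The generator emulates the statistical structure of curated reaction-rate
datasets: a handful of reaction-type templates (distinct reaction-center
graphs), small substituent alphabets, condition variation (solvent,
temperature), a property that is a noisy linear function of CGR fragment
counts and conditions, a controllable fraction of gross Y-outliers, and an
injectable non-native reaction type.  Four template families are built in:

- substitution: R-CH2-X + HO-  ->  R-CH2-OH + X-   (halide leaving groups)
- elimination:  X-CH2-CH2-R + HO-  ->  CH2=CH-R + X- + H2O
- cycloaddition: substituted butadiene + ethylene -> cyclohexene ring
- zwitterion tautomerization: +H3N-CH(R)-COO-  ->  H2N-CH(R)-COOH, whose
  CGR changes only atomic charges (no dynamic bonds)
- a "leaving-group shift" variant of substitution planting a cluster with a
  methanesulfonate leaving group, novel at the reaction center, whose
  property deviates systematically from the native law

The property law assigns each fragment a weight through a salted hash of
its canonical string, so train and test sets drawn with different seeds
obey the same underlying law.  Hidden per-row flags (true type, planted
outlier, novel cluster) live in a sidecar table, never in the model-facing
columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import norm

from .io import ReactionDataset
from .descriptors import enumerate_fragments
from .reaction_graph import build_cgr, parse_reaction

__all__ = ["Substituent", "GeneratorSpec", "SyntheticDataset", "generate", "builtin_suites"]

_BOND_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}


@dataclass(frozen=True)
class Substituent:
    """A small attached group: atoms plus bonds; parent index -1 is the core atom."""

    name: str
    atoms: tuple[tuple[str, int, bool], ...]            # (element, charge, aromatic)
    bonds: tuple[tuple[int, int, object], ...]          # (atom, parent_or_atom, order)


SUBSTITUENTS = {
    s.name: s
    for s in [
        Substituent("H", (), ()),
        Substituent("methyl", (("C", 0, False),), ((0, -1, 1),)),
        Substituent("ethyl", (("C", 0, False), ("C", 0, False)), ((0, -1, 1), (1, 0, 1))),
        Substituent("n-propyl", (("C", 0, False),) * 3, ((0, -1, 1), (1, 0, 1), (2, 1, 1))),
        Substituent("methoxymethyl", (("C", 0, False), ("O", 0, False), ("C", 0, False)),
                    ((0, -1, 1), (1, 0, 1), (2, 1, 1))),
        Substituent("aminomethyl", (("C", 0, False), ("N", 0, False)), ((0, -1, 1), (1, 0, 1))),
        Substituent("phenyl", (("C", 0, True),) * 6,
                    ((0, -1, 1), (1, 0, "ar"), (2, 1, "ar"), (3, 2, "ar"),
                     (4, 3, "ar"), (5, 4, "ar"), (0, 5, "ar"))),
        Substituent("glycyl", (("C", 0, False), ("N", 0, False), ("C", 0, False),
                               ("O", 0, False), ("O", 0, False)),
                    ((0, -1, 1), (1, 0, 1), (2, 0, 1), (3, 2, 2), (4, 2, 1))),
        Substituent("carboxymethyl", (("C", 0, False), ("C", 0, False),
                                      ("O", 0, False), ("O", 0, False)),
                    ((0, -1, 1), (1, 0, 1), (2, 1, 2), (3, 1, 1))),
    ]
}


class _MolBuilder:
    def __init__(self) -> None:
        self.mol = Chem.RWMol()

    def atom(self, element: str, map_number: int, charge: int = 0, aromatic: bool = False) -> int:
        a = Chem.Atom(element)
        a.SetFormalCharge(charge)
        a.SetIsAromatic(aromatic)
        a.SetAtomMapNum(map_number)
        return self.mol.AddAtom(a)

    def bond(self, i: int, j: int, order: object = 1) -> None:
        self.mol.AddBond(i, j, _BOND_ORDERS[order])

    def attach(self, core_idx: int, sub: Substituent, map_start: int) -> int:
        """Attach a substituent; returns the next free map number."""
        idx = []
        for k, (el, chg, arom) in enumerate(sub.atoms):
            idx.append(self.atom(el, map_start + k, chg, arom))
        for a, b, order in sub.bonds:
            target = core_idx if b == -1 else idx[b]
            self.bond(idx[a], target, order)
        return map_start + len(sub.atoms)

    def smiles(self) -> str:
        mol = self.mol.GetMol()
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)


def _substitution(sub: Substituent, lg: str, novel_lg: bool = False) -> str:
    def side(products: bool) -> str:
        b = _MolBuilder()
        c = b.atom("C", 1)
        if novel_lg:
            # methanesulfonate ester: C1-O2-S(=O)(=O)-CH3
            o = b.atom("O", 2, charge=-1 if products else 0)
            s = b.atom("S", 20)
            b.bond(o, s, 1)
            b.bond(s, b.atom("O", 21), 2)
            b.bond(s, b.atom("O", 22), 2)
            b.bond(s, b.atom("C", 23), 1)
            lg_idx = o
        else:
            lg_idx = b.atom(lg, 2, charge=-1 if products else 0)
        nu = b.atom("O", 3, charge=0 if products else -1)
        if products:
            b.bond(c, nu, 1)
        else:
            b.bond(c, lg_idx, 1)
        b.attach(c, sub, 10)
        return b.smiles()

    return side(False) + ">>" + side(True)


def _elimination(sub: Substituent, lg: str) -> str:
    def side(products: bool) -> str:
        b = _MolBuilder()
        c1 = b.atom("C", 1)
        c2 = b.atom("C", 2)
        x = b.atom(lg, 3, charge=-1 if products else 0)
        o = b.atom("O", 4, charge=0 if products else -1)
        if products:
            b.bond(c1, c2, 2)
        else:
            b.bond(c1, c2, 1)
            b.bond(c1, x, 1)
        b.attach(c2, sub, 10)
        return b.smiles()

    return side(False) + ">>" + side(True)


def _cycloaddition(sub1: Substituent, sub2: Substituent) -> str:
    def side(products: bool) -> str:
        b = _MolBuilder()
        c = [b.atom("C", k + 1) for k in range(6)]
        if products:
            ring = [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 0, 1)]
            for i, j, order in ring:
                b.bond(c[i], c[j], order)
        else:
            b.bond(c[0], c[1], 2)
            b.bond(c[1], c[2], 1)
            b.bond(c[2], c[3], 2)
            b.bond(c[4], c[5], 2)
        nxt = b.attach(c[0], sub1, 10)
        b.attach(c[5], sub2, nxt)
        return b.smiles()

    return side(False) + ">>" + side(True)


def _zwitterion(sub: Substituent) -> str:
    def side(products: bool) -> str:
        b = _MolBuilder()
        n = b.atom("N", 1, charge=0 if products else 1)
        c2 = b.atom("C", 2)
        c3 = b.atom("C", 3)
        o4 = b.atom("O", 4)
        o5 = b.atom("O", 5, charge=0 if products else -1)
        b.bond(n, c2, 1)
        b.bond(c2, c3, 1)
        b.bond(c3, o4, 2)
        b.bond(c3, o5, 1)
        b.attach(c2, sub, 10)
        return b.smiles()

    return side(False) + ">>" + side(True)


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to draw one synthetic dataset deterministically."""

    name: str
    template: str                       # substitution | elimination | cycloaddition | zwitterion
    seed: int = 0
    n_reactions: int = 100
    substituents: tuple[str, ...] = ("H", "methyl", "ethyl")
    leaving_groups: tuple[str, ...] = ("Cl", "Br")
    solvents: tuple[str, ...] = ("water", "methanol", "ethanol", "acetonitrile")
    temperature_range: tuple[float, float] = (280.0, 360.0)
    molar_ratio: float = 100.0
    noise_sd: float = 0.3
    outlier_fraction: float = 0.0
    outlier_offset: float = 6.0         # added with a random sign to planted outliers
    novel_cluster_fraction: float = 0.0  # substitution only: methanesulfonate cluster
    novel_cluster_offset: float = 2.5
    frag_weight_scale: float = 0.35
    frag_active_fraction: float = 0.4
    weight_inv_T: float = -1500.0       # Arrhenius-like slope on 1/T
    weight_spp: float = 2.0             # solvent polarity term
    weight_molar_ratio: float = 0.0
    property_law_seed: int = 0          # salt of the fragment-weight hash


@dataclass
class SyntheticDataset:
    """Model-facing table plus hidden per-row flags (tests only)."""

    table: pd.DataFrame
    flags: pd.DataFrame
    spec: GeneratorSpec

    def to_reaction_dataset(self) -> ReactionDataset:
        return ReactionDataset(self.table.copy())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        self.flags.to_csv(path.with_suffix(".flags.csv"), index=False)


def fragment_weight(fragment: str, law_seed: int, active_fraction: float, scale: float) -> float:
    """Deterministic per-fragment weight: hash-selected, hash-valued Gaussian."""
    digest = hashlib.sha256(f"{law_seed}|{fragment}".encode()).digest()
    u_select = int.from_bytes(digest[:8], "big") / 2**64
    if u_select >= active_fraction:
        return 0.0
    u_value = (int.from_bytes(digest[8:16], "big") + 0.5) / 2**64
    return scale * float(norm.ppf(u_value))


def _draw_reaction(spec: GeneratorSpec, rng: np.random.Generator, novel: bool) -> tuple[str, str]:
    subs = [SUBSTITUENTS[s] for s in spec.substituents]
    sub = subs[rng.integers(len(subs))]
    if spec.template == "substitution":
        if novel:
            return _substitution(sub, "", novel_lg=True), f"substitution:OMs:{sub.name}"
        lg = spec.leaving_groups[rng.integers(len(spec.leaving_groups))]
        return _substitution(sub, lg), f"substitution:{lg}:{sub.name}"
    if spec.template == "elimination":
        lg = spec.leaving_groups[rng.integers(len(spec.leaving_groups))]
        return _elimination(sub, lg), f"elimination:{lg}:{sub.name}"
    if spec.template == "cycloaddition":
        sub2 = subs[rng.integers(len(subs))]
        return _cycloaddition(sub, sub2), f"cycloaddition:{sub.name}:{sub2.name}"
    if spec.template == "zwitterion":
        return _zwitterion(sub), f"zwitterion:{sub.name}"
    raise ValueError(f"unknown template {spec.template!r}")


def generate(spec: GeneratorSpec, n: int | None = None, seed: int | None = None) -> SyntheticDataset:
    """Draw a dataset; ``n``/``seed`` override the GeneratorSpec fields when given."""
    if n is not None or seed is not None:
        spec = replace(spec, n_reactions=n or spec.n_reactions,
                       seed=spec.seed if seed is None else seed)
    if spec.noise_sd > 0 and spec.outlier_fraction > 0 and spec.outlier_offset < 5 * spec.noise_sd:
        raise ValueError("outlier offset must be at least 5x the noise sd")
    rng = np.random.default_rng(spec.seed)
    rows, types, novel_flags = [], [], []
    for _ in range(spec.n_reactions):
        novel = spec.template == "substitution" and rng.random() < spec.novel_cluster_fraction
        try:
            smi, type_id = _draw_reaction(spec, rng, novel)
        except Exception as exc:  # template must parse; name the offender
            raise ValueError(f"template {spec.template!r} of suite {spec.name!r} failed: {exc}")
        solvent = spec.solvents[rng.integers(len(spec.solvents))]
        temp = float(rng.uniform(*spec.temperature_range))
        rows.append((smi, solvent, temp))
        types.append(type_id)
        novel_flags.append(novel)

    # property = fragment law + condition terms + noise (+ planted offsets)
    from .solvents import SolventTable

    table = SolventTable.bundled()
    y = np.zeros(spec.n_reactions)
    for k, (smi, solvent, temp) in enumerate(rows):
        cgr = build_cgr(parse_reaction(smi))
        for frag, count in enumerate_fragments(cgr).items():
            w = fragment_weight(frag, spec.property_law_seed,
                                spec.frag_active_fraction, spec.frag_weight_scale)
            y[k] += w * count
        spp = table.lookup(solvent)[0]
        y[k] += spec.weight_inv_T / temp + spec.weight_spp * spp
        y[k] += spec.weight_molar_ratio * spec.molar_ratio
    y += rng.normal(0.0, spec.noise_sd, size=spec.n_reactions)

    # exact count keeps the realized contamination at the requested fraction;
    # Bernoulli fluctuations would let 3x RMSE drift up towards the offset
    n_out = int(round(spec.outlier_fraction * spec.n_reactions))
    outlier = np.zeros(spec.n_reactions, dtype=bool)
    if n_out:
        outlier[rng.choice(spec.n_reactions, size=n_out, replace=False)] = True
    signs = np.where(rng.random(spec.n_reactions) < 0.5, -1.0, 1.0)
    y = y + outlier * signs * spec.outlier_offset
    y = y + np.asarray(novel_flags) * spec.novel_cluster_offset

    frame = pd.DataFrame(
        {
            "reaction": [r[0] for r in rows],
            "property": np.round(y, 6),
            "solvent": [r[1] for r in rows],
            "temperature_K": np.round([r[2] for r in rows], 3),
            "molar_ratio": spec.molar_ratio,
        }
    )
    flags = pd.DataFrame(
        {
            "type_id": types,
            "planted_outlier": outlier,
            "novel_cluster": novel_flags,
        }
    )
    return SyntheticDataset(table=frame, flags=flags, spec=spec)


def builtin_suites() -> dict[str, GeneratorSpec]:
    """Named generator specs mirroring the benchmark's study conditions."""
    return {
        "substitution-like": GeneratorSpec(
            name="substitution-like",
            template="substitution",
            substituents=("H", "methyl", "ethyl", "n-propyl", "methoxymethyl", "phenyl"),
        ),
        "elimination-like": GeneratorSpec(
            name="elimination-like",
            template="elimination",
            substituents=("H", "methyl", "ethyl", "aminomethyl", "glycyl", "carboxymethyl"),
        ),
        "cycloaddition-like": GeneratorSpec(
            name="cycloaddition-like",
            template="cycloaddition",
            substituents=("H", "methyl", "ethyl", "phenyl"),
        ),
        "zwitterion-tautomer-like": GeneratorSpec(
            name="zwitterion-tautomer-like",
            template="zwitterion",
            substituents=("H", "methyl"),
        ),
        "leaving-group-shift": GeneratorSpec(
            name="leaving-group-shift",
            template="substitution",
            substituents=("H", "methyl", "ethyl", "n-propyl", "methoxymethyl", "phenyl"),
            novel_cluster_fraction=0.3,
        ),
    }
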