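"""Condensed Graphs of Reaction (CGR), reaction centers and canonical signatures.

A CGR superposes the reactant and product states of a fully atom-mapped
reaction in a single graph: every atom carries its charge, heavy-neighbor
count and hybridization *before* and *after* the transformation, and every
bond carries its order on both sides ("none" when the bond exists on one
side only).  Bonds whose order changes are *dynamic bonds*; atoms whose
state changes (or which touch a dynamic bond) are *dynamic atoms*.  The
connected components of the dynamic subgraph are the *reaction centers*,
and the canonical string of a center together with its radius-R atom
neighborhood is the *reaction signature*: two reactions belong to the same
reaction type exactly when their signature sets coincide.

Atom-mapped reaction SMILES is the only input format.  RDKit is used for
SMILES parsing; aromaticity is taken from the input notation (lowercase
atoms / aromatic bonds) rather than re-perceived, so parsing is
deterministic.  Hydrogens are implicit throughout and heavy-neighbor
counts exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReactionParseError",
    "MappingError",
    "Atom",
    "Bond",
    "Molecule",
    "Reaction",
    "CGRAtom",
    "CGRBond",
    "CGR",
    "ReactionCenter",
    "Signature",
    "parse_reaction",
    "build_cgr",
    "find_reaction_centers",
    "perceive_hybridization",
    "signature",
    "signature_set",
    "BOND_TOKENS",
]


class ReactionParseError(ValueError):
    """Raised when reaction SMILES cannot be parsed."""


class MappingError(ValueError):
    """Raised when the atom-to-atom mapping is absent, duplicated or unbalanced."""


#: bond order -> single-character token used in signatures and fragments
BOND_TOKENS = {"none": ".", "single": "-", "double": "=", "triple": "#", "aromatic": ":"}

_RDKIT_ORDERS = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int
    n_hydrogens: int
    aromatic: bool
    map_number: int


@dataclass(frozen=True)
class Bond:
    i: int  # atom-map numbers, not positional indices
    j: int
    order: str


@dataclass(frozen=True)
class Molecule:
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]

    def neighbor_counts(self) -> dict[int, int]:
        """Heavy-atom degree keyed by atom-map number (hydrogens excluded)."""
        counts = {a.map_number: 0 for a in self.atoms}
        for b in self.bonds:
            counts[b.i] += 1
            counts[b.j] += 1
        return counts


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]

    @property
    def map_numbers(self) -> frozenset[int]:
        return frozenset(a.map_number for m in self.reactants for a in m.atoms)


@dataclass(frozen=True)
class CGRAtom:
    element: str
    charge_before: int
    charge_after: int
    neighbors_before: int
    neighbors_after: int
    hybridization_before: str
    hybridization_after: str

    @property
    def changed(self) -> bool:
        return (
            self.charge_before != self.charge_after
            or self.neighbors_before != self.neighbors_after
            or self.hybridization_before != self.hybridization_after
        )

    def label(self) -> str:
        """Signature atom token: element, neighbor counts, hybridization, charge."""
        return (
            f"{self.element}:{self.neighbors_before}>>{self.neighbors_after}"
            f":{self.hybridization_before}>>{self.hybridization_after}"
            f":{self.charge_before:+d}>>{self.charge_after:+d}"
        )


@dataclass(frozen=True)
class CGRBond:
    i: int
    j: int
    order_before: str
    order_after: str

    @property
    def dynamic(self) -> bool:
        return self.order_before != self.order_after

    def label(self) -> str:
        return f"{BOND_TOKENS[self.order_before]}>>{BOND_TOKENS[self.order_after]}"


@dataclass
class CGR:
    """Condensed Graph of Reaction keyed by atom-map number."""

    atoms: dict[int, CGRAtom]
    bonds: dict[tuple[int, int], CGRBond]  # keyed by sorted map-number pair
    _adjacency: dict[int, list[int]] = field(default=None, repr=False)  # type: ignore[assignment]

    def adjacency(self) -> dict[int, list[int]]:
        if self._adjacency is None:
            adj: dict[int, list[int]] = {n: [] for n in self.atoms}
            for (i, j) in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adjacency = adj
        return self._adjacency

    def dynamic_bonds(self) -> list[CGRBond]:
        return [b for b in self.bonds.values() if b.dynamic]

    def dynamic_atoms(self) -> set[int]:
        """Atoms with a state change or incident to a dynamic bond."""
        dyn = {n for n, a in self.atoms.items() if a.changed}
        for b in self.dynamic_bonds():
            dyn.add(b.i)
            dyn.add(b.j)
        return dyn


@dataclass(frozen=True)
class ReactionCenter:
    atoms: frozenset[int]
    bonds: frozenset[tuple[int, int]]


@dataclass(frozen=True)
class Signature:
    string: str
    radius: int
    center_index: int


# ---------------------------------------------------------------------------
# parsing


def _molecule_from_rdkit(mol: Chem.Mol) -> Molecule:
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                n_hydrogens=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                map_number=a.GetAtomMapNum(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        order = _RDKIT_ORDERS.get(b.GetBondType())
        if order is None:
            raise ReactionParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(
            Bond(
                i=b.GetBeginAtom().GetAtomMapNum(),
                j=b.GetEndAtom().GetAtomMapNum(),
                order=order,
            )
        )
    return Molecule(atoms=tuple(atoms), bonds=tuple(bonds))


def _parse_side(smiles: str, side: str) -> tuple[Molecule, ...]:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ReactionParseError(f"cannot parse {side} SMILES: {smiles!r}")
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    ring_info = mol.GetRingInfo()
    for a in mol.GetAtoms():
        if a.GetIsAromatic() and ring_info.NumAtomRings(a.GetIdx()) == 0:
            raise ReactionParseError(
                f"aromatic atom outside a ring in {side} SMILES: {smiles!r}"
            )
    unmapped = [a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomMapNum() < 1]
    if unmapped:
        raise MappingError(f"unmapped heavy atoms {unmapped} on {side} side")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return tuple(_molecule_from_rdkit(f) for f in frags)


def parse_reaction(text: str) -> Reaction:
    """Parse an atom-mapped reaction SMILES into a :class:`Reaction`.

    The standard ``reactants>agents>products`` grammar is accepted; the
    agents field, if present, is ignored.  Every heavy atom must carry a
    map number and the multiset of map numbers must balance across sides.
    """
    if not text or not text.strip():
        raise ReactionParseError("empty reaction SMILES")
    parts = text.strip().split(">")
    if len(parts) == 3:
        left, _agents, right = parts
    else:
        raise ReactionParseError(f"not a reaction SMILES (need '>>'): {text!r}")
    if not left or not right:
        raise ReactionParseError(f"missing reactant or product side: {text!r}")
    reactants = _parse_side(left, "reactant")
    products = _parse_side(right, "product")

    def _maps(mols: Sequence[Molecule], side: str) -> set[int]:
        seen: set[int] = set()
        for m in mols:
            for a in m.atoms:
                if a.map_number in seen:
                    raise MappingError(f"duplicate map number {a.map_number} on {side} side")
                seen.add(a.map_number)
        return seen

    rmaps = _maps(reactants, "reactant")
    pmaps = _maps(products, "product")
    if rmaps != pmaps:
        missing = sorted(rmaps ^ pmaps)
        raise MappingError(f"unbalanced atom mapping, one-sided map numbers: {missing}")
    return Reaction(reactants=reactants, products=products)


# ---------------------------------------------------------------------------
# hybridization and CGR assembly


def perceive_hybridization(molecule: Molecule) -> dict[int, str]:
    """Hybridization label per atom-map number.

    Aromatic atoms get the dedicated ``aromatic`` label; aliphatic atoms are
    classified from their incident multiple bonds: any triple bond or at
    least two double bonds gives ``sp``, exactly one double bond ``sp2``,
    anything else ``sp3``.
    """
    doubles = {a.map_number: 0 for a in molecule.atoms}
    triples = {a.map_number: 0 for a in molecule.atoms}
    for b in molecule.bonds:
        if b.order == "double":
            doubles[b.i] += 1
            doubles[b.j] += 1
        elif b.order == "triple":
            triples[b.i] += 1
            triples[b.j] += 1
    labels = {}
    for a in molecule.atoms:
        if a.aromatic:
            labels[a.map_number] = "aromatic"
        elif triples[a.map_number] >= 1 or doubles[a.map_number] >= 2:
            labels[a.map_number] = "sp"
        elif doubles[a.map_number] == 1:
            labels[a.map_number] = "sp2"
        else:
            labels[a.map_number] = "sp3"
    return labels


def _side_state(mols: Sequence[Molecule]) -> tuple[dict[int, Atom], dict[int, int], dict[int, str], dict[tuple[int, int], str]]:
    atoms: dict[int, Atom] = {}
    neighbors: dict[int, int] = {}
    hybrid: dict[int, str] = {}
    bonds: dict[tuple[int, int], str] = {}
    for m in mols:
        hyb = perceive_hybridization(m)
        nbc = m.neighbor_counts()
        for a in m.atoms:
            atoms[a.map_number] = a
            neighbors[a.map_number] = nbc[a.map_number]
            hybrid[a.map_number] = hyb[a.map_number]
        for b in m.bonds:
            key = (min(b.i, b.j), max(b.i, b.j))
            bonds[key] = b.order
    return atoms, neighbors, hybrid, bonds


def build_cgr(reaction: Reaction) -> CGR:
    """Superpose reactant and product states into a Condensed Graph of Reaction."""
    r_atoms, r_nb, r_hyb, r_bonds = _side_state(reaction.reactants)
    p_atoms, p_nb, p_hyb, p_bonds = _side_state(reaction.products)
    atoms: dict[int, CGRAtom] = {}
    for n, ra in r_atoms.items():
        pa = p_atoms[n]
        if ra.element != pa.element:
            raise MappingError(
                f"inconsistent mapping: map {n} is {ra.element} in reactants "
                f"but {pa.element} in products"
            )
        atoms[n] = CGRAtom(
            element=ra.element,
            charge_before=ra.charge,
            charge_after=pa.charge,
            neighbors_before=r_nb[n],
            neighbors_after=p_nb[n],
            hybridization_before=r_hyb[n],
            hybridization_after=p_hyb[n],
        )
    bonds: dict[tuple[int, int], CGRBond] = {}
    for key in sorted(set(r_bonds) | set(p_bonds)):
        bonds[key] = CGRBond(
            i=key[0],
            j=key[1],
            order_before=r_bonds.get(key, "none"),
            order_after=p_bonds.get(key, "none"),
        )
    return CGR(atoms=atoms, bonds=bonds)


def find_reaction_centers(cgr: CGR) -> list[ReactionCenter]:
    """Connected components of the dynamic subgraph, ordered by smallest atom map."""
    dyn_atoms = cgr.dynamic_atoms()
    dyn_bonds = {(b.i, b.j) for b in cgr.dynamic_bonds()}
    adj: dict[int, list[int]] = {n: [] for n in dyn_atoms}
    for i, j in dyn_bonds:
        adj[i].append(j)
        adj[j].append(i)
    centers = []
    seen: set[int] = set()
    for start in sorted(dyn_atoms):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        comp_bonds = frozenset(
            (i, j) for (i, j) in dyn_bonds if i in comp and j in comp
        )
        centers.append(ReactionCenter(atoms=frozenset(comp), bonds=comp_bonds))
    return centers


# ---------------------------------------------------------------------------
# canonicalization (Morgan-like iterative refinement + DFS serialization)


def _dense_rank(keys: Mapping[int, object]) -> dict[int, int]:
    order = sorted(set(keys.values()))  # type: ignore[type-var]
    index = {k: r for r, k in enumerate(order)}
    return {n: index[keys[n]] for n in keys}


def _refine(inv: dict[int, int], adj: dict[int, list[tuple[int, str]]]) -> dict[int, int]:
    """Iterative extended-connectivity refinement until the partition stabilizes."""
    while True:
        keys = {
            n: (inv[n], tuple(sorted((bl, inv[m]) for m, bl in adj[n])))
            for n in inv
        }
        new = _dense_rank(keys)
        if len(set(new.values())) == len(set(inv.values())):
            return new
        inv = new


def _serialize(
    nodes: Sequence[int],
    ranks: dict[int, int],
    labels: dict[int, str],
    adj: dict[int, list[tuple[int, str]]],
    bond_labels: dict[tuple[int, int], str],
) -> str:
    """Deterministic depth-first SMILES-like serialization given total atom ranks."""
    root = min(nodes, key=lambda n: ranks[n])
    visited: set[int] = set()
    tree: dict[int, list[int]] = {n: [] for n in nodes}
    back_edges: list[tuple[int, int]] = []  # (first-visited atom, second)
    used: set[tuple[int, int]] = set()
    order_of_visit: dict[int, int] = {}

    stack = [root]
    visited.add(root)
    order_of_visit[root] = 0
    # iterative DFS recording tree edges and back (ring-closure) edges
    while stack:
        node = stack.pop()
        for nb, _bl in sorted(adj[node], key=lambda t: ranks[t[0]]):
            key = (min(node, nb), max(node, nb))
            if key in used:
                continue
            if nb in visited:
                used.add(key)
                back_edges.append((nb, node))
            else:
                used.add(key)
                visited.add(nb)
                order_of_visit[nb] = len(order_of_visit)
                tree[node].append(nb)
                stack.append(nb)
    # DFS with an explicit stack visits children in reverse push order; re-sort
    for n in nodes:
        tree[n].sort(key=lambda m: ranks[m])

    closure_ids: dict[tuple[int, int], int] = {}
    closures_at: dict[int, list[tuple[int, str, bool]]] = {n: [] for n in nodes}
    for cid, (a, b) in enumerate(
        sorted(back_edges, key=lambda e: (order_of_visit[e[0]], order_of_visit[e[1]]))
    ):
        key = (min(a, b), max(a, b))
        closure_ids[key] = cid
        bl = bond_labels[key]
        closures_at[a].append((cid, bl, True))
        closures_at[b].append((cid, bl, False))

    def emit(node: int, bond_in: str | None) -> str:
        parts = []
        if bond_in is not None:
            parts.append("{" + bond_in + "}")
        parts.append("[" + labels[node] + "]")
        for cid, bl, first in sorted(closures_at[node]):
            parts.append("{" + bl + "}%" + str(cid))
        children = tree[node]
        for child in children[:-1]:
            key = (min(node, child), max(node, child))
            parts.append("(" + emit(child, bond_labels[key]) + ")")
        if children:
            child = children[-1]
            key = (min(node, child), max(node, child))
            parts.append(emit(child, bond_labels[key]))
        return "".join(parts)

    return emit(root, None)


def _canonical_string(
    nodes: Sequence[int],
    labels: dict[int, str],
    bond_labels: dict[tuple[int, int], str],
) -> str:
    """Canonical string of a labeled graph.

    Initial atom invariants are the label strings; ties remaining after
    refinement are broken by individualization with exhaustive enumeration,
    taking the lexicographically smallest serialization.  Invariant to the
    input ordering of ``nodes``.
    """
    adj: dict[int, list[tuple[int, str]]] = {n: [] for n in nodes}
    for (i, j), bl in bond_labels.items():
        adj[i].append((j, bl))
        adj[j].append((i, bl))

    def search(inv: dict[int, float]) -> str:
        ranks = _refine(_dense_rank(inv), adj)
        cells: dict[int, list[int]] = {}
        for n, r in ranks.items():
            cells.setdefault(r, []).append(n)
        multi = [r for r, members in cells.items() if len(members) > 1]
        if not multi:
            return _serialize(list(nodes), ranks, labels, adj, bond_labels)
        target = min(multi)
        best: str | None = None
        for n in cells[target]:
            child = {m: 2 * ranks[m] for m in ranks}
            child[n] -= 1  # individualize: strictly smaller than its cell mates
            s = search(child)
            if best is None or s < best:
                best = s
        return best  # type: ignore[return-value]

    return search({n: labels[n] for n in nodes})  # type: ignore[arg-type]


def signature(cgr: CGR, center: ReactionCenter, radius: int, center_index: int = 0) -> Signature:
    """Canonical signature of one reaction center with its radius-R neighborhood.

    The encoded subgraph contains the center atoms plus every atom within
    graph distance ``radius`` of any center atom, together with all CGR
    bonds among the included atoms.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    adj = cgr.adjacency()
    included = set(center.atoms)
    frontier = set(center.atoms)
    for _ in range(radius):
        frontier = {nb for n in frontier for nb in adj[n]} - included
        included |= frontier
    bond_labels = {
        (i, j): b.label()
        for (i, j), b in cgr.bonds.items()
        if i in included and j in included
    }
    labels = {n: cgr.atoms[n].label() for n in included}
    string = _canonical_string(sorted(included), labels, bond_labels)
    return Signature(string=string, radius=radius, center_index=center_index)


def signature_set(reaction: Reaction, radius: int) -> set[str]:
    """One signature string per reaction center; empty for a change-free reaction."""
    cgr = build_cgr(reaction)
    centers = find_reaction_centers(cgr)
    return {
        signature(cgr, c, radius, center_index=k).string for k, c in enumerate(centers)
    }


def signature_set_from_cgr(cgr: CGR, radius: int) -> set[str]:
    centers = find_reaction_centers(cgr)
    return {
        signature(cgr, c, radius, center_index=k).string for k, c in enumerate(centers)
    }
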