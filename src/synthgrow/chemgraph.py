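"""Molecule I/O and pharmacophore typing of atoms.

Molecules are handled as hydrogen-suppressed graphs whose vertices carry one
of eight pharmacophoric feature types:

    A  hydrogen-bond acceptor
    D  hydrogen-bond donor
    E  hydrogen-bond donor & acceptor
    P  positive charge (or protonatable aliphatic amine)
    N  negative charge (or deprotonated acid)
    R  aromatic
    L  lipophilic
    0  no type

Typing is a fixed priority cascade (P > N > E > D > A > R > L > 0) over
substructure rules, which makes it single-valued and deterministic: an atom
matching both the donor and the acceptor rule receives E, an aromatic
heteroatom keeps its heteroatom type (pyridine nitrogen is an acceptor, not
merely aromatic) while its ring membership remains visible to the reduced
graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

#: the eight pharmacophore type symbols
PHARMACOPHORE_TYPES = ("A", "D", "E", "P", "N", "R", "L", "0")

#: bond order symbols used on molecular-graph edges
AROMATIC = "ar"


class MoleculeError(ValueError):
    """Raised for unusable molecular input."""


# -- typing rules -------------------------------------------------------------
# Each rule is a SMARTS pattern; cascade priority is applied per atom.
# Positive/negative charge centers exclude ylide-style adjacent opposite
# charges (nitro, azide) so those groups fall through to acceptor typing.
_SMARTS = {
    "pos_charge": "[+1,+2;!$([+1]~[-1]);!$([+2]~[-1])]",
    "basic_amine": (
        "[NX3;+0;!$(N[a]);!$(N*=[O,S,N,P]);!$(N[C,S,P]=[O,S,N]);!$(N[N,O])]"
    ),
    "neg_charge": "[-1,-2;!$([-1]~[+1]);!$([-2]~[+1])]",
    "donor": "[$([N;H1,H2,H3;+0]),$([N;H1,H2,H3;+1]),$([OX2H1]),$([SX2H1]),$([nH1])]",
    "acceptor": (
        "[$([OX1;+0]),$([OX2;+0]),$([nX2;+0]),"
        "$([NX2;+0;!$(N=N);!$(N=O)]),$([NX1;+0]),"
        "$([NX3;+0;!$(N[a]);!$(N[C,S,P]=[O,S,N]);!$(NN)])]"
    ),
    "lipophilic": "[$([C;!$(C~[!#6;!#1])]),$([F,Cl,Br,I;$(*[#6,#1])])]",
}
_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in _SMARTS.items()}


@dataclass(frozen=True)
class AtomVertex:
    """One heavy atom of a typed molecular graph."""

    element: str
    aromatic: bool
    formal_charge: int
    degree: int  # heavy-neighbor degree
    ptype: str  # one of PHARMACOPHORE_TYPES


@dataclass
class TypedMolecularGraph:
    """Hydrogen-suppressed molecular graph with pharmacophore-typed vertices.

    ``edges`` holds ``(i, j, order)`` with order in ``{1, 2, 3, "ar"}``;
    vertex indices follow RDKit atom indices of ``mol``.
    """

    mol: Chem.Mol
    source_id: str
    vertices: list[AtomVertex] = field(default_factory=list)
    edges: list[tuple[int, int, object]] = field(default_factory=list)

    @property
    def heavy_atom_count(self) -> int:
        return len(self.vertices)

    @property
    def types(self) -> list[str]:
        return [v.ptype for v in self.vertices]

    def neighbors(self, i: int) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtomWithIdx(i).GetNeighbors()]

    def to_smiles(self) -> str:
        return canonical_smiles(self.mol)


def canonical_smiles(mol: Chem.Mol) -> str:
    """Toolkit-canonical SMILES; the determinism anchor used everywhere."""
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    return mol


def _bond_order(bond: Chem.Bond) -> object:
    if bond.GetIsAromatic():
        return AROMATIC
    return int(bond.GetBondTypeAsDouble())


def assign_pharmacophore_types(mol: Chem.Mol) -> list[str]:
    """Type every heavy atom by the priority cascade; pure and idempotent."""
    hits = {
        name: {i for match in mol.GetSubstructMatches(pat) for i in match}
        for name, pat in _PATTERNS.items()
    }
    types: list[str] = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if i in hits["pos_charge"] or i in hits["basic_amine"]:
            types.append("P")
        elif i in hits["neg_charge"]:
            types.append("N")
        elif i in hits["donor"] and i in hits["acceptor"]:
            types.append("E")
        elif i in hits["donor"]:
            types.append("D")
        elif i in hits["acceptor"]:
            types.append("A")
        elif atom.GetIsAromatic():
            types.append("R")
        elif i in hits["lipophilic"]:
            types.append("L")
        else:
            types.append("0")
    return types


def build_graph(mol: Chem.Mol, source_id: str = "") -> TypedMolecularGraph:
    """Typed molecular graph of a sanitized RDKit molecule (H-suppressed)."""
    mol = Chem.RemoveHs(mol)
    types = assign_pharmacophore_types(mol)
    vertices = [
        AtomVertex(
            element=a.GetSymbol(),
            aromatic=a.GetIsAromatic(),
            formal_charge=a.GetFormalCharge(),
            degree=a.GetDegree(),
            ptype=types[a.GetIdx()],
        )
        for a in mol.GetAtoms()
    ]
    edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order(b))
        for b in mol.GetBonds()
    ]
    return TypedMolecularGraph(mol=mol, source_id=source_id, vertices=vertices, edges=edges)


def graph_from_smiles(smiles: str, source_id: str = "") -> TypedMolecularGraph:
    return build_graph(mol_from_smiles(smiles), source_id=source_id)


# -- file I/O -----------------------------------------------------------------

def _iter_smiles_table(path: Path) -> Iterable[tuple[str, str | None]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            yield parts[0], (parts[1] if len(parts) > 1 else None)


def load_molecules(path: str | Path) -> list[TypedMolecularGraph]:
    """Load a SMILES table or an SDF into typed molecular graphs.

    Invalid records are skipped with a logged warning; records without an ID
    get one assigned from their position. An unreadable file or a file with
    zero valid records is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeError(f"no such file: {path}")
    graphs: list[TypedMolecularGraph] = []
    skipped = 0
    if path.suffix.lower() in {".sdf", ".sd", ".mol"}:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                log.warning("skipping unreadable SDF record %d in %s", i + 1, path)
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"rec{i + 1}"
            graphs.append(build_graph(mol, source_id=rid))
    else:
        for i, (smi, rid) in enumerate(_iter_smiles_table(path)):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                skipped += 1
                log.warning("skipping unparsable SMILES record %d (%r) in %s", i + 1, smi, path)
                continue
            graphs.append(build_graph(mol, source_id=rid or f"rec{i + 1}"))
    if not graphs:
        raise MoleculeError(f"no valid records in {path} ({skipped} skipped)")
    # ensure unique ids
    seen: dict[str, int] = {}
    for g in graphs:
        if g.source_id in seen:
            seen[g.source_id] += 1
            g.source_id = f"{g.source_id}_{seen[g.source_id]}"
        else:
            seen[g.source_id] = 0
    if skipped:
        log.warning("%d invalid record(s) skipped in %s", skipped, path)
    return graphs


def write_smiles_table(graphs: Sequence[TypedMolecularGraph], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(f"{g.to_smiles()}\t{g.source_id}\n")


def molecular_weight(mol: Chem.Mol) -> float:
    return Descriptors.MolWt(mol)
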