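"""Building-block catalog preparation: standardize, filter, preprocess, annotate.

The three-stage protocol turns a raw vendor-style catalog into the block
library the design algorithm consumes:

1. *Standardize & filter* — keep the largest organic fragment, reject blocks
   by mass window (30-300 Da), ring count (> 4 SSSR rings), element
   whitelist, fluorine count (> 3), invalid valences, unwanted-substructure
   alerts, and duplicates; then set protonation states (carboxylic acids
   deprotonated, aliphatic non-amide amines protonated) for scoring.
2. *FGA/FGI preprocessing* — every one-component functional-group
   addition/interconversion applicable to a block yields an extra derived
   block (the original is kept); derived blocks re-enter all filters except
   the alert screen (handles introduced on purpose survive) and are not
   preprocessed again.
3. *Annotation* — a block is recorded as a reactant for a reaction component
   only when it matches that component's reaction center exactly once, so
   duplicated functional groups (e.g. a diacid) never serve as partners.

The persisted store is a deterministic sorted JSON flat file; rebuilding
from the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemgraph import canonical_smiles
from .reactions import (
    ReactionApplicationError,
    ReactionTemplate,
    apply_reaction,
    count_matches,
)

log = logging.getLogger(__name__)

MASS_MIN = 30.0
MASS_MAX = 300.0
MAX_RINGS = 4
MAX_FLUORINE = 3
ALLOWED_ELEMENTS = frozenset(
    {"C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se"}
)

_ACID_O = Chem.MolFromSmarts("[OX2H1;$(O[CX3]=[OX1])]")
_BASIC_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;!$(N[a]);!$(N*=[O,S,N,P]);!$(N[C,S,P]=[O,S,N]);!$(N[N,O])]"
)
_AMMONIUM = Chem.MolFromSmarts("[NX4+;!$([N+]~[-1]);H1,H2,H3]")
_CARBOXYLATE = Chem.MolFromSmarts("[OX1-;$([O-][CX3]=[OX1])]")


class CatalogError(ValueError):
    pass


@dataclass
class BuildingBlock:
    """A curated catalog molecule with its reaction-role annotations."""

    id: str
    smiles: str  # standardized (charged) canonical form, used for scoring
    neutral_smiles: str  # neutral parent, used for matching and reactions
    mass: float  # Da, neutral form
    parent_id: str | None = None  # set on FGA/FGI-derived blocks
    fga_fgi_id: str | None = None
    annotations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return bool(self.annotations)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    def neutral_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.neutral_smiles)


# -- standardization ----------------------------------------------------------

def largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(m: Chem.Mol) -> tuple:
        has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
        return (has_c, m.GetNumAtoms(), canonical_smiles(m))

    return max(frags, key=key)


def standardize(mol: Chem.Mol) -> Chem.Mol:
    """Largest organic fragment; acids deprotonated, basic amines protonated."""
    mol = Chem.Mol(largest_organic_fragment(mol))
    for (idx,) in mol.GetSubstructMatches(_ACID_O):
        atom = mol.GetAtomWithIdx(idx)
        atom.SetFormalCharge(-1)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    for (idx,) in mol.GetSubstructMatches(_BASIC_AMINE):
        atom = mol.GetAtomWithIdx(idx)
        atom.SetFormalCharge(1)
        atom.SetNoImplicit(False)
    Chem.SanitizeMol(mol)
    return mol


def neutral_form(mol: Chem.Mol) -> Chem.Mol:
    """Reverse the protonation/deprotonation wash (reaction-ready parent)."""
    mol = Chem.Mol(mol)
    for (idx,) in mol.GetSubstructMatches(_AMMONIUM):
        atom = mol.GetAtomWithIdx(idx)
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
        atom.SetNoImplicit(False)
    for (idx,) in mol.GetSubstructMatches(_CARBOXYLATE):
        atom = mol.GetAtomWithIdx(idx)
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(False)
    Chem.SanitizeMol(mol)
    return mol


# -- filtering ----------------------------------------------------------------

@dataclass
class FilterResult:
    accepted: bool
    reasons: list[str]  # all failing rules, first one is the reason code

    @property
    def reason(self) -> str | None:
        return self.reasons[0] if self.reasons else None


def load_alerts(path: str | Path | None = None) -> list[tuple[str, Chem.Mol]]:
    if path is None:
        text = resources.files("synthgrow.data").joinpath("alerts.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    alerts = []
    for rec in (doc or {}).get("alerts", []):
        pat = Chem.MolFromSmarts(rec["smarts"])
        if pat is None:
            raise CatalogError(f"bad alert SMARTS for {rec.get('id')}")
        alerts.append((rec["id"], pat))
    return alerts


def filter_block(
    mol: Chem.Mol,
    alerts: list[tuple[str, Chem.Mol]],
    seen: set[str] | None = None,
    *,
    apply_alerts: bool = True,
) -> FilterResult:
    """Evaluate every curation rule; reason code is the first failing rule."""
    reasons: list[str] = []
    mass = Descriptors.MolWt(mol)
    if mass < MASS_MIN or mass > MASS_MAX:
        reasons.append("mass")
    if mol.GetRingInfo().NumRings() > MAX_RINGS:
        reasons.append("rings")
    if any(a.GetSymbol() not in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
        reasons.append("element")
    if sum(a.GetSymbol() == "F" for a in mol.GetAtoms()) > MAX_FLUORINE:
        reasons.append("fluorine")
    if apply_alerts:
        for alert_id, pat in alerts:
            if mol.HasSubstructMatch(pat):
                reasons.append(f"alert:{alert_id}")
                break
    if seen is not None and canonical_smiles(mol) in seen:
        reasons.append("duplicate")
    return FilterResult(accepted=not reasons, reasons=reasons)


# -- preprocessing and annotation ---------------------------------------------

def annotate_block(mol: Chem.Mol, coupling: list[ReactionTemplate]) -> list[tuple[str, int]]:
    """(reaction, component) roles the neutral molecule can serve, exactly-once."""
    annotations = []
    for template in coupling:
        for comp in range(template.n_components):
            if count_matches(mol, template.reactant_pattern(comp)) == 1:
                annotations.append((template.id, comp))
    return annotations


def apply_preprocessing_reactions(
    blocks: list[BuildingBlock],
    fga_fgi: list[ReactionTemplate],
    alerts: list[tuple[str, Chem.Mol]],
    seen: set[str],
    report: dict | None = None,
) -> list[BuildingBlock]:
    """Derive FGA/FGI variants of every block; originals are always kept.

    Derived blocks are filtered on every rule except the alert screen, join
    the duplicate pool, and are not preprocessed recursively.
    """
    out = list(blocks)
    for block in blocks:
        mol = block.neutral_mol()
        for template in fga_fgi:
            if template.n_components != 1:
                raise CatalogError(f"{template.id}: preprocessing templates must be one-component")
            if count_matches(mol, template.reactant_pattern(0)) != 1:
                continue
            try:
                product = apply_reaction(template, [mol])
            except ReactionApplicationError as exc:
                log.warning("preprocessing skipped: %s", exc)
                continue
            std = standardize(product)
            res = filter_block(std, alerts, seen, apply_alerts=False)
            if report is not None:
                report.setdefault("fga_fgi", {}).setdefault(template.id, 0)
                report["fga_fgi"][template.id] += res.accepted
            if not res.accepted:
                continue
            seen.add(canonical_smiles(std))
            out.append(
                BuildingBlock(
                    id=f"{block.id}@{template.id}",
                    smiles=canonical_smiles(std),
                    neutral_smiles=canonical_smiles(neutral_form(std)),
                    mass=Descriptors.MolWt(neutral_form(std)),
                    parent_id=block.id,
                    fga_fgi_id=template.id,
                )
            )
    return out


# -- catalog ------------------------------------------------------------------

@dataclass
class Catalog:
    """Annotated building-block store with a (reaction, component) index."""

    blocks: list[BuildingBlock]
    report: dict

    def __post_init__(self) -> None:
        self._by_id = {b.id: b for b in self.blocks}
        self._partners: dict[tuple[str, int], list[str]] = {}
        for b in self.blocks:
            for rid, comp in b.annotations:
                self._partners.setdefault((rid, comp), []).append(b.id)
        for ids in self._partners.values():
            ids.sort()

    def __len__(self) -> int:
        return len(self.blocks)

    def get(self, block_id: str) -> BuildingBlock:
        return self._by_id[block_id]

    def partners(self, reaction_id: str, component: int) -> list[BuildingBlock]:
        return [self.get(i) for i in self._partners.get((reaction_id, component), [])]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "synthgrow-catalog/1",
            "blocks": [
                {
                    "id": b.id,
                    "smiles": b.smiles,
                    "neutral_smiles": b.neutral_smiles,
                    "mass": round(b.mass, 4),
                    "parent_id": b.parent_id,
                    "fga_fgi_id": b.fga_fgi_id,
                    "annotations": [list(a) for a in b.annotations],
                }
                for b in sorted(self.blocks, key=lambda b: b.id)
            ],
            "report": self.report,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "Catalog":
        with open(path) as fh:
            payload = json.load(fh)
        blocks = [
            BuildingBlock(
                id=rec["id"],
                smiles=rec["smiles"],
                neutral_smiles=rec["neutral_smiles"],
                mass=rec["mass"],
                parent_id=rec.get("parent_id"),
                fga_fgi_id=rec.get("fga_fgi_id"),
                annotations=[tuple(a) for a in rec.get("annotations", [])],
            )
            for rec in payload["blocks"]
        ]
        return cls(blocks=blocks, report=payload.get("report", {}))


def _iter_records(path: Path):
    """Yield (id, raw mol or None, parse_ok) records without sanitizing."""
    if path.suffix.lower() in {".sdf", ".sd"}:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, mol in enumerate(supplier):
            rid = None
            if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name"):
                rid = mol.GetProp("_Name")
            yield rid or f"rec{i + 1}", mol
    else:
        with open(path) as fh:
            n = 0
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                n += 1
                parts = line.split()
                mol = Chem.MolFromSmiles(parts[0], sanitize=False)
                yield (parts[1] if len(parts) > 1 else f"rec{n}"), mol


def build_catalog(
    input_path: str | Path,
    coupling: list[ReactionTemplate],
    fga_fgi: list[ReactionTemplate] | None = None,
    alerts: list[tuple[str, Chem.Mol]] | None = None,
) -> Catalog:
    """Run the full three-stage preparation protocol on a raw catalog file."""
    input_path = Path(input_path)
    if not input_path.exists():
        raise CatalogError(f"no such file: {input_path}")
    alerts = load_alerts() if alerts is None else alerts
    fga_fgi = fga_fgi or []

    report: dict = {
        "input_records": 0,
        "accepted": 0,
        "rejections": {},
        "decisions": {},
        "fga_fgi": {},
        "annotations": {},
    }
    seen: set[str] = set()
    blocks: list[BuildingBlock] = []
    for rid, raw in _iter_records(input_path):
        report["input_records"] += 1
        if raw is None:
            report["rejections"]["parse"] = report["rejections"].get("parse", 0) + 1
            report["decisions"][rid] = "reject:parse"
            continue
        try:
            mol = Chem.Mol(raw)
            Chem.SanitizeMol(mol)
        except Exception:  # noqa: BLE001
            report["rejections"]["valence"] = report["rejections"].get("valence", 0) + 1
            report["decisions"][rid] = "reject:valence"
            continue
        mol = largest_organic_fragment(mol)
        res = filter_block(mol, alerts)
        if res.accepted:
            std = standardize(mol)
            if canonical_smiles(std) in seen:
                res = FilterResult(accepted=False, reasons=["duplicate"])
        if not res.accepted:
            report["rejections"][res.reason] = report["rejections"].get(res.reason, 0) + 1
            report["decisions"][rid] = f"reject:{res.reason}"
            continue
        seen.add(canonical_smiles(std))
        neutral = neutral_form(std)
        blocks.append(
            BuildingBlock(
                id=rid,
                smiles=canonical_smiles(std),
                neutral_smiles=canonical_smiles(neutral),
                mass=Descriptors.MolWt(neutral),
            )
        )
        report["decisions"][rid] = "accept"

    blocks = apply_preprocessing_reactions(blocks, fga_fgi, alerts, seen, report)

    for block in blocks:
        block.annotations = annotate_block(block.neutral_mol(), coupling)
        for rid_comp in block.annotations:
            key = f"{rid_comp[0]}/{rid_comp[1]}"
            report["annotations"][key] = report["annotations"].get(key, 0) + 1

    report["accepted"] = len(blocks)
    report["unusable"] = sum(not b.usable for b in blocks)
    if not blocks:
        raise CatalogError("no building blocks survived preparation")
    return Catalog(blocks=blocks, report=report)
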