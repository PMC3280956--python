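"""Virtual reaction templates: loading, matching, and application.

Reactions are one- or two-component couplings encoded as reaction SMARTS
with atom maps. A reactant is specified only by its reaction center — the
substructure essential for the reaction — so each template applies to a
broad family of reactants with variable R-groups. Every template declares:

* a minimal dummy fragment per component (the smallest molecule satisfying
  that component's reaction center), used to form *dummy products* that let
  the design algorithm score a reaction before committing to a partner
  block; one-component reactions define none,
* a leaving-group formula and, where an invariant reagent contributes atoms
  (condensing agents, reductants), a reagent-gain formula, so that product
  mass equals the reactant masses plus reagent gain minus leaving group,
* provenance fields (name, literature reference, regioisomer group).

A molecule is an eligible reactant for a component only when it matches that
component's pattern *exactly once* (symmetry-reduced), which avoids side
products from duplicated functional groups. All matching and application
happen on neutral-form molecules; charge standardization for scoring lives
in :mod:`synthgrow.blockprep`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from ._formula import formula_mass
from .chemgraph import canonical_smiles, mol_from_smiles

log = logging.getLogger(__name__)

#: tolerance (Da) for the mass bookkeeping self-test
MASS_TOL = 0.05


class ReactionLibraryError(ValueError):
    """Fatal problem in a reaction library file."""


class ReactionApplicationError(RuntimeError):
    """A template could not be applied cleanly; the caller skips the candidate."""


@dataclass
class DummyFragment:
    reaction_id: str
    component_index: int
    molecule: Chem.Mol

    def to_smiles(self) -> str:
        return canonical_smiles(self.molecule)


@dataclass
class ReactionTemplate:
    id: str
    name: str
    n_components: int
    smarts: str
    rxn: AllChem.ChemicalReaction
    dummy_smiles: list[str]
    ring_forming: bool = False
    regioisomer_group: str | None = None
    leaving_group: str | None = None
    reagent_gain: str | None = None
    reference: str = ""

    def reactant_pattern(self, component: int) -> Chem.Mol:
        return self.rxn.GetReactantTemplate(component)

    @property
    def mass_delta(self) -> float:
        """Expected product mass minus summed reactant masses."""
        return formula_mass(self.reagent_gain) - formula_mass(self.leaving_group)


def count_matches(mol: Chem.Mol, pattern: Chem.Mol) -> int:
    """Symmetry-reduced substructure match count (same atom set counts once)."""
    return len(mol.GetSubstructMatches(pattern, uniquify=True))


def matches_exactly_once(mol: Chem.Mol, pattern: Chem.Mol) -> bool:
    return count_matches(mol, pattern) == 1


def minimal_dummy_fragment(template: ReactionTemplate, component: int) -> DummyFragment | None:
    """Minimal molecule realizing a component's reaction center.

    One-component reactions define no dummy fragment (they apply directly).
    """
    if template.n_components == 1:
        return None
    if not 0 <= component < template.n_components:
        raise ReactionLibraryError(
            f"{template.id}: component {component} out of range"
        )
    return DummyFragment(
        reaction_id=template.id,
        component_index=component,
        molecule=mol_from_smiles(template.dummy_smiles[component]),
    )


def apply_reaction(template: ReactionTemplate, reactants: list[Chem.Mol]) -> Chem.Mol:
    """Run a template on 1 or 2 reactants; returns the single sanitized product.

    Preconditions: each reactant matches its component pattern exactly once.
    Symmetric duplicate products collapse to one; anything else (no product,
    several distinct products, sanitization failure) raises
    :class:`ReactionApplicationError` naming the template and reactants.
    """
    if len(reactants) != template.n_components:
        raise ReactionApplicationError(
            f"{template.id}: expected {template.n_components} reactants, got {len(reactants)}"
        )
    tagged = []
    for comp, mol in enumerate(reactants):
        if not matches_exactly_once(mol, template.reactant_pattern(comp)):
            raise ReactionApplicationError(
                f"{template.id}: reactant {comp} ({canonical_smiles(mol)}) does not "
                "match its reaction center exactly once"
            )
        mol = Chem.Mol(mol)
        for atom in mol.GetAtoms():
            atom.SetIntProp("src_component", comp)
        tagged.append(mol)

    product_by_smiles: dict[str, Chem.Mol] = {}
    for prods in template.rxn.RunReactants(tuple(tagged)):
        if len(prods) != 1:
            continue
        prod = prods[0]
        try:
            Chem.SanitizeMol(prod)
        except Exception:  # noqa: BLE001 - RDKit raises several exception types
            continue
        product_by_smiles.setdefault(canonical_smiles(prod), prod)
    if not product_by_smiles:
        raise ReactionApplicationError(
            f"{template.id}: no sanitizable product from "
            f"{[canonical_smiles(m) for m in reactants]}"
        )
    if len(product_by_smiles) > 1:
        raise ReactionApplicationError(
            f"{template.id}: ambiguous products {sorted(product_by_smiles)} from "
            f"{[canonical_smiles(m) for m in reactants]}"
        )
    return next(iter(product_by_smiles.values()))


def atom_provenance(product: Chem.Mol) -> list[int | None]:
    """Which reactant component contributed each product atom (None = new)."""
    prov: list[int | None] = []
    for atom in product.GetAtoms():
        prov.append(
            atom.GetIntProp("src_component") if atom.HasProp("src_component") else None
        )
    return prov


def find_applicable_reactions(
    mol: Chem.Mol, library: list[ReactionTemplate]
) -> list[tuple[ReactionTemplate, int, tuple[int, ...]]]:
    """All (template, component, match) whose center matches mol exactly once."""
    hits = []
    for template in library:
        for comp in range(template.n_components):
            pattern = template.reactant_pattern(comp)
            matches = mol.GetSubstructMatches(pattern, uniquify=True)
            if len(matches) == 1:
                hits.append((template, comp, matches[0]))
    return hits


def _self_test(template: ReactionTemplate) -> None:
    """Round-trip a template on its declared dummy fragments."""
    dummies = [mol_from_smiles(s) for s in template.dummy_smiles]
    for comp, dummy in enumerate(dummies):
        n = count_matches(dummy, template.reactant_pattern(comp))
        if n != 1:
            raise ReactionLibraryError(
                f"{template.id}: dummy fragment {template.dummy_smiles[comp]} matches "
                f"component {comp} pattern {n} times (expected exactly once)"
            )
    product = apply_reaction(template, dummies)
    expected = sum(Descriptors.MolWt(d) for d in dummies) + template.mass_delta
    got = Descriptors.MolWt(product)
    if abs(got - expected) > MASS_TOL:
        raise ReactionLibraryError(
            f"{template.id}: mass bookkeeping off by {got - expected:+.3f} Da "
            f"(product {canonical_smiles(product)}; check leaving_group/reagent_gain)"
        )


def load_reaction_library(path: str | Path | None = None, *, bundled: str | None = None) -> list[ReactionTemplate]:
    """Load and validate a YAML reaction library.

    ``bundled`` names one of the libraries shipped with the package
    ("coupling" or "fga_fgi"); otherwise ``path`` is read. Every template is
    validated by round-tripping on its own dummy fragments; any malformed
    pattern, duplicate ID, or failed self-test is fatal.
    """
    if bundled is not None:
        text = resources.files("synthgrow.data").joinpath(f"{bundled}.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    records = (doc or {}).get("templates") or []
    if not records:
        raise ReactionLibraryError("reaction library is empty")
    templates: list[ReactionTemplate] = []
    seen: set[str] = set()
    for rec in records:
        tid = rec.get("id")
        if not tid:
            raise ReactionLibraryError(f"template without id: {rec!r}")
        if tid in seen:
            raise ReactionLibraryError(f"duplicate template id {tid!r}")
        seen.add(tid)
        try:
            rxn = AllChem.ReactionFromSmarts(rec["smarts"])
        except Exception as exc:  # noqa: BLE001
            raise ReactionLibraryError(f"{tid}: bad reaction SMARTS: {exc}") from exc
        if rxn is None:
            raise ReactionLibraryError(f"{tid}: bad reaction SMARTS")
        n_components = rxn.GetNumReactantTemplates()
        if n_components not in (1, 2):
            raise ReactionLibraryError(f"{tid}: {n_components} components (must be 1 or 2)")
        if rxn.GetNumProductTemplates() != 1:
            raise ReactionLibraryError(f"{tid}: must yield exactly one product")
        dummies = rec.get("dummy_fragments") or []
        if len(dummies) != n_components:
            raise ReactionLibraryError(
                f"{tid}: {len(dummies)} dummy fragments for {n_components} components"
            )
        template = ReactionTemplate(
            id=tid,
            name=rec.get("name", tid),
            n_components=n_components,
            smarts=rec["smarts"],
            rxn=rxn,
            dummy_smiles=[str(s) for s in dummies],
            ring_forming=bool(rec.get("ring_forming", False)),
            regioisomer_group=rec.get("regioisomer_group"),
            leaving_group=rec.get("leaving_group"),
            reagent_gain=rec.get("reagent_gain"),
            reference=rec.get("reference", ""),
        )
        _self_test(template)
        templates.append(template)
    return templates
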