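"""Deterministic reaction-driven growing of candidate ligands.

Designs grow from top-scoring start blocks through repeated extension
cycles. Each cycle has two steps: (1) every reaction applicable to the
current intermediate Z is ranked by applying it with the complementary
minimal dummy fragment and scoring the resulting *dummy product* (a
one-component reaction competes with its actual product), and the
top-scoring reaction(s) — all exact ties — proceed; (2) for each selected
two-component reaction every annotated partner block is coupled to Z, all
products are scored, and the top-scoring product(s) (ties, capped at the
beam width) become the next intermediates.

Stop control: while Z is below the lower mass bound (70% of the reference
mass) every extension is accepted even if the score drops; once the lower
bound is crossed a further step is accepted only if it strictly improves
the score and stays at or below the upper bound (130%), otherwise the
previous intermediate is finalized. A pathway is interrupted
unconditionally after the maximum number of synthesis steps. Every design
carries its full synthesis route (reactions, block IDs with FGA/FGI
provenance, literature references) and replaying the route reproduces the
product exactly. The whole algorithm is deterministic: ties are broken by
score, then canonical SMILES, then block ID.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import Descriptors

from .blockprep import BuildingBlock, Catalog, standardize
from .chemgraph import build_graph, canonical_smiles
from .kernel import DEFAULT_ALPHA, KernelParams, molecule_similarity
from .reactions import (
    ReactionApplicationError,
    ReactionTemplate,
    apply_reaction,
    find_applicable_reactions,
    minimal_dummy_fragment,
)
from .reduced_graph import build_reduced_graph

log = logging.getLogger(__name__)


class DesignError(RuntimeError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """Run parameters; the algorithm is deterministic (no seed)."""

    n_starts: int = 200
    beam_width: int = 10
    max_steps: int = 4
    mass_low_frac: float = 0.70
    mass_high_frac: float = 1.30
    representation: str = "reduced"  # {"molgraph", "reduced"}
    alpha: float | None = None  # None -> representation default
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.mass_low_frac < 1 < self.mass_high_frac:
            raise ValueError("mass window must satisfy 0 < low < 1 < high")
        if self.beam_width < 1 or self.max_steps < 1 or self.n_starts < 1:
            raise ValueError("beam_width, max_steps and n_starts must be >= 1")
        if self.representation not in DEFAULT_ALPHA:
            raise ValueError(f"unknown representation {self.representation!r}")

    @property
    def kernel_params(self) -> KernelParams:
        alpha = DEFAULT_ALPHA[self.representation] if self.alpha is None else self.alpha
        return KernelParams(alpha=alpha, tol=self.tol, max_iter=self.max_iter)


@dataclass
class RouteStep:
    reaction_id: str
    reaction_name: str
    component_of_intermediate: int  # which component Z served as
    partner_block_id: str | None  # None for one-component reactions
    partner_parent_id: str | None
    partner_fga_fgi_id: str | None
    product_smiles: str  # neutral canonical form after this step
    score: float = 0.0
    mass: float = 0.0
    reference: str = ""

    def to_json(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "reaction_name": self.reaction_name,
            "component_of_intermediate": self.component_of_intermediate,
            "partner_block_id": self.partner_block_id,
            "partner_parent_id": self.partner_parent_id,
            "partner_fga_fgi_id": self.partner_fga_fgi_id,
            "product_smiles": self.product_smiles,
            "score": self.score,
            "mass": self.mass,
            "reference": self.reference,
        }


@dataclass
class SynthesisRoute:
    start_block_id: str
    steps: list[RouteStep]
    final_smiles: str
    score: float
    mass: float
    finalize_reason: str  # {"score_rule", "no_reaction", "step_cap"}
    mass_flag: str  # {"in_window", "below_mass_window", "above_mass_window"}

    def to_json(self) -> dict:
        return {
            "schema": "synthgrow-route/1",
            "start_block_id": self.start_block_id,
            "steps": [s.to_json() for s in self.steps],
            "final_smiles": self.final_smiles,
            "score": self.score,
            "mass": self.mass,
            "finalize_reason": self.finalize_reason,
            "mass_flag": self.mass_flag,
        }


@dataclass
class DesignState:
    """A growing intermediate product Z with its route so far."""

    mol: Chem.Mol  # neutral form
    smiles: str
    score: float
    mass: float
    steps: list[RouteStep]
    start_block_id: str

    @property
    def steps_taken(self) -> int:
        return len(self.steps)


class Scorer:
    """Similarity-to-reference scoring with a canonical-SMILES cache.

    Returns None for molecules that cannot be scored (reduced-graph vertex
    above the degree limit); such candidates are discarded.
    """

    def __init__(self, reference: Chem.Mol, config: DesignConfig) -> None:
        self.config = config
        self.params = config.kernel_params
        self.ref_graph = self._represent(standardize(reference))
        if self.ref_graph is None:
            raise DesignError("reference molecule exceeds the degree limit; cannot score")
        self.ref_mass = Descriptors.MolWt(reference)
        self._cache: dict[str, float | None] = {}

    def _represent(self, std_mol: Chem.Mol):
        graph = build_graph(std_mol)
        if self.config.representation == "molgraph":
            return graph
        rg = build_reduced_graph(graph)
        return None if rg.rejected else rg

    def score_neutral(self, mol: Chem.Mol) -> float | None:
        key = canonical_smiles(mol)
        if key not in self._cache:
            try:
                rep = self._represent(standardize(Chem.MolFromSmiles(key)))
            except Exception:  # noqa: BLE001 - unscorable candidates are skipped
                rep = None
            self._cache[key] = (
                None if rep is None else molecule_similarity(self.ref_graph, rep, self.params)
            )
        return self._cache[key]

    def score_block(self, block: BuildingBlock) -> float | None:
        return self.score_neutral(block.neutral_mol())


def select_start_fragments(
    catalog: Catalog, scorer: Scorer, config: DesignConfig
) -> list[tuple[BuildingBlock, float]]:
    """All catalog blocks ranked by similarity to the reference.

    Ties break by canonical form then block ID. Unscorable blocks are
    omitted. The design loop consumes this ranking lazily, extending past
    ``n_starts`` when pathways die.
    """
    scored = []
    for block in catalog.blocks:
        s = scorer.score_block(block)
        if s is None:
            continue
        scored.append((block, s))
    scored.sort(key=lambda bs: (-bs[1], bs[0].neutral_smiles, bs[0].id))
    if config.n_starts > len(scored):
        log.warning(
            "n_starts=%d exceeds catalog size %d; using whole catalog",
            config.n_starts, len(scored),
        )
    return scored


def _candidate_sort_key(cand: tuple[float, str, str, RouteStep]) -> tuple:
    score, smiles, block_id, _ = cand
    return (-score, smiles, block_id)


def extension_cycle(
    state: DesignState,
    catalog: Catalog,
    library: list[ReactionTemplate],
    scorer: Scorer,
    config: DesignConfig,
) -> list[DesignState]:
    """One two-step extension of Z; at most ``beam_width`` new states.

    Returns an empty list when no reaction applies or nothing survives
    sanitization/scoring (the pathway dies at the caller).
    """
    hits = find_applicable_reactions(state.mol, library)
    # Step 1: rank reactions by their dummy products
    ranked: list[tuple[float, str, int, Chem.Mol | None]] = []  # score, tid, comp, 1-comp product
    by_id = {t.id: t for t in library}
    for template, comp, _match in hits:
        try:
            if template.n_components == 1:
                product = apply_reaction(template, [state.mol])
            else:
                other = 1 - comp
                dummy = minimal_dummy_fragment(template, other)
                reactants: list[Chem.Mol] = [None, None]  # type: ignore[list-item]
                reactants[comp] = state.mol
                reactants[other] = dummy.molecule
                product = apply_reaction(template, reactants)
        except ReactionApplicationError as exc:
            log.debug("dummy product failed: %s", exc)
            continue
        s = scorer.score_neutral(product)
        if s is None:
            continue
        ranked.append((s, template.id, comp, product if template.n_components == 1 else None))
    if not ranked:
        return []
    best = max(r[0] for r in ranked)
    selected = sorted((r for r in ranked if r[0] == best), key=lambda r: (r[1], r[2]))

    # Step 2: enumerate partner blocks for the selected reaction(s)
    candidates: list[tuple[float, str, str, RouteStep]] = []
    for s, tid, comp, one_comp_product in selected:
        template = by_id[tid]
        if template.n_components == 1:
            step = RouteStep(
                reaction_id=tid,
                reaction_name=template.name,
                component_of_intermediate=0,
                partner_block_id=None,
                partner_parent_id=None,
                partner_fga_fgi_id=None,
                product_smiles=canonical_smiles(one_comp_product),
                score=s,
                mass=Descriptors.MolWt(one_comp_product),
                reference=template.reference,
            )
            candidates.append((s, step.product_smiles, "", step))
            continue
        other = 1 - comp
        for block in catalog.partners(tid, other):
            reactants = [None, None]  # type: ignore[list-item]
            reactants[comp] = state.mol
            reactants[other] = block.neutral_mol()
            try:
                product = apply_reaction(template, reactants)
            except ReactionApplicationError as exc:
                log.debug("product failed: %s", exc)
                continue
            ps = scorer.score_neutral(product)
            if ps is None:
                continue
            step = RouteStep(
                reaction_id=tid,
                reaction_name=template.name,
                component_of_intermediate=comp,
                partner_block_id=block.id,
                partner_parent_id=block.parent_id,
                partner_fga_fgi_id=block.fga_fgi_id,
                product_smiles=canonical_smiles(product),
                score=ps,
                mass=Descriptors.MolWt(product),
                reference=template.reference,
            )
            candidates.append((ps, step.product_smiles, block.id, step))
    if not candidates:
        return []
    top = max(c[0] for c in candidates)
    winners = sorted((c for c in candidates if c[0] == top), key=_candidate_sort_key)
    winners = winners[: config.beam_width]
    out = []
    for score, smiles, _bid, step in winners:
        mol = Chem.MolFromSmiles(smiles)
        out.append(
            DesignState(
                mol=mol,
                smiles=smiles,
                score=score,
                mass=step.mass,
                steps=state.steps + [step],
                start_block_id=state.start_block_id,
            )
        )
    return out


def check_stop(
    prev: DesignState, nxt: DesignState, reference_mass: float, config: DesignConfig
) -> str:
    """Decide on one proposed extension: "accept" or "finalize_prev".

    Below the lower mass bound every extension is accepted, even on a score
    drop; at or above it, only strict score improvement within the upper
    mass bound. The step-count cap is enforced by the caller.
    """
    low = config.mass_low_frac * reference_mass
    high = config.mass_high_frac * reference_mass
    if prev.mass < low:
        return "accept"
    if nxt.score > prev.score and nxt.mass <= high:
        return "accept"
    return "finalize_prev"


def _finalize(state: DesignState, reason: str, scorer: Scorer, config: DesignConfig) -> SynthesisRoute:
    low = config.mass_low_frac * scorer.ref_mass
    high = config.mass_high_frac * scorer.ref_mass
    if state.mass < low:
        flag = "below_mass_window"
    elif state.mass > high:
        flag = "above_mass_window"
    else:
        flag = "in_window"
    return SynthesisRoute(
        start_block_id=state.start_block_id,
        steps=list(state.steps),
        final_smiles=state.smiles,
        score=state.score,
        mass=state.mass,
        finalize_reason=reason,
        mass_flag=flag,
    )


def _grow_one_start(
    block: BuildingBlock,
    score: float,
    catalog: Catalog,
    library: list[ReactionTemplate],
    scorer: Scorer,
    config: DesignConfig,
) -> list[SynthesisRoute]:
    mol = block.neutral_mol()
    start = DesignState(
        mol=mol,
        smiles=block.neutral_smiles,
        score=score,
        mass=block.mass,
        steps=[],
        start_block_id=block.id,
    )
    active = [start]
    finals: list[SynthesisRoute] = []
    while active:
        nxt_active: list[DesignState] = []
        for state in active:
            if state.steps_taken >= config.max_steps:
                finals.append(_finalize(state, "step_cap", scorer, config))
                continue
            candidates = extension_cycle(state, catalog, library, scorer, config)
            accepted = [
                c for c in candidates
                if check_stop(state, c, scorer.ref_mass, config) == "accept"
            ]
            if accepted:
                nxt_active.extend(accepted)
            elif state.steps_taken >= 1:
                reason = "score_rule" if candidates else "no_reaction"
                finals.append(_finalize(state, reason, scorer, config))
            # a start that cannot take a single step yields no route
        nxt_active.sort(key=lambda s: (-s.score, s.smiles, s.start_block_id))
        active = nxt_active[: config.beam_width]
    return finals


def run_design(
    catalog: Catalog,
    reference: Chem.Mol,
    library: list[ReactionTemplate],
    config: DesignConfig,
) -> list[SynthesisRoute]:
    """Full design run: at least ``n_starts`` productive starts if possible.

    Start blocks are consumed in similarity rank order; a start that dies
    without producing a route is skipped and the start budget extends by
    one. Output is sorted by score (desc), then final canonical form, then
    start block and route length; repeated runs are bit-identical.
    """
    scorer = Scorer(reference, config)
    ranking = select_start_fragments(catalog, scorer, config)
    if not ranking:
        raise DesignError("catalog contains no scorable building blocks")
    routes: list[SynthesisRoute] = []
    productive = 0
    for block, score in ranking:
        if productive >= config.n_starts:
            break
        finals = _grow_one_start(block, score, catalog, library, scorer, config)
        if finals:
            productive += 1
            routes.extend(finals)
    if not routes:
        raise DesignError(
            "no routes could be produced; check reaction coverage and mass window "
            f"(reference mass {scorer.ref_mass:.1f} Da, catalog of {len(catalog)} blocks)"
        )
    routes.sort(key=lambda r: (-r.score, r.final_smiles, r.start_block_id, len(r.steps)))
    return routes


def replay_route(
    route: SynthesisRoute, catalog: Catalog, library: list[ReactionTemplate]
) -> str:
    """Re-run a route's steps through the reaction engine; returns the final
    canonical form (must equal ``route.final_smiles``)."""
    by_id = {t.id: t for t in library}
    mol = catalog.get(route.start_block_id).neutral_mol()
    for step in route.steps:
        template = by_id[step.reaction_id]
        if template.n_components == 1:
            mol = apply_reaction(template, [mol])
        else:
            reactants = [None, None]  # type: ignore[list-item]
            reactants[step.component_of_intermediate] = mol
            other = 1 - step.component_of_intermediate
            reactants[other] = catalog.get(step.partner_block_id).neutral_mol()
            mol = apply_reaction(template, reactants)
    return canonical_smiles(mol)


# -- output writers -----------------------------------------------------------

def collapse_duplicates(routes: list[SynthesisRoute]) -> dict[str, list[SynthesisRoute]]:
    """Group routes by final product; insertion order follows route order."""
    grouped: dict[str, list[SynthesisRoute]] = {}
    for route in routes:
        grouped.setdefault(route.final_smiles, []).append(route)
    return grouped


def write_outputs(routes: list[SynthesisRoute], out_dir: str | Path) -> None:
    """Write designs.sdf (unique products), routes.json, summary.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grouped = collapse_duplicates(routes)
    writer = Chem.SDWriter(str(out_dir / "designs.sdf"))
    writer.SetForceV3000(False)
    for i, (smiles, group) in enumerate(grouped.items(), 1):
        mol = Chem.MolFromSmiles(smiles)
        best = group[0]
        mol.SetProp("_Name", f"design{i}")
        mol.SetProp("score", f"{best.score:.6f}")
        mol.SetProp("mass", f"{best.mass:.2f}")
        mol.SetProp("n_routes", str(len(group)))
        mol.SetProp("mass_flag", best.mass_flag)
        mol.SetProp("finalize_reason", best.finalize_reason)
        writer.write(mol)
    writer.close()
    with open(out_dir / "routes.json", "w") as fh:
        json.dump([r.to_json() for r in routes], fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("rank\tsmiles\tscore\tmass\tsteps\tstart_block\tmass_flag\treason\n")
        for i, route in enumerate(routes, 1):
            fh.write(
                f"{i}\t{route.final_smiles}\t{route.score:.6f}\t{route.mass:.2f}\t"
                f"{len(route.steps)}\t{route.start_block_id}\t{route.mass_flag}\t"
                f"{route.finalize_reason}\n"
            )
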