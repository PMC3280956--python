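"""Design engine: ranking, extension cycles, stop rules, full-run invariants.

The exhaustive-tree oracle below re-implements the greedy/beam/stop rules
directly as a recursive enumeration over a small fixture, independent of the
DesignState machinery it checks.
"""

import json

import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from synthgrow.blockprep import build_catalog
from synthgrow.chemgraph import canonical_smiles, mol_from_smiles
from synthgrow.design import (
    DesignConfig,
    DesignError,
    DesignState,
    Scorer,
    check_stop,
    collapse_duplicates,
    extension_cycle,
    replay_route,
    run_design,
    select_start_fragments,
)
from synthgrow.kernel import molecule_similarity
from synthgrow.reactions import apply_reaction, find_applicable_reactions, minimal_dummy_fragment

REFERENCE = "O=C(NCCc1ccccc1)c1ccccc1"  # N-phenethylbenzamide, 225.3 Da

SMALL_BLOCKS = [
    ("OC(=O)c1ccccc1", "acid_benzoic"),
    ("OC(=O)C1CCCCC1", "acid_cyclohexane"),
    ("NCCc1ccccc1", "amine_phenethyl"),
    ("NCCC", "amine_propyl"),
    ("OCc1ccccc1", "alcohol_benzyl"),
]


@pytest.fixture(scope="module")
def small_catalog(tmp_path_factory, coupling_library):
    path = tmp_path_factory.mktemp("small") / "blocks.smi"
    path.write_text("".join(f"{s}\t{i}\n" for s, i in SMALL_BLOCKS))
    lib = [t for t in coupling_library if t.id in ("amide_coupling", "ester_formation")]
    return build_catalog(path, lib, []), lib


@pytest.fixture(scope="module")
def small_config():
    return DesignConfig(n_starts=3, representation="reduced")


def oracle_design(catalog, reference_smiles, library, config):
    """Independent recursive enumeration honoring the greedy/beam/stop rules."""
    scorer = Scorer(mol_from_smiles(reference_smiles), config)
    ref_mass = scorer.ref_mass
    low, high = config.mass_low_frac * ref_mass, config.mass_high_frac * ref_mass

    def candidates(smiles):
        mol = Chem.MolFromSmiles(smiles)
        dummy_ranked = []
        for template, comp, _ in find_applicable_reactions(mol, library):
            other = 1 - comp
            reactants = [None, None]
            reactants[comp] = mol
            reactants[other] = minimal_dummy_fragment(template, other).molecule
            product = apply_reaction(template, reactants)
            dummy_ranked.append((scorer.score_neutral(product), template, comp))
        if not dummy_ranked:
            return []
        best = max(s for s, _, _ in dummy_ranked)
        out = []
        for s, template, comp in dummy_ranked:
            if s != best:
                continue
            other = 1 - comp
            for block in catalog.partners(template.id, other):
                reactants = [None, None]
                reactants[comp] = mol
                reactants[other] = block.neutral_mol()
                product = apply_reaction(template, reactants)
                psmi = canonical_smiles(product)
                out.append((scorer.score_neutral(product), psmi, block.id))
        top = max(c[0] for c in out)
        winners = sorted([c for c in out if c[0] == top], key=lambda c: (c[1], c[2]))
        return winners[: config.beam_width]

    finals = []

    def extend(smiles, score, mass, depth, start):
        if depth >= config.max_steps:
            finals.append((start, smiles, score, "step_cap"))
            return
        cands = candidates(smiles)
        accepted = []
        for s2, smi2, _bid in cands:
            m2 = Descriptors.MolWt(Chem.MolFromSmiles(smi2))
            if mass < low or (s2 > score and m2 <= high):
                accepted.append((s2, smi2, m2))
        if not accepted:
            if depth >= 1:
                finals.append((start, smiles, score, "score_rule" if cands else "no_reaction"))
            return
        for s2, smi2, m2 in accepted:
            extend(smi2, s2, m2, depth + 1, start)

    productive = 0
    for block, score in select_start_fragments(catalog, scorer, config):
        if productive >= config.n_starts:
            break
        before = len(finals)
        extend(block.neutral_smiles, score, block.mass, 0, block.id)
        if len(finals) > before:
            productive += 1
    return finals


class TestStartSelection:
    def test_reference_in_catalog_ranks_first(self, small_catalog, small_config):
        catalog, _lib = small_catalog
        scorer = Scorer(mol_from_smiles("NCCc1ccccc1"), small_config)
        ranked = select_start_fragments(catalog, scorer, small_config)
        assert ranked[0][0].id == "amine_phenethyl"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_order_matches_brute_force_scoring(self, small_catalog, small_config):
        catalog, _lib = small_catalog
        scorer = Scorer(mol_from_smiles(REFERENCE), small_config)
        ranked = select_start_fragments(catalog, scorer, small_config)
        params = small_config.kernel_params
        expected = []
        for block in catalog.blocks:
            rep = scorer._represent(Chem.MolFromSmiles(block.smiles))
            expected.append((block.id, molecule_similarity(scorer.ref_graph, rep, params)))
        expected.sort(key=lambda t: -t[1])
        assert [b.id for b, _ in ranked][: len(expected)] == [i for i, _ in expected]


class TestCheckStop:
    def _state(self, score, mass):
        return DesignState(mol=None, smiles="", score=score, mass=mass, steps=[], start_block_id="s")

    def test_below_lower_bound_accepts_score_drop(self):
        cfg = DesignConfig()
        # prev at 60% of a 100 Da reference, next scores lower -> still accepted
        assert check_stop(self._state(0.9, 60.0), self._state(0.5, 90.0), 100.0, cfg) == "accept"

    def test_above_lower_bound_requires_improvement(self):
        cfg = DesignConfig()
        assert check_stop(self._state(0.9, 80.0), self._state(0.5, 95.0), 100.0, cfg) == "finalize_prev"
        assert check_stop(self._state(0.5, 80.0), self._state(0.9, 95.0), 100.0, cfg) == "accept"

    def test_equal_score_is_not_improvement(self):
        cfg = DesignConfig()
        assert check_stop(self._state(0.7, 80.0), self._state(0.7, 95.0), 100.0, cfg) == "finalize_prev"

    def test_upper_mass_bound_finalizes(self):
        cfg = DesignConfig()
        assert check_stop(self._state(0.5, 80.0), self._state(0.9, 135.0), 100.0, cfg) == "finalize_prev"


class TestExtensionCycle:
    def test_only_top_scoring_reaction_enumerated(self, small_catalog, small_config):
        catalog, lib = small_catalog
        scorer = Scorer(mol_from_smiles(REFERENCE), small_config)
        acid = catalog.get("acid_benzoic")
        state = DesignState(
            mol=acid.neutral_mol(), smiles=acid.neutral_smiles,
            score=scorer.score_block(acid), mass=acid.mass, steps=[], start_block_id=acid.id,
        )
        # reference is an amide: the amide dummy product must outrank the ester
        out = extension_cycle(state, catalog, lib, scorer, small_config)
        assert out
        assert {s.steps[-1].reaction_id for s in out} == {"amide_coupling"}

    def test_beam_cap_with_twelve_way_tie(self, coupling_library, tmp_path):
        # 12 hexylamine isomers: same pharmacophore-type multiset and size, so
        # with alpha=0 every amide product scores identically -> 10 survive
        isomers = [
            "NCCCCCC", "NCCCCC(C)", "NCCCC(C)C", "NCCC(C)CC", "NCC(C)CCC",
            "NC(C)CCCC", "NCC(CC)CC", "NCCC(C)(C)C", "NCC(C)(C)CC",
            "NC(C)C(C)CC", "NC(CC)CCC", "NCC(C)C(C)C",
        ]
        path = tmp_path / "amines.smi"
        path.write_text("OC(=O)c1ccccc1\tacid\n" + "".join(
            f"{s}\tam{i}\n" for i, s in enumerate(isomers)))
        lib = [t for t in coupling_library if t.id == "amide_coupling"]
        catalog = build_catalog(path, lib, [])
        cfg = DesignConfig(n_starts=1, representation="molgraph", alpha=0.0)
        scorer = Scorer(mol_from_smiles("O=C(NCCCCCC)c1ccccc1"), cfg)
        acid = catalog.get("acid")
        state = DesignState(
            mol=acid.neutral_mol(), smiles=acid.neutral_smiles,
            score=scorer.score_block(acid), mass=acid.mass, steps=[], start_block_id="acid",
        )
        out = extension_cycle(state, catalog, lib, scorer, cfg)
        assert len(out) == cfg.beam_width == 10
        assert len({s.score for s in out}) == 1

    def test_dead_molecule_gives_empty_set(self, small_catalog, small_config):
        catalog, lib = small_catalog
        scorer = Scorer(mol_from_smiles(REFERENCE), small_config)
        toluene = mol_from_smiles("Cc1ccccc1")
        state = DesignState(
            mol=toluene, smiles=canonical_smiles(toluene), score=0.5,
            mass=92.1, steps=[], start_block_id="x",
        )
        assert extension_cycle(state, catalog, lib, scorer, small_config) == []


class TestRunDesign:
    def test_matches_exhaustive_tree_oracle(self, small_catalog, small_config):
        catalog, lib = small_catalog
        routes = run_design(catalog, mol_from_smiles(REFERENCE), lib, small_config)
        got = sorted(
            (r.start_block_id, r.final_smiles, round(r.score, 9), r.finalize_reason)
            for r in routes
        )
        expected = sorted(
            (start, smi, round(score, 9), reason)
            for start, smi, score, reason in oracle_design(catalog, REFERENCE, lib, small_config)
        )
        assert got == expected

    def test_routes_replay_exactly(self, small_catalog, small_config):
        catalog, lib = small_catalog
        routes = run_design(catalog, mol_from_smiles(REFERENCE), lib, small_config)
        for route in routes:
            assert replay_route(route, catalog, lib) == route.final_smiles

    def test_mass_window_for_score_rule_finals(self, prepared_catalog, coupling_library):
        cfg = DesignConfig(n_starts=4, representation="reduced")
        routes = run_design(
            prepared_catalog, mol_from_smiles(REFERENCE), coupling_library, cfg
        )
        low, high = 0.70 * 225.29, 1.30 * 225.29
        for route in routes:
            if route.finalize_reason == "score_rule":
                assert low - 0.1 <= route.mass <= high + 0.1
                assert route.mass_flag == "in_window"

    def test_score_monotone_above_lower_bound(self, prepared_catalog, coupling_library):
        cfg = DesignConfig(n_starts=4, representation="reduced")
        ref_mass = Descriptors.MolWt(mol_from_smiles(REFERENCE))
        routes = run_design(
            prepared_catalog, mol_from_smiles(REFERENCE), coupling_library, cfg
        )
        for route in routes:
            crossed = False
            prev_score = None
            for step in route.steps:
                if crossed:
                    assert step.score > prev_score
                prev_score = step.score
                if step.mass >= 0.70 * ref_mass:
                    crossed = True

    def test_at_least_n_productive_starts(self, prepared_catalog, coupling_library):
        cfg = DesignConfig(n_starts=3, representation="reduced")
        routes = run_design(
            prepared_catalog, mol_from_smiles(REFERENCE), coupling_library, cfg
        )
        assert len({r.start_block_id for r in routes}) >= 3

    def test_dead_start_skipped_and_budget_extended(self, coupling_library, tmp_path):
        # toluene offers no attachment point; it ranks first against itself
        # as reference, dies, and the start budget moves on
        path = tmp_path / "blocks.smi"
        path.write_text(
            "Cc1ccccc1\ttoluene\nOC(=O)c1ccccc1\tacid\nNCCc1ccccc1\tamine1\nNCCC\tamine2\n"
        )
        lib = [t for t in coupling_library if t.id == "amide_coupling"]
        catalog = build_catalog(path, lib, [])
        cfg = DesignConfig(n_starts=2, representation="reduced")
        routes = run_design(catalog, mol_from_smiles("Cc1ccccc1CCNC(C)=O"), lib, cfg)
        starts = {r.start_block_id for r in routes}
        assert "toluene" not in starts
        assert len(starts) >= 2

    def test_byte_identical_repeat_runs(self, small_catalog, small_config):
        catalog, lib = small_catalog
        ref = mol_from_smiles(REFERENCE)
        a = json.dumps([r.to_json() for r in run_design(catalog, ref, lib, small_config)])
        b = json.dumps([r.to_json() for r in run_design(catalog, ref, lib, small_config)])
        assert a == b

    def test_zero_routes_fatal(self, coupling_library, tmp_path):
        path = tmp_path / "blocks.smi"
        path.write_text("Cc1ccccc1\ttoluene\n")
        lib = [t for t in coupling_library if t.id == "amide_coupling"]
        catalog = build_catalog(path, lib, [])
        with pytest.raises(DesignError):
            run_design(catalog, mol_from_smiles(REFERENCE), lib, DesignConfig(n_starts=1))

    def test_duplicate_finals_collapsed_with_routes_retained(self, small_catalog, small_config):
        catalog, lib = small_catalog
        routes = run_design(catalog, mol_from_smiles(REFERENCE), lib, small_config)
        grouped = collapse_duplicates(routes)
        assert sum(len(v) for v in grouped.values()) == len(routes)
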