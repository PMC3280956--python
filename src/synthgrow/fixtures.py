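"""Deterministic synthetic building-block catalog for tests and demos.

The generator enumerates scaffold x functional-group combinations — most
records carry a single reactive group, plus a few bifunctional linkers whose
two *different* groups each occur exactly once (multi-step growth needs
them; the exactly-once rule is about repeated groups) — and appends planted
violations of the curation filters. Alongside the catalog it writes a manifest that
states, *by construction*, the expected accept/reject outcome, the expected
reaction-role annotations, and the expected FGA/FGI-derived children of
every record — an independent oracle for the catalog-preparation pipeline,
authored from the chemistry of each group rather than computed by it.

The catalog emulates a small vendor catalog with full coverage of the
shipped coupling chemistry (at least two partner blocks per reaction
component, counting FGA/FGI-derived handles); it does not emulate the
property distributions of a real vendor catalog.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["FixtureSpec", "generate_catalog", "FixtureError"]


class FixtureError(ValueError):
    pass


# primary-amine roles (H2 nitrogen): every amine-consuming component
_AMINE1 = [
    ["amide_coupling", 1], ["sulfonamide_formation", 1], ["buchwald_amination", 1],
    ["n_alkylation", 1], ["reductive_amination", 1], ["carbamate_formation", 1],
    ["urea_formation", 1], ["thiourea_formation", 1], ["paal_knorr_pyrrole", 1],
]
# secondary-amine roles (H1): as above minus the H2-only reactions
_AMINE2 = [a for a in _AMINE1 if a[0] not in ("reductive_amination", "paal_knorr_pyrrole")]
_ACID = [["amide_coupling", 0], ["ester_formation", 0], ["benzimidazole_formation", 1]]
_ALCOHOL = [["ester_formation", 1], ["sulfonate_ester_formation", 1], ["williamson_ether", 1]]
_AZIDE = [["triazole_click_14", 0], ["triazole_click_15", 0]]

# scaffold name -> SMILES template ({} replaced by the group fragment, which
# always starts at its attachment atom)
_SCAFFOLDS = {
    "phenyl": "c1ccc({})cc1",
    "p-tolyl": "Cc1ccc({})cc1",
    "pyridinyl": "c1ccc({})nc1",
    "anisyl": "COc1ccc({})cc1",
    "naphthyl": "c1ccc2cc({})ccc2c1",
    "cyclohexyl": "C1CCC({})CC1",
    "benzyl": "C({})c1ccccc1",
    "phenethyl": "c1ccccc1CC{}",
    "methyl": "C{}",
    "ethyl": "CC{}",
    "propyl": "CCC{}",
    "butyl": "CCCC{}",
}


@dataclass(frozen=True)
class _Child:
    fga_fgi_id: str
    fragment: str  # group fragment of the derived block, same scaffold
    annotations: tuple


@dataclass(frozen=True)
class _Group:
    name: str
    fragment: str
    scaffolds: tuple[str, ...]
    annotations: tuple
    children: tuple[_Child, ...] = ()


def _t(rows) -> tuple:
    return tuple(tuple(r) for r in rows)


_GROUPS = [
    _Group("acid", "C(=O)O", ("phenyl", "pyridinyl"), _t(_ACID)),
    _Group("alcohol", "CO", ("phenyl", "benzyl"), _t(_ALCOHOL)),
    _Group(
        "primary_amine", "N", ("propyl", "phenethyl"), _t(_AMINE1),
        (_Child("fga_amine_to_isocyanate", "N=C=O", _t([["urea_formation", 0]])),),
    ),
    _Group("aldehyde", "C=O", ("phenyl", "cyclohexyl"),
           _t([["reductive_amination", 0], ["acylhydrazone_formation", 0]])),
    _Group(
        "aryl_bromide", "Br", ("phenyl", "pyridinyl", "anisyl"),
        _t([["suzuki_coupling", 0], ["buchwald_amination", 0], ["sonogashira_coupling", 0]]),
        (_Child("fgi_bromide_to_boronic_acid", "B(O)O", _t([["suzuki_coupling", 1]])),),
    ),
    _Group(
        "benzylic_bromide", "CBr", ("phenyl", "p-tolyl"),
        _t([["williamson_ether", 0], ["n_alkylation", 0]]),
        (_Child("fgi_halide_to_azide", "CN=[N+]=[N-]", _t(_AZIDE)),),
    ),
    _Group(
        "alpha_bromoketone", "C(=O)CBr", ("phenyl", "methyl"),
        _t([["hantzsch_thiazole", 0], ["williamson_ether", 0], ["n_alkylation", 0]]),
        (_Child("fgi_halide_to_azide", "C(=O)CN=[N+]=[N-]", _t(_AZIDE)),),
    ),
    _Group("boronic_acid", "B(O)O", ("p-tolyl", "naphthyl"), _t([["suzuki_coupling", 1]])),
    _Group("sulfonyl_chloride", "S(=O)(=O)Cl", ("phenyl", "p-tolyl"),
           _t([["sulfonamide_formation", 0], ["sulfonate_ester_formation", 0]])),
    _Group("chloroformate", "OC(=O)Cl", ("ethyl", "benzyl"), _t([["carbamate_formation", 0]])),
    _Group("isothiocyanate", "N=C=S", ("phenyl", "methyl"), _t([["thiourea_formation", 0]])),
    _Group("thioamide", "C(=S)N", ("phenyl", "methyl"), _t([["hantzsch_thiazole", 1]])),
    _Group("diketone_1_4", "C(=O)CCC(=O)C", ("phenyl", "methyl"), _t([["paal_knorr_pyrrole", 0]])),
    _Group("diketone_1_3", "C(=O)CC(=O)C", ("phenyl", "methyl"),
           _t([["pyrazole_formation_a", 0], ["pyrazole_formation_b", 0]])),
    _Group("hydrazine", "NN", ("phenyl", "methyl"),
           _t([["pyrazole_formation_a", 1], ["pyrazole_formation_b", 1]])),
    _Group("acylhydrazide", "C(=O)NN", ("phenyl", "methyl"), _t([["acylhydrazone_formation", 1]])),
    _Group("azide", "N=[N+]=[N-]", ("phenethyl", "butyl"), _t(_AZIDE)),
    _Group("alkyne", "C#C", ("phenyl", "butyl"),
           _t([["sonogashira_coupling", 1], ["triazole_click_14", 1], ["triazole_click_15", 1]])),
    _Group(
        "nitrile", "C#N", ("phenyl", "pyridinyl"),
        _t([["tetrazole_from_nitrile", 0]]),
        (_Child("fgi_nitrile_reduction", "CN", _t(_AMINE1)),),
    ),
    _Group(
        "nitro", "[N+](=O)[O-]", ("phenyl", "p-tolyl"), (),
        (_Child("fgi_nitro_reduction", "N", _t(_AMINE1)),),
    ),
    _Group(
        "methyl_ester", "C(=O)OC", ("p-tolyl",), (),
        (_Child("fgi_ester_hydrolysis", "C(=O)O", _t(_ACID)),),
    ),
]

# standalone records that a plain scaffold x group product cannot express;
# each entry: (tag, smiles, annotations, children-as-dicts)
_STANDALONE = [
    ("piperidine", "C1CCNCC1", _t(_AMINE2), ()),
    ("n_methylpiperazine", "CN1CCNCC1", _t(_AMINE2), ()),
    ("o_phenylenediamine", "Nc1ccccc1N", _t([["benzimidazole_formation", 0]]), ()),
    ("methyl_o_phenylenediamine", "Cc1ccc(N)c(N)c1", _t([["benzimidazole_formation", 0]]), ()),
    # planted diacid: accepted, but the exactly-once rule voids every acid role
    ("terephthalic_diacid", "OC(=O)c1ccc(C(=O)O)cc1", (), ()),
    # bifunctional linkers: two different groups, each exactly once, so
    # coupling products keep a live attachment point for the next step
    (
        "linker_aminomethyl_benzoic_acid", "NCc1ccc(C(=O)O)cc1",
        _t(_AMINE1 + _ACID),
        (
            {
                "fga_fgi_id": "fga_amine_to_isocyanate",
                "smiles": "O=C=NCc1ccc(C(=O)O)cc1",
                "annotations": [["urea_formation", 0]] + [list(a) for a in _t(_ACID)],
            },
        ),
    ),
    (
        "linker_aminocyclopentanol", "NC1CCCC1O",
        _t(_AMINE1 + _ALCOHOL),
        (
            {
                "fga_fgi_id": "fga_amine_to_isocyanate",
                "smiles": "O=C=NC1CCCC1O",
                "annotations": [["urea_formation", 0]] + [list(a) for a in _t(_ALCOHOL)],
            },
        ),
    ),
    ("linker_hydroxymethyl_benzoic_acid", "OCc1ccc(C(=O)O)cc1", _t(_ALCOHOL + _ACID), ()),
    (
        "linker_bromo_benzaldehyde", "O=Cc1ccc(Br)cc1",
        _t([["reductive_amination", 0], ["acylhydrazone_formation", 0],
            ["suzuki_coupling", 0], ["buchwald_amination", 0], ["sonogashira_coupling", 0]]),
        (
            {
                "fga_fgi_id": "fgi_bromide_to_boronic_acid",
                "smiles": "O=Cc1ccc(B(O)O)cc1",
                "annotations": [["suzuki_coupling", 1], ["reductive_amination", 0],
                                ["acylhydrazone_formation", 0]],
            },
        ),
    ),
]

# planted filter violators: rule -> pool of (tag, SMILES)
_VIOLATIONS = {
    "mass_low": [("methane", "C"), ("ethane", "CC")],
    "mass_high": [("c25_alkane", "C" * 25), ("c30_alkane", "C" * 30)],
    "rings": [("perylene", "c1ccc2cc3c4cccc5cccc(c3cc2c1)c45")],
    "element": [("tetramethylstannane", "C[Sn](C)(C)C"), ("silane_germane", "C[Ge](C)C")],
    "fluorine": [("hexafluoroethane", "FC(F)(F)C(F)(F)F"), ("perfluoropropane", "FC(F)(F)C(F)(F)C(F)(F)F")],
    "valence": [("trivalent_fluorine", "C[F](C)C"), ("pentavalent_carbon", "C[C](C)(C)(C)C")],
    "alert": [("acetyl_chloride", "CC(=O)Cl"), ("butyl_bromide", "CCCCBr"), ("dimethyl_peroxide", "COOC")],
    # same molecule as the phenyl+acid record, different input SMILES
    "duplicate": [("benzoic_acid_again", "OC(=O)c1ccccc1")],
}
_VIOLATION_REASON = {
    "mass_low": "mass", "mass_high": "mass", "rings": "rings", "element": "element",
    "fluorine": "fluorine", "valence": "valence", "duplicate": "duplicate",
}
_ALERT_REASON = {
    "acetyl_chloride": "alert:acyl_halide",
    "butyl_bromide": "alert:unactivated_alkyl_halide",
    "dimethyl_peroxide": "alert:peroxide",
}

_DEFAULT_VIOLATIONS = {
    "mass_low": 1, "mass_high": 1, "rings": 1, "element": 1,
    "fluorine": 1, "valence": 1, "alert": 2, "duplicate": 1,
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic catalog.

    ``n_blocks`` is the total record count (clean + planted); extra records
    beyond the covering enumeration are inert alkylbenzenes. ``seed`` only
    shuffles the clean-record order (content is fixed by the tables above).
    """

    seed: int = 0
    n_blocks: int | None = None
    planted_violations: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_VIOLATIONS))


def _clean_records() -> list[dict]:
    records = []
    for group in _GROUPS:
        for scaffold in group.scaffolds:
            template = _SCAFFOLDS[scaffold]
            rec = {
                "tag": f"{scaffold}_{group.name}",
                "smiles": template.format(group.fragment),
                "expect": "accept",
                "annotations": [list(a) for a in group.annotations],
                "children": [
                    {
                        "fga_fgi_id": child.fga_fgi_id,
                        "smiles": template.format(child.fragment),
                        "annotations": [list(a) for a in child.annotations],
                    }
                    for child in group.children
                ],
            }
            records.append(rec)
    for tag, smiles, annotations, children in _STANDALONE:
        records.append(
            {
                "tag": tag,
                "smiles": smiles,
                "expect": "accept",
                "annotations": [list(a) for a in annotations],
                "children": list(children),
            }
        )
    return records


def _violation_records(counts: dict[str, int]) -> list[dict]:
    records = []
    for rule, count in counts.items():
        pool = _VIOLATIONS.get(rule)
        if pool is None:
            raise FixtureError(f"unknown violation rule {rule!r}")
        if count > len(pool):
            raise FixtureError(f"only {len(pool)} planted {rule!r} violators available")
        for tag, smiles in pool[:count]:
            reason = _ALERT_REASON[tag] if rule == "alert" else _VIOLATION_REASON[rule]
            records.append(
                {
                    "tag": tag,
                    "smiles": smiles,
                    "expect": f"reject:{reason}",
                    "annotations": [],
                    "children": [],
                }
            )
    return records


def _filler_records(n: int) -> list[dict]:
    # inert alkylbenzenes: accepted, zero annotations
    return [
        {
            "tag": f"filler_alkylbenzene_{i + 1}",
            "smiles": "C" * (i + 2) + "c1ccccc1",
            "expect": "accept",
            "annotations": [],
            "children": [],
        }
        for i in range(n)
    ]


def coverage_table(records: list[dict]) -> dict[str, int]:
    """Partner-block count per (reaction, component), counting derived blocks."""
    cover: dict[str, int] = {}
    for rec in records:
        if rec["expect"] != "accept":
            continue
        pools = [rec["annotations"]] + [c["annotations"] for c in rec["children"]]
        for pool in pools:
            for rid, comp in pool:
                cover[f"{rid}/{comp}"] = cover.get(f"{rid}/{comp}", 0) + 1
    return cover


def generate_catalog(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write catalog.smi and manifest.json; deterministic for a given seed."""
    clean = _clean_records()
    rng = random.Random(spec.seed)
    rng.shuffle(clean)
    violations = _violation_records(spec.planted_violations)
    n_base = len(clean) + len(violations)
    if spec.n_blocks is not None:
        if spec.n_blocks < n_base:
            raise FixtureError(
                f"n_blocks={spec.n_blocks} below the covering enumeration ({n_base}); "
                "coverage would be unsatisfiable"
            )
        clean += _filler_records(spec.n_blocks - n_base)
    # violations last: the duplicate record must follow its original
    records = clean + violations
    for i, rec in enumerate(records):
        rec["id"] = f"B{i + 1:03d}"

    cover = coverage_table(records)
    from .reactions import load_reaction_library  # local import to keep generation light

    for template in load_reaction_library(bundled="coupling"):
        for comp in range(template.n_components):
            if cover.get(f"{template.id}/{comp}", 0) < 2:
                raise FixtureError(
                    f"coverage unsatisfiable: component {template.id}/{comp} has "
                    f"{cover.get(f'{template.id}/{comp}', 0)} partner block(s)"
                )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog_path = out_dir / "catalog.smi"
    manifest_path = out_dir / "manifest.json"
    with open(catalog_path, "w") as fh:
        fh.write("# synthetic building-block catalog (generated fixture)\n")
        for rec in records:
            fh.write(f"{rec['smiles']}\t{rec['id']}\n")
    manifest = {
        "format": "synthgrow-fixture/1",
        "seed": spec.seed,
        "n_records": len(records),
        "n_expected_accept": sum(r["expect"] == "accept" for r in records),
        "records": [
            {
                "id": r["id"],
                "tag": r["tag"],
                "smiles": r["smiles"],
                "expect": r["expect"],
                "annotations": r["annotations"],
                "children": [
                    {
                        "id": f"{r['id']}@{c['fga_fgi_id']}",
                        "fga_fgi_id": c["fga_fgi_id"],
                        "smiles": c["smiles"],
                        "annotations": c["annotations"],
                    }
                    for c in r["children"]
                ],
            }
            for r in records
        ],
        "coverage": dict(sorted(cover.items())),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return catalog_path, manifest_path
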