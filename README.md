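# synthgrow

Reaction-driven *de novo* design of ligand candidates. `synthgrow` grows new
molecules by virtually applying named chemical reactions (amide coupling,
Suzuki coupling, Paal–Knorr pyrrole synthesis, click cycloadditions, …) to a
curated catalog of purchasable-style building blocks, steering a
deterministic greedy/beam construction with a graph-kernel similarity score
against a known reference ligand. Because every growing step *is* a reaction
applied to real blocks, every design comes with a replayable synthesis
route: the ordered reactions, the block IDs (with functional-group
interconversion provenance), and a literature reference per step.

It is aimed at medicinal/computational chemists who want ligand-based idea
generation — scaffold hopping and bioisosteric replacement starting from a
single known active — with synthesizability built into the search rather
than bolted on afterwards.

## Method

**Scoring.** Candidates are compared with the reference by an iterative
similarity optimal-assignment graph kernel (ISOAK-family). Molecules are
hydrogen-suppressed graphs whose atoms carry one of eight pharmacophore
types (A acceptor, D donor, E both, P positive, N negative, R aromatic,
L lipophilic, 0 none). Vertex-pair similarity is iterated to its fixed
point,

    s(u,v) = (1 − α)·base(u,v) + α·neighbor(u,v),

where `neighbor` is a maximum-weight one-to-one matching of the two
neighbor lists (edge orders must agree) and `α ∈ [0,1)` sets the weight of
the neighborhood. The final score is the optimal assignment of the smaller
graph's vertices onto the larger one, scaled by the larger heavy-atom
count: symmetric, in [0,1], and exactly 1 for self-comparison.

Alternatively, molecules are abstracted to a *reduced graph*: SSSR rings
collapse to single vertices (fused systems whose atoms sit in more than two
rings collapse whole), clusters of lipophilic/untyped acyclic atoms
collapse, and fused rings are joined by order-2 edges so naphthalene and
biphenyl stay distinguishable. Each vertex carries a 10-bit label (8 types +
ring + amalgamated-ring) and an atom count; vertex similarity is the
Tanimoto index of the labels damped by a size-difference penalty that
vanishes when the counts differ by more than five. Defaults: α = 0.875 for
molecular graphs, α = 0.4 for reduced graphs.

**Construction.** Each extension cycle first ranks the reactions applicable
to the intermediate `Z` by applying them with *minimal dummy fragments* (the
smallest molecule satisfying a reaction component) and scoring the dummy
products; the top reaction(s) then couple `Z` with every annotated catalog
block, and the best product(s) — ties included, ten at most — continue.
Growth is free below 70 % of the reference mass, must strictly improve the
score between 70 % and 130 %, and is cut after four steps. The whole search
is deterministic: two runs with identical inputs are byte-identical.

**Catalog preparation.** Raw catalogs pass a three-stage protocol:
standardize and filter (30–300 Da, ≤ 4 rings, element whitelist, ≤ 3 F,
valence, reactive/toxic substructure alerts, duplicates; acids deprotonated,
basic amines protonated), derive extra blocks via functional-group
addition/interconversion reactions (originals kept), and annotate each
block with the reaction components whose center it matches *exactly once* —
duplicated functional groups disqualify a block as a partner.

## Worked example

The bundled fixture generator writes a 60-record synthetic catalog (51
clean records and 9 planted filter violations, with a manifest of expected
outcomes), so the full pipeline runs without any downloads:

```bash
synthgrow fixtures --seed 1 --out fix
synthgrow prep --in fix/catalog.smi --out catalog.json --report report.json
# -> catalog: 68 blocks (4 without annotations) -> catalog.json
echo "Cc1ccc(C(=O)NCC2CCCC2OC(=O)c2ccc(CN)cc2)cc1 ref1" > ref.smi
synthgrow design --catalog catalog.json --reference ref.smi --n-starts 3 --out designs
# -> 3 routes / 3 unique designs -> designs
head -3 designs/summary.tsv
```

    rank  smiles                                            score     mass    steps  start_block  mass_flag  reason
    1     Cc1ccc(S(=O)(=O)NCc2ccc(C(=O)OC3CCCC3N)cc2)cc1    0.850111  388.49  2      B028         in_window  score_rule
    2     NC1CCCC1OC(=O)c1ccc(CNC(=O)OCc2ccccc2)cc1         0.816453  368.43  2      B003         in_window  score_rule

The 68 blocks are the 51 accepted records plus 17 blocks derived by
functional-group interconversion (nitro→amine, bromide→boronic acid,
amine→isocyanate, …). The top design scores 0.85 against the reference and
sits inside the 70–130 % mass window; `synthgrow report designs` renders
its route step by step:

    1. Sulfonamide formation (sulfonamide_formation) with B003 -> Cc1ccc(S(=O)(=O)NCc2ccc(C(=O)O)cc2)cc1
    2. Ester formation (ester_formation) with B049 -> Cc1ccc(S(=O)(=O)NCc2ccc(C(=O)OC3CCCC3N)cc2)cc1

i.e. tosylate the aminomethyl-benzoic-acid linker, then esterify the free
acid with 2-aminocyclopentanol — the ester forms while the partner's amine
survives, and the route replays exactly through the reaction engine
(`replay_route` verifies this for every emitted design). Route 3 starts
from `B003@fga_amine_to_isocyanate`, a block that exists only through the
amine→isocyanate preprocessing step; the provenance is recorded in the
route.

The library surface mirrors the CLI: `synthgrow.load_molecules`,
`build_reduced_graph`, `molecule_similarity`, `load_reaction_library`,
`build_catalog`, and `run_design` compose the same pipeline in Python.

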