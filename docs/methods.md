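# Methods

This note records the models, parameter choices, and numerical decisions
behind `synthgrow`, including the places where the design space was
genuinely open and what the bundled synthetic data does and does not show.

## Pharmacophore typing (`chemgraph`)

Atoms of the hydrogen-suppressed molecular graph receive exactly one of
eight types through a fixed priority cascade:

P (positive charge, or neutral protonatable aliphatic amine) ≻ N (negative
charge) ≻ E (donor **and** acceptor) ≻ D (donor) ≻ A (acceptor) ≻ R
(aromatic) ≻ L (carbon/halogen without hetero neighbor) ≻ 0.

The cascade makes typing single-valued and idempotent. Choices worth
noting:

* Aromatic *hetero*atoms keep their heteroatom character: pyridine N is an
  acceptor (A), not merely aromatic; its ring membership still reaches the
  reduced graph through the ring bits. Furan O and thiophene S fall through
  to R (their acceptor strength is marginal and no downstream rule depends
  on it).
* Ylide-like charge pairs (nitro, azide) are *not* charge centers; they
  fall through to acceptor/0 typing.
* Neutral aliphatic amines count as P because the charge wash protonates
  them anyway; anilines, amides, and hydrazines are excluded from that
  rule. Neutral guanidines type as E/D rather than P — acceptable because
  references and blocks pass through the same wash before scoring.

## Reduced graph (`reduced_graph`)

* SSSR rings → one vertex each; a fused system containing an atom in more
  than two SSSR rings collapses whole, with the `amalgamated` bit set. The
  >2-rings test is applied literally, so bridged polycyclics such as
  adamantane also amalgamate — the text leaves this case open and the
  literal rule is the simplest defensible reading.
* Member-atom sets partition the heavy atoms. Atoms shared by fused rings
  are assigned to the lower-indexed ring; the full ring atom sets are kept
  separately to drive the order-2 (fused) edge test, so atom counts stay
  conservative (they sum to the heavy-atom count) while fusion is still
  visible.
* Acyclic L/0 atoms merge into maximal connected clusters; every other
  acyclic atom is its own vertex. Ring membership wins over cluster
  membership (partition requirement).
* The size-difference penalty `sdFactor(Δ) = max(0, 1 − Δ/6)` is the
  simplest curve that is 1 at Δ=0, strictly between 0 and 1 for 1 ≤ Δ ≤ 5,
  and 0 beyond 5. Only these constraints are fixed by the method; the decay
  shape between the endpoints is a package choice, isolated in one function.
* Vertices with more than six neighbors cannot be processed by the kernel;
  such molecules are flagged and discarded by the callers (scoring returns
  `None`, design skips the candidate).

## Similarity kernel (`kernel`)

The update `s ← (1−α)·base + α·neighbor` is a contraction for α < 1;
synchronous iteration from the all-base initialization converges to the
unique fixed point regardless of vertex order. Details fixed here:

* `neighbor(u,v)` is a maximum-weight one-to-one matching
  (`scipy.optimize.linear_sum_assignment`) between the neighbor lists,
  pair weight = edge compatibility × current similarity, normalized by the
  **larger** neighbor count. Edge compatibility is 1 iff bond orders match
  (aromatic is its own order; reduced-graph orders are 1/2).
* When *both* vertices are isolated the neighbor term is 1 (a vacuous
  matching is perfect), which makes a pair of identical single-vertex
  graphs score exactly 1 for every α; when only one side is isolated the
  term is 0.
* Final score = optimal assignment over the converged matrix divided by
  the larger vertex count. Dividing by the larger count makes
  self-similarity exactly 1 and penalizes size mismatch.
* Convergence: `tol = 1e-6`, `max_iter = 200`. The error decays like α^t,
  so α = 0.875 needs ≈ 100 iterations and α = 0.4 about 15; 200 leaves
  headroom. Non-convergence returns the last iterate flagged, never raises.
* Defaults α = 0.875 (molecular graph) and α = 0.4 (reduced graph). These
  normalization and matching conventions are this package's own; absolute
  scores are comparable within `synthgrow`, not across other kernel
  implementations.

## Reaction engine (`reactions`)

Templates are reaction SMARTS with atom maps, one or two components, one
product. Conventions:

* Matching and application run on **neutral-form** molecules; the charged
  standardized form exists for scoring only. This replaces per-charge-state
  template variants with a single template per reaction.
* "Applicable" means the component pattern matches *exactly once* after
  symmetry reduction (matches covering the same atom set count once), which
  is what disqualifies, e.g., terephthalic acid as an acid partner.
* Each template declares its minimal dummy fragments explicitly (smallest
  molecule satisfying the component center, e.g. methylamine for amine
  components, hexane-2,5-dione for the 1,4-diketone). They are validated at
  load time: each must match its pattern exactly once and the template must
  produce exactly one sanitized product from them. Declaring rather than
  auto-realizing the fragments keeps the library auditable and the
  validation catches drift.
* Mass bookkeeping: product mass = Σ reactant masses + `reagent_gain` −
  `leaving_group`, both given as formula strings. `reagent_gain` covers
  atoms contributed by invariant reagents that the encoding does not list
  as components (the carbonyl of phosgene in amine→isocyanate, H₂ in
  reductions, HN₃ in tetrazole formation). The boronation entry's leaving
  formula (`HBrO`) balances mass only and is not mechanistic. Every shipped
  template passes this check to 0.05 Da.
* The shipped coupling library has 22 templates (8 ring-forming, two
  regioisomer pairs, one one-component reaction) and the preprocessing
  library has 6 FGA/FGI templates. Both files document their schema and are
  meant to be extended; no selectivity or reactivity ranking between
  competing groups is attempted.

## Catalog preparation (`blockprep`)

Filter order follows the preparation protocol: structural filters on the
input form (mass 30–300 Da, ≤ 4 SSSR rings, element whitelist
C/N/O/S/P/F/Cl/Br/I/B/Si/Se, ≤ 3 F, valence, alerts), then the charge wash,
then duplicate removal on the standardized form (so protomers collapse —
the protocol leaves this order open). All failing rules are recorded; the
first is the reason code.

The alert list is a configurable, Hann-style reactive/toxic set. Two
deliberate scope choices: azides are allowed (the click templates need
them), and the alkyl-halide alert exempts benzylic/allylic/α-carbonyl
halides (they are the intended alkylation handles). FGA/FGI-derived blocks
re-enter every filter *except* the alert screen — handles introduced on
purpose (isocyanates from amines) must survive — and are not preprocessed
recursively. Derived blocks carry `parent_id` and the preprocessing
reaction ID, which propagates into design routes.

The store is a sorted JSON flat file keyed by block ID; rebuilding from the
same inputs is byte-identical, and blocks without annotations are kept but
flagged unusable.

## Design algorithm (`design`)

Two-step extension cycles under a deterministic greedy/beam regime, with
these fixed readings of open points:

* One-component reactions compete in Step 1 with their actual product as
  the dummy product.
* "Top-scoring" means exact float equality; all tied reactions proceed to
  Step 2, and tied products are kept up to the beam width (10) after
  sorting by score desc, canonical SMILES, block ID. Exact-equality ties
  are reproducible because identical inputs give identical floats.
* The step that first crosses the 70 % mass bound is accepted
  unconditionally; the strict-improvement rule applies from the following
  step. "Improvement" is strictly greater, preventing score plateaus.
* Pathways are cut after `max_steps` = 4; step-cap finals outside the mass
  window are kept and flagged (`below_mass_window`/`above_mass_window`)
  rather than dropped, since the last valid intermediate is the design.
* A start that cannot take a single step yields no route and the start
  budget extends by one, so a run produces at least `n_starts` productive
  starts while the catalog lasts.
* Scores are cached by canonical SMILES; with the reduced representation a
  fixture-scale run (≈ 70 blocks, 5 starts) takes seconds on one core. The
  bundled default for `n_starts` is 200 to match realistic use, but all
  bundled examples and checks run with 3–5 starts against the fixture
  catalog — the problem sizes the package's own tests exercise.

## Synthetic fixture catalog (`fixtures`)

The generator enumerates scaffold × functional-group combinations (phenyl,
tolyl, pyridinyl, anisyl, naphthyl, cyclohexyl, benzyl, phenethyl, alkyl ×
acid, alcohol, amine, aldehyde, halides, boronic acid, sulfonyl chloride,
diketones, hydrazines, azides, alkynes, nitriles, nitro, esters, …), plus
standalone records (secondary amines, arylenediamines, a diacid) and four
bifunctional linkers. Alongside it writes a manifest stating, by
construction, each record's expected accept/reject outcome, reaction-role
annotations, and FGA/FGI children — an oracle authored from the chemistry
tables, not computed by the preparation code it checks.

Design points:

* Most records carry one reactive group so the exactly-once rule is
  exercised from the accepting side; the planted diacid exercises the
  rejecting side. The four linkers carry two *different* groups (amine +
  acid, amine + alcohol, alcohol + acid, aldehyde + aryl bromide), each
  present once: without them every coupling product would be chemically
  inert and no pathway could exceed one step, so multi-step construction
  would be untestable.
* Defaults: 51 clean records + 9 planted violations (low/high mass, ring
  count, element, fluorine, valence, two alerts, one duplicate) = 60
  records; preparation yields 68 blocks including 17 derived ones. Every
  coupling component has ≥ 2 partner blocks, counting derived handles.
* The seed shuffles record order only; content is fixed by the tables.
  `n_blocks` can pad with inert alkylbenzenes, never shrink below coverage.
* The fixture emulates coverage and rule violations, **not** the property
  distributions, redundancy, or noise of a real vendor catalog. Green tests
  show the machinery is correct at fixture scale; they do not show that
  designs from a real 10⁴–10⁵-block catalog would be chemically attractive,
  nor do they validate the biological relevance of any score.

## Known limitations

* Scoring is 2D; stereochemistry passes through I/O untouched and no 3D
  pharmacophore or conformer information enters the score.
* No protecting-group logic and no reactivity ranking between competing
  functional groups; routes may need protection steps in practice.
* Drug-likeness/logP/synthesizability post-filters and vendor availability
  checks are out of scope.
* The typing rules and alert list are documented stand-ins that users can
  override per run; absolute kernel scores are implementation-specific.
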