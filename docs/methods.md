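# Methods

This note documents the models and procedures implemented in `kinfrags`,
the parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic fixtures do and do not emulate, and the
known limitations.

## Fragment model

A fragment is a molecular graph in which every severed bond is represented
by a placeholder ("dummy") atom. The placeholder's isotope number carries
the BRICS chemical-environment type (1–16) of the cut end, and each
placeholder is annotated with the subpocket of the fragment formerly bonded
there. This keeps an SDF/CSV record self-describing: the
`neighbor_subpockets` field lists the neighbor labels in placeholder
file-order, and the environment types travel inside the connection table as
isotopes. All chemistry-level operations (substructure matching, descriptor
calculation, InChI, fingerprints, scoring) run on the *dummy-free* form —
placeholders are deleted and the freed valence refilled with implicit
hydrogens — so an attachment point can never mask or create a match and
never shifts a property value.

Libraries are pools keyed by subpocket (AP, FP, SE, GA, B1, B2, plus X for
unassigned). Pool order is a stable sort by provenance (kinase, PDB,
ligand) then canonical SMILES, which makes every downstream artifact
deterministic across runs and platforms. When deduplication collapses
several fragments, the first under this order is kept; the tie-break is a
package choice, made for reproducibility.

## Fragmentation and subpocket assignment

Ligands are cut at the bonds found by the published BRICS rules (RDKit's
implementation finds the bonds and environment labels; the 7a/7b alkene
sub-labels map to environment 7). All cuts are applied simultaneously; the
severed bond's order is recorded and restored on re-joining, which is
equivalent to the convention that only the alkene environment restores a
double bond. Each placeholder is placed at the 3D position of the lost
partner atom, and the two placeholders of one cut share a bookkeeping id,
so re-joining all pieces reconstructs the input graph exactly — this
round-trip is a tested invariant.

A piece is assigned to the subpocket whose geometric center is closest to
the piece's **heavy-atom centroid** (placeholders and hydrogens excluded).
The distance cutoff is 8 Å; beyond it the piece goes to pool X. Ties break
in the fixed order AP, FP, SE, GA, B1, B2. Centroid-vs-nearest-atom was an
open choice; the centroid is implemented because it is insensitive to a
single protruding atom, and the geometry object keeps the cutoff and the
subpocket adjacency explicit and configurable. Adjacent pieces sharing a
subpocket are merged by re-bonding their common cuts (union–find over the
same-subpocket relation); surviving placeholders inherit the label of the
piece on the far side of their cut.

## Prefilters

Three independent predicates, applied in a fixed order only for report
comparability (the surviving set is order-invariant, and tested to be):

- **Deduplicate** per subpocket on the standard InChI of the dummy-free
  fragment. This merges fragments that differ only in attachment position;
  a `key="smiles"` switch keeps them apart for users who want positional
  isomers preserved. A fragment whose InChI generation fails is flagged and
  treated as unique — never silently merged.
- **Unfragmented** structures (no attachment point) are removed: they cannot
  recombine and may span several subpockets.
- **Pool X** and fragments whose every connection points to pool X are
  removed: they cannot be joined to any standard subpocket.

## Filters

All fragment-level filters produce independent per-fragment pass flags on
the prefiltered library and are then intersected. This single-pass design
yields the three reporting surfaces at once: independent removal counts per
filter and subpocket, sequential remaining counts along the cascade, and
the symmetric overlap matrix of fragments jointly rejected by filter pairs
(diagonal = per-filter totals). Every filter is optional and reorderable.

- **Unwanted substructures.** Default catalogs are the published PAINS
  (480 entries) and Brenk (105 entries) lists, loaded from RDKit's filter
  catalog; user catalogs load from two-column CSV (name, SMARTS) and any
  non-compiling SMARTS is an error at load time. Aromaticity follows
  RDKit's default perception model.
- **Rule of Three**: MW < 300 Da (strict), HBA ≤ 3, HBD ≤ 3, logP ≤ 3,
  NROT ≤ 3, PSA ≤ 60 Å². The allowed number of rule mismatches defaults
  to 0 and is user-settable. HBA/HBD definitions are pinned and
  configurable (`lipinski`: N+O and NH+OH counts, the default; or
  `topological`: typed acceptor/donor counts) because Ro3 counts are
  definition-sensitive. logP is the atom-contribution octanol–water
  estimate; PSA is topological.
- **QED** is the weighted geometric mean of eight double-sigmoid
  desirability functions (MW, logP, HBA, HBD, PSA, NROT, aromatic rings,
  structural alerts), score ∈ (0, 1]. Desirabilities and parameters come
  from RDKit; the score is recomputed from them by the geometric-mean
  formula so that the published weight sets (`mean` — the default, `max`,
  `unit`) are selectable, and equality with the reference implementation is
  a test. The default acceptance threshold is **0.464**, the lower-quartile
  QED of fragments cut from approved/clinical kinase inhibitors;
  `derive_qed_threshold` reproduces the derivation for any reference
  fragment set using the linear-interpolation (type-7) quantile — the
  quantile convention was unstated upstream and is pinned here.
- **Synthesizability score.** A Bernoulli log-odds model over radius-2
  circular substructures hashed to 32-bit ids:
  `w(f) = log2 (n_easy(f)+s)/(N_easy+2s) − log2 (n_hard(f)+s)/(N_hard+2s)`
  with Laplace pseudo-count s = 1 (configurable), where n counts molecules
  containing f (presence, not multiplicity). A molecule scores the sum of
  weights over its distinct substructures; unseen substructures contribute
  the pure-smoothing weight. Positive = easier to synthesize; fragments
  scoring below 0 (strictly negative) are removed by default. The exact
  substructure vocabulary of the original published score is not restated
  in the source this follows; the functional form is preserved, the
  vocabulary pinned (Morgan radius-2), and a weight-table loader lets users
  substitute externally published weights. Package scores are therefore
  never compared numerically to published score values.
- **Building blocks.** A fragment passes when its dummy-free form embeds as
  a substructure of at least one molecule in the supplied commercial
  building-block set (RDKit substructure library; stereo ignored by
  default). An empty block set fails everything — absence of evidence is
  treated as failure, not a bypass.
- **Retrosynthesis gate.** Valid pairs require: adjacent subpockets; an
  attachment on each fragment pointing at the other's subpocket with equal
  severed-bond order; BRICS link-compatible environment types (the 16×16
  relation is derived at import time from the published BRICS reaction
  definitions); and both fragments passing all

  prior filters. Each unordered pair is emitted once — when several
  attachment combinations validate the same pair, the first in attachment
  order is used. The recombined product (placeholders hydrogen-capped) is
  sent to a backend (`suggest(product_smiles) → suggestions`); a pair is
  feasible when some suggestion has two *distinct* precursors containing
  the two fragments as substructures (either assignment). A fragment
  passes when it joins at least one feasible pair; fragments with no valid
  partner fail by default (`retro_keep_unpaired` retains them — the
  upstream convention is ambiguous, so it is a switch). Backend responses
  are cached by product canonical SMILES (JSON-lines file); caching is
  tested not to change results, and a backend failure marks the pair
  undetermined and reported — never silently feasible.

## Recombination and molecule-level evaluation

Enumeration grows molecules from a core AP fragment (every product contains
exactly one), at most one fragment per subpocket and 2–4 fragments total
(both bounds configurable; a single fragment is not a recombination), with
every junction obeying the same adjacency/mutual-annotation/bond-order/
BRICS rules as pair building. Products are deduplicated by (constituent
fragment set, canonical SMILES) and streamed lazily in deterministic order;
open attachment points are hydrogen-capped at finalization, matching the
dummy-free convention used everywhere else. Stratified sampling by fragment
count uses largest-remainder apportionment and a seeded generator; strata
short of quota are exhausted and logged. Default size proportions are
uniform — the reference fragment-count distribution is not published — and
are a config vector. Evaluation reports Lipinski Rule of Five (MW ≤ 500,
logP ≤ 5, HBD ≤ 5, HBA ≤ 10), Veber (NROT ≤ 10, PSA ≤ 140 Å²), QED and the
synthesizability score, with per-molecule descriptor failures excluded from
aggregates and counted.

## Diversity analytics

- **Tanimoto.** Mean ± sd of 1 − Jaccard similarity over all unordered
  pairs of 2048-bit topological path fingerprints (paths up to length 7),
  computed dummy-free, exactly (O(n²), no sampling). The sd is the
  population standard deviation (ddof = 0; the upstream convention is
  unstated).
- **Scaffold entropy.** Fragments reduce to Murcko scaffolds (ring systems
  plus linkers); ring-free fragments have no scaffold and are excluded and
  reported as a fraction. SE = −Σ pᵢ log₂ pᵢ with pᵢ = cᵢ/P over the n
  counted scaffolds; SSE = SE/log₂ n ∈ [0, 1], defined as 0 when n = 1.
  The source formula for SE is printed without the minus sign; the standard
  non-negative entropy is the only reading consistent with SSE ∈ [0, 1] and
  "1 = high diversity", and is what is implemented. `top_n` restricts the
  entropy to the n most frequent scaffolds (ties broken by scaffold
  SMILES); the default is all scaffolds, since the upstream truncation, if
  any, is unstated.
- **Kinase coverage.** Per subpocket, a kinase counts as covered when at
  least one of its ligands contributes a fragment (identified by dummy-free
  standard InChI) still present in that pool; a total counts kinases
  covered in any subpocket.

## Synthetic fixtures: what they emulate, and what they don't

The fixture module makes the entire pipeline testable offline:

- **Toy libraries** are built from a fixed vocabulary: ~23 clean bodies
  (drug-like bicyclics that pass Ro3, QED ≥ 0.464 and both catalogs) plus
  seeded offenders — PAINS motifs (a dialkyl-aniline pattern that is
  PAINS-only, catechol and thioketone which are PAINS+Brenk, mirroring the
  real overlap between the two lists), Brenk-only nitro motifs, alert-free
  Rule-of-Three violators (one per violated rule class), low-QED small
  heterocycles, and fragments decorated with a gem-difluorocyclopropane
  marker for the synthesizability gate. The vocabulary is a verified
  *substructure antichain*: no body embeds in another body or in another
  body's methylated superstructure, which is what makes mock
  building-block coverage exact — `make_mock_bb_set` emits methylated
  superstructures for a chosen fraction of distinct structures and exactly
  that fraction passes the filter. Ground-truth labels (per filter, per
  fragment) are emitted alongside; QED and synthesizability labels are the
  computed scores (a continuous 8-property score cannot be forced by
  construction), so end-to-end tests check cascade bookkeeping against
  those labels while the scores' own correctness is tested by independent
  routes (geometric-mean reconstruction vs the reference QED; hand
  log-odds arithmetic for the trainable score).
- **Score corpora**: "easy" molecules are methyl-decorated clean bodies,
  "hard" molecules are bare bodies carrying the marker; shared cores get
  near-zero weights, decorations positive, marker environments strongly
  negative, so held-out marker-bearing probes separate from clean probes
  (≥95 %, a tested property).
- **Toy complexes** assemble aromatic bodies at subpocket centers joined by
  single aromatic–aromatic bonds (always a BRICS bond), with jittered
  coordinates; the expected decomposition is constructed by independent
  explicit graph assembly. Recovery is compared on (subpocket, dummy-free
  structure, neighbor labels); environment labels are checked separately
  against the reference BRICS implementation.
- **Mock retrosynthesis backend**: a lookup table from product SMILES to
  precursor lists, with a call log.

The fixtures exercise code paths and bookkeeping exactly; they do **not**
emulate the statistical realism of kinase chemistry — real fragment
libraries have heavy-tailed scaffold distributions, charged and zwitterionic
species, stereochemistry, and far larger pools. Passing fixture tests
therefore demonstrates the correctness of the pipeline's logic, not the
field performance of the filters on crystal-structure data. The problem
sizes used in the test suite and the acceptance script (a ~60-fragment
library, ~40-molecule corpora, ≤ 20-fragment enumeration oracles) were
chosen as the smallest sizes that exercise every code path, including every
seeded offender class in every subpocket group.

## Numerical and degenerate-input choices

- Quantiles: linear interpolation (type 7). Tanimoto sd: ddof = 0.
- SSE(n = 1) := 0 avoids division by log₂ 1.
- Scaffold-entropy on a set with no ring-containing fragment is an explicit
  error, as is pairwise Tanimoto on fewer than two fragments.
- Fragments failing valence sanitization are quarantined (skipped with a
  logged reject record), never passed downstream; a record without a
  subpocket is a hard error.
- Score exactly 0 passes the synthesizability cutoff (only strictly
  negative scores are removed).
- All randomness flows through seeded NumPy generators; there is no global
  random state.

## Known limitations

- The pocket-residue geometry itself (subpocket centers) is an input, not
  computed from structures.
- The retrosynthesis backend contract covers one-step suggestions only; the
  HTTP client's query parameters are config passthroughs and deployments
  must supply their service's recommended values.
- Building-block matching ignores stereochemistry by default.
- Deduplication on dummy-free InChI merges attachment-position isomers; the
  SMILES-key switch is provided but changes downstream counts.
- The trainable synthesizability score depends on its training corpora;
  shipped fixtures are toy corpora, and users reproducing published
  decisions should load the corresponding published weight table.
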