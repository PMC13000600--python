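# kinfrags

Curation, filtering and recombination analytics for subpocket-annotated
kinase fragment libraries.

## The problem

Fragment libraries cut from kinase–ligand crystal structures are a powerful
starting point for fragment-based design of kinase inhibitors: every
fragment is annotated with the binding-site subpocket it occupied (AP —
adenine pocket at the hinge, FP — front pocket, SE — solvent-exposed pocket,
GA — gate area, B1/B2 — back pockets) and with the subpocket its severed
bonds pointed to, so fragments can be recombined along the pocket topology
into candidate inhibitors. But an uncurated library of thousands of
fragments spans a recombination space of up to billions of molecules — far
too many to enumerate — and many fragments are assay-interference motifs,
not fragment-like, or hard to obtain and synthesize.

`kinfrags` implements the full curation pipeline that turns such a raw
library into a small, drug-like, synthesis-friendly one, plus the
fragmentation, recombination and diversity analytics around it:

1. **Fragmentation** — dissect 3D ligands at BRICS bonds (retrosynthetically
   meaningful cuts; each cut end is labeled with one of 16 chemical
   environments), assign each piece to the nearest subpocket center
   (centroid rule, 8 Å cutoff, pool X beyond it), and merge adjacent pieces
   that share a subpocket.
2. **Prefilters** — per-subpocket deduplication on the standard InChI of the
   dummy-free fragment, removal of unfragmented ligands, and removal of
   pool X and of fragments connected only to pool X.
3. **Unwanted substructures** — PAINS (480 patterns) and Brenk (105
   patterns) catalog screening, or any user catalog from a CSV of SMARTS.
4. **Drug-likeness** — Rule of Three (MW < 300 Da, HBA ≤ 3, HBD ≤ 3,
   logP ≤ 3, NROT ≤ 3, PSA ≤ 60 Å², configurable number of allowed
   mismatches) and QED with default threshold 0.464 (the lower-quartile QED
   of fragments cut from approved/clinical kinase inhibitors; the same
   derivation is available for any reference set via
   `derive_qed_threshold`).
5. **Synthesizability** — a trainable Bernoulli fragment score in the SYBA
   functional form, `score(m) = Σ_f [log2 P(f|easy) − log2 P(f|hard)]` over
   the molecule's radius-2 circular substructures (negative scores are
   removed); a commercial building-block filter (a fragment must embed as a
   substructure of at least one building block); and a retrosynthesis gate:
   all valid fragment pairs (adjacent subpockets, mutually pointing
   attachments, BRICS-compatible environments, all prior filters passed) are
   recombined and sent to a pluggable one-step retrosynthesis backend; a
   pair is feasible when the proposed precursors contain the two fragments
   as substructures, and a fragment survives when it takes part in at least
   one feasible pair.
6. **Analytics** — exact mean ± sd pairwise Tanimoto distance (2048-bit
   topological fingerprints, paths up to length 7), Murcko-scaffold Shannon
   entropy SE = −Σ pᵢ log₂ pᵢ and its standardized form SSE = SE/log₂ n,
   kinase coverage per subpocket, and the cascade reports: per-filter
   independent removals, sequential remaining counts, and the
   filter-overlap matrix of jointly rejected fragments.
7. **Recombination** — exhaustive, duplicate-free enumeration of 2–4
   fragment molecules rooted in an AP core fragment, stratified sampling by
   fragment count, and molecule-level evaluation (Lipinski Rule of Five,
   Veber, QED, synthesizability score).

Every filter is optional, reorderable and parameterized through
`PipelineConfig`; every removal decision is traceable in a per-fragment
audit table.

## Worked example

The package ships deterministic synthetic fixtures (a toy library with
seeded PAINS/Brenk/Rule-of-Three/QED/synthesizability offenders, a mock
building-block set and a scripted retrosynthesis backend), so the whole
cascade can be run end to end without external data:

```python
from kinfrags import PipelineConfig, run_pipeline
from kinfrags.core import DEFAULT_ADJACENCY
from kinfrags.analysis import diversity_stats
from kinfrags.fixtures import (FixtureSpec, MockRetroBackend, make_mock_bb_set,
                               make_syba_corpus, make_toy_library)
from kinfrags.pairs import enumerate_valid_pairs
from kinfrags.pipeline import compute_flags
from kinfrags.prefilter import prefilter
from kinfrags.synth import build_bb_index, train_syba

spec = FixtureSpec(
    seed=1,
    pool_sizes={"AP": 16, "FP": 10, "SE": 8, "GA": 8, "B1": 5, "B2": 5},
    pains_fraction=0.12, brenk_fraction=0.08, ro3_fraction=0.12,
    qed_fraction=0.06, syba_fraction=0.1,
    n_duplicates=2, n_unfragmented=2, n_x_pool=2, n_x_only=2,
)
library, labels = make_toy_library(spec)
prefiltered, _ = prefilter(library)

blocks, _ = make_mock_bb_set(prefiltered, coverage_fraction=0.8, seed=2)
easy, hard = make_syba_corpus(seed=3)
bb_index, model = build_bb_index(blocks), train_syba(easy, hard)

flags = compute_flags(prefiltered, PipelineConfig(), bb_index=bb_index, syba_model=model)
pairs = enumerate_valid_pairs(prefiltered, DEFAULT_ADJACENCY, prior_flags=flags)
backend = MockRetroBackend.approving(pairs)

result = run_pipeline(PipelineConfig(), library=library,
                      bb_index=bb_index, syba_model=model, retro_backend=backend)

print(f"{len(library)} fragments -> {len(prefiltered)} prefiltered -> {len(result.library)} curated")
before = diversity_stats(prefiltered.fragments())
after = diversity_stats(result.library.fragments())
print(f"mean Tanimoto distance: {before.mean_tanimoto_distance:.2f} -> {after.mean_tanimoto_distance:.2f}")
print(f"scaffold SSE:           {before.sse:.2f} -> {after.sse:.2f}")
print(result.report.sequential_remaining)
```

prints

```
60 fragments -> 52 prefiltered -> 13 curated
mean Tanimoto distance: 0.83 -> 0.57
scaffold SSE:           0.88 -> 0.87
                 AP  FP  SE  GA  B1  B2  total
pains            14   9   7   7   4   4     45
brenk            13   8   6   6   4   4     41
ro3              11   7   5   5   3   3     34
qed              10   6   5   5   3   3     32
building_blocks   8   6   5   5   3   3     30
syba              4   3   2   2   1   1     13
```

The sequential table lists the fragments remaining in each subpocket pool
after each cascade step: the prefilters removed 8 of 60 fragments
(duplicates, uncut ligands, pool X), the substructure/property filters
removed the seeded offenders, the building-block filter removed the
fragments outside the mock commercial set, and the synthesizability score
removed the marker-bearing fragments; 13 fragments survive with scaffold
diversity (SSE) nearly unchanged. On real libraries the same call takes an
SDF with fields `subpocket`, `neighbor_subpockets`, `kinase`, `pdb`,
`ligand` (`read_library` / `write_library`), a building-block SMILES/SDF
file, a trained or loaded score model, and an HTTP retrosynthesis backend.

A `kinfrags` command line mirrors the library:
`fragment`, `prefilter`, `filter`, `pairs`, `recombine`, `analyze`,
`report` — see `kinfrags --help`.

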