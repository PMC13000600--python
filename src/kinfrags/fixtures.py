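"""Deterministic toy fixtures: fragment libraries with known ground truth,
3D complexes with known decompositions, mock building-block sets, training
corpora for the synthesizability score, and a scripted retrosynthesis
backend.  Everything is a pure function of a seed/spec, so the whole
pipeline is testable offline.

Ground-truth exactness relies on the fixture vocabulary being a substructure
antichain: no body (dummy-free) embeds in any other body or in another
body's methylated superstructure.  Clean bodies are therefore single
heterocycles with pairwise distinct ring compositions, and the alert/Ro3
motifs carry unique functional groups.  Fixtures exercise code paths; they
do not emulate the statistical realism of kinase chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .core import (
    DEFAULT_ADJACENCY,
    POOL_X,
    SUBPOCKETS,
    Fragment,
    FragmentLibrary,
    Provenance,
    SubpocketGeometry,
    strip_attachment_points,
)
from .fragmentation import Ligand3D
from .pairs import RetroBackend, RetroSuggestion
from .properties import DEFAULT_QED_THRESHOLD, qed

logger = logging.getLogger(__name__)

# clean bodies: alert-free, Ro3-passing, QED above the default threshold,
# pairwise non-embeddable (distinct ring systems, checked against each
# other's methylated superstructures).  Attachment dummies are added
# programmatically on aromatic CH positions (environment 16).
CLEAN_BODIES: tuple[str, ...] = (
    "CN(C)C(=O)c1ccc2ncccc2c1",  # quinoline carboxamide
    "Cc1nc2ccccc2c(=O)n1C",  # quinazolinone
    "CC(=O)Cc1c[nH]c2ccccc12",  # indolyl ketone
    "CNC(=O)c1cc2ccccc2o1",  # benzofuran carboxamide
    "CC(=O)Nc1cc2ccccc2s1",  # benzothiophene acetamide
    "Cc1nc2ccccc2n1C",  # dimethylbenzimidazole
    "O=C1CCOc2ccccc12",  # chromanone
    "Cc1cnc2ccccc2n1",  # methylquinoxaline
    "Cc1ccc2ncccc2n1",  # methylnaphthyridine
    "Cc1nc2ccccc2o1",  # methylbenzoxazole
    "CN(C)c1nc2ccccc2s1",  # dimethylaminobenzothiazole
    "CC(=O)N1CCCc2ccccc21",  # acetyl tetrahydroquinoline
    "CC(=O)N1CCc2ccccc21",  # acetyl indoline
    "Cc1c[nH]c2ncccc12",  # methylpyrrolopyridine
    "Cc1cnc2ccccn12",  # methylimidazopyridine
    "CNC(=O)c1ccc2c(c1)CCO2",  # dihydrobenzofuran carboxamide
    "CC(=O)N1CCOc2ccccc21",  # acetyl benzoxazine
    "Cc1cc(=O)n(C)c2ccccc12",  # dimethylquinolinone
    "Cc1ncc2cccnc2n1",  # methylpyridopyrimidine
    "Cn1cnc2ccncc21",  # methylimidazopyridine isomer
    "CS(=O)(=O)N1CCc2ccccc21",  # methanesulfonyl indoline
    "Cc1n[nH]c2ncccc12",  # methylpyrazolopyridine
    "Cc1nnc2ccccn12",  # methyltriazolopyridine
)


def _with_attachments(core_smiles: str, n: int, env: int = 16) -> str:
    """Core body SMILES with ``n`` placeholder atoms added on aromatic CH."""
    mol = Chem.MolFromSmiles(core_smiles)
    anchors = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]
    if len(anchors) < n:
        raise ValueError(f"body {core_smiles!r} has only {len(anchors)} aromatic CH positions")
    rw = Chem.RWMol(mol)
    for idx in anchors[:n]:
        dummy = Chem.Atom(0)
        dummy.SetIsotope(env)
        d = rw.AddAtom(dummy)
        rw.AddBond(idx, d, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(idx).SetNumExplicitHs(0)
        rw.GetAtomWithIdx(idx).SetNoImplicit(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)

# alert motifs; flags: (pains, brenk) hit by the published catalogs
PAINS_BODIES: tuple[tuple[str, bool, bool], ...] = (
    ("[8*]Cc1ccc(N(C)C)cc1", True, False),  # dialkyl aniline (PAINS only)
    ("[16*]c1ccc(O)c(O)c1", True, True),  # catechol
    ("[8*]CC(=S)CC", True, True),  # thioketone
)
BRENK_BODIES: tuple[tuple[str, bool, bool], ...] = (
    ("[16*]c1ccc(cc1)[N+](=O)[O-]", False, True),  # aromatic nitro
    ("[8*]CC[N+](=O)[O-]", False, True),  # aliphatic nitro
)
# alert-free, Ro3-passing bodies whose QED sits below the default threshold
QED_BODIES: tuple[str, ...] = (
    "[16*]c1nnco1",  # 1,3,4-oxadiazole
    "[16*]c1oncn1",  # 1,2,4-oxadiazole
)
# Ro3 violators, alert-free
RO3_BODIES: tuple[str, ...] = (
    "[8*]CC(C)(COC)COC",  # > 3 rotatable bonds (ring-free)
    "[16*]c1ccc(-c2ccc(-c3ccc(-c4ccccc4)cc3)cc2)cc1",  # MW > 300, logP > 3
    "[16*]CC(O)C(O)C(O)C(O)CO",  # HBD > 3, PSA > 60 (ring-free)
)

UNFRAGMENTED_BODIES = ("C1CCNCC1", "C1CCOC1", "C1CCCCC1", "C1CCCC1")
X_ONLY_BODIES = ("[8*]C1CCOCC1", "[8*]C1CCNC1", "[8*]C1COCO1")
X_POOL_BODIES = ("[8*]C1CCSC1", "[8*]C1CCSCC1", "[8*]C1CCSCCC1")

#: subpocket -> adjacent subpockets, canonical order
ADJACENT: dict[str, tuple[str, ...]] = {
    s: tuple(t for t in SUBPOCKETS if frozenset((s, t)) in DEFAULT_ADJACENCY)
    for s in SUBPOCKETS
}

DEFAULT_POOL_SIZES: dict[str, int] = {"AP": 8, "FP": 6, "SE": 5, "GA": 4, "B1": 3, "B2": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy library; generation is a pure function of the spec."""

    seed: int = 0
    pool_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_POOL_SIZES))
    pains_fraction: float = 0.0
    brenk_fraction: float = 0.0
    ro3_fraction: float = 0.0
    qed_fraction: float = 0.0
    syba_fraction: float = 0.0
    n_duplicates: int = 0
    n_unfragmented: int = 0
    n_x_pool: int = 0
    n_x_only: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pains_fraction",
            "brenk_fraction",
            "ro3_fraction",
            "qed_fraction",
            "syba_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if (
            self.pains_fraction
            + self.brenk_fraction
            + self.ro3_fraction
            + self.qed_fraction
            + self.syba_fraction
        ) > 1.0 + 1e-9:
            raise ValueError("seeded fractions must not exceed 1 in total")
        for pocket, size in self.pool_sizes.items():
            if pocket not in SUBPOCKETS:
                raise ValueError(f"unknown subpocket {pocket!r} in pool sizes")
            if size < 0:
                raise ValueError("pool sizes must be non-negative")


def _counts(spec: FixtureSpec, n: int) -> tuple[int, int, int, int, int, int]:
    n_pains = int(round(spec.pains_fraction * n))
    n_brenk = int(round(spec.brenk_fraction * n))
    n_ro3 = int(round(spec.ro3_fraction * n))
    n_qed = int(round(spec.qed_fraction * n))
    n_syba = int(round(spec.syba_fraction * n))
    n_clean = n - n_pains - n_brenk - n_ro3 - n_qed - n_syba
    if (
        n_pains > len(PAINS_BODIES)
        or n_brenk > len(BRENK_BODIES)
        or n_ro3 > len(RO3_BODIES)
        or n_qed > len(QED_BODIES)
    ):
        raise ValueError("infeasible fixture spec: not enough distinct seeded motifs")
    if n_clean < 0 or n_clean + n_syba > len(CLEAN_BODIES):
        raise ValueError("infeasible fixture spec: pool size vs clean vocabulary")
    return n_clean, n_pains, n_brenk, n_ro3, n_qed, n_syba


def _marker_variant(core_smiles: str) -> str:
    """Core body with the hard-to-synthesize marker bonded at its last
    aromatic CH (the first stays free for the attachment point)."""
    mol = Chem.MolFromSmiles(core_smiles)
    marker = Chem.MolFromSmiles(HARD_MARKER)
    anchors = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]
    if len(anchors) < 2:
        raise ValueError(f"body {core_smiles!r} lacks positions for marker + attachment")
    rw = Chem.RWMol(Chem.CombineMols(mol, marker))
    ch2 = mol.GetNumAtoms() + 3  # a CH2 of the marker ring
    rw.AddBond(anchors[-1], ch2, Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(anchors[-1]).SetNumExplicitHs(0)
    rw.GetAtomWithIdx(anchors[-1]).SetNoImplicit(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def make_toy_library(spec: FixtureSpec) -> tuple[FragmentLibrary, pd.DataFrame]:
    """Build a toy library plus a per-fragment ground-truth label table.

    Labels (keyed by the unique ligand id): is_duplicate / is_unfragmented /
    is_x_pool / is_x_only for the prefilters; should_fail_pains /
    should_fail_brenk / should_fail_ro3 by seeded motif; the fragment's QED
    score and should_fail_qed relative to the default threshold.  Align the
    table to a library with :func:`align_labels`.
    """
    fragments: list[Fragment] = []
    rows: list[dict] = []

    def add(
        smiles: str,
        pocket: str,
        neighbors: Sequence[str],
        ligand: str,
        kinase: str,
        **labels,
    ) -> None:
        frag = Fragment.from_smiles(
            smiles,
            pocket,
            neighbors,
            Provenance(kinase=kinase, pdb=f"P-{ligand}", ligand=ligand),
        )
        fragments.append(frag)
        q = qed(frag).score
        row = {
            "ligand": ligand,
            "subpocket": pocket,
            "smiles": frag.smiles,
            "is_duplicate": False,
            "is_unfragmented": False,
            "is_x_pool": False,
            "is_x_only": False,
            "should_fail_pains": False,
            "should_fail_brenk": False,
            "should_fail_ro3": False,
            "has_syba_marker": False,
            "qed": q,
            "should_fail_qed": q < DEFAULT_QED_THRESHOLD,
        }
        row.update(labels)
        rows.append(row)

    # marker bodies are drawn from the top of the vocabulary in every pool;
    # the clean and marker core sets must stay globally disjoint because
    # building-block coverage is decided per structure across the library
    all_counts = {p: _counts(spec, int(spec.pool_sizes.get(p, 0))) for p in SUBPOCKETS}
    max_clean = max((c[0] for c in all_counts.values()), default=0)
    max_syba = max((c[5] for c in all_counts.values()), default=0)
    if max_clean + max_syba > len(CLEAN_BODIES):
        raise ValueError("infeasible fixture spec: clean and marker vocabularies overlap")

    for pocket in SUBPOCKETS:
        n = int(spec.pool_sizes.get(pocket, 0))
        if n == 0:
            continue
        n_clean, n_pains, n_brenk, n_ro3, n_qed, n_syba = all_counts[pocket]
        adjacent = ADJACENT[pocket]
        entries: list[tuple[str, dict]] = []
        for i in range(n_clean):
            use_two = i % 2 == 0 and len(adjacent) >= 2
            entries.append((_with_attachments(CLEAN_BODIES[i], 2 if use_two else 1), {}))
        for i in range(n_syba):
            # marker bodies come from the far end of the vocabulary so their
            # cores never coincide with this pool's clean bodies
            variant = _marker_variant(CLEAN_BODIES[len(CLEAN_BODIES) - 1 - i])
            entries.append((_with_attachments(variant, 1), {"has_syba_marker": True}))
        for i in range(n_pains):
            smi, pains, brenk = PAINS_BODIES[i]
            entries.append((smi, {"should_fail_pains": pains, "should_fail_brenk": brenk}))
        for i in range(n_brenk):
            smi, pains, brenk = BRENK_BODIES[i]
            entries.append((smi, {"should_fail_pains": pains, "should_fail_brenk": brenk}))
        for i in range(n_ro3):
            entries.append((RO3_BODIES[i], {"should_fail_ro3": True}))
        for i in range(n_qed):
            entries.append((QED_BODIES[i], {}))  # should_fail_qed set from the score
        for j, (smiles, labels) in enumerate(entries):
            n_attach = smiles.count("*")
            neighbors = [adjacent[(j + k) % len(adjacent)] for k in range(n_attach)]
            add(
                smiles,
                pocket,
                neighbors,
                ligand=f"{pocket}-L{j:03d}",
                kinase=f"KIN{1 + j % 3}",
                **labels,
            )

    # prefilter seeds (all placed in/around the AP pool)
    for k in range(spec.n_duplicates):
        one = _with_attachments(CLEAN_BODIES[k % len(CLEAN_BODIES)], 1)
        add(one, "AP", ["FP"], ligand=f"AP-DUP{k:02d}", kinase="ZZZDUP", is_duplicate=True)
    for k in range(spec.n_unfragmented):
        add(
            UNFRAGMENTED_BODIES[k % len(UNFRAGMENTED_BODIES)],
            "AP",
            [],
            ligand=f"AP-UNF{k:02d}",
            kinase="ZZZUNF",
            is_unfragmented=True,
        )
    for k in range(spec.n_x_only):
        add(
            X_ONLY_BODIES[k % len(X_ONLY_BODIES)],
            "AP",
            [POOL_X],
            ligand=f"AP-XON{k:02d}",
            kinase="ZZZXON",
            is_x_only=True,
        )
    for k in range(spec.n_x_pool):
        add(
            X_POOL_BODIES[k % len(X_POOL_BODIES)],
            POOL_X,
            ["AP"],
            ligand=f"X-L{k:03d}",
            kinase="ZZZX",
            is_x_pool=True,
        )

    labels = pd.DataFrame(rows).set_index("ligand")
    labels["prefilter_survivor"] = ~(
        labels["is_duplicate"]
        | labels["is_unfragmented"]
        | labels["is_x_pool"]
        | labels["is_x_only"]
    )
    return FragmentLibrary(fragments, metadata={"source": f"fixture(seed={spec.seed})"}), labels


def align_labels(library: FragmentLibrary, labels: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth labels reindexed to the library's fragment order."""
    order = [f.provenance.ligand for f in library.fragments()]
    return labels.loc[order].reset_index()


# --------------------------------------------------------------------------
# mock building blocks
# --------------------------------------------------------------------------


def make_mock_bb_set(
    library: FragmentLibrary, coverage_fraction: float, seed: int
) -> tuple[list[str], pd.Series]:
    """Building-block SMILES covering an exact fraction of the library.

    For each covered fragment a methylated superstructure of its dummy-free
    form is emitted.  Coverage is decided per distinct dummy-free structure
    (fragments sharing a structure are covered together); with the antichain
    fixture vocabulary, exactly the chosen structures match.  Returns the
    block SMILES and a boolean should-pass series aligned to the library.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage fraction must lie in [0, 1]")
    fragments = library.fragments()
    stripped = [Chem.MolToSmiles(strip_attachment_points(f)) for f in fragments]
    unique = sorted(set(stripped))
    n_covered = int(round(coverage_fraction * len(unique)))
    rng = np.random.default_rng(seed)
    covered = set(
        unique[i] for i in sorted(rng.choice(len(unique), size=n_covered, replace=False))
    )
    blocks = [_methylate(Chem.MolFromSmiles(s)) for s in sorted(covered)]
    should_pass = pd.Series([s in covered for s in stripped], name="should_pass_bb")
    return blocks, should_pass


def _methylate(mol: Chem.Mol) -> str:
    """SMILES of the molecule with one methyl added at the first viable atom."""
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() > 0:
            rw = Chem.RWMol(mol)
            c = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(atom.GetIdx(), c, Chem.BondType.SINGLE)
            rw.GetAtomWithIdx(atom.GetIdx()).SetNumExplicitHs(0)
            rw.GetAtomWithIdx(atom.GetIdx()).SetNoImplicit(False)
            try:
                out = rw.GetMol()
                Chem.SanitizeMol(out)
                return Chem.MolToSmiles(out)
            except Chem.rdchem.MolSanitizeException:
                continue
    return Chem.MolToSmiles(mol)  # fully substituted: the block is the fragment itself


# --------------------------------------------------------------------------
# synthesizability-score corpora
# --------------------------------------------------------------------------

#: marker substructure that tags hard-to-synthesize fixture molecules
HARD_MARKER = "FC1(F)CC1"


def _decorated_body(rng: np.random.Generator, with_marker: bool) -> Chem.Mol:
    """One fixture molecule: a methyl-decorated clean body (easy) or a bare
    body carrying the hard marker (hard).

    Easy and hard molecules share the heterocycle cores (those substructures
    end up with near-zero weights) and differ in their peripheral chemistry:
    methylated ring environments occur only in the easy corpus, the marker
    only in the hard one.
    """
    body = CLEAN_BODIES[int(rng.integers(len(CLEAN_BODIES)))]
    mol = Chem.MolFromSmiles(body)
    if not with_marker:
        for _ in range(1 + int(rng.integers(0, 3))):
            mol = Chem.MolFromSmiles(_methylate(mol))
    if with_marker:
        marker = Chem.MolFromSmiles(HARD_MARKER)
        rw = Chem.RWMol(Chem.CombineMols(mol, marker))
        ring_atoms = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
        anchor = ring_atoms[int(rng.integers(len(ring_atoms)))]
        ch2 = mol.GetNumAtoms() + 3  # a CH2 of the marker ring
        rw.AddBond(anchor, ch2, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(anchor).SetNumExplicitHs(0)
        rw.GetAtomWithIdx(anchor).SetNoImplicit(False)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    return mol


def make_syba_corpus(
    seed: int, n_easy: int = 40, n_hard: int = 40
) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    """Training corpora: easy = decorated clean bodies; hard = the same
    construction seeded with the marker substructure."""
    rng = np.random.default_rng(seed)
    easy = [_decorated_body(rng, with_marker=False) for _ in range(n_easy)]
    hard = [_decorated_body(rng, with_marker=True) for _ in range(n_hard)]
    return easy, hard


def make_syba_probes(seed: int, n: int = 20) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    """Held-out probe molecules (marker-free, marker-bearing) for separation checks."""
    rng = np.random.default_rng(seed + 104729)  # distinct stream from the corpus
    clean = [_decorated_body(rng, with_marker=False) for _ in range(n)]
    marked = [_decorated_body(rng, with_marker=True) for _ in range(n)]
    return clean, marked


# --------------------------------------------------------------------------
# scripted retrosynthesis backend
# --------------------------------------------------------------------------


class MockRetroBackend(RetroBackend):
    """Lookup-table one-step retrosynthesis: product SMILES -> precursor lists.

    Unlisted products yield no routes.  Every query is recorded in
    ``call_log`` for test assertions.
    """

    def __init__(self, approval_table: Mapping[str, Sequence[Sequence[str]]] | None = None):
        self.table = {
            Chem.CanonSmiles(k): [list(p) for p in v] for k, v in (approval_table or {}).items()
        }
        self.call_log: list[str] = []

    def suggest(self, product_smiles: str) -> list[RetroSuggestion]:
        self.call_log.append(product_smiles)
        key = Chem.CanonSmiles(product_smiles)
        suggestions = []
        for precursors in self.table.get(key, []):
            mols = tuple(m for m in (Chem.MolFromSmiles(s) for s in precursors) if m)
            suggestions.append(RetroSuggestion(precursors=mols, score=1.0))
        return suggestions

    @classmethod
    def approving(cls, pairs) -> "MockRetroBackend":
        """Backend that approves exactly the given pairs (precursors = the
        pair's dummy-free fragments)."""
        table = {}
        for pair in pairs:
            table[pair.query_smiles] = [
                [
                    Chem.MolToSmiles(strip_attachment_points(pair.frag_a)),
                    Chem.MolToSmiles(strip_attachment_points(pair.frag_b)),
                ]
            ]
        return cls(table)


# --------------------------------------------------------------------------
# toy 3D complexes with known decompositions
# --------------------------------------------------------------------------

#: geometry with well-separated centers so assignments are unambiguous
def toy_geometry() -> SubpocketGeometry:
    return SubpocketGeometry(
        centers={
            "AP": np.array([0.0, 0.0, 0.0]),
            "FP": np.array([20.0, 0.0, 0.0]),
            "SE": np.array([0.0, 20.0, 0.0]),
            "GA": np.array([-20.0, 0.0, 0.0]),
            "B1": np.array([-40.0, 0.0, 0.0]),
            "B2": np.array([-40.0, 20.0, 0.0]),
        },
        distance_cutoff=8.0,
    )


_BODY_MOLS = {  # dummy-free bodies used to assemble ligands
    "pyridine": "c1ccncc1",
    "pyrimidine": "c1cncnc1",
    "pyrazine": "c1cnccn1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "oxazole": "c1ocnc1",
    "thiazole": "c1scnc1",
    "pyridazine": "c1ccnnc1",
}


def _assemble_ligand(
    pieces: Sequence[tuple[str, np.ndarray]],
    junctions: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    provenance: Provenance,
) -> tuple[Ligand3D, list[tuple[Chem.Mol, list[int]]]]:
    """Join aromatic bodies by single bonds; atoms jittered around positions.

    Returns the ligand and, per piece, (body mol, junction partner indices)
    for expected-library construction.
    """
    mols = [Chem.MolFromSmiles(_BODY_MOLS[name]) for name, _ in pieces]
    offsets = np.cumsum([0] + [m.GetNumAtoms() for m in mols[:-1]]).tolist()
    combined = mols[0]
    for m in mols[1:]:
        combined = Chem.CombineMols(combined, m)
    rw = Chem.RWMol(combined)
    used_h: dict[int, int] = {i: 0 for i in range(len(pieces))}

    def junction_atom(piece: int) -> int:
        """n-th aromatic CH of the piece, counted per use."""
        count = 0
        for atom in mols[piece].GetAtoms():
            if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0 and atom.GetAtomicNum() == 6:
                if count == used_h[piece]:
                    used_h[piece] += 1
                    return offsets[piece] + atom.GetIdx()
                count += 1
        raise ValueError("piece has no free aromatic CH left")

    partner_lists: list[list[int]] = [[] for _ in pieces]
    for i, j in junctions:
        ai, aj = junction_atom(i), junction_atom(j)
        rw.AddBond(ai, aj, Chem.BondType.SINGLE)
        for idx in (ai, aj):
            rw.GetAtomWithIdx(idx).SetNumExplicitHs(0)
            rw.GetAtomWithIdx(idx).SetNoImplicit(False)
        partner_lists[i].append(j)
        partner_lists[j].append(i)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for p, (_, center) in enumerate(pieces):
        n_atoms = mols[p].GetNumAtoms()
        jitter = rng.normal(scale=0.8, size=(n_atoms, 3))
        for a in range(n_atoms):
            x, y, z = center + jitter[a]
            conf.SetAtomPosition(offsets[p] + a, Point3D(x, y, z))
    mol.AddConformer(conf)
    return Ligand3D(mol=mol, provenance=provenance), list(zip(mols, partner_lists))


def fragment_signature(fragment: Fragment) -> tuple[str, str, tuple[str, ...]]:
    """(subpocket, dummy-free canonical SMILES, sorted neighbor subpockets).

    The recovery contract for toy complexes compares fragments by this
    signature; BRICS environment labels are checked separately against the
    reference implementation.
    """
    return (
        fragment.subpocket,
        Chem.MolToSmiles(strip_attachment_points(fragment)),
        tuple(sorted(fragment.neighbor_subpockets)),
    )


def make_toy_complexes(
    seed: int,
) -> tuple[list[Ligand3D], SubpocketGeometry, list[tuple[str, str, tuple[str, ...]]]]:
    """Toy ligands whose fragmentation outcome is known by construction.

    Returns (ligands, geometry, expected fragment signatures): one ligand
    spanning AP/FP, one with two AP pieces that must merge, and one with a
    piece placed beyond the cutoff (pool X).
    """
    rng = np.random.default_rng(seed)
    geometry = toy_geometry()
    centers = geometry.centers
    far = np.array([30.0, 30.0, 30.0])

    ligands: list[Ligand3D] = []
    expected: list[tuple[str, str, tuple[str, ...]]] = []

    # ligand 1: pyridine@AP - furan@FP
    lig, bodies = _assemble_ligand(
        [("pyridine", centers["AP"]), ("furan", centers["FP"])],
        [(0, 1)],
        rng,
        Provenance(kinase="TOY1", pdb="TOY1", ligand="LIG1"),
    )
    ligands.append(lig)
    expected.append(("AP", Chem.CanonSmiles("c1ccncc1"), ("FP",)))
    expected.append(("FP", Chem.CanonSmiles("c1ccoc1"), ("AP",)))

    # ligand 2: thiophene@AP - pyrimidine@AP - oxazole@FP; the two AP pieces merge
    lig, _ = _assemble_ligand(
        [
            ("thiophene", centers["AP"] + np.array([-2.0, 0, 0])),
            ("pyrimidine", centers["AP"] + np.array([2.0, 0, 0])),
            ("oxazole", centers["FP"]),
        ],
        [(0, 1), (1, 2)],
        rng,
        Provenance(kinase="TOY2", pdb="TOY2", ligand="LIG2"),
    )
    ligands.append(lig)
    # the merged AP fragment is the thiophene-pyrimidine assembly alone (the
    # oxazole junction atom keeps its hydrogen); built by the same explicit
    # graph construction, independent of the fragmentation code under test
    merged_lig, _ = _assemble_ligand(
        [
            ("thiophene", centers["AP"] + np.array([-2.0, 0, 0])),
            ("pyrimidine", centers["AP"] + np.array([2.0, 0, 0])),
        ],
        [(0, 1)],
        np.random.default_rng(seed),
        Provenance(kinase="TOY2", pdb="TOY2", ligand="LIG2-EXPECTED"),
    )
    expected.append(("AP", Chem.MolToSmiles(merged_lig.mol), ("FP",)))
    expected.append(("FP", Chem.CanonSmiles("c1ocnc1"), ("AP",)))

    # ligand 3: pyrazine@AP - thiazole beyond the cutoff -> pool X
    lig, _ = _assemble_ligand(
        [("pyrazine", centers["AP"]), ("thiazole", far)],
        [(0, 1)],
        rng,
        Provenance(kinase="TOY3", pdb="TOY3", ligand="LIG3"),
    )
    ligands.append(lig)
    expected.append(("AP", Chem.CanonSmiles("c1cnccn1"), (POOL_X,)))
    expected.append((POOL_X, Chem.CanonSmiles("c1scnc1"), ("AP",)))

    return ligands, geometry, expected


def make_random_ligands(seed: int, n: int = 50) -> tuple[list[Ligand3D], SubpocketGeometry]:
    """Random chains of 2-4 aromatic bodies for fragmentation round-trip tests."""
    rng = np.random.default_rng(seed)
    geometry = toy_geometry()
    names = list(_BODY_MOLS)
    center_labels = list(SUBPOCKETS)
    ligands = []
    for k in range(n):
        n_pieces = int(rng.integers(2, 5))
        chosen = [names[int(rng.integers(len(names)))] for _ in range(n_pieces)]
        labels = list(rng.choice(center_labels, size=n_pieces, replace=False))
        pieces = [(name, geometry.centers[lbl]) for name, lbl in zip(chosen, labels)]
        junctions = [(i, i + 1) for i in range(n_pieces - 1)]
        try:
            ligand, _ = _assemble_ligand(
                pieces,
                junctions,
                rng,
                Provenance(kinase="RND", pdb=f"RND{k:03d}", ligand=f"R{k:03d}"),
            )
        except ValueError:
            continue  # a piece ran out of free aromatic CH positions
        ligands.append(ligand)
    return ligands, geometry
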