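"""Synthesizability filters: a trainable Bernoulli fragment score and a
commercial building-block substructure filter.

The score follows the SYBA (synthetic Bayesian accessibility) functional
form: a molecule is decomposed into radius-2 circular substructures (hashed
to 32-bit ids) and each distinct substructure f contributes a log-odds
weight estimated from two training corpora, one of easy-to-synthesize and
one of hard-to-synthesize molecules:

    w(f) = log2 (n_easy(f) + s) / (N_easy + 2s)
         - log2 (n_hard(f) + s) / (N_hard + 2s)

with Laplace pseudo-count s (default 1).  n_*(f) counts molecules that
contain f; N_* are corpus sizes.  The molecule score is the sum of weights
over its distinct substructures: 0 means both corpora are equally likely,
positive means easier to synthesize, negative harder.  Fragments scoring
below the cutoff (default 0, i.e. strictly negative scores) are removed.

The building-block filter keeps a fragment only when its dummy-free form
embeds as a substructure of at least one molecule in a commercial
building-block set, indicating the fragment is commercially accessible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdSubstructLibrary

from .core import Fragment, FragmentLibrary, strip_attachment_points

logger = logging.getLogger(__name__)

_MORGAN_RADIUS = 2
_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=_MORGAN_RADIUS)


def substructure_ids(mol_or_fragment: Fragment | Chem.Mol) -> frozenset[int]:
    """Distinct hashed radius-2 circular substructure ids of the dummy-free graph."""
    mol = strip_attachment_points(mol_or_fragment)
    fp = _morgan.GetSparseCountFingerprint(mol)
    return frozenset(fp.GetNonzeroElements().keys())


@dataclass
class SybaModel:
    """Log-odds weights over circular substructures plus training metadata."""

    weights: dict[int, float]
    n_easy: int
    n_hard: int
    smoothing: float = 1.0

    @property
    def default_weight(self) -> float:
        """Weight of a substructure never seen in training (pure smoothing)."""
        s = self.smoothing
        return math.log2(s / (self.n_easy + 2 * s)) - math.log2(s / (self.n_hard + 2 * s))

    def weight(self, sub_id: int) -> float:
        return self.weights.get(sub_id, self.default_weight)

    def save(self, path: str | Path) -> None:
        """Write weights as two-column CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(
            sorted(self.weights.items()), columns=["substructure_id", "weight"]
        ).to_csv(path, index=False)
        meta = {"n_easy": self.n_easy, "n_hard": self.n_hard, "smoothing": self.smoothing}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SybaModel":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            weights={int(r.substructure_id): float(r.weight) for r in frame.itertuples()},
            n_easy=int(meta["n_easy"]),
            n_hard=int(meta["n_hard"]),
            smoothing=float(meta["smoothing"]),
        )


def train_syba(
    easy: Sequence[Chem.Mol],
    hard: Sequence[Chem.Mol],
    smoothing: float = 1.0,
) -> SybaModel:
    """Estimate substructure log-odds weights from easy/hard training corpora.

    Counts are per molecule (Bernoulli: a substructure is present or not).
    Swapping the corpora negates every weight.
    """
    if len(easy) == 0 or len(hard) == 0:
        raise ValueError("both training corpora must be non-empty")
    n_easy, n_hard = len(easy), len(hard)
    counts_easy: dict[int, int] = {}
    counts_hard: dict[int, int] = {}
    for mol in easy:
        for sub in substructure_ids(mol):
            counts_easy[sub] = counts_easy.get(sub, 0) + 1
    for mol in hard:
        for sub in substructure_ids(mol):
            counts_hard[sub] = counts_hard.get(sub, 0) + 1
    s = smoothing
    weights = {}
    for sub in set(counts_easy) | set(counts_hard):
        p_easy = (counts_easy.get(sub, 0) + s) / (n_easy + 2 * s)
        p_hard = (counts_hard.get(sub, 0) + s) / (n_hard + 2 * s)
        weights[sub] = math.log2(p_easy) - math.log2(p_hard)
    return SybaModel(weights=weights, n_easy=n_easy, n_hard=n_hard, smoothing=s)


def syba_score(model: SybaModel, mol_or_fragment: Fragment | Chem.Mol) -> float:
    """Sum of substructure weights over the molecule's distinct substructures.

    Scored on the dummy-free graph, so attachment decoration does not change
    the value.
    """
    return sum(model.weight(sub) for sub in substructure_ids(mol_or_fragment))


def filter_syba(
    library: FragmentLibrary, model: SybaModel, cutoff: float = 0.0
) -> pd.DataFrame:
    """Pass flags (column ``syba``): fail iff score < cutoff (exactly 0 passes)."""
    fragments = library.fragments()
    return pd.DataFrame(
        {"syba": [syba_score(model, f) >= cutoff for f in fragments]},
        index=range(len(fragments)),
    )


class BuildingBlockIndex:
    """A building-block molecule set prepared for substructure queries."""

    def __init__(self, mols: Iterable[Chem.Mol | str], source: str = ""):
        self._lib = rdSubstructLibrary.SubstructLibrary()
        self.source = source
        n_skipped = 0
        for entry in mols:
            mol = Chem.MolFromSmiles(entry) if isinstance(entry, str) else entry
            if mol is None:
                n_skipped += 1
                continue
            self._lib.AddMol(mol)
        if n_skipped:
            logger.warning("building-block index: skipped %d unparseable entries", n_skipped)
        self.n_skipped = n_skipped

    def __len__(self) -> int:
        return len(self._lib)

    def has_superstructure(self, query: Chem.Mol) -> bool:
        """True when the query embeds in at least one indexed building block."""
        if len(self._lib) == 0:
            return False
        return len(self._lib.GetMatches(query, maxResults=1)) > 0

    @classmethod
    def from_file(cls, path: str | Path) -> "BuildingBlockIndex":
        """Load building blocks from a SMILES file (one per line) or SDF."""
        path = Path(path)
        if path.suffix.lower() in (".sdf", ".sd"):
            mols: Iterable = Chem.SDMolSupplier(str(path), sanitize=True)
        else:
            mols = [
                line.split()[0]
                for line in path.read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
        return cls(mols, source=str(path))


def build_bb_index(building_blocks: Iterable[Chem.Mol | str], source: str = "") -> BuildingBlockIndex:
    """Index a building-block set for substructure queries (invalid entries skipped)."""
    return BuildingBlockIndex(building_blocks, source=source)


def filter_building_blocks(library: FragmentLibrary, index: BuildingBlockIndex) -> pd.DataFrame:
    """Pass flags (column ``building_blocks``): the dummy-free fragment must be
    a substructure of at least one indexed building block."""
    fragments = library.fragments()
    return pd.DataFrame(
        {
            "building_blocks": [
                index.has_superstructure(strip_attachment_points(f)) for f in fragments
            ]
        },
        index=range(len(fragments)),
    )
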