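"""Fragment pairs and the one-step retrosynthesis gate.

A pair of fragments is *valid* when (i) the two fragments sit in adjacent
subpockets and each carries an attachment point pointing at the other's
subpocket, (ii) the BRICS environment types of the two attachment points are
link-compatible, and (iii) both fragments passed all earlier filters.  Each
valid pair is recombined into the molecule the two fragments would form; a
pluggable one-step retrosynthesis backend proposes precursors for that
product, and the pair counts as feasible when the two fragments embed (as
substructures, dummy-free) into two distinct proposed precursors.  A
fragment survives the gate when it takes part in at least one feasible pair.
"""

from __future__ import annotations

import json
import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS

from .core import Fragment, FragmentLibrary, strip_attachment_points

logger = logging.getLogger(__name__)

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE}


def _build_brics_compatibility() -> frozenset[tuple[int, int]]:
    """Unordered BRICS link-compatible environment-type pairs (published rules)."""
    pairs = set()
    for group in BRICS.reactionDefs:
        for la, lb, _bond in group:
            a, b = int(la.rstrip("ab")), int(lb.rstrip("ab"))
            pairs.add((min(a, b), max(a, b)))
    return frozenset(pairs)


#: 16x16 BRICS environment link-compatibility relation, as unordered pairs
BRICS_COMPATIBLE: frozenset[tuple[int, int]] = _build_brics_compatibility()


def brics_link_compatible(env_a: int, env_b: int) -> bool:
    return (min(env_a, env_b), max(env_a, env_b)) in BRICS_COMPATIBLE


@dataclass
class FragmentPair:
    """Two fragments joined at one attachment point each.

    ``product`` keeps unused attachment points as placeholders for
    bookkeeping; ``query_smiles`` is the hydrogen-capped form sent to the
    retrosynthesis backend.
    """

    index_a: int
    index_b: int
    frag_a: Fragment
    frag_b: Fragment
    attach_a: int
    attach_b: int
    product: Chem.Mol

    @property
    def query_smiles(self) -> str:
        return Chem.MolToSmiles(strip_attachment_points(self.product))


@dataclass(frozen=True)
class RetroSuggestion:
    """One proposed single-step route: precursor molecules plus backend confidence."""

    precursors: tuple[Chem.Mol, ...]
    score: float = 0.0


class RetroBackend(ABC):
    """Contract for a one-step retrosynthesis service."""

    @abstractmethod
    def suggest(self, product_smiles: str) -> list[RetroSuggestion]:
        """Proposed one-step routes for the product; empty when none is found."""


class HttpRetroBackend(RetroBackend):
    """Client for an HTTP one-step retrosynthesis endpoint.

    POSTs ``{"smiles": <product>, **params}`` as JSON and expects
    ``{"suggestions": [{"precursors": [smiles...], "score": x}, ...]}``.
    Query parameters are surfaced in the pipeline config so deployments can
    mirror their service's recommended settings.
    """

    def __init__(
        self,
        url: str,
        timeout: float = 30.0,
        max_suggestions: int = 10,
        params: dict | None = None,
    ):
        self.url = url
        self.timeout = timeout
        self.max_suggestions = max_suggestions
        self.params = dict(params or {})

    def suggest(self, product_smiles: str) -> list[RetroSuggestion]:
        import urllib.request

        payload = json.dumps({"smiles": product_smiles, **self.params}).encode()
        request = urllib.request.Request(
            self.url, data=payload, headers={"Content-Type": "application/json"}
        )
        with urllib.request.urlopen(request, timeout=self.timeout) as response:
            body = json.loads(response.read().decode())
        suggestions = []
        for item in body.get("suggestions", [])[: self.max_suggestions]:
            precursors = tuple(
                m for m in (Chem.MolFromSmiles(s) for s in item.get("precursors", [])) if m
            )
            suggestions.append(RetroSuggestion(precursors=precursors, score=item.get("score", 0.0)))
        return suggestions


def recombine_pair(
    frag_a: Fragment, frag_b: Fragment, attach_a: int, attach_b: int
) -> Chem.Mol:
    """Join two fragments at the given attachment points.

    The two placeholders vanish and one bond of the recorded order forms
    between their anchor atoms; all other placeholders remain.  Raises on a
    valence violation.
    """
    ap_a = frag_a.attachments[attach_a]
    ap_b = frag_b.attachments[attach_b]
    if ap_a.bond_order != ap_b.bond_order:
        raise ValueError("attachment bond orders differ; cannot recombine")
    mol_a, mol_b = frag_a.mol, frag_b.mol
    offset = mol_a.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    idx_a = ap_a.atom_index
    idx_b = ap_b.atom_index + offset
    anchors = []
    for dummy_idx in (idx_a, idx_b):
        atom = combined.GetAtomWithIdx(dummy_idx)
        if atom.GetAtomicNum() != 0:
            raise ValueError("attachment index does not point at a placeholder atom")
        anchors.append(atom.GetBonds()[0].GetOtherAtom(atom).GetIdx())
    combined.AddBond(anchors[0], anchors[1], _BOND_TYPES[ap_a.bond_order])
    for dummy_idx in sorted((idx_a, idx_b), reverse=True):
        combined.RemoveAtom(dummy_idx)
    product = combined.GetMol()
    Chem.SanitizeMol(product)  # raises on valence violations
    return product


def _pair_attachments(
    frag_a: Fragment, frag_b: Fragment
) -> tuple[int, int] | None:
    """First attachment combination (deterministic order) that links a to b."""
    for i, ap_a in enumerate(frag_a.attachments):
        if ap_a.neighbor_subpocket != frag_b.subpocket:
            continue
        for j, ap_b in enumerate(frag_b.attachments):
            if ap_b.neighbor_subpocket != frag_a.subpocket:
                continue
            if ap_a.bond_order != ap_b.bond_order:
                continue
            if brics_link_compatible(ap_a.environment_type, ap_b.environment_type):
                return i, j
    return None


def enumerate_valid_pairs(
    library: FragmentLibrary,
    adjacency: frozenset[frozenset[str]],
    prior_flags: pd.DataFrame | None = None,
) -> list[FragmentPair]:
    """All valid unordered fragment pairs, in deterministic library order.

    ``prior_flags`` (boolean columns aligned to ``library.fragments()``)
    restricts pairing to fragments that passed all earlier filters.  When
    several attachment combinations validate the same pair, the first in
    attachment order is used; the pair is emitted once.
    """
    fragments = library.fragments()
    if prior_flags is not None:
        eligible = prior_flags.all(axis=1).to_numpy()
    else:
        eligible = [True] * len(fragments)
    pairs: list[FragmentPair] = []
    for i, frag_a in enumerate(fragments):
        if not eligible[i]:
            continue
        for j in range(i + 1, len(fragments)):
            frag_b = fragments[j]
            if not eligible[j]:
                continue
            if frozenset((frag_a.subpocket, frag_b.subpocket)) not in adjacency:
                continue
            found = _pair_attachments(frag_a, frag_b)
            if found is None:
                continue
            try:
                product = recombine_pair(frag_a, frag_b, *found)
            except (ValueError, Chem.rdchem.MolSanitizeException) as exc:
                logger.warning("dropping pair (%d, %d): %s", i, j, exc)
                continue
            pairs.append(
                FragmentPair(
                    index_a=i,
                    index_b=j,
                    frag_a=frag_a,
                    frag_b=frag_b,
                    attach_a=found[0],
                    attach_b=found[1],
                    product=product,
                )
            )
    return pairs


def pair_feasible(pair: FragmentPair, suggestions: Sequence[RetroSuggestion]) -> bool:
    """True when some suggestion contains two distinct precursors embedding the
    two fragments (dummy-free, substructure match, either assignment)."""
    query_a = strip_attachment_points(pair.frag_a)
    query_b = strip_attachment_points(pair.frag_b)
    for suggestion in suggestions:
        precursors = suggestion.precursors
        for p in range(len(precursors)):
            for q in range(len(precursors)):
                if p == q:
                    continue
                if precursors[p].HasSubstructMatch(query_a) and precursors[q].HasSubstructMatch(
                    query_b
                ):
                    return True
    return False


@dataclass
class RetroGateResult:
    """Outcome of the retrosynthesis gate over a pair set."""

    flags: pd.DataFrame  # column 'retro', aligned to the library
    feasible_pairs: list[FragmentPair] = field(default_factory=list)
    undetermined: list[str] = field(default_factory=list)  # query SMILES that errored out


def filter_retro(
    library: FragmentLibrary,
    pairs: Sequence[FragmentPair],
    backend: RetroBackend,
    keep_unpaired: bool = False,
    max_retries: int = 1,
    cache: dict[str, list[RetroSuggestion]] | None = None,
    cache_path: str | Path | None = None,
) -> RetroGateResult:
    """Gate fragments on retrosynthetic feasibility of their pairs.

    A fragment passes iff it appears in >= 1 feasible pair.  Fragments with
    no valid pair fail by default (``keep_unpaired`` retains them).  Backend
    responses are cached by product canonical SMILES; backend failures mark
    the pair undetermined (infeasible, reported, retried up to
    ``max_retries``) - never silently feasible.
    """
    cache = cache if cache is not None else {}
    if cache_path is not None and Path(cache_path).exists():
        for line in Path(cache_path).read_text().splitlines():
            entry = json.loads(line)
            cache[entry["product"]] = [
                RetroSuggestion(
                    precursors=tuple(
                        m for m in (Chem.MolFromSmiles(s) for s in sug["precursors"]) if m
                    ),
                    score=sug.get("score", 0.0),
                )
                for sug in entry["suggestions"]
            ]
    new_entries: list[dict] = []
    undetermined: list[str] = []
    feasible_pairs: list[FragmentPair] = []
    passing: set[int] = set()
    for pair in pairs:
        key = pair.query_smiles
        if key not in cache:
            suggestions = None
            for _attempt in range(max_retries + 1):
                try:
                    suggestions = backend.suggest(key)
                    break
                except Exception as exc:  # noqa: BLE001 - backend failures are expected
                    logger.warning("retro backend failed for %s: %s", key, exc)
            if suggestions is None:
                undetermined.append(key)
                continue
            cache[key] = suggestions
            new_entries.append(
                {
                    "product": key,
                    "suggestions": [
                        {
                            "precursors": [Chem.MolToSmiles(m) for m in s.precursors],
                            "score": s.score,
                        }
                        for s in suggestions
                    ],
                }
            )
        if pair_feasible(pair, cache[key]):
            feasible_pairs.append(pair)
            passing.update((pair.index_a, pair.index_b))
    if cache_path is not None and new_entries:
        with open(cache_path, "a") as fh:
            for entry in new_entries:
                fh.write(json.dumps(entry) + "\n")
    n = len(library)
    paired = {p.index_a for p in pairs} | {p.index_b for p in pairs}
    flags = []
    for i in range(n):
        if i in passing:
            flags.append(True)
        elif i not in paired:
            flags.append(keep_unpaired)
        else:
            flags.append(False)
    return RetroGateResult(
        flags=pd.DataFrame({"retro": flags}, index=range(n)),
        feasible_pairs=feasible_pairs,
        undetermined=undetermined,
    )
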