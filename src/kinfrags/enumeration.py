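"""Subpocket-guided enumeration of multi-fragment molecules.

Starting from a core adenine-pocket (AP) fragment, molecules are grown by
joining further fragments at attachment points, one fragment per subpocket
at most, obeying the subpocket adjacency and BRICS link rules at every
junction.  Enumeration is exhaustive and duplicate-free (by canonical
product SMILES plus constituent-fragment multiset), emitted lazily in a
deterministic order.  Open attachment points are hydrogen-capped when the
molecule is finalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .core import Fragment, FragmentLibrary, strip_attachment_points
from .pairs import _BOND_TYPES, brics_link_compatible
from .properties import qed, ro5_veber_table
from .synth import SybaModel, syba_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnumeratedMolecule:
    """A recombination product with its constituent-fragment provenance."""

    mol: Chem.Mol  # hydrogen-capped, dummy-free
    smiles: str
    fragment_indices: tuple[int, ...]  # library positions, sorted
    subpockets: tuple[str, ...]  # aligned with fragment_indices

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_indices)


def _assemble(
    nodes: Sequence[tuple[int, Fragment]],
    bonds: Sequence[tuple[int, int, int, int]],  # (node_i, att_i, node_j, att_j)
) -> Chem.Mol:
    """Join the chosen fragments at the chosen attachment pairs, cap the rest."""
    offsets = []
    combined: Chem.Mol | None = None
    for _, frag in nodes:
        offsets.append(combined.GetNumAtoms() if combined is not None else 0)
        combined = frag.mol if combined is None else Chem.CombineMols(combined, frag.mol)
    rw = Chem.RWMol(combined)
    to_remove = []
    for node_i, att_i, node_j, att_j in bonds:
        ap_i = nodes[node_i][1].attachments[att_i]
        ap_j = nodes[node_j][1].attachments[att_j]
        di = ap_i.atom_index + offsets[node_i]
        dj = ap_j.atom_index + offsets[node_j]
        anchor_i = rw.GetAtomWithIdx(di).GetBonds()[0].GetOtherAtom(rw.GetAtomWithIdx(di)).GetIdx()
        anchor_j = rw.GetAtomWithIdx(dj).GetBonds()[0].GetOtherAtom(rw.GetAtomWithIdx(dj)).GetIdx()
        rw.AddBond(anchor_i, anchor_j, _BOND_TYPES[ap_i.bond_order])
        to_remove.extend((di, dj))
    for idx in sorted(to_remove, reverse=True):
        rw.RemoveAtom(idx)
    product = rw.GetMol()
    Chem.SanitizeMol(product)
    return strip_attachment_points(product)  # cap remaining attachment points


def enumerate_molecules(
    library: FragmentLibrary,
    adjacency: frozenset[frozenset[str]],
    max_fragments: int = 4,
    min_fragments: int = 2,
    core: str = "AP",
) -> Iterator[EnumeratedMolecule]:
    """Lazily enumerate all valid recombinations rooted in a core-subpocket fragment.

    Every product contains exactly one ``core`` fragment, at most one
    fragment per subpocket, between ``min_fragments`` and ``max_fragments``
    fragments in total, and only junctions allowed by subpocket adjacency,
    mutual attachment annotation, matching bond order and BRICS link
    compatibility.
    """
    fragments = list(enumerate(library.fragments()))
    by_subpocket: dict[str, list[tuple[int, Fragment]]] = {}
    for idx, frag in fragments:
        by_subpocket.setdefault(frag.subpocket, []).append((idx, frag))
    seen: set[tuple[tuple[int, ...], str]] = set()

    def grow(
        nodes: list[tuple[int, Fragment]],
        bonds: list[tuple[int, int, int, int]],
        used_attachments: set[tuple[int, int]],
    ) -> Iterator[EnumeratedMolecule]:
        if len(nodes) >= min_fragments:
            try:
                product = _assemble(nodes, bonds)
            except Chem.rdchem.MolSanitizeException as exc:
                logger.warning("dropping assembly %s: %s", [i for i, _ in nodes], exc)
                product = None
            if product is not None:
                indices = tuple(sorted(i for i, _ in nodes))
                smiles = Chem.MolToSmiles(product)
                key = (indices, smiles)
                if key not in seen:
                    seen.add(key)
                    order = np.argsort([i for i, _ in nodes])
                    yield EnumeratedMolecule(
                        mol=product,
                        smiles=smiles,
                        fragment_indices=indices,
                        subpockets=tuple(nodes[k][1].subpocket for k in order),
                    )
        if len(nodes) >= max_fragments:
            return
        used_subpockets = {frag.subpocket for _, frag in nodes}
        for node_pos, (_, frag) in enumerate(nodes):
            for att_pos, ap in enumerate(frag.attachments):
                if (node_pos, att_pos) in used_attachments:
                    continue
                target = ap.neighbor_subpocket
                if target in used_subpockets or target not in by_subpocket:
                    continue
                if frozenset((frag.subpocket, target)) not in adjacency:
                    continue
                for new_idx, new_frag in by_subpocket[target]:
                    for new_att, new_ap in enumerate(new_frag.attachments):
                        if new_ap.neighbor_subpocket != frag.subpocket:
                            continue
                        if new_ap.bond_order != ap.bond_order:
                            continue
                        if not brics_link_compatible(
                            ap.environment_type, new_ap.environment_type
                        ):
                            continue
                        new_nodes = nodes + [(new_idx, new_frag)]
                        new_bonds = bonds + [(node_pos, att_pos, len(nodes), new_att)]
                        new_used = used_attachments | {
                            (node_pos, att_pos),
                            (len(nodes), new_att),
                        }
                        yield from grow(new_nodes, new_bonds, new_used)

    for idx, frag in by_subpocket.get(core, []):
        yield from grow([(idx, frag)], [], set())


def sample_by_size(
    molecules: Sequence[EnumeratedMolecule],
    proportions: Mapping[int, float],
    n_total: int,
    seed: int,
) -> list[EnumeratedMolecule]:
    """Stratified uniform sampling without replacement by fragment count.

    ``proportions`` maps fragment count -> target fraction (must sum to 1).
    Strata with fewer molecules than their quota are exhausted and logged.
    Reproducible under a fixed seed.
    """
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"size proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[EnumeratedMolecule]] = {}
    for mol in molecules:
        strata.setdefault(mol.n_fragments, []).append(mol)
    # largest-remainder apportionment of n_total over the strata
    raw = {k: v * n_total for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    leftover = n_total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:leftover]:
        counts[k] += 1
    sample: list[EnumeratedMolecule] = []
    for size in sorted(counts):
        pool = strata.get(size, [])
        quota = counts[size]
        if len(pool) < quota:
            logger.warning(
                "stratum n_fragments=%d exhausted: %d available < %d requested",
                size,
                len(pool),
                quota,
            )
            sample.extend(pool)
        else:
            chosen = rng.choice(len(pool), size=quota, replace=False)
            sample.extend(pool[i] for i in sorted(chosen))
    return sample


def evaluate_molecules(
    molecules: Sequence[EnumeratedMolecule],
    syba_model: SybaModel | None = None,
    qed_weights: str = "mean",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Molecule-level property table plus aggregate pass fractions.

    Columns: Ro5 and Veber descriptors and pass flags, QED score, and (when a
    model is given) the synthesizability score.  Rows whose descriptors fail
    are flagged (``descriptor_error``) and excluded from the aggregates.
    """
    rows = []
    errors = 0
    for em in molecules:
        try:
            base = ro5_veber_table([em.mol]).iloc[0].to_dict()
            base["qed"] = qed(em.mol, weights=qed_weights).score
            if syba_model is not None:
                base["syba"] = syba_score(syba_model, em.mol)
            base["smiles"] = em.smiles
            base["n_fragments"] = em.n_fragments
            base["descriptor_error"] = False
        except Exception as exc:  # noqa: BLE001 - per-molecule failures excluded, counted
            logger.warning("descriptor failure for %s: %s", em.smiles, exc)
            base = {"smiles": em.smiles, "n_fragments": em.n_fragments, "descriptor_error": True}
            errors += 1
        rows.append(base)
    table = pd.DataFrame(rows)
    valid = table[~table["descriptor_error"]]
    aggregates: dict[str, float] = {"n_molecules": len(table), "n_descriptor_errors": errors}
    if len(valid):
        aggregates["ro5_pass_fraction"] = float(valid["ro5_pass"].mean())
        aggregates["veber_pass_fraction"] = float(valid["veber_pass"].mean())
        aggregates["mean_qed"] = float(valid["qed"].mean())
        if syba_model is not None:
            aggregates["mean_syba"] = float(valid["syba"].mean())
            aggregates["syba_negative_fraction"] = float((valid["syba"] < 0).mean())
    return table, aggregates
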