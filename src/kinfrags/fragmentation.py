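"""Dissection of 3D kinase ligands into subpocket-assigned fragments.

Bound ligands are cut at BRICS bonds (retrosynthetically meaningful bonds);
each cut end receives a placeholder atom whose isotope encodes the BRICS
chemical-environment type.  Fragments inherit the ligand's 3D coordinates and
are assigned to the subpocket whose geometric center is closest to the
fragment's heavy-atom centroid (pool X beyond the distance cutoff).  Adjacent
fragments that fall into the same subpocket are re-joined into one larger,
more representative subpocket fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS
from rdkit.Geometry import Point3D

from .core import (
    POOL_X,
    SUBPOCKETS,
    Fragment,
    FragmentLibrary,
    Provenance,
    SubpocketGeometry,
    _attachments_from_mol,
)

logger = logging.getLogger(__name__)

# atom-map numbers on placeholder atoms identify the cut a placeholder
# belongs to; the two placeholders of one cut share a map number.


@dataclass
class Ligand3D:
    """A bound ligand: molecular graph with one 3D conformation."""

    mol: Chem.Mol
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        if self.mol.GetNumConformers() != 1:
            raise ValueError("ligand must carry exactly one conformation")
        pos = self.mol.GetConformer().GetPositions()
        if not np.all(np.isfinite(pos)):
            raise ValueError("ligand coordinates must be finite")


@dataclass
class RawFragment:
    """A BRICS piece before merging; placeholders carry cut ids as map numbers."""

    mol: Chem.Mol
    provenance: Provenance = field(default_factory=Provenance)
    subpocket: str | None = None

    def cut_ids(self) -> list[int]:
        return [
            a.GetAtomMapNum()
            for a in self.mol.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
        ]


def _brics_env(label: str) -> int:
    """Map a BRICS label such as '7a'/'7b' to its integer environment type."""
    return int(label.rstrip("ab"))


def brics_cut(ligand: Ligand3D) -> list[RawFragment]:
    """Cut a ligand at all BRICS bonds.

    Each severed bond produces two placeholder atoms that sit at the position
    of the lost partner atom, are isotope-labeled with the BRICS environment
    type of their side, and share an atom-map number identifying the cut.
    A ligand without BRICS bonds comes back intact as a single piece.
    """
    mol = Chem.Mol(ligand.mol)
    bonds = list(BRICS.FindBRICSBonds(mol))
    rw = Chem.RWMol(mol)
    conf = rw.GetConformer()
    for cut_id, ((ai, aj), (la, lb)) in enumerate(bonds, start=1):
        bond = rw.GetBondBetweenAtoms(ai, aj)
        order = bond.GetBondType()
        pos_i = conf.GetAtomPosition(ai)
        pos_j = conf.GetAtomPosition(aj)
        rw.RemoveBond(ai, aj)
        for anchor, env, pos in ((ai, la, pos_j), (aj, lb, pos_i)):
            dummy = Chem.Atom(0)
            dummy.SetIsotope(_brics_env(env))
            dummy.SetAtomMapNum(cut_id)
            d_idx = rw.AddAtom(dummy)
            rw.AddBond(anchor, d_idx, order)
            conf.SetAtomPosition(d_idx, Point3D(pos.x, pos.y, pos.z))
    pieces = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True)
    return [RawFragment(mol=p, provenance=ligand.provenance) for p in pieces]


def _heavy_centroid(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    coords = [
        conf.GetAtomPosition(a.GetIdx()) for a in mol.GetAtoms() if a.GetAtomicNum() > 1
    ]
    if not coords:
        raise ValueError("fragment has no heavy atoms")
    return np.mean([[p.x, p.y, p.z] for p in coords], axis=0)


def assign_subpocket(fragment: RawFragment | Chem.Mol, geometry: SubpocketGeometry) -> str:
    """Nearest-center subpocket of a fragment's heavy-atom centroid.

    Ties are broken in the fixed order AP, FP, SE, GA, B1, B2; a minimum
    distance beyond the cutoff yields pool X.  Placeholder atoms do not
    contribute to the centroid.
    """
    mol = fragment.mol if isinstance(fragment, RawFragment) else fragment
    if mol.GetNumConformers() == 0:
        raise ValueError("fragment has no coordinates; subpocket assignment impossible")
    centroid = _heavy_centroid(mol)
    best_label, best_dist = None, np.inf
    for label in SUBPOCKETS:  # fixed order = tie-break order
        dist = float(np.linalg.norm(centroid - geometry.centers[label]))
        if dist < best_dist:
            best_label, best_dist = label, dist
    return best_label if best_dist <= geometry.distance_cutoff else POOL_X


def _rejoin(pieces: list[RawFragment], internal: set[int]) -> Chem.Mol:
    """Re-bond pieces at the given cut ids; the paired placeholders vanish."""
    combined = pieces[0].mol
    for piece in pieces[1:]:
        combined = Chem.CombineMols(combined, piece.mol)
    rw = Chem.RWMol(combined)
    for cut_id in sorted(internal):
        dummies = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == cut_id
        ]
        if len(dummies) != 2:
            raise ValueError(f"inconsistent cut bookkeeping: cut {cut_id} has {len(dummies)} ends")
        anchors, orders = [], []
        for d in dummies:
            atom = rw.GetAtomWithIdx(d)
            bond = atom.GetBonds()[0]
            anchors.append(bond.GetOtherAtom(atom).GetIdx())
            orders.append(bond.GetBondType())
        if orders[0] != orders[1]:
            raise ValueError(f"inconsistent cut bookkeeping: cut {cut_id} bond orders differ")
        rw.AddBond(anchors[0], anchors[1], orders[0])
        for d in sorted(dummies, reverse=True):
            rw.RemoveAtom(d)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def reassemble(pieces: list[RawFragment]) -> Chem.Mol:
    """Re-join *all* pieces of one ligand at their matching cut bonds.

    Inverse of :func:`brics_cut`; the result is graph-identical to the input
    ligand (used as the round-trip oracle).
    """
    all_cuts = {c for p in pieces for c in p.cut_ids()}
    mol = _rejoin(pieces, all_cuts)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol


def merge_same_subpocket(pieces: list[RawFragment]) -> list[Fragment]:
    """Merge adjacent pieces that share a subpocket into one fragment each.

    Connected components of the "same-subpocket neighbor" relation are
    re-bonded at their shared cuts.  Each remaining placeholder is annotated
    with the subpocket of the piece on the far side of its cut.
    """
    if any(p.subpocket is None for p in pieces):
        raise ValueError("all pieces must have an assigned subpocket before merging")
    # map cut id -> indices of the two pieces it connects
    sides: dict[int, list[int]] = {}
    for i, piece in enumerate(pieces):
        for cut in piece.cut_ids():
            sides.setdefault(cut, []).append(i)
    for cut, members in sides.items():
        if len(members) != 2:
            raise ValueError(f"inconsistent cut bookkeeping: cut {cut} has {len(members)} sides")

    # union-find over pieces connected by a same-subpocket cut
    parent = list(range(len(pieces)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cut, (i, j) in sides.items():
        if pieces[i].subpocket == pieces[j].subpocket and find(i) != find(j):
            parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in range(len(pieces)):
        components.setdefault(find(i), []).append(i)

    fragments = []
    for members in components.values():
        group = [pieces[i] for i in members]
        member_set = set(members)
        internal = {
            cut for cut, (i, j) in sides.items() if i in member_set and j in member_set
        }
        mol = _rejoin(group, internal)
        # annotate surviving placeholders with the far side's subpocket
        neighbor_by_cut = {}
        for cut, (i, j) in sides.items():
            if cut not in internal and (i in member_set or j in member_set):
                other = j if i in member_set else i
                neighbor_by_cut[cut] = pieces[other].subpocket
        neighbors = []
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                neighbors.append(neighbor_by_cut[atom.GetAtomMapNum()])
                atom.SetAtomMapNum(0)
        fragments.append(
            Fragment(
                mol=mol,
                subpocket=group[0].subpocket,
                attachments=_attachments_from_mol(mol, neighbors),
                provenance=group[0].provenance,
            )
        )
    return fragments


def fragment_ligand(ligand: Ligand3D, geometry: SubpocketGeometry) -> list[Fragment]:
    """Cut one ligand, assign subpockets, and merge same-subpocket neighbors."""
    pieces = brics_cut(ligand)
    for piece in pieces:
        piece.subpocket = assign_subpocket(piece, geometry)
    return merge_same_subpocket(pieces)


def fragment_complexes(
    ligands: list[Ligand3D], geometry: SubpocketGeometry
) -> FragmentLibrary:
    """Fragment a set of ligands into one library; per-ligand failures are skipped."""
    fragments: list[Fragment] = []
    for ligand in ligands:
        try:
            fragments.extend(fragment_ligand(ligand, geometry))
        except Exception as exc:  # noqa: BLE001 - contract: log and skip
            logger.warning(
                "skipping ligand %s/%s: %s",
                ligand.provenance.pdb,
                ligand.provenance.ligand,
                exc,
            )
    return FragmentLibrary(fragments, metadata={"source": "fragmentation"})
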