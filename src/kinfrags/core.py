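"""Domain types for subpocket-annotated kinase fragments and fragment libraries.

A *fragment* is a piece of a co-crystallized kinase ligand, cut at
retrosynthetically meaningful (BRICS) bonds.  Every severed bond leaves a
placeholder ("dummy") atom on the fragment; the placeholder's isotope number
carries the BRICS chemical-environment type (1-16) of the cut end, and each
placeholder is annotated with the binding-site subpocket of the fragment it
used to be bonded to.  Fragments are grouped into per-subpocket pools:

    AP  adenine pocket (hinge region)   FP  front pocket
    SE  solvent-exposed pocket          GA  gate area
    B1 / B2  back pockets               X   unassigned (> cutoff from any center)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

#: the six standard subpockets, in canonical (tie-break) order
SUBPOCKETS: tuple[str, ...] = ("AP", "FP", "SE", "GA", "B1", "B2")
#: pool for fragments farther than the distance cutoff from every center
POOL_X = "X"
ALL_POOLS: tuple[str, ...] = SUBPOCKETS + (POOL_X,)

#: default subpocket adjacency: which pockets share a boundary, i.e. between
#: which pockets a severed ligand bond may run
DEFAULT_ADJACENCY: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("AP", "FP"),
        ("AP", "GA"),
        ("AP", "SE"),
        ("FP", "SE"),
        ("GA", "B1"),
        ("GA", "B2"),
        ("B1", "B2"),
    ]
)


class LibraryFormatError(ValueError):
    """Raised for malformed library files (e.g. a record without a subpocket)."""


def _require_subpocket(label: str, allow_x: bool = True) -> str:
    valid = ALL_POOLS if allow_x else SUBPOCKETS
    if label not in valid:
        raise ValueError(f"invalid subpocket label {label!r}; expected one of {valid}")
    return label


@dataclass(frozen=True)
class AttachmentPoint:
    """One severed bond of a fragment.

    atom_index
        index of the placeholder (dummy) atom within the fragment graph.
    environment_type
        BRICS chemical-environment type of this cut end, 1-16.
    neighbor_subpocket
        subpocket of the fragment formerly bonded here.
    bond_order
        order of the severed bond (1 or 2; 2 only for the alkene environment).
    """

    atom_index: int
    environment_type: int
    neighbor_subpocket: str
    bond_order: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.environment_type <= 16:
            raise ValueError(f"BRICS environment type must be 1-16, got {self.environment_type}")
        _require_subpocket(self.neighbor_subpocket)
        if self.bond_order not in (1, 2):
            raise ValueError(f"severed bond order must be 1 or 2, got {self.bond_order}")


@dataclass(frozen=True)
class Provenance:
    """Origin of a fragment: which kinase/structure/ligand it was cut from."""

    kinase: str = ""
    kinase_group: str = ""
    pdb: str = ""
    ligand: str = ""

    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.kinase, self.pdb, self.ligand, self.kinase_group)


def _attachments_from_mol(
    mol: Chem.Mol, neighbor_subpockets: Sequence[str]
) -> tuple[AttachmentPoint, ...]:
    """Derive attachment points from a fragment graph.

    Placeholder atoms are taken in atom-index order; ``neighbor_subpockets``
    must list the former neighbor's subpocket for each, in the same order.
    """
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != len(neighbor_subpockets):
        raise LibraryFormatError(
            f"fragment has {len(dummies)} placeholder atoms but "
            f"{len(neighbor_subpockets)} neighbor subpockets were given"
        )
    attachments = []
    for atom, neighbor in zip(dummies, neighbor_subpockets):
        bonds = atom.GetBonds()
        if len(bonds) != 1:
            raise LibraryFormatError("placeholder atom must have exactly one bond")
        order = int(bonds[0].GetBondTypeAsDouble())
        env = atom.GetIsotope()
        attachments.append(
            AttachmentPoint(
                atom_index=atom.GetIdx(),
                environment_type=env,
                neighbor_subpocket=neighbor,
                bond_order=order,
            )
        )
    return tuple(attachments)


@dataclass(frozen=True)
class Fragment:
    """A subpocket-assigned ligand fragment.

    ``mol`` carries one placeholder atom per attachment point with the
    placeholder isotope equal to the BRICS environment type.  Optional 3D
    coordinates live on the mol as an RDKit conformer.
    """

    mol: Chem.Mol
    subpocket: str
    attachments: tuple[AttachmentPoint, ...] = ()
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        _require_subpocket(self.subpocket)
        n_dummies = sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() == 0)
        if n_dummies != len(self.attachments):
            raise ValueError(
                f"fragment has {n_dummies} placeholder atoms but "
                f"{len(self.attachments)} attachment points"
            )

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        subpocket: str,
        neighbor_subpockets: Sequence[str] = (),
        provenance: Provenance | None = None,
    ) -> "Fragment":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls(
            mol=mol,
            subpocket=subpocket,
            attachments=_attachments_from_mol(mol, neighbor_subpockets),
            provenance=provenance or Provenance(),
        )

    @property
    def smiles(self) -> str:
        """Canonical SMILES including placeholder atoms."""
        return Chem.MolToSmiles(self.mol)

    @property
    def neighbor_subpockets(self) -> tuple[str, ...]:
        return tuple(a.neighbor_subpocket for a in self.attachments)

    def sort_key(self) -> tuple:
        return (*self.provenance.sort_key(), self.smiles)

    def with_subpocket(self, subpocket: str) -> "Fragment":
        return replace(self, subpocket=subpocket)

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)


def as_mol(obj: "Fragment | Chem.Mol") -> Chem.Mol:
    return obj.mol if isinstance(obj, Fragment) else obj


def strip_attachment_points(obj: "Fragment | Chem.Mol") -> Chem.Mol:
    """Return the fragment graph with every placeholder atom replaced by hydrogen.

    The hydrogen is implicit: the placeholder is deleted and the former
    neighbor's implicit-hydrogen count grows to fill the freed valence (two
    hydrogens for a double-bonded placeholder).  Heavy-atom and ring counts
    are unchanged.
    """
    mol = as_mol(obj)
    rw = Chem.RWMol(mol)
    dummy_idx = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    for idx in sorted(dummy_idx, reverse=True):
        atom = rw.GetAtomWithIdx(idx)
        for nbr in atom.GetNeighbors():
            # let RDKit refill the freed valence with implicit hydrogens
            nbr.SetNoImplicit(False)
            nbr.SetNumExplicitHs(0)
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def standard_inchi(obj: "Fragment | Chem.Mol") -> str | None:
    """Standard InChI of the dummy-free fragment graph.

    Returns None when InChI generation fails; callers must treat such
    fragments as unique (they are flagged, never silently merged).
    """
    try:
        mol = strip_attachment_points(obj)
        inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    except Exception:  # noqa: BLE001 - InChI failure path is part of the contract
        logger.warning("InChI generation failed for %r", Chem.MolToSmiles(as_mol(obj)))
        return None
    if not inchi:
        logger.warning("empty InChI for %r", Chem.MolToSmiles(as_mol(obj)))
        return None
    return inchi


@dataclass(frozen=True)
class SubpocketGeometry:
    """Geometric description of the binding site used for fragment assignment.

    centers
        subpocket label -> 3D center (angstrom); all six standard subpockets.
    distance_cutoff
        fragments whose centroid is farther than this from every center go to
        pool X (angstrom).
    adjacency
        unordered pairs of subpockets that share a boundary.
    """

    centers: Mapping[str, np.ndarray]
    distance_cutoff: float = 8.0
    adjacency: frozenset[frozenset[str]] = DEFAULT_ADJACENCY

    def __post_init__(self) -> None:
        if set(self.centers) != set(SUBPOCKETS):
            raise ValueError(f"geometry must define centers for exactly {SUBPOCKETS}")
        if not self.distance_cutoff > 0:
            raise ValueError("distance cutoff must be positive")
        object.__setattr__(
            self, "centers", {k: np.asarray(v, dtype=float) for k, v in self.centers.items()}
        )
        for pair in self.adjacency:
            for label in pair:
                _require_subpocket(label, allow_x=False)
            if len(pair) != 2:
                raise ValueError("adjacency entries must be unordered pairs of two subpockets")

    def are_adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centers": {k: list(map(float, v)) for k, v in self.centers.items()},
            "distance_cutoff": self.distance_cutoff,
            "adjacency": sorted(sorted(p) for p in self.adjacency),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubpocketGeometry":
        payload = json.loads(Path(path).read_text())
        return cls(
            centers={k: np.asarray(v, float) for k, v in payload["centers"].items()},
            distance_cutoff=float(payload["distance_cutoff"]),
            adjacency=frozenset(frozenset(p) for p in payload["adjacency"]),
        )


class FragmentLibrary:
    """Subpocket-keyed fragment pools.

    Pool order is deterministic: fragments are stable-sorted by provenance,
    then canonical SMILES, so identical inputs always produce an identical
    library regardless of insertion order.
    """

    def __init__(
        self,
        fragments: Iterable[Fragment] = (),
        metadata: Mapping[str, str] | None = None,
        sort: bool = True,
    ) -> None:
        pools: dict[str, list[Fragment]] = {p: [] for p in ALL_POOLS}
        for frag in fragments:
            pools[frag.subpocket].append(frag)
        if sort:
            for pool in pools.values():
                pool.sort(key=Fragment.sort_key)
        self.pools: dict[str, list[Fragment]] = pools
        self.metadata: dict[str, str] = dict(metadata or {})

    def fragments(self) -> list[Fragment]:
        """All fragments in canonical pool order (AP, FP, SE, GA, B1, B2, X)."""
        return [f for pool in ALL_POOLS for f in self.pools[pool]]

    def __len__(self) -> int:
        return sum(len(p) for p in self.pools.values())

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments())

    def sizes(self) -> dict[str, int]:
        return {p: len(self.pools[p]) for p in ALL_POOLS}

    def subset(self, keep: Sequence[bool]) -> "FragmentLibrary":
        """New library with fragments where ``keep`` (aligned to fragments()) is True."""
        frags = self.fragments()
        if len(keep) != len(frags):
            raise ValueError("keep mask length must equal library size")
        return FragmentLibrary(
            (f for f, k in zip(frags, keep) if k), metadata=self.metadata, sort=False
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fragments()):
            rows.append(
                {
                    "index": i,
                    "smiles": f.smiles,
                    "subpocket": f.subpocket,
                    "neighbor_subpockets": ";".join(f.neighbor_subpockets),
                    "kinase": f.provenance.kinase,
                    "kinase_group": f.provenance.kinase_group,
                    "pdb": f.provenance.pdb,
                    "ligand": f.provenance.ligand,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "index",
                "smiles",
                "subpocket",
                "neighbor_subpockets",
                "kinase",
                "kinase_group",
                "pdb",
                "ligand",
            ],
        ).set_index("index")


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_SDF_PROPS = ("subpocket", "neighbor_subpockets", "kinase", "kinase_group", "pdb", "ligand")
_CSV_COLUMNS = ("smiles", "subpocket", "neighbor_subpockets", "kinase", "pdb", "ligand")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return "sdf"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer library format from {path.name!r}; pass format=")


def _fragment_from_record(
    mol: Chem.Mol | None,
    subpocket: str | None,
    neighbors: str,
    kinase: str,
    kinase_group: str,
    pdb: str,
    ligand: str,
) -> Fragment:
    if mol is None:
        raise LibraryFormatError("unparseable record")
    if subpocket is None or subpocket == "":
        raise LibraryFormatError("record is missing the required 'subpocket' property")
    _require_subpocket(subpocket)
    neighbor_list = [n for n in neighbors.split(";") if n] if neighbors else []
    return Fragment(
        mol=mol,
        subpocket=subpocket,
        attachments=_attachments_from_mol(mol, neighbor_list),
        provenance=Provenance(kinase=kinase, kinase_group=kinase_group, pdb=pdb, ligand=ligand),
    )


def read_library(
    path: str | Path, format: str | None = None
) -> tuple[FragmentLibrary, pd.DataFrame]:
    """Read a fragment library from SDF or CSV.

    Returns the library and a rejects report (one row per skipped record).
    Unparseable or valence-invalid records are skipped with a logged warning;
    a record without a subpocket property is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    fragments: list[Fragment] = []
    rejects: list[dict] = []

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparseable SDF record %d in %s", i, path.name)
                rejects.append({"record": i, "reason": "unparseable"})
                continue
            props = {k: mol.GetProp(k) if mol.HasProp(k) else "" for k in _SDF_PROPS}
            if not mol.HasProp("subpocket"):
                raise LibraryFormatError(f"SDF record {i} in {path.name} has no 'subpocket' field")
            try:
                fragments.append(
                    _fragment_from_record(
                        mol,
                        props["subpocket"],
                        props["neighbor_subpockets"],
                        props["kinase"],
                        props["kinase_group"],
                        props["pdb"],
                        props["ligand"],
                    )
                )
            except LibraryFormatError as exc:
                logger.warning("skipping SDF record %d in %s: %s", i, path.name, exc)
                rejects.append({"record": i, "reason": str(exc)})
    elif fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = {"smiles", "subpocket"} - set(frame.columns)
        if missing:
            raise LibraryFormatError(f"CSV manifest missing required columns: {sorted(missing)}")
        for i, row in frame.iterrows():
            if row["subpocket"] == "":
                raise LibraryFormatError(f"CSV row {i} has an empty subpocket")
            mol = Chem.MolFromSmiles(row["smiles"])
            try:
                fragments.append(
                    _fragment_from_record(
                        mol,
                        row["subpocket"],
                        row.get("neighbor_subpockets", ""),
                        row.get("kinase", ""),
                        row.get("kinase_group", ""),
                        row.get("pdb", ""),
                        row.get("ligand", ""),
                    )
                )
            except LibraryFormatError as exc:
                logger.warning("skipping CSV row %d in %s: %s", i, path.name, exc)
                rejects.append({"record": int(i), "reason": str(exc)})
    else:
        raise ValueError(f"unknown library format {fmt!r}")

    library = FragmentLibrary(fragments, metadata={"source": str(path), "format": fmt})
    return library, pd.DataFrame(rejects, columns=["record", "reason"])


def write_library(library: FragmentLibrary, path: str | Path, format: str | None = None) -> None:
    """Write a library to SDF (V2000, named data fields) or a CSV manifest."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for f in library.fragments():
                mol = Chem.Mol(f.mol)
                mol.SetProp("subpocket", f.subpocket)
                mol.SetProp("neighbor_subpockets", ";".join(f.neighbor_subpockets))
                mol.SetProp("kinase", f.provenance.kinase)
                mol.SetProp("kinase_group", f.provenance.kinase_group)
                mol.SetProp("pdb", f.provenance.pdb)
                mol.SetProp("ligand", f.provenance.ligand)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        frame = library.to_frame().reset_index(drop=True)
        frame[list(_CSV_COLUMNS) + ["kinase_group"]].to_csv(path, index=False)
    else:
        raise ValueError(f"unknown library format {fmt!r}")
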