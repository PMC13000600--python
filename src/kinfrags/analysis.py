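"""Diversity, coverage and cascade-reporting analytics for fragment libraries.

Diversity is measured two ways: (i) mean +/- sd pairwise Tanimoto *distance*
(1 - Jaccard similarity of 2048-bit topological path fingerprints, paths up
to length 7, computed dummy-free) and (ii) the Shannon entropy of Murcko
scaffold frequencies,

    SE  = - sum_i p_i log2 p_i,      p_i = c_i / P,
    SSE = SE / log2 n   (0 when n = 1),

over the n counted scaffolds, where c_i is the number of fragments with
scaffold i and P the number of fragments within the counted scaffolds.
Ring-free fragments have no Murcko scaffold; they are excluded from the
entropy and reported as a fraction.  SSE lies in [0, 1], reaching 1 exactly
for a uniform scaffold distribution over n >= 2 scaffolds.

Note on the entropy sign: the non-negative (standard) Shannon entropy is the
only reading consistent with SSE in [0, 1] and "1 = high diversity";
see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .core import ALL_POOLS, SUBPOCKETS, Fragment, FragmentLibrary, strip_attachment_points

_fp_generator = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=2048)


@dataclass(frozen=True)
class DiversityStats:
    """Library diversity summary."""

    mean_tanimoto_distance: float
    sd_tanimoto_distance: float
    se: float  # bits
    sse: float  # in [0, 1]
    n_scaffolds: int
    ringless_fraction: float


def pairwise_tanimoto_stats(
    fragments: Sequence[Fragment | Chem.Mol],
) -> tuple[float, float]:
    """Exact mean and sd of Tanimoto distance over all unordered pairs.

    O(n^2), no sampling; requires at least two fragments.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments for pairwise distances")
    fps = [_fp_generator.GetFingerprint(strip_attachment_points(f)) for f in fragments]
    distances = []
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        distances.extend(1.0 - s for s in sims)
    arr = np.asarray(distances)
    return float(arr.mean()), float(arr.std(ddof=0))


def murcko_scaffold_smiles(fragment: Fragment | Chem.Mol) -> str:
    """Canonical SMILES of the dummy-free Murcko scaffold ('' when ring-free)."""
    scaffold = MurckoScaffold.GetScaffoldForMol(strip_attachment_points(fragment))
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def scaffold_entropy(
    fragments: Sequence[Fragment | Chem.Mol], top_n: int | None = None
) -> tuple[float, float, int, float]:
    """Shannon entropy of Murcko scaffold frequencies.

    Returns (SE, SSE, n_scaffolds, ringless_fraction).  ``top_n`` restricts
    the entropy to the n most frequent scaffolds (ties broken by scaffold
    SMILES); default: all observed scaffolds.  Raises when no fragment
    contains a ring.
    """
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    scaffolds = [murcko_scaffold_smiles(f) for f in fragments]
    ringless = sum(1 for s in scaffolds if s == "")
    counts = pd.Series([s for s in scaffolds if s != ""]).value_counts()
    if counts.empty:
        raise ValueError("no ring-containing fragments: scaffold entropy undefined")
    if top_n is not None:
        order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        counts = pd.Series(dict(order))
    p = counts.to_numpy(dtype=float)
    p = p / p.sum()
    se = float(-(p * np.log2(p)).sum())
    n = len(counts)
    sse = se / np.log2(n) if n > 1 else 0.0
    return se, float(sse), n, ringless / len(fragments)


def diversity_stats(
    fragments: Sequence[Fragment | Chem.Mol], top_n: int | None = None
) -> DiversityStats:
    """Combined Tanimoto + scaffold-entropy diversity summary."""
    mean_d, sd_d = pairwise_tanimoto_stats(fragments)
    se, sse, n_scaffolds, ringless = scaffold_entropy(fragments, top_n=top_n)
    return DiversityStats(
        mean_tanimoto_distance=mean_d,
        sd_tanimoto_distance=sd_d,
        se=se,
        sse=sse,
        n_scaffolds=n_scaffolds,
        ringless_fraction=ringless,
    )


def kinase_coverage(
    library: FragmentLibrary, reference_index: pd.DataFrame
) -> dict[str, int]:
    """Covered-kinase counts per subpocket, plus a 'total' over any subpocket.

    ``reference_index`` has columns (kinase, ligand, subpocket, inchi): the
    constituent fragment identities (dummy-free standard InChI) of every
    reference ligand.  A kinase is covered in a subpocket when at least one
    of its ligands contributes a fragment that is still in the library's
    pool for that subpocket.
    """
    from .core import standard_inchi

    present: dict[str, set[str]] = {
        pocket: {standard_inchi(f) for f in library.pools[pocket]} for pocket in ALL_POOLS
    }
    coverage = {pocket: 0 for pocket in SUBPOCKETS}
    covered_any: set[str] = set()
    if len(reference_index) == 0:
        coverage["total"] = 0
        return coverage
    for pocket in SUBPOCKETS:
        rows = reference_index[reference_index["subpocket"] == pocket]
        covered = set()
        for kinase, group in rows.groupby("kinase"):
            if any(i in present[pocket] for i in group["inchi"]):
                covered.add(kinase)
        coverage[pocket] = len(covered)
        covered_any |= covered
    coverage["total"] = len(covered_any)
    return coverage


@dataclass
class FilterReport:
    """Cascade reporting surfaces.

    independent_removed
        filters x subpockets: fragments removed when each filter is applied
        alone to the input library.
    sequential_remaining
        cascade steps x subpockets: fragments remaining after each step when
        the filters are applied one after the other.
    overlap
        filters x filters: fragments jointly rejected by each filter pair
        (diagonal: per-filter rejection totals).
    """

    independent_removed: pd.DataFrame
    sequential_remaining: pd.DataFrame
    overlap: pd.DataFrame

    def validate(self) -> None:
        ov = self.overlap.to_numpy()
        diag = np.diag(ov)
        if not np.allclose(ov, ov.T):
            raise AssertionError("overlap matrix must be symmetric")
        for i in range(len(diag)):
            for j in range(len(diag)):
                if ov[i, j] > min(diag[i], diag[j]):
                    raise AssertionError("overlap(i,j) cannot exceed min(diag)")
        totals = self.sequential_remaining["total"].to_numpy()
        if np.any(np.diff(totals) > 0):
            raise AssertionError("sequential remaining counts must be non-increasing")


def build_reports(
    library: FragmentLibrary,
    flags: pd.DataFrame,
    cascade_order: Sequence[str] | None = None,
) -> FilterReport:
    """Independent-mode removals, sequential remaining counts and the overlap matrix.

    ``flags`` carries one boolean pass column per filter, aligned to
    ``library.fragments()``; ``cascade_order`` defaults to column order.
    """
    order = list(cascade_order) if cascade_order is not None else list(flags.columns)
    subpockets = [f.subpocket for f in library.fragments()]
    frame = flags.copy()
    frame["subpocket"] = subpockets

    pockets = [p for p in ALL_POOLS if p in set(subpockets)]
    independent = {}
    for name in order:
        rejected = frame.loc[~frame[name]]
        row = {p: int((rejected["subpocket"] == p).sum()) for p in pockets}
        row["total"] = len(rejected)
        independent[name] = row
    independent_removed = pd.DataFrame(independent).T[pockets + ["total"]]

    surviving = pd.Series(True, index=frame.index)
    seq_rows = {}
    for name in order:
        surviving &= frame[name]
        alive = frame.loc[surviving]
        row = {p: int((alive["subpocket"] == p).sum()) for p in pockets}
        row["total"] = len(alive)
        seq_rows[name] = row
    sequential_remaining = pd.DataFrame(seq_rows).T[pockets + ["total"]]

    rejected_mask = ~flags[order]
    overlap = pd.DataFrame(
        rejected_mask.T.astype(int) @ rejected_mask.astype(int), dtype=int
    )
    report = FilterReport(
        independent_removed=independent_removed,
        sequential_remaining=sequential_remaining,
        overlap=overlap,
    )
    report.validate()
    return report
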