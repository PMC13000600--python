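"""Prefilters: deduplication, removal of unfragmented ligands and of pool X.

These run before any property/synthesizability filter.  Duplicates are
detected per subpocket by the standard InChI of the dummy-free fragment
(which merges fragments differing only in attachment position; a config
switch keeps them separate).  Unfragmented structures carry no connection
point and cannot be recombined; pool-X fragments, and fragments whose every
connection points to pool X, cannot be joined to any standard subpocket.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ALL_POOLS, POOL_X, Fragment, FragmentLibrary, standard_inchi


def _dedup_key(fragment: Fragment, key: str) -> str | object:
    if key == "inchi":
        inchi = standard_inchi(fragment)
        # failed InChI -> treat as unique, never merge silently
        return inchi if inchi is not None else object()
    if key == "smiles":
        return fragment.smiles
    raise ValueError(f"unknown dedup key {key!r}; expected 'inchi' or 'smiles'")


def deduplicate(library: FragmentLibrary, key: str = "inchi") -> FragmentLibrary:
    """Keep one fragment per duplicate group within each subpocket pool.

    The representative is the first fragment under the library's
    deterministic order.  Identical structures in *different* pools are all
    retained (deduplication is per subpocket).  ``key='smiles'`` deduplicates
    on the attachment-decorated SMILES instead, which keeps positional
    attachment isomers apart.
    """
    keep: list[Fragment] = []
    for pool in ALL_POOLS:
        seen: set = set()
        for fragment in library.pools[pool]:
            k = _dedup_key(fragment, key)
            if k in seen:
                continue
            seen.add(k)
            keep.append(fragment)
    return FragmentLibrary(keep, metadata=library.metadata, sort=False)


def remove_unfragmented(library: FragmentLibrary) -> FragmentLibrary:
    """Drop fragments without any attachment point (whole, uncut ligands)."""
    return FragmentLibrary(
        (f for f in library.fragments() if len(f.attachments) >= 1),
        metadata=library.metadata,
        sort=False,
    )


def remove_pool_x(library: FragmentLibrary) -> FragmentLibrary:
    """Drop pool X and fragments connected exclusively to pool X."""
    keep = []
    for f in library.fragments():
        if f.subpocket == POOL_X:
            continue
        if not any(a.neighbor_subpocket != POOL_X for a in f.attachments):
            continue
        keep.append(f)
    return FragmentLibrary(keep, metadata=library.metadata, sort=False)


@dataclass
class PrefilterReport:
    """Removal counts per prefilter step and subpocket."""

    removed: pd.DataFrame  # index: step, columns: subpockets + 'total'

    @property
    def total_removed(self) -> int:
        return int(self.removed["total"].sum())


def prefilter(library: FragmentLibrary, dedup_key: str = "inchi") -> tuple[FragmentLibrary, PrefilterReport]:
    """Run the three prefilter steps and report removals per step and pool.

    Step order (deduplicate, remove unfragmented, remove pool X) only affects
    the bookkeeping; the surviving set is order-independent because the three
    predicates are mutually independent.
    """
    steps = [
        ("deduplicate", lambda lib: deduplicate(lib, key=dedup_key)),
        ("unfragmented", remove_unfragmented),
        ("pool_x", remove_pool_x),
    ]
    rows = []
    current = library
    for name, step in steps:
        before = current.sizes()
        current = step(current)
        after = current.sizes()
        row = {p: before[p] - after[p] for p in ALL_POOLS}
        row["total"] = sum(row.values())
        rows.append(pd.Series(row, name=name))
    report = PrefilterReport(removed=pd.DataFrame(rows))
    return current, report
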