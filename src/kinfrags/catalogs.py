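"""Unwanted-substructure screening against SMARTS catalogs.

Two catalogs are used by default: PAINS (480 pan-assay interference
substructures, frequent screening false positives) and the Brenk list (105
reactive/toxic/otherwise undesirable substructures).  Matching is performed
on the dummy-free form of each fragment, so an attachment point never masks
or creates an alert.  Users can substitute their own catalogs as two-column
CSV files (name, SMARTS).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .core import Fragment, FragmentLibrary, strip_attachment_points

_BUILTIN = {"pains": "PAINS", "brenk": "BRENK"}


class SubstructureCatalog:
    """A named list of (pattern name, SMARTS) alert substructures.

    All SMARTS are compiled at load time; a pattern that does not compile is
    an immediate error, never a silent non-match.
    """

    def __init__(self, name: str, entries: Iterable[tuple[str, str]]):
        self.name = name
        self.entries: list[tuple[str, str]] = []
        self._patterns: list[Chem.Mol] = []
        for pattern_name, smarts in entries:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(
                    f"catalog {name!r}: SMARTS for {pattern_name!r} does not compile: {smarts!r}"
                )
            self.entries.append((pattern_name, smarts))
            self._patterns.append(query)

    def __len__(self) -> int:
        return len(self.entries)

    def matches(self, mol: Chem.Mol) -> list[str]:
        return [
            name
            for (name, _), query in zip(self.entries, self._patterns)
            if mol.HasSubstructMatch(query)
        ]

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "SubstructureCatalog":
        """Load a catalog from a two-column CSV (name, SMARTS)."""
        path = Path(path)
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        if frame.shape[1] < 2:
            raise ValueError(f"catalog CSV {path.name} needs two columns (name, smarts)")
        cols = list(frame.columns[:2])
        return cls(name or path.stem, list(frame[cols].itertuples(index=False, name=None)))


class _RDKitCatalog(SubstructureCatalog):
    """Published PAINS/Brenk list via RDKit's filter-catalog data."""

    def __init__(self, name: str):
        params = FilterCatalogParams()
        params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, _BUILTIN[name]))
        self._catalog = FilterCatalog(params)
        self.name = name
        # entries are exposed by description; the patterns live inside RDKit
        self.entries = [
            (self._catalog.GetEntryWithIdx(i).GetDescription(), "")
            for i in range(self._catalog.GetNumEntries())
        ]
        self._patterns = []

    def matches(self, mol: Chem.Mol) -> list[str]:
        return [entry.GetDescription() for entry in self._catalog.GetMatches(mol)]


def load_catalog(source: str | Path) -> SubstructureCatalog:
    """Load ``'pains'``/``'brenk'`` (published lists) or a CSV catalog path."""
    if isinstance(source, str) and source.lower() in _BUILTIN:
        return _RDKitCatalog(source.lower())
    return SubstructureCatalog.from_csv(source)


def match_catalog(fragment: Fragment | Chem.Mol, catalog: SubstructureCatalog) -> list[str]:
    """Names of all catalog entries embedded in the dummy-free fragment."""
    return catalog.matches(strip_attachment_points(fragment))


def filter_unwanted(
    library: FragmentLibrary, catalogs: Sequence[SubstructureCatalog]
) -> pd.DataFrame:
    """Per-fragment pass flags, one boolean column per catalog (True = clean)."""
    fragments = library.fragments()
    flags = {}
    for catalog in catalogs:
        flags[catalog.name] = [
            len(match_catalog(f, catalog)) == 0 for f in fragments
        ]
    return pd.DataFrame(flags, index=range(len(fragments)))
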