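"""Fragment-pair validity, recombination and the retrosynthesis gate."""

import pytest
from rdkit import Chem

from kinfrags.core import DEFAULT_ADJACENCY, Fragment, FragmentLibrary
from kinfrags.fixtures import MockRetroBackend
from kinfrags.pairs import (
    FragmentPair,
    RetroSuggestion,
    brics_link_compatible,
    enumerate_valid_pairs,
    filter_retro,
    pair_feasible,
    recombine_pair,
)


def frag(smiles, subpocket, neighbors):
    return Fragment.from_smiles(smiles, subpocket, neighbors)


from oracles import brute_force_pairs


class TestCompatibilityTable:
    @pytest.mark.parametrize(
        "env_a, env_b, expected",
        [(1, 3, True), (1, 5, True), (16, 16, True), (7, 7, True), (8, 16, True),
         (1, 16, False), (1, 2, False), (8, 8, False)],
    )
    def test_published_link_rules(self, env_a, env_b, expected):
        assert brics_link_compatible(env_a, env_b) is expected


class TestEnumerateValidPairs:
    def test_non_adjacent_subpockets_never_pair(self):
        lib = FragmentLibrary(
            [frag("[16*]c1ccncc1", "AP", ["B1"]), frag("[16*]c1ccoc1", "B1", ["AP"])]
        )
        assert enumerate_valid_pairs(lib, DEFAULT_ADJACENCY) == []

    def test_mutually_pointing_compatible_pair(self):
        lib = FragmentLibrary(
            [frag("[16*]c1ccncc1", "AP", ["FP"]), frag("[16*]c1ccoc1", "FP", ["AP"])]
        )
        pairs = enumerate_valid_pairs(lib, DEFAULT_ADJACENCY)
        assert len(pairs) == 1
        assert {pairs[0].frag_a.subpocket, pairs[0].frag_b.subpocket} == {"AP", "FP"}

    def test_one_sided_annotation_is_not_enough(self):
        lib = FragmentLibrary(
            [frag("[16*]c1ccncc1", "AP", ["FP"]), frag("[16*]c1ccoc1", "FP", ["SE"])]
        )
        assert enumerate_valid_pairs(lib, DEFAULT_ADJACENCY) == []

    def test_equals_brute_force_oracle(self, prefiltered):
        library, _ = prefiltered
        assert len(library) <= 52
        pairs = enumerate_valid_pairs(library, DEFAULT_ADJACENCY)
        got = sorted((p.index_a, p.index_b) for p in pairs)
        assert got == sorted(brute_force_pairs(library, DEFAULT_ADJACENCY))

    def test_prior_flags_restrict_pairing(self, prefiltered):
        import pandas as pd

        library, _ = prefiltered
        flags = pd.DataFrame({"f": [False] * len(library)})
        assert enumerate_valid_pairs(library, DEFAULT_ADJACENCY, prior_flags=flags) == []


class TestRecombinePair:
    def test_biaryl_product(self):
        a = frag("[16*]c1ccccc1", "AP", ["FP"])
        b = frag("[16*]c1ccncc1", "FP", ["AP"])
        product = recombine_pair(a, b, 0, 0)
        assert Chem.MolToSmiles(product) == Chem.CanonSmiles("c1ccc(-c2ccncc2)cc1")

    def test_heavy_atom_conservation(self, prefiltered):
        library, _ = prefiltered
        pairs = enumerate_valid_pairs(library, DEFAULT_ADJACENCY)
        for pair in pairs[:100]:
            product_heavy = sum(
                1 for a in pair.product.GetAtoms() if a.GetAtomicNum() > 1
            )
            assert product_heavy == pair.frag_a.heavy_atom_count() + pair.frag_b.heavy_atom_count()

    def test_product_independent_of_operand_order(self):
        a = frag("[16*]c1ccccc1", "AP", ["FP"])
        b = frag("[16*]c1ccncc1", "FP", ["AP"])
        ab = Chem.MolToSmiles(recombine_pair(a, b, 0, 0))
        ba = Chem.MolToSmiles(recombine_pair(b, a, 0, 0))
        assert ab == ba

    def test_unused_attachments_survive_as_placeholders(self):
        a = Fragment.from_smiles("[16*]c1ccc([16*])nc1", "AP", ["FP", "SE"])
        b = frag("[16*]c1ccoc1", "FP", ["AP"])
        product = recombine_pair(a, b, 0, 0)
        assert sum(1 for atom in product.GetAtoms() if atom.GetAtomicNum() == 0) == 1


class TestPairFeasible:
    def make_pair(self):
        a = frag("[16*]c1ccccc1", "AP", ["FP"])
        b = frag("[16*]c1ccncc1", "FP", ["AP"])
        return FragmentPair(0, 1, a, b, 0, 0, recombine_pair(a, b, 0, 0))

    def suggestion(self, *smiles):
        return RetroSuggestion(precursors=tuple(Chem.MolFromSmiles(s) for s in smiles))

    def test_exact_fragments_as_precursors(self):
        pair = self.make_pair()
        assert pair_feasible(pair, [self.suggestion("c1ccccc1", "c1ccncc1")])

    def test_empty_suggestions_infeasible(self):
        assert not pair_feasible(self.make_pair(), [])

    def test_protected_precursors_match_by_substructure(self):
        # precursors carry leaving/protecting groups around the fragments
        pair = self.make_pair()
        assert pair_feasible(
            pair, [self.suggestion("Brc1ccccc1", "OB(O)c1ccncc1")]
        )

    def test_both_fragments_must_embed_in_distinct_precursors(self):
        pair = self.make_pair()
        assert not pair_feasible(pair, [self.suggestion("c1ccccc1", "c1ccccc1")])

    def test_monotone_in_suggestion_list(self):
        pair = self.make_pair()
        bad = [self.suggestion("CCO", "CCN")]
        good = bad + [self.suggestion("c1ccccc1", "c1ccncc1")]
        assert not pair_feasible(pair, bad)
        assert pair_feasible(pair, good)


class TestFilterRetro:
    def pairs_and_library(self, prefiltered):
        library, _ = prefiltered
        pairs = enumerate_valid_pairs(library, DEFAULT_ADJACENCY)
        return library, pairs

    def test_approving_backend_passes_all_paired_fragments(self, prefiltered):
        library, pairs = self.pairs_and_library(prefiltered)
        backend = MockRetroBackend.approving(pairs)
        result = filter_retro(library, pairs, backend)
        paired = {p.index_a for p in pairs} | {p.index_b for p in pairs}
        flags = result.flags["retro"]
        assert all(flags[i] for i in paired)
        assert len(result.feasible_pairs) == len(pairs)

    def test_rejecting_backend_fails_everything(self, prefiltered):
        library, pairs = self.pairs_and_library(prefiltered)
        result = filter_retro(library, pairs, MockRetroBackend({}))
        assert not result.flags["retro"].any()

    def test_unpaired_fragments_fail_by_default(self):
        library = FragmentLibrary(
            [
                frag("[16*]c1ccncc1", "AP", ["FP"]),
                frag("[16*]c1ccoc1", "FP", ["AP"]),
                # points at AP, but no AP fragment points back at SE
                frag("[16*]c1ccsc1", "SE", ["AP"]),
            ]
        )
        pairs = enumerate_valid_pairs(library, DEFAULT_ADJACENCY)
        backend = MockRetroBackend.approving(pairs)
        paired = {p.index_a for p in pairs} | {p.index_b for p in pairs}
        unpaired = set(range(len(library))) - paired
        assert unpaired
        default = filter_retro(library, pairs, backend).flags["retro"]
        kept = filter_retro(library, pairs, backend, keep_unpaired=True).flags["retro"]
        assert not any(default[i] for i in unpaired)
        assert all(kept[i] for i in unpaired)

    def test_cache_does_not_change_results(self, prefiltered, tmp_path):
        library, pairs = self.pairs_and_library(prefiltered)
        backend = MockRetroBackend.approving(pairs)
        plain = filter_retro(library, pairs, backend).flags
        cache_path = tmp_path / "cache.jsonl"
        warm = filter_retro(library, pairs, MockRetroBackend.approving(pairs), cache_path=cache_path).flags
        # second run answers everything from the cache: backend never queried
        silent_backend = MockRetroBackend({})
        cached = filter_retro(library, pairs, silent_backend, cache_path=cache_path).flags
        assert plain.equals(warm)
        assert warm.equals(cached)
        assert silent_backend.call_log == []

    def test_backend_failure_is_never_silently_feasible(self, prefiltered):
        library, pairs = self.pairs_and_library(prefiltered)

        class FailingBackend(MockRetroBackend):
            def suggest(self, product_smiles):
                raise RuntimeError("backend down")

        result = filter_retro(library, pairs, FailingBackend({}), max_retries=1)
        assert not result.flags["retro"].any()
        assert len(result.undetermined) == len(pairs)  # nothing cached, all reported
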