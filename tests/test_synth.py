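"""Trainable synthesizability score and building-block substructure filter."""

import math

import numpy as np
import pytest
from rdkit import Chem

from kinfrags.core import Fragment, FragmentLibrary
from kinfrags.fixtures import make_syba_probes
from kinfrags.synth import (
    BuildingBlockIndex,
    SybaModel,
    build_bb_index,
    filter_building_blocks,
    filter_syba,
    substructure_ids,
    syba_score,
    train_syba,
)


def mols(*smiles):
    return [Chem.MolFromSmiles(s) for s in smiles]


class TestTraining:
    def test_identical_corpora_give_zero_weights(self):
        corpus = mols("CCO", "c1ccncc1")
        model = train_syba(corpus, corpus)
        assert all(w == pytest.approx(0.0) for w in model.weights.values())
        assert model.default_weight == pytest.approx(0.0)

    def test_swapping_corpora_negates_every_weight(self):
        easy, hard = mols("CCO", "CCN"), mols("c1ccncc1", "c1ccsc1")
        forward = train_syba(easy, hard)
        backward = train_syba(hard, easy)
        assert set(forward.weights) == set(backward.weights)
        for key, w in forward.weights.items():
            assert backward.weights[key] == pytest.approx(-w)

    def test_weights_equal_direct_formula_arithmetic(self):
        """Weights match the smoothed log-odds computed independently from
        per-molecule substructure document counts."""
        easy, hard = mols("CCO", "CC"), mols("CC", "CCF")
        model = train_syba(easy, hard, smoothing=1)
        counts_easy, counts_hard = {}, {}
        for m in easy:
            for sub in substructure_ids(m):
                counts_easy[sub] = counts_easy.get(sub, 0) + 1
        for m in hard:
            for sub in substructure_ids(m):
                counts_hard[sub] = counts_hard.get(sub, 0) + 1
        for sub in set(counts_easy) | set(counts_hard):
            expected = math.log2((counts_easy.get(sub, 0) + 1) / 4) - math.log2(
                (counts_hard.get(sub, 0) + 1) / 4
            )
            assert model.weights[sub] == pytest.approx(expected, abs=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_syba([], mols("CC"))


class TestScoring:
    def test_zero_weight_model_scores_zero(self):
        corpus = mols("CCO", "c1ccncc1")
        model = train_syba(corpus, corpus)
        assert syba_score(model, Chem.MolFromSmiles("CCOC")) == pytest.approx(0.0)

    def test_negated_model_negates_the_score(self):
        easy, hard = mols("CCO", "CCN"), mols("c1ccncc1", "c1ccsc1")
        forward, backward = train_syba(easy, hard), train_syba(hard, easy)
        probe = Chem.MolFromSmiles("CCOc1ccncc1")
        assert syba_score(backward, probe) == pytest.approx(-syba_score(forward, probe))

    def test_score_is_sum_of_distinct_substructure_weights(self):
        easy, hard = mols("CCO"), mols("CCF")
        model = train_syba(easy, hard)
        probe = Chem.MolFromSmiles("CCO")
        expected = sum(model.weight(sub) for sub in substructure_ids(probe))
        assert syba_score(model, probe) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_atom_ordering_and_attachments(self, syba_model):
        a = Chem.MolFromSmiles("c1ccc2ncccc2c1")
        b = Chem.MolFromSmiles("c1ccc2c(c1)cccn2")
        assert syba_score(syba_model, a) == pytest.approx(syba_score(syba_model, b))
        bare = Chem.MolFromSmiles("c1ccncc1")
        decorated = Fragment.from_smiles("[16*]c1ccncc1", "AP", ["FP"])
        assert syba_score(syba_model, decorated) == pytest.approx(
            syba_score(syba_model, bare)
        )

    def test_marker_separation_on_held_out_probes(self, syba_model):
        """Marker-bearing probes score negative, marker-free positive (>= 95%)."""
        clean, marked = make_syba_probes(3)
        clean_ok = np.mean([syba_score(syba_model, m) > 0 for m in clean])
        marked_ok = np.mean([syba_score(syba_model, m) < 0 for m in marked])
        assert clean_ok >= 0.95
        assert marked_ok >= 0.95

    def test_model_io_round_trip(self, syba_model, tmp_path):
        path = tmp_path / "model.csv"
        syba_model.save(path)
        back = SybaModel.load(path)
        probe = Chem.MolFromSmiles("Cc1cnc2ccccc2n1")
        assert syba_score(back, probe) == pytest.approx(syba_score(syba_model, probe))


class TestFilterSyba:
    def test_cutoff_minus_infinity_passes_all(self, prefiltered, syba_model):
        library, _ = prefiltered
        flags = filter_syba(library, syba_model, cutoff=float("-inf"))
        assert flags["syba"].all()

    def test_score_exactly_zero_passes_default_cutoff(self):
        corpus = mols("CCO", "c1ccncc1")
        model = train_syba(corpus, corpus)  # every score is exactly 0
        library = FragmentLibrary([Fragment.from_smiles("[16*]c1ccncc1", "AP", ["FP"])])
        assert filter_syba(library, model, cutoff=0.0)["syba"].all()

    def test_partition_matches_score_sign(self, prefiltered, syba_model):
        library, _ = prefiltered
        flags = filter_syba(library, syba_model)["syba"].to_numpy()
        signs = np.array([syba_score(syba_model, f) >= 0 for f in library.fragments()])
        assert (flags == signs).all()


class TestBuildingBlocks:
    def test_empty_index(self, prefiltered):
        library, _ = prefiltered
        index = build_bb_index([])
        assert len(index) == 0
        assert not filter_building_blocks(library, index)["building_blocks"].any()

    def test_invalid_entries_skipped(self):
        index = build_bb_index(["CCO", "not_a_smiles", "c1ccccc1", "(((("])
        assert len(index) == 2
        assert index.n_skipped == 2

    def test_fragment_identical_to_block_passes(self):
        library = FragmentLibrary([Fragment.from_smiles("[16*]c1ccncc1", "AP", ["FP"])])
        index = build_bb_index(["c1ccncc1"])
        assert filter_building_blocks(library, index)["building_blocks"].all()

    def test_substructure_of_block_passes(self):
        library = FragmentLibrary([Fragment.from_smiles("[16*]c1ccccc1", "AP", ["FP"])])
        index = build_bb_index(["Cc1ccccc1"])  # toluene-only index, benzene query
        assert filter_building_blocks(library, index)["building_blocks"].all()

    def test_pass_set_monotone_in_block_set(self, prefiltered):
        library, _ = prefiltered
        from kinfrags.fixtures import make_mock_bb_set

        blocks_small, _ = make_mock_bb_set(library, 0.3, seed=9)
        blocks_large, _ = make_mock_bb_set(library, 0.3, seed=9)
        blocks_large = blocks_large + ["c1ccncc1"]
        small = filter_building_blocks(library, build_bb_index(blocks_small))
        large = filter_building_blocks(library, build_bb_index(blocks_large))
        assert (small["building_blocks"] <= large["building_blocks"]).all()

    def test_file_loading(self, tmp_path):
        path = tmp_path / "blocks.smi"
        path.write_text("CCO block1\nc1ccccc1 block2\n")
        index = BuildingBlockIndex.from_file(path)
        assert len(index) == 2
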