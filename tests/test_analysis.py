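"""Diversity statistics, kinase coverage and cascade reports."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from kinfrags.analysis import (
    build_reports,
    diversity_stats,
    kinase_coverage,
    murcko_scaffold_smiles,
    pairwise_tanimoto_stats,
    scaffold_entropy,
)
from kinfrags.core import Fragment, FragmentLibrary, Provenance, standard_inchi


def frag(smiles, subpocket="AP", neighbors=("FP",), **prov):
    return Fragment.from_smiles(smiles, subpocket, neighbors, Provenance(**prov))


class TestPairwiseTanimoto:
    def test_duplicates_have_zero_distance(self):
        mols = [Chem.MolFromSmiles("c1ccncc1")] * 4
        mean, sd = pairwise_tanimoto_stats(mols)
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(0.0)

    def test_values_in_unit_interval(self, prefiltered):
        library, _ = prefiltered
        mean, sd = pairwise_tanimoto_stats(library.fragments())
        assert 0.0 <= mean <= 1.0
        assert sd >= 0.0

    def test_matches_manual_pair_loop(self):
        """Mean/sd equal an explicit loop over all unordered fingerprint pairs."""
        smiles = ["CCO", "CCN", "c1ccccc1", "c1ccncc1", "CC(=O)N"]
        mols = [Chem.MolFromSmiles(s) for s in smiles]
        generator = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=2048)
        fps = [generator.GetFingerprint(m) for m in mols]
        manual = [
            1.0 - DataStructs.TanimotoSimilarity(fps[i], fps[j])
            for i in range(len(fps))
            for j in range(i + 1, len(fps))
        ]
        mean, sd = pairwise_tanimoto_stats(mols)
        assert mean == pytest.approx(np.mean(manual), abs=1e-12)
        assert sd == pytest.approx(np.std(manual), abs=1e-12)

    def test_permutation_invariant(self, prefiltered):
        library, _ = prefiltered
        fragments = library.fragments()[:15]
        mean_a, sd_a = pairwise_tanimoto_stats(fragments)
        mean_b, sd_b = pairwise_tanimoto_stats(fragments[::-1])
        assert mean_a == pytest.approx(mean_b)
        assert sd_a == pytest.approx(sd_b)

    def test_fewer_than_two_fragments_error(self):
        with pytest.raises(ValueError):
            pairwise_tanimoto_stats([Chem.MolFromSmiles("CC")])


def scaffold_set(scaffold_smiles, count, decoration="C" * 0):
    """Fragments sharing a Murcko scaffold, distinguished by side chains."""
    mols = []
    for k in range(count):
        side = "C" * (k + 1)
        mols.append(Chem.MolFromSmiles(f"{side}{scaffold_smiles}"))
    return mols


class TestScaffoldEntropy:
    def test_uniform_distribution_reaches_sse_one(self):
        mols = [Chem.MolFromSmiles(s) for s in ("c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1")]
        se, sse, n, ringless = scaffold_entropy(mols)
        assert n == 4
        assert se == pytest.approx(2.0)
        assert sse == pytest.approx(1.0)
        assert ringless == 0.0

    def test_single_scaffold_by_convention(self):
        mols = [Chem.MolFromSmiles(s) for s in ("Cc1ccccc1", "CCc1ccccc1")]
        se, sse, n, _ = scaffold_entropy(mols)
        assert n == 1
        assert se == pytest.approx(0.0)
        assert sse == 0.0

    def test_hand_computed_844_distribution(self):
        """Counts {8, 4, 4}: SE = 1.5 bits, SSE = 1.5/log2(3)."""
        mols = (
            scaffold_set("c1ccccc1", 8)
            + scaffold_set("c1ccncc1", 4)
            + scaffold_set("c1ccoc1", 4)
        )
        se, sse, n, _ = scaffold_entropy(mols)
        assert n == 3
        assert se == pytest.approx(1.5)
        assert sse == pytest.approx(1.5 / np.log2(3))

    def test_ringless_fragments_excluded_and_counted(self):
        mols = [Chem.MolFromSmiles(s) for s in ("c1ccccc1", "c1ccncc1", "CCO", "CCCC")]
        se, sse, n, ringless = scaffold_entropy(mols)
        assert n == 2
        assert ringless == pytest.approx(0.5)

    def test_all_ringless_is_an_error(self):
        with pytest.raises(ValueError):
            scaffold_entropy([Chem.MolFromSmiles("CCO"), Chem.MolFromSmiles("CCC")])

    def test_top_n_truncation(self):
        mols = (
            scaffold_set("c1ccccc1", 6)
            + scaffold_set("c1ccncc1", 2)
            + scaffold_set("c1ccoc1", 2)
        )
        se_all, _, n_all, _ = scaffold_entropy(mols)
        se_top, _, n_top, _ = scaffold_entropy(mols, top_n=1)
        assert n_all == 3 and n_top == 1
        assert se_top == pytest.approx(0.0)

    def test_sse_bounds_on_fixture(self, prefiltered):
        library, _ = prefiltered
        stats = diversity_stats(library.fragments())
        assert 0.0 <= stats.sse <= 1.0
        assert stats.se >= 0.0
        assert 0.0 <= stats.ringless_fraction <= 1.0

    def test_murcko_reduction_drops_side_chains(self):
        assert murcko_scaffold_smiles(Chem.MolFromSmiles("CCc1ccccc1C")) == Chem.CanonSmiles(
            "c1ccccc1"
        )
        assert murcko_scaffold_smiles(Chem.MolFromSmiles("CCCC")) == ""


class TestKinaseCoverage:
    def build(self):
        fragments = [
            frag("[16*]c1ccncc1", "AP", ["FP"], kinase="K1", ligand="l1"),
            frag("[16*]c1ccoc1", "FP", ["AP"], kinase="K1", ligand="l1"),
            frag("[16*]c1ccsc1", "AP", ["FP"], kinase="K2", ligand="l2"),
            frag("[16*]c1cncnc1", "AP", ["FP"], kinase="K3", ligand="l3"),
        ]
        library = FragmentLibrary(fragments)
        index = pd.DataFrame(
            [
                {"kinase": f.provenance.kinase, "ligand": f.provenance.ligand,
                 "subpocket": f.subpocket, "inchi": standard_inchi(f)}
                for f in fragments
            ]
        )
        return library, index

    def test_full_library_covers_every_kinase(self):
        library, index = self.build()
        coverage = kinase_coverage(library, index)
        assert coverage["AP"] == 3
        assert coverage["FP"] == 1
        assert coverage["total"] == 3

    def test_empty_library_covers_nothing(self):
        _, index = self.build()
        coverage = kinase_coverage(FragmentLibrary(), index)
        assert coverage["total"] == 0

    def test_filtering_out_one_kinase_reduces_count(self):
        library, index = self.build()
        keep = [f.provenance.kinase != "K3" for f in library.fragments()]
        coverage = kinase_coverage(library.subset(keep), index)
        assert coverage["AP"] == 2
        assert coverage["total"] == 2

    def test_empty_index_all_zero(self):
        library, _ = self.build()
        coverage = kinase_coverage(library, pd.DataFrame(columns=["kinase", "ligand", "subpocket", "inchi"]))
        assert coverage["total"] == 0


class TestBuildReports:
    def flags_frame(self, values):
        return pd.DataFrame(values)

    def library_of(self, n):
        bodies = ["[16*]c1ccncc1", "[16*]c1ccoc1", "[16*]c1ccsc1", "[16*]c1cncnc1"]
        frags = [
            Fragment.from_smiles(
                bodies[i % 4], "AP" if i % 2 == 0 else "FP",
                ["FP"] if i % 2 == 0 else ["AP"],
                Provenance(ligand=f"l{i}"),
            )
            for i in range(n)
        ]
        return FragmentLibrary(frags, sort=False)

    def test_single_filter_diagonal(self):
        library = self.library_of(4)
        flags = self.flags_frame({"a": [True, False, False, True]})
        report = build_reports(library, flags)
        assert report.overlap.loc["a", "a"] == 2
        assert report.independent_removed.loc["a", "total"] == 2

    def test_disjoint_filters_have_zero_overlap(self):
        library = self.library_of(4)
        flags = self.flags_frame({"a": [False, True, True, True], "b": [True, False, True, True]})
        report = build_reports(library, flags)
        assert report.overlap.loc["a", "b"] == 0

    def test_constructed_joint_rejections(self):
        library = self.library_of(5)
        flags = self.flags_frame(
            {"a": [False, False, True, True, False], "b": [False, True, False, True, False]}
        )
        report = build_reports(library, flags)
        assert report.overlap.loc["a", "a"] == 3
        assert report.overlap.loc["b", "b"] == 3
        assert report.overlap.loc["a", "b"] == 2  # rows 0 and 4 jointly rejected
        # sequential: after a -> {2,3}; after b -> {3}
        assert report.sequential_remaining.loc["a", "total"] == 2
        assert report.sequential_remaining.loc["b", "total"] == 1

    def test_sequential_equals_intersection_of_independent_flags(self, prefiltered, bb_setup, syba_model):
        from kinfrags.pipeline import PipelineConfig, compute_flags

        library, _ = prefiltered
        bb_index, _ = bb_setup
        flags = compute_flags(library, PipelineConfig(), bb_index=bb_index, syba_model=syba_model)
        report = build_reports(library, flags)
        last_step = report.sequential_remaining.iloc[-1]
        assert last_step["total"] == int(flags.all(axis=1).sum())
        report.validate()
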