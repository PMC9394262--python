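"""Supermatrix construction, NJ correctness and bootstrap behavior."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from _oracles import random_additive
from mitocomp.errors import MitocompError
from mitocomp.phylo import (
    SUPERMATRIX_GENES,
    bipartitions,
    bootstrap_support,
    build_supermatrix,
    k2p_distance_matrix,
    nj_tree,
    robinson_foulds,
)
from mitocomp.syndata import DEFAULT_GENE_LENGTHS, SynthSpec, generate_cohort


class TestSupermatrix:
    def test_identical_genomes_align_trivially(self):
        records, _ = generate_cohort(SynthSpec(n_genomes=3, divergence=0.0, seed=70))
        sm = build_supermatrix(records)
        assert len(sm.partitions) == 14
        rows = list(sm.rows.values())
        assert rows[0] == rows[1] == rows[2]

    def test_columns_equal_sum_of_gene_lengths_at_zero_divergence(self):
        records, _ = generate_cohort(SynthSpec(n_genomes=3, divergence=0.0, seed=71))
        sm = build_supermatrix(records)
        assert sm.length == sum(DEFAULT_GENE_LENGTHS[g] for g in SUPERMATRIX_GENES)

    def test_partitions_tile_without_overlap(self, study_records):
        sm = build_supermatrix(study_records)
        pos = 1
        for gene, start, end in sm.partitions:
            assert start == pos
            assert end >= start
            pos = end + 1
        assert pos - 1 == sm.length
        assert "rps3" not in [p[0] for p in sm.partitions]

    def test_missing_gene_padded_with_gaps(self):
        records, _ = generate_cohort(SynthSpec(n_genomes=3, divergence=0.01, seed=72))
        mutilated = records[0]
        mutilated.features = [f for f in mutilated.features if f.name != "nad6"]
        sm = build_supermatrix(records)
        (part,) = [p for p in sm.partitions if p[0] == "nad6"]
        segment = sm.rows[records[0].id][part[1] - 1:part[2]]
        assert set(segment) == {"-"}

    def test_too_few_taxa(self):
        records, _ = generate_cohort(SynthSpec(n_genomes=2, divergence=0.0, seed=73))
        with pytest.raises(MitocompError):
            build_supermatrix(records)


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        records, _ = generate_cohort(SynthSpec(n_genomes=3, divergence=0.0, seed=74))
        dm = k2p_distance_matrix(build_supermatrix(records))
        assert np.allclose(dm.data, 0.0)

    def test_no_shared_columns_is_error(self):
        from mitocomp.phylo import Supermatrix

        sm = Supermatrix(taxa=["a", "b", "c"],
                         rows={"a": "ACGT----", "b": "----ACGT", "c": "ACGTACGT"},
                         partitions=[("g", 1, 8)])
        with pytest.raises(MitocompError, match="a / b"):
            k2p_distance_matrix(sm)


class TestNJ:
    def test_exact_recovery_on_additive_four_taxon_matrix(self):
        # tree ((a:1,b:2):3,(c:3,d:4)); pairwise path lengths below
        dm = DistanceMatrix(
            [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 7], [8, 9, 7, 0]],
            ids=["a", "b", "c", "d"])
        tws = nj_tree(dm)
        assert bipartitions(tws.tree) == {frozenset({"c", "d"})}
        total = sum(n.length for n in tws.tree.traverse() if n.length)
        assert total == pytest.approx(13.0)  # exact branch lengths recovered

    def test_three_taxa_star(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 3], [3, 3, 0]], ids=list("abc"))
        tws = nj_tree(dm)
        assert sorted(t.name for t in tws.tree.tips()) == ["a", "b", "c"]

    def test_exact_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(75)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            true_tree, dm = random_additive(rng, n)
            tws = nj_tree(dm)
            assert robinson_foulds(tws.tree, true_tree) == 0

    def test_nonsymmetric_matrix_rejected(self):
        import pandas as pd

        df = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
                          index=list("abc"), columns=list("abc"))
        with pytest.raises(MitocompError):
            nj_tree(df)

    def test_planted_thirteen_taxon_topology_recovered(self, study_cohort):
        records, truth = study_cohort
        sm = build_supermatrix(records)
        tws = nj_tree(k2p_distance_matrix(sm))
        true_tree = TreeNode.read(io.StringIO(truth.tree_newick),
                                  convert_underscores=False)
        assert robinson_foulds(tws.tree, true_tree) == 0


class TestBootstrap:
    def test_same_seed_reproduces_supports(self, study_records):
        sm = build_supermatrix(study_records[:6])
        a = bootstrap_support(sm, replicates=20, seed=5)
        b = bootstrap_support(sm, replicates=20, seed=5)
        assert a.supports == b.supports

    def test_clean_simulation_high_support(self, study_cohort):
        records, _ = study_cohort
        sm = build_supermatrix(records)
        tws = bootstrap_support(sm, replicates=40, seed=6)
        assert all(v >= 95.0 for v in tws.supports.values())

    def test_identical_rows_zero_support_with_warning(self, caplog):
        records, _ = generate_cohort(SynthSpec(n_genomes=4, divergence=0.0, seed=76))
        sm = build_supermatrix(records)
        import logging

        with caplog.at_level(logging.WARNING, logger="mitocomp.phylo"):
            tws = bootstrap_support(sm, replicates=5, seed=7)
        assert "no variable columns" in caplog.text

    def test_replicates_below_one_rejected(self, study_records):
        sm = build_supermatrix(study_records[:3])
        with pytest.raises(MitocompError):
            bootstrap_support(sm, replicates=0, seed=1)
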