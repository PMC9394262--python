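"""Intron position classes: projection, matrix recovery, gain/loss parsimony."""

import itertools

import numpy as np
import pytest

from mitocomp.errors import HomologyError, MitocompError
from mitocomp.pcl import (
    assign_pcls,
    infer_gain_loss,
    intron_summary,
    leaf_states_from_events,
    project_insertion_site,
)
from mitocomp.syndata import IntronPlant, SynthSpec, generate_cohort, mutate_sequence


def _random_cds(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestProjection:
    def test_identical_sequences_identity_mapping(self):
        rng = np.random.default_rng(1)
        ref = _random_cds(rng, 600)
        assert project_insertion_site(ref, ref, 100) == 100

    def test_deletion_upstream_shifts_host_coordinates(self):
        rng = np.random.default_rng(2)
        ref = _random_cds(rng, 600)
        host = ref[:50] + ref[53:]  # 3-nt deletion upstream of the site
        assert project_insertion_site(host, ref, 97) == 100

    def test_insertion_spanning_site_uses_nearest_left_reference_column(self):
        rng = np.random.default_rng(3)
        ref = _random_cds(rng, 600)
        insert = "TTTTTT"
        host = ref[:200] + insert + ref[200:]
        # positions inside the host-only insertion all map to reference 200
        for off in (201, 203, 206):
            assert project_insertion_site(host, ref, off) == 200
        # downstream of the insertion the mapping resumes shifted by 6
        assert project_insertion_site(host, ref, 300) == 294

    def test_projection_exact_under_substitutions_only(self):
        rng = np.random.default_rng(4)
        hits = 0
        for i in range(50):
            ref = _random_cds(rng, 900)
            host = mutate_sequence(ref, 0.05, seed=1000 + i)
            pos = int(rng.integers(1, 900))
            if project_insertion_site(host, ref, pos) == pos:
                hits += 1
        assert hits == 50

    def test_low_identity_refused(self):
        rng = np.random.default_rng(5)
        a, b = _random_cds(rng, 300), _random_cds(rng, 300)
        with pytest.raises(HomologyError):
            project_insertion_site(a, b, 100)

    def test_offset_out_of_range(self):
        with pytest.raises(MitocompError):
            project_insertion_site("ACGT", "ACGT", 5)


class TestMatrix:
    def test_planted_matrix_recovered_exactly(self, study_cohort):
        records, truth = study_cohort
        reference = next(r for r in records if r.id == "G_calidophilum")
        matrix = assign_pcls(records, reference, include_rrna=False)
        got = {(a.genome, a.gene, a.reference_position)
               for a in matrix.assignments}
        expected = set(zip(truth.introns.genome, truth.introns.gene,
                           truth.introns.ref_position))
        assert got == expected

    def test_row_sums_match_annotation_geometry(self, study_cohort):
        records, truth = study_cohort
        reference = next(r for r in records if r.id == "G_calidophilum")
        matrix = assign_pcls(records, reference, include_rrna=False)
        sums = matrix.row_sums()
        for rec in records:
            count = sum(f.n_implied_introns for f in rec.features
                        if f.kind == "core_pcg")
            assert sums[rec.id] == count

    def test_intron_free_genome_gives_all_absent_row(self):
        records, _ = generate_cohort(SynthSpec(
            n_genomes=3, divergence=0.02, seed=40,
            intron_plants=(IntronPlant("G01", "cox1", 500, 400),)))
        matrix = assign_pcls(records, records[0], include_rrna=False)
        assert matrix.row_sums()["G02"] == 0
        assert matrix.row_sums()["G03"] == 0

    def test_shared_site_yields_single_column(self):
        records, _ = generate_cohort(SynthSpec(
            n_genomes=3, divergence=0.03, seed=41,
            intron_plants=(IntronPlant("G01", "cox1", 1305, 400),
                           IntronPlant("G02", "cox1", 1305, 400))))
        matrix = assign_pcls(records, records[2], include_rrna=False)
        assert list(matrix.table.columns) == [("cox1", "P1305")]
        col = matrix.table[("cox1", "P1305")]
        assert col["G01"] and col["G02"] and not col["G03"]


FOUR_LEAF_TREE = "((A:1,B:1):1,(C:1,D:1):1);"


def _oracle_min_changes(pattern: dict[str, int]) -> int:
    """Exhaustive minimum-change count on the fixed 4-leaf topology:
    internal nodes are the AB ancestor, CD ancestor and the root."""
    best = 99
    for ab, cd, root in itertools.product((0, 1), repeat=3):
        changes = (
            (pattern["A"] != ab) + (pattern["B"] != ab)
            + (pattern["C"] != cd) + (pattern["D"] != cd)
            + (ab != root) + (cd != root) + (root != 0)  # absent below the root
        )
        best = min(best, changes)
    return best


class TestGainLoss:
    def _single_pcl_matrix(self, present, leaves=("A", "B", "C", "D")):
        import pandas as pd

        from mitocomp.pcl import PclMatrix

        cols = pd.MultiIndex.from_tuples([("cox1", "P100")], names=["gene", "pcl"])
        table = pd.DataFrame(
            [[leaf in present] for leaf in leaves],
            index=pd.Index(leaves, name="genome"), columns=cols)
        return PclMatrix(table=table, assignments=[])

    def test_present_in_all_leaves_single_root_gain(self):
        m = self._single_pcl_matrix({"A", "B", "C", "D"})
        for criterion in ("dollo", "fitch"):
            ev = infer_gain_loss(m, FOUR_LEAF_TREE, criterion)
            assert ev.total_gains == 1 and ev.total_losses == 0

    def test_single_carrier_terminal_gain(self):
        m = self._single_pcl_matrix({"B"})
        ev = infer_gain_loss(m, FOUR_LEAF_TREE, "dollo")
        assert ev.events[("cox1", "P100")] == [("B", "gain")]

    def test_two_leaf_clade_gains_on_stem(self):
        m = self._single_pcl_matrix({"C", "D"})
        for criterion in ("dollo", "fitch"):
            ev = infer_gain_loss(m, FOUR_LEAF_TREE, criterion)
            assert ev.events[("cox1", "P100")] == [("{C,D}", "gain")]

    def test_event_counts_match_exhaustive_enumeration(self):
        for bits in itertools.product((0, 1), repeat=4):
            pattern = dict(zip("ABCD", bits))
            present = {k for k, v in pattern.items() if v}
            m = self._single_pcl_matrix(present)
            ev = infer_gain_loss(m, FOUR_LEAF_TREE, "fitch")
            n_events = ev.total_gains + ev.total_losses
            assert n_events == _oracle_min_changes(pattern)

    def test_reconstructions_replay_to_leaf_patterns(self, study_cohort):
        records, truth = study_cohort
        reference = next(r for r in records if r.id == "G_calidophilum")
        matrix = assign_pcls(records, reference, include_rrna=False)
        for criterion in ("dollo", "fitch"):
            ev = infer_gain_loss(matrix, truth.tree_newick, criterion)
            for col, events in ev.events.items():
                observed = set(matrix.table.index[matrix.table[col]])
                assert leaf_states_from_events(truth.tree_newick, events) == observed

    def test_fitch_never_needs_more_events_than_dollo(self, study_cohort):
        records, truth = study_cohort
        reference = next(r for r in records if r.id == "G_calidophilum")
        matrix = assign_pcls(records, reference, include_rrna=False)
        dollo = infer_gain_loss(matrix, truth.tree_newick, "dollo")
        fitch = infer_gain_loss(matrix, truth.tree_newick, "fitch")
        assert (fitch.total_gains + fitch.total_losses
                <= dollo.total_gains + dollo.total_losses)

    def test_leaf_mismatch_reported(self):
        m = self._single_pcl_matrix({"A"}, leaves=("A", "B", "C", "D", "E"))
        with pytest.raises(MitocompError, match="E"):
            infer_gain_loss(m, FOUR_LEAF_TREE, "dollo")


class TestSummary:
    def test_host_gene_ranking(self, study_cohort):
        records, truth = study_cohort
        summary = intron_summary(records)
        assert summary["host_ranking"][0] == "cox1"
        assert "nad6" not in summary["per_gene"]

    def test_single_genome_all_pcls_rare(self):
        records, _ = generate_cohort(SynthSpec(
            n_genomes=1, divergence=0.0, seed=42,
            intron_plants=(IntronPlant("G01", "cox1", 100, 400),
                           IntronPlant("G01", "cob", 393, 400))))
        matrix = assign_pcls(records, records[0], include_rrna=False)
        summary = intron_summary(records, matrix)
        assert sorted(summary["rare_pcls"]) == ["cob:P393", "cox1:P100"]

    def test_empty_cohort(self):
        summary = intron_summary([])
        assert summary["per_genome"] == {} and summary["per_gene"] == {}
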