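"""Free-standing ORF translation and homolog clustering."""

import numpy as np
import pytest

from mitocomp.errors import MitocompError
from mitocomp.homologs import cluster_orfs, translate_orf
from mitocomp.io_annotation import GeneFeature, MitogenomeRecord
from mitocomp.compstats import amino_acid


def _record_with_orfs(rec_id, orfs):
    """Build a genome holding the given (name, cds, product) free ORFs."""
    spacer = "ATATATATAT"
    parts, feats, cursor = [], [], 0
    for name, cds, product in orfs:
        parts.append(spacer)
        cursor += len(spacer)
        feats.append(GeneFeature(name, "orf", "+", ((cursor, cursor + len(cds)),),
                                 product=product))
        parts.append(cds)
        cursor += len(cds)
    parts.append(spacer)
    return MitogenomeRecord(rec_id, "".join(parts), feats)


def _random_orf(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if amino_acid(c) != "*":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


class TestTranslate:
    def test_tga_translates_to_trp(self):
        rec = _record_with_orfs("x", [("orf2", "ATGTGATAA", "")])
        assert translate_orf(rec.features[0], rec) == "MW"

    def test_trailing_stop_removed(self):
        rng = np.random.default_rng(60)
        cds = _random_orf(rng, 149)  # start + 149 codons + stop = 151 codons
        rec = _record_with_orfs("x", [("orf150", cds, "")])
        assert len(translate_orf(rec.features[0], rec)) == 150

    def test_frame_broken_orf_rejected(self):
        rec = _record_with_orfs("x", [("bad", "ATGAAAT", "")])
        with pytest.raises(MitocompError):
            translate_orf(rec.features[0], rec)

    def test_internal_stop_rejected(self):
        rec = _record_with_orfs("x", [("bad", "ATGTAAAAATAA", "")])
        with pytest.raises(MitocompError, match="internal stop"):
            translate_orf(rec.features[0], rec)


class TestClustering:
    def test_identical_orf_in_six_genomes_single_cluster(self):
        rng = np.random.default_rng(61)
        cds = _random_orf(rng, 108)  # 109-aa protein
        records = [_record_with_orfs(f"g{i}", [("orf109", cds, "RNA polymerase")])
                   for i in range(6)]
        clusters, matrix = cluster_orfs(records)
        assert len(clusters) == 1
        assert clusters[0].label == "orf109"
        assert clusters[0].function_note == "RNA polymerase"
        assert matrix["orf109"].all()

    def test_dissimilar_orfs_stay_separate(self):
        rng = np.random.default_rng(62)
        a, b = _random_orf(rng, 100), _random_orf(rng, 100)
        records = [_record_with_orfs("g1", [("orfA", a, "")]),
                   _record_with_orfs("g2", [("orfB", b, "")])]
        clusters, _ = cluster_orfs(records)
        assert len(clusters) == 2

    def test_length_variants_cluster_together(self):
        # homologs of 429 and 439 codons at ~85% identity
        rng = np.random.default_rng(63)
        base = _random_orf(rng, 428)
        codons = [base[i:i + 3] for i in range(0, len(base), 3)]
        variant = codons[:-1]
        for i in range(1, len(variant) - 1):
            if rng.random() < 0.15:
                alt = "".join(rng.choice(list("ACGT"), size=3))
                if amino_acid(alt) != "*":
                    variant[i] = alt
        extra = []
        while len(extra) < 10:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if amino_acid(c) != "*":
                extra.append(c)
        variant = variant + extra + ["TAA"]
        records = [_record_with_orfs("g1", [("orf429", base, "hypothetical protein")]),
                   _record_with_orfs("g2", [("orf439", "".join(variant), "hypothetical protein")])]
        clusters, matrix = cluster_orfs(records)
        assert len(clusters) == 1
        assert matrix.iloc[0, 0] and matrix.iloc[1, 0]

    def test_clustering_is_input_order_independent(self, study_records):
        clusters_fwd, _ = cluster_orfs(study_records)
        clusters_rev, _ = cluster_orfs(study_records[::-1])
        fwd = {frozenset(c.members) for c in clusters_fwd}
        rev = {frozenset(c.members) for c in clusters_rev}
        assert fwd == rev

    def test_raising_identity_threshold_never_merges(self, study_records):
        loose, _ = cluster_orfs(study_records, min_identity=40.0)
        strict, _ = cluster_orfs(study_records, min_identity=80.0)
        loose_sets = [frozenset(c.members) for c in loose]
        for cluster in strict:
            members = frozenset(cluster.members)
            assert any(members <= ls for ls in loose_sets)

    def test_every_orf_in_exactly_one_cluster(self, study_records):
        clusters, _ = cluster_orfs(study_records)
        seen = [m for c in clusters for m in c.members]
        assert len(seen) == len(set(seen))
        n_orfs = sum(len(r.features_of_kind("orf")) for r in study_records)
        assert len(seen) == n_orfs

    def test_planted_families_recovered(self, study_records, study_truth):
        clusters, matrix = cluster_orfs(study_records)
        by_family = study_truth.orf_members.groupby("family")["genome"].apply(set)
        cluster_genomes = [set(m[0] for m in c.members) for c in clusters]
        for family, genomes in by_family.items():
            assert genomes in cluster_genomes
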