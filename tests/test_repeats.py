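"""Repeat detection against planted truth and brute-force interval oracles."""

import numpy as np
import pytest

from mitocomp.io_annotation import MitogenomeRecord, revcomp
from mitocomp.repeats import (
    RepeatPair,
    TandemRepeat,
    find_interspersed_repeats,
    find_tandem_repeats,
    repeat_fraction,
)


def _random_record(n: int, seed: int, gc: float = 0.26) -> MitogenomeRecord:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
    return MitogenomeRecord("rand", seq, [])


class TestInterspersed:
    def test_random_uniform_sequence_has_no_repeats(self):
        rec = _random_record(50_000, seed=42, gc=0.5)
        assert find_interspersed_repeats(rec) == []

    def test_planted_exact_duplication_found(self):
        rec = _random_record(20_000, seed=1)
        unit = rec.sequence[5_000:5_100]
        seq = rec.sequence[:12_000] + unit + rec.sequence[12_000:]
        planted = MitogenomeRecord("p", seq, [])
        pairs = find_interspersed_repeats(planted)
        direct = [p for p in pairs if p.orientation == "direct"]
        assert len(direct) == 1
        (p,) = direct
        assert p.interval_a[0] <= 5_000 and p.interval_a[1] >= 5_100
        assert p.interval_b[0] <= 12_000 and p.interval_b[1] >= 12_100
        assert p.identity == pytest.approx(100.0)

    def test_planted_inverted_copy_found_as_inverted(self):
        rec = _random_record(20_000, seed=2)
        unit = rec.sequence[3_000:3_090]
        seq = rec.sequence[:15_000] + revcomp(unit) + rec.sequence[15_000:]
        pairs = find_interspersed_repeats(MitogenomeRecord("p", seq, []))
        inverted = [p for p in pairs if p.orientation == "inverted"]
        assert len(inverted) == 1
        assert inverted[0].length >= 90

    def test_all_planted_exact_repeats_found(self, small_cohort):
        records, truth = small_cohort
        by_id = {r.id: r for r in records}
        dup = truth.repeats[truth.repeats.kind == "direct"]
        for genome, group in dup.groupby("genome"):
            pairs = find_interspersed_repeats(by_id[genome])
            intervals = [iv for p in pairs for iv in (p.interval_a, p.interval_b)]
            for _, row in group.iterrows():
                assert any(s <= row.start and e >= row.end for s, e in intervals)

    def test_no_pair_below_identity_floor(self, study_records):
        for rec in study_records[:3]:
            for p in find_interspersed_repeats(rec, min_identity=85.0):
                assert p.identity >= 85.0

    def test_sequence_too_short_rejected(self):
        from mitocomp.errors import MitocompError

        with pytest.raises(MitocompError):
            find_interspersed_repeats(MitogenomeRecord("s", "ACGT" * 10, []))


class TestTandem:
    def test_planted_unit_45_by_3(self):
        rec = _random_record(10_000, seed=3)
        unit = rec.sequence[100:145]
        seq = rec.sequence[:6_000] + unit * 3 + rec.sequence[6_000:]
        arrays = find_tandem_repeats(MitogenomeRecord("t", seq, []))
        hits = [t for t in arrays if t.unit_length == 45]
        assert len(hits) == 1
        assert hits[0].copy_number == pytest.approx(3.0, abs=0.1)
        assert hits[0].start <= 6_000 <= hits[0].end

    def test_homopolymer_reported_as_period_one(self):
        seq = "GC" * 40 + "A" * 40 + "GC" * 40
        arrays = find_tandem_repeats(MitogenomeRecord("h", seq, []))
        period1 = [t for t in arrays if t.unit_length == 1 and t.consensus_unit == "A"]
        assert len(period1) == 1
        assert period1[0].copy_number == pytest.approx(40.0)

    def test_shuffled_sequence_has_no_long_multicopy_arrays(self):
        rec = _random_record(20_000, seed=4)
        shuffled = "".join(
            np.random.default_rng(5).permutation(list(rec.sequence)))
        arrays = find_tandem_repeats(MitogenomeRecord("s", shuffled, []))
        assert not [t for t in arrays
                    if t.unit_length > 5 and t.copy_number >= 3]


class TestFraction:
    def test_no_repeats_zero(self):
        rec = _random_record(1_000, seed=6)
        assert repeat_fraction(rec, [], []) == 0.0

    def test_overlapping_intervals_union(self):
        rec = _random_record(10_000, seed=7)
        pair = RepeatPair((0, 1000), (500, 1500), "direct", 1000, 100.0)
        assert repeat_fraction(rec, [pair], []) == pytest.approx(15.0)

    def test_against_per_base_marking_oracle(self):
        rng = np.random.default_rng(8)
        rec = _random_record(5_000, seed=8)
        pairs, tandems = [], []
        for _ in range(20):
            s = int(rng.integers(0, 4_800))
            e = s + int(rng.integers(10, 200))
            if rng.random() < 0.5:
                s2 = int(rng.integers(0, 4_800))
                pairs.append(RepeatPair((s, min(e, 5_000)),
                                        (s2, min(s2 + e - s, 5_000)),
                                        "direct", e - s, 100.0))
            else:
                tandems.append(TandemRepeat(s, min(e, 5_000), 5, 2.0, "AAAAA"))
        mask = np.zeros(5_000, dtype=bool)
        for p in pairs:
            mask[p.interval_a[0]:p.interval_a[1]] = True
            mask[p.interval_b[0]:p.interval_b[1]] = True
        for t in tandems:
            mask[t.start:t.end] = True
        expected = 100.0 * mask.sum() / 5_000
        assert repeat_fraction(rec, pairs, tandems) == pytest.approx(expected)

    def test_planted_coverage_fraction(self, small_cohort):
        records, truth = small_cohort
        by_id = {r.id: r for r in records}
        g1 = truth.repeats[truth.repeats.genome == "G01"]
        rec = by_id["G01"]
        pairs = find_interspersed_repeats(rec)
        frac = repeat_fraction(rec, pairs, [])
        planted = (g1.end - g1.start).sum()
        assert frac >= 100.0 * planted / rec.length * 0.9

    def test_fraction_monotone_in_min_len(self, study_records):
        rec = study_records[9]  # carries planted repeats
        fr = []
        for min_len in (100, 50, 30):
            pairs = find_interspersed_repeats(rec, min_len=min_len)
            fr.append(repeat_fraction(rec, pairs, []))
        assert fr == sorted(fr)
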