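"""Intra-genomic repeat detection.

Interspersed repeats come from a deterministic seed-and-extend self-comparison
(exact k-mer seeds, gapless extension with an x-drop, both orientations);
tandem repeats from a period scan.  Explicit (min_len, min_identity)
thresholds replace engine-specific E-values, keeping the contract
deterministic across machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MitocompError
from .io_annotation import MitogenomeRecord, revcomp

SEED_K = 12
XDROP = 20.0
_MATCH, _MISMATCH = 1.0, -2.0


@dataclass(frozen=True)
class RepeatPair:
    interval_a: tuple[int, int]  # 0-based half-open, interval_a < interval_b
    interval_b: tuple[int, int]
    orientation: str  # "direct" | "inverted"
    length: int
    identity: float  # percent


@dataclass(frozen=True)
class TandemRepeat:
    start: int
    end: int
    unit_length: int
    copy_number: float
    consensus_unit: str


# --------------------------------------------------------------------------
# interspersed repeats
# --------------------------------------------------------------------------


def _extend_gapless(a: np.ndarray, b: np.ndarray, ai: int, bi: int,
                    k: int) -> tuple[int, int, int, int]:
    """Extend an exact k-mer seed (a[ai:ai+k] == b[bi:bi+k]) both ways with
    x-drop; returns (a_start, a_end, matches, length) of the best window."""
    na, nb = len(a), len(b)

    def _walk(step_a: int, step_b: int, limit: int) -> tuple[int, int]:
        best_len, best_matches, best_score = 0, 0, 0.0
        score, matches = 0.0, 0
        for d in range(1, limit + 1):
            m = a[ai + step_a * d + (k - 1 if step_a > 0 else 0)] == \
                b[bi + step_b * d + (k - 1 if step_b > 0 else 0)]
            score += _MATCH if m else _MISMATCH
            matches += int(m)
            if score > best_score:  # strict: ties keep the shorter window
                best_len, best_matches, best_score = d, matches, score
            elif score < best_score - XDROP:
                break
        return best_len, best_matches

    right_limit = min(na - (ai + k), nb - (bi + k))
    best_r, matches_r = _walk(1, 1, right_limit)
    left_limit = min(ai, bi)
    best_l, matches_l = _walk(-1, -1, left_limit)
    a_start = ai - best_l
    a_end = ai + k + best_r
    matches = matches_l + k + matches_r
    return a_start, a_end, matches, a_end - a_start


def _overlap_frac(x: tuple[int, int], y: tuple[int, int]) -> float:
    inter = max(0, min(x[1], y[1]) - max(x[0], y[0]))
    return inter / max(1, min(x[1] - x[0], y[1] - y[0]))


def _merge_pairs(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs whose both intervals overlap a longer kept pair by >= 50%."""
    kept: list[RepeatPair] = []
    for p in sorted(pairs, key=lambda q: (-q.length, q.interval_a, q.interval_b)):
        dup = any(
            p.orientation == q.orientation
            and _overlap_frac(p.interval_a, q.interval_a) >= 0.5
            and _overlap_frac(p.interval_b, q.interval_b) >= 0.5
            for q in kept
        )
        if not dup:
            kept.append(p)
    return sorted(kept, key=lambda q: (q.interval_a, q.interval_b))


def _seed_pairs_same(arr: np.ndarray, k: int):
    """Yield (i, j) seed positions (i < j) of identical k-mers within arr."""
    index: dict[bytes, list[int]] = {}
    view = arr.tobytes()
    for i in range(len(arr) - k + 1):
        index.setdefault(view[i:i + k], []).append(i)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions) - 1):
            for y in range(x + 1, len(positions)):
                yield positions[x], positions[y]


def find_interspersed_repeats(record: MitogenomeRecord, min_len: int = 30,
                              min_identity: float = 80.0) -> list[RepeatPair]:
    """Self-comparison repeat search (direct and inverted orientations).

    The trivial self-match of the whole sequence is excluded; overlapping
    hits merge onto the longest representative.
    """
    seq = record.sequence.upper()
    if len(seq) < 2 * min_len:
        raise MitocompError("sequence shorter than twice min_len")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    n = len(seq)
    results: list[RepeatPair] = []

    # direct: seed pairs within the sequence, skipping the trivial diagonal
    done_diag: dict[int, int] = {}
    for i, j in _seed_pairs_same(arr, SEED_K):
        d = j - i
        if d == 0:
            continue
        if done_diag.get(d, -1) >= i:
            continue
        s, e, matches, length = _extend_gapless(arr, arr, i, j, SEED_K)
        done_diag[d] = e
        ident = 100.0 * matches / length
        if length >= min_len and ident >= min_identity:
            results.append(RepeatPair((s, e), (s + d, e + d), "direct", length, ident))

    # inverted: compare against the reverse complement
    done_anti: dict[int, int] = {}
    index: dict[bytes, list[int]] = {}
    rc_bytes = rc.tobytes()
    for i in range(n - SEED_K + 1):
        index.setdefault(rc_bytes[i:i + SEED_K], []).append(i)
    fwd_bytes = arr.tobytes()
    for i in range(n - SEED_K + 1):
        for j in index.get(fwd_bytes[i:i + SEED_K], ()):
            anti = i + j
            if done_anti.get(anti, -1) >= i:
                continue
            s, e, matches, length = _extend_gapless(arr, rc, i, j, SEED_K)
            done_anti[anti] = e
            # map the rc interval back to forward coordinates
            js = j + (s - i)
            je = js + length
            f_s, f_e = n - je, n - js
            if length < min_len or 100.0 * matches / length < min_identity:
                continue
            iv_a, iv_b = ((s, e), (f_s, f_e)) if s <= f_s else ((f_s, f_e), (s, e))
            if iv_a == iv_b or _overlap_frac(iv_a, iv_b) >= 0.9:
                continue  # palindromic self-hit
            results.append(RepeatPair(iv_a, iv_b, "inverted", length,
                                      100.0 * matches / length))

    return _merge_pairs(results)


# --------------------------------------------------------------------------
# tandem repeats
# --------------------------------------------------------------------------


def find_tandem_repeats(record: MitogenomeRecord, min_array_len: int = 10,
                        max_period: int = 500) -> list[TandemRepeat]:
    """Period scan: maximal arrays of >= 2 copies with array length exceeding
    *min_array_len*.  Overlapping calls keep the smallest explaining period."""
    seq = record.sequence.upper()
    if not seq:
        raise MitocompError("empty sequence")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    candidates: list[TandemRepeat] = []
    for p in range(1, min(max_period, n // 2) + 1):
        eq = arr[p:] == arr[:-p]
        if not eq.any():
            continue
        # runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            run = e - s  # matched positions; array spans run + p bases
            array_len = run + p
            if run >= p and array_len > min_array_len:
                candidates.append(TandemRepeat(
                    start=int(s), end=int(s) + array_len, unit_length=p,
                    copy_number=array_len / p,
                    consensus_unit=seq[int(s): int(s) + p],
                ))
    # prefer smaller periods when arrays overlap substantially
    kept: list[TandemRepeat] = []
    for c in sorted(candidates, key=lambda t: (t.unit_length, t.start)):
        span = (c.start, c.end)
        if any(_overlap_frac(span, (k.start, k.end)) >= 0.8 for k in kept):
            continue
        kept.append(c)
    return sorted(kept, key=lambda t: t.start)


# --------------------------------------------------------------------------
# repeat fraction
# --------------------------------------------------------------------------


def repeat_fraction(record: MitogenomeRecord, pairs: list[RepeatPair],
                    tandems: list[TandemRepeat]) -> float:
    """Percent of the genome covered by the union of all repeat intervals."""
    intervals: list[tuple[int, int]] = []
    for p in pairs:
        intervals.extend([p.interval_a, p.interval_b])
    intervals.extend((t.start, t.end) for t in tandems)
    for s, e in intervals:
        if not (0 <= s <= e <= record.length):
            raise MitocompError(f"repeat interval ({s}, {e}) outside genome")
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return 100.0 * covered / record.length
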