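"""Pairwise K2P distances and NG86 Ka/Ks under the mold mitochondrial code.

K2P: d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)] with P, Q the transition and
transversion proportions over retained (gap/N-free) columns.

NG86 (Nei & Gojobori): per-codon synonymous/nonsynonymous site counting with
mutations to stop codons counted as nonsynonymous, equal-weight pathway
averaging for multi-hit codon pairs with stop-routed pathways excluded, and
Jukes-Cantor correction of the proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import MitocompError, SaturationError
from .compstats import CODE4, amino_acid
from .io_annotation import CORE_PCGS, MitogenomeRecord, extract_coding_exons

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = "ACGT"


@dataclass(frozen=True)
class K2pResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # K2P distance, substitutions/site
    sites: int


@dataclass(frozen=True)
class PairwiseRates:
    gene: str
    pair: tuple[str, str]
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0
    selection_class: str  # purifying | positive_or_relaxed | undefined


# --------------------------------------------------------------------------
# K2P
# --------------------------------------------------------------------------


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def k2p_distance(aln_a: str, aln_b: str) -> K2pResult:
    """Kimura two-parameter distance between two aligned sequences.

    Columns where either sequence has a gap or ambiguous base are excluded
    pairwise.  Saturated pairs (log argument <= 0) raise SaturationError.
    """
    if len(aln_a) != len(aln_b):
        raise MitocompError("aligned sequences differ in length")
    ts = tv = sites = 0
    for x, y in zip(aln_a.upper(), aln_b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        sites += 1
        if x != y:
            if _is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise MitocompError("no comparable columns")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2pResult(P=P, Q=Q, d=d, sites=sites)


# --------------------------------------------------------------------------
# NG86
# --------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a codon; mutations to stop
    codons count as nonsynonymous."""
    aa = amino_acid(codon)
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if amino_acid(mut) == aa and amino_acid(mut) != "*":
                syn += 1 / 3
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all substitution pathways with equal weights; pathways passing
    through a stop codon are excluded (all-blocked pairs fall back to the
    full set)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if amino_acid(nxt) == "*" and step < len(order) - 1:
                blocked = True
            if amino_acid(cur) == amino_acid(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    valid = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float, what: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{what} proportion {p:.4f} >= 3/4: saturated")
    return -0.75 * math.log(1 - 4 * p / 3)


def _split_codons(seq: str, label: str) -> list[str]:
    if len(seq) % 3:
        raise MitocompError(f"{label}: length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons[:-1]):
        if amino_acid(c) == "*":
            raise MitocompError(f"{label}: internal stop codon at codon {i + 1}")
    if codons and amino_acid(codons[-1]) == "*":
        codons = codons[:-1]
    return codons


def ng86_ka_ks(codon_aln_a: str, codon_aln_b: str, gene: str = "",
               pair: tuple[str, str] = ("a", "b")) -> PairwiseRates:
    """NG86 Ka/Ks between two codon-aligned coding sequences (code 4)."""
    ca = _split_codons(codon_aln_a.upper(), "sequence a")
    cb = _split_codons(codon_aln_b.upper(), "sequence b")
    if len(ca) != len(cb):
        raise MitocompError("codon alignments differ in length")
    S = N = Sd = Nd = 0.0
    for c1, c2 in zip(ca, cb):
        if set(c1 + c2) - set(_BASES):
            continue  # gapped or ambiguous codon column
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _codon_diffs(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise MitocompError("no comparable codons")
    ks = _jukes_cantor(Sd / S, "synonymous") if Sd else 0.0
    ka = _jukes_cantor(Nd / N, "nonsynonymous") if Nd else 0.0
    if ks == 0.0:
        ratio: float | None = None
        cls = "undefined"
    else:
        ratio = ka / ks
        cls = "positive_or_relaxed" if ratio > 1 else "purifying"
    return PairwiseRates(gene=gene, pair=pair, ka=ka, ks=ks, ratio=ratio,
                         selection_class=cls)


# --------------------------------------------------------------------------
# alignment helpers
# --------------------------------------------------------------------------


def _dna_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global", match_score=1, mismatch_score=-1,
                              open_gap_score=-5, extend_gap_score=-1)
    return a


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global", open_gap_score=-11,
                              extend_gap_score=-1)
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return a


def align_dna(a: str, b: str) -> tuple[str, str]:
    """Global DNA alignment (ungapped pass-through when lengths match)."""
    if len(a) == len(b):
        return a, b
    aln = _dna_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def _translate(codons: list[str]) -> str:
    return "".join(amino_acid(c) for c in codons)


def codon_align(a: str, b: str) -> tuple[str, str]:
    """Codon-level pairwise alignment, protein-guided to preserve frame.

    Returns two equal-length codon sequences containing only the codon
    columns where both proteins align without gaps.
    """
    ca = _split_codons(a.upper(), "sequence a")
    cb = _split_codons(b.upper(), "sequence b")
    if len(ca) == len(cb):
        return "".join(ca), "".join(cb)
    pa, pb = _translate(ca), _translate(cb)
    aln = _protein_aligner().align(pa, pb)[0]
    out_a, out_b = [], []
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        for k in range(ae - as_):
            out_a.append(ca[as_ + k])
            out_b.append(cb[bs + k])
    return "".join(out_a), "".join(out_b)


# --------------------------------------------------------------------------
# cohort-level rate tables
# --------------------------------------------------------------------------


def rates_matrix(records: list[MitogenomeRecord],
                 genes: list[str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-pair K2P and NG86 statistics plus per-gene summaries.

    Returns (pairs, summary).  Genes present in fewer than two genomes are
    skipped with a log entry; saturated or degenerate pairs yield NaN cells.
    """
    genes = genes if genes is not None else sorted(CORE_PCGS)
    rows = []
    for gene in genes:
        have = [(r.id, extract_coding_exons(r, gene).cds)
                for r in records if r.has_gene(gene)]
        if len(have) < 2:
            logger.info("gene %s present in %d genome(s); skipped", gene, len(have))
            continue
        for (ida, sa), (idb, sb) in itertools.combinations(have, 2):
            row = {"gene": gene, "a": ida, "b": idb, "P": np.nan, "Q": np.nan,
                   "d": np.nan, "ka": np.nan, "ks": np.nan, "ratio": np.nan,
                   "selection_class": "undefined"}
            try:
                k = k2p_distance(*align_dna(sa, sb))
                row.update(P=k.P, Q=k.Q, d=k.d)
            except MitocompError as exc:
                logger.warning("K2P %s %s/%s: %s", gene, ida, idb, exc)
            try:
                pr = ng86_ka_ks(*codon_align(sa, sb), gene=gene, pair=(ida, idb))
                row.update(ka=pr.ka, ks=pr.ks,
                           ratio=np.nan if pr.ratio is None else pr.ratio,
                           selection_class=pr.selection_class)
            except MitocompError as exc:
                logger.warning("NG86 %s %s/%s: %s", gene, ida, idb, exc)
            rows.append(row)
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        return pairs, pd.DataFrame()
    summary = (
        pairs.groupby("gene")
        .agg(mean_d=("d", "mean"), mean_ka=("ka", "mean"), mean_ks=("ks", "mean"),
             mean_ratio=("ratio", "mean"), n_pairs=("d", "size"))
        .reset_index()
    )
    summary["rank_by_d"] = summary["mean_d"].rank(ascending=False, method="min")
    summary["rank_by_ka"] = summary["mean_ka"].rank(ascending=False, method="min")
    summary["rank_by_ks"] = summary["mean_ks"].rank(ascending=False, method="min")
    return pairs, summary
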