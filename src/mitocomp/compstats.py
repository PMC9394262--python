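"""Base composition, strand skews, codon usage (genetic code 4), start/stop
codon tables, and the intron-count vs genome-size correlation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import MitocompError
from .io_annotation import CORE_PCGS, MitogenomeRecord, extract_coding_exons

logger = logging.getLogger(__name__)

#: Mold mitochondrial code: TGA encodes Trp, stops are TAA/TAG.
CODE4 = CodonTable.unambiguous_dna_by_id[4]


def amino_acid(codon: str) -> str:
    """One-letter amino acid under genetic code 4, '*' for a stop."""
    c = codon.upper()
    if c in CODE4.stop_codons:
        return "*"
    return CODE4.forward_table[c]


@dataclass(frozen=True)
class SkewStats:
    gc_percent: float
    at_percent: float
    at_skew: float | None  # None marks an undefined (zero) denominator
    gc_skew: float | None


def base_composition(seq: str) -> SkewStats:
    """AT/GC content and strand skews, (A-T)/(A+T) and (G-C)/(G+C).

    N bases are excluded from every count; a zero denominator yields None.
    """
    if not seq:
        raise MitocompError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    total = a + c + g + t
    if total == 0:
        raise MitocompError("sequence contains no unambiguous bases")
    return SkewStats(
        gc_percent=100.0 * (g + c) / total,
        at_percent=100.0 * (a + t) / total,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


def codon_usage(cds_list: list[str]) -> pd.DataFrame:
    """64-row codon usage table over spliced CDS sequences.

    Columns: codon, amino_acid, count, frequency (per amino acid; NaN for
    codons of amino acids never observed).  Reading frame starts at position
    0 of each CDS; a trailing partial codon is dropped with a warning.
    """
    counts: dict[str, int] = {}
    for cds in cds_list:
        s = cds.upper()
        if len(s) % 3:
            logger.warning("CDS length %d not a multiple of 3; trailing bases dropped",
                           len(s))
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
    if not cds_list:
        return pd.DataFrame(columns=["codon", "amino_acid", "count", "frequency"])
    bases = "TCAG"
    rows = []
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                rows.append({"codon": codon, "amino_acid": amino_acid(codon),
                             "count": counts.get(codon, 0)})
    df = pd.DataFrame(rows)
    aa_totals = df.groupby("amino_acid")["count"].transform("sum")
    df["frequency"] = np.where(aa_totals > 0, df["count"] / aa_totals, np.nan)
    return df


def start_stop_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """First and last codon of each spliced core PCG, per genome.

    Missing genes yield empty cells; genes shorter than 6 nt are flagged.
    """
    rows = []
    for rec in records:
        for gene in sorted(CORE_PCGS):
            if not rec.has_gene(gene):
                rows.append({"genome": rec.id, "gene": gene, "start_codon": "",
                             "stop_codon": "", "flag": "absent"})
                continue
            cds = extract_coding_exons(rec, gene).cds
            if len(cds) < 6:
                rows.append({"genome": rec.id, "gene": gene, "start_codon": "",
                             "stop_codon": "", "flag": "too_short"})
                continue
            rows.append({"genome": rec.id, "gene": gene,
                         "start_codon": cds[:3], "stop_codon": cds[-3:], "flag": ""})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    spearman_rho: float
    pearson_p: float
    spearman_p: float
    n: int


def count_introns(record: MitogenomeRecord) -> int:
    """Intron count from annotation geometry: implied by multi-segment genes."""
    return sum(
        f.n_implied_introns
        for f in record.features
        if f.kind in ("core_pcg", "orf", "rRNA")
    )


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom if denom else float("nan")


def _exact_perm_p(x: np.ndarray, y: np.ndarray, observed: float,
                  use_ranks: bool) -> float:
    import itertools

    if use_ranks:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    hits = total = 0
    for perm in itertools.permutations(range(len(y))):
        r = _pearson_r(x, y[list(perm)])
        total += 1
        if abs(r) >= abs(observed) - 1e-12:
            hits += 1
    return hits / total


# Exact permutation p-values are enumerated up to this cohort size; beyond it
# (including the 13-genome study scale) the t-approximation is used.
_EXACT_PERM_MAX_N = 8


def _correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    n = len(x)
    if n < 3:
        raise MitocompError(f"correlation needs >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant input: undefined, not an error
        nan = float("nan")
        return CorrelationResult(nan, nan, nan, nan, n)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)  # midrank ties
    pp, sp = float(pr.pvalue), float(sr.pvalue)
    if n <= _EXACT_PERM_MAX_N:
        pp = _exact_perm_p(x, y, float(pr.statistic), use_ranks=False)
        sp = _exact_perm_p(x, y, float(sr.statistic), use_ranks=True)
    return CorrelationResult(
        pearson_r=float(pr.statistic), spearman_rho=float(sr.statistic),
        pearson_p=pp, spearman_p=sp, n=n,
    )


def intron_size_correlation(records: list[MitogenomeRecord]) -> CorrelationResult:
    """Pearson and Spearman correlation of per-genome intron count against
    genome length across the cohort."""
    x = np.array([count_introns(r) for r in records], dtype=float)
    y = np.array([r.length for r in records], dtype=float)
    return _correlation(x, y)


def composition_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """One composition/skew row per genome (direct strand)."""
    rows = []
    for rec in records:
        st = base_composition(rec.sequence)
        rows.append({
            "genome": rec.id, "length_bp": rec.length,
            "gc_percent": st.gc_percent, "at_percent": st.at_percent,
            "at_skew": st.at_skew, "gc_skew": st.gc_skew,
            "introns": count_introns(rec),
        })
    return pd.DataFrame(rows)
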