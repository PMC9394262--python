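"""14-gene supermatrix construction and a desk-scale distance tree.

The concatenated gene set excludes rps3 and all intron regions.  Per-gene
multiple alignment is a star alignment around the longest sequence; tree
inference is neighbor joining on K2P distances with nonparametric bootstrap
support from column resampling.  Alignment and partition writers (FASTA,
relaxed PHYLIP, NEXUS, RAxML-style partitions) let external ML/Bayesian
tools run on the same supermatrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import LookupFailure, MitocompError, SaturationError
from .evorates import _dna_aligner, k2p_distance
from .io_annotation import CORE_PCGS, MitogenomeRecord, extract_coding_exons

logger = logging.getLogger(__name__)

#: genes of the concatenated set: the core PCGs minus rps3
SUPERMATRIX_GENES: tuple[str, ...] = tuple(sorted(CORE_PCGS - {"rps3"}))


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]  # taxon -> aligned concatenated sequence
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column_array(self) -> np.ndarray:
        return np.array([list(self.rows[t]) for t in self.taxa])


@dataclass
class TreeWithSupport:
    tree: TreeNode
    supports: dict[frozenset, float] | None = None

    @property
    def newick(self) -> str:
        return str(self.tree).strip()


# --------------------------------------------------------------------------
# star alignment
# --------------------------------------------------------------------------


def _star_align(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple alignment by pairwise alignment of every sequence to the
    longest one, merged on the shared center columns."""
    if not seqs:
        return {}
    center_taxon = max(seqs, key=lambda t: (len(seqs[t]), t))
    c = seqs[center_taxon]
    L = len(c)
    aligner = _dna_aligner()
    per_seq: dict[str, tuple[list[str], list[str]]] = {}
    for taxon, s in seqs.items():
        if taxon == center_taxon:
            continue
        if len(s) == len(c):
            per_seq[taxon] = ([""] * (L + 1), list(s))
            continue
        aln = aligner.align(c, s)[0]
        inserts = [""] * (L + 1)
        chars = ["-"] * L
        prev_ce = prev_se = 0
        for (cs, ce), (ss, se) in zip(*aln.aligned):
            inserts[cs] += s[prev_se:ss]
            for k in range(ce - cs):
                chars[cs + k] = s[ss + k]
            prev_ce, prev_se = ce, se
        inserts[L] += s[prev_se:]
        per_seq[taxon] = (inserts, chars)
    pad = [0] * (L + 1)
    for inserts, _ in per_seq.values():
        for i, ins in enumerate(inserts):
            pad[i] = max(pad[i], len(ins))
    out: dict[str, str] = {}
    center_row = []
    for i in range(L):
        center_row.append("-" * pad[i] + c[i])
    center_row.append("-" * pad[L])
    out[center_taxon] = "".join(center_row)
    for taxon, (inserts, chars) in per_seq.items():
        row = []
        for i in range(L):
            row.append(inserts[i].ljust(pad[i], "-") + chars[i])
        row.append(inserts[L].ljust(pad[L], "-"))
        out[taxon] = "".join(row)
    return out


def build_supermatrix(records: list[MitogenomeRecord],
                      genes: tuple[str, ...] = SUPERMATRIX_GENES) -> Supermatrix:
    """Concatenated intron-free alignment of the 14-gene set with partition
    bookkeeping; taxa lacking a gene get gap rows (logged)."""
    if len(records) < 3:
        raise MitocompError(f"supermatrix needs >= 3 genomes, got {len(records)}")
    taxa = [r.id for r in records]
    blocks: dict[str, dict[str, str]] = {}
    for gene in genes:
        seqs = {}
        for rec in records:
            try:
                seqs[rec.id] = extract_coding_exons(rec, gene).cds
            except LookupFailure:
                logger.warning("%s lacks %s; gap row in that partition", rec.id, gene)
        if seqs:
            blocks[gene] = _star_align(seqs)
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for gene in genes:
        if gene not in blocks:
            continue
        width = len(next(iter(blocks[gene].values())))
        for t in taxa:
            rows[t].append(blocks[gene].get(t, "-" * width))
        partitions.append((gene, pos + 1, pos + width))
        pos += width
    return Supermatrix(taxa=taxa, rows={t: "".join(v) for t, v in rows.items()},
                       partitions=partitions)


# --------------------------------------------------------------------------
# distances and NJ
# --------------------------------------------------------------------------


def k2p_distance_matrix(sm: Supermatrix) -> DistanceMatrix:
    """Pairwise K2P over the shared non-gap columns of the supermatrix."""
    n = len(sm.taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sm.rows[sm.taxa[i]], sm.rows[sm.taxa[j]]
            try:
                mat[i, j] = mat[j, i] = k2p_distance(a, b).d
            except SaturationError:
                raise SaturationError(
                    f"saturated pair: {sm.taxa[i]} / {sm.taxa[j]}"
                )
            except MitocompError as exc:
                raise MitocompError(
                    f"{sm.taxa[i]} / {sm.taxa[j]}: {exc}"
                )
    return DistanceMatrix(mat, ids=sm.taxa)


def nj_tree(dm: DistanceMatrix | pd.DataFrame) -> TreeWithSupport:
    """Neighbor joining with negative branch lengths clamped to zero."""
    if isinstance(dm, pd.DataFrame):
        if not np.allclose(dm.values, dm.values.T):
            raise MitocompError("distance matrix is not symmetric")
        dm = DistanceMatrix(dm.values, ids=list(dm.index))
    if dm.shape[0] < 3:
        raise MitocompError("NJ needs >= 3 taxa")
    tree = nj(dm, neg_as_zero=True)
    return TreeWithSupport(tree=tree)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized to
    the side not containing the alphabetically first taxon."""
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Symmetric bipartition difference between two unrooted trees."""
    pa, pb = bipartitions(a), bipartitions(b)
    return len(pa ^ pb)


def bootstrap_support(sm: Supermatrix, replicates: int = 1000,
                      seed: int = 0) -> TreeWithSupport:
    """NJ tree with bootstrap support from supermatrix column resampling.

    Support for each bipartition of the point-estimate tree is the percent
    of successful replicates containing it; replicates whose distance matrix
    is undefined (saturation) are skipped with a log entry.
    """
    if replicates < 1:
        raise MitocompError("replicates must be >= 1")
    point = nj_tree(k2p_distance_matrix(sm)).tree
    cols = sm.column_array()
    if all(len(set(cols[:, j])) == 1 for j in range(cols.shape[1])):
        logger.warning("alignment has no variable columns; supports are 0")
    rng = np.random.default_rng(seed)
    target = bipartitions(point)
    hits = {bp: 0 for bp in target}
    done = 0
    n_cols = cols.shape[1]
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        res = cols[:, idx]
        rep_sm = Supermatrix(
            taxa=sm.taxa,
            rows={t: "".join(res[i]) for i, t in enumerate(sm.taxa)},
            partitions=[("all", 1, n_cols)],
        )
        try:
            rep_tree = nj_tree(k2p_distance_matrix(rep_sm)).tree
        except MitocompError as exc:
            logger.info("bootstrap replicate skipped: %s", exc)
            continue
        done += 1
        rep_bps = bipartitions(rep_tree)
        for bp in target & rep_bps:
            hits[bp] += 1
    supports = {bp: (100.0 * h / done if done else 0.0) for bp, h in hits.items()}
    # annotate internal nodes of the point tree
    all_tips = frozenset(t.name for t in point.tips())
    ref = min(all_tips)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = side if ref not in side else all_tips - side
        if key in supports:
            node.name = str(int(round(supports[key])))
    return TreeWithSupport(tree=point, supports=supports)


def root_with_outgroup(tws: TreeWithSupport, outgroup: str) -> TreeWithSupport:
    """Root the reported tree on the branch leading to *outgroup* (display
    only; falls back to the unrooted tree if re-rooting fails)."""
    try:
        node = tws.tree.find(outgroup)
        rooted = tws.tree.root_at(node.parent)
        return TreeWithSupport(tree=rooted, supports=tws.supports)
    except Exception as exc:  # skbio rooting API varies between versions
        logger.warning("could not root at %s: %s", outgroup, exc)
        return tws


# --------------------------------------------------------------------------
# writers for external tools
# --------------------------------------------------------------------------


def write_fasta_alignment(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n{sm.rows[t]}\n")


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def write_nexus(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t in sm.taxa:
            fh.write(f"    {t}  {sm.rows[t]}\n")
        fh.write("  ;\nEND;\n")
        fh.write("BEGIN SETS;\n")
        for gene, start, end in sm.partitions:
            fh.write(f"  CHARSET {gene} = {start}-{end};\n")
        fh.write("END;\n")


def write_partitions(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file."""
    with open(path, "w") as fh:
        for gene, start, end in sm.partitions:
            fh.write(f"DNA, {gene} = {start}-{end}\n")


def write_newick(tws: TreeWithSupport, path: str | Path) -> None:
    Path(path).write_text(tws.newick + "\n")
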