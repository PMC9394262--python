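"""Intron position classes (Pcls): projection, matrix, gain/loss inference.

An intron's insertion site in its host gene is projected through a global
alignment onto the homologous reference gene; introns from different genomes
landing on the same reference coordinate form one position class (named
"P<position>", the 1-based count of reference coding nucleotides 5' of the
intron).  Orthology is thus read off alignment coordinates, and presence/
absence of each Pcl across genomes supports parsimony reconstruction of
gain and loss events on a phylogeny.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from skbio import TreeNode

from .errors import HomologyError, LookupFailure, MitocompError
from .io_annotation import CORE_PCGS, MitogenomeRecord, RRNA_GENES, extract_coding_exons

logger = logging.getLogger(__name__)

#: identity floor below which a projection is refused (paralog guard)
MIN_PROJECTION_IDENTITY = 50.0


@dataclass(frozen=True)
class PclAssignment:
    genome: str
    gene: str
    host_offset: int  # 1-based coding position in the host gene
    reference_position: int  # 1-based coding position in the reference gene
    pcl_name: str


@dataclass
class PclMatrix:
    """Genomes x position-classes presence/absence table.

    ``table`` has genome rows and a (gene, pcl) MultiIndex on columns,
    ordered by gene then numeric position.
    """

    table: pd.DataFrame
    assignments: list[PclAssignment]

    def row_sums(self) -> pd.Series:
        return self.table.sum(axis=1)


def _projection_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(mode="global", match_score=2, mismatch_score=-1,
                                 open_gap_score=-10, extend_gap_score=-0.5)


def project_insertion_site(host_exonic_cds: str, reference_cds: str,
                           host_offset: int) -> int:
    """Map a host coding position onto the reference gene through a global
    alignment.

    ``host_offset`` is the 1-based count of host coding nucleotides 5' of the
    intron.  If the mapped column is a reference gap, the nearest
    reference-aligned column to the left is used.  Identity below 50% refuses
    the projection (HomologyError).
    """
    if not 1 <= host_offset <= len(host_exonic_cds):
        raise MitocompError(
            f"host offset {host_offset} outside [1, {len(host_exonic_cds)}]"
        )
    aln = _projection_aligner().align(host_exonic_cds.upper(),
                                      reference_cds.upper())[0]
    blocks = list(zip(*aln.aligned))  # ((hs, he), (rs, re)) ungapped blocks
    matches = sum(
        1
        for (hs, he), (rs, re) in blocks
        for k in range(he - hs)
        if host_exonic_cds[hs + k].upper() == reference_cds[rs + k].upper()
    )
    aligned_cols = sum(he - hs for (hs, he), _ in blocks)
    identity = 100.0 * matches / max(aligned_cols, 1)
    if identity < MIN_PROJECTION_IDENTITY:
        raise HomologyError(
            f"alignment identity {identity:.1f}% below "
            f"{MIN_PROJECTION_IDENTITY}%: projection refused"
        )
    i = host_offset - 1  # 0-based index of the last host nt before the intron
    ref_before = 0
    for (hs, he), (rs, re) in blocks:
        if i < hs:
            # host position sits in a host-only insertion before this block:
            # nearest reference column to the left
            return ref_before
        if i < he:
            return rs + (i - hs) + 1
        ref_before = re
    return ref_before


def assign_pcls(records: list[MitogenomeRecord], reference: MitogenomeRecord,
                include_rrna: bool = True,
                position_tolerance: int = 0) -> PclMatrix:
    """Assign every core-PCG (and optionally rRNA) intron of every genome to
    a position class against the reference genome.

    ``position_tolerance`` optionally merges classes within +/- that many nt
    of one another (off by default: Pcl names are exact integers).
    """
    genes = sorted(CORE_PCGS) + (list(RRNA_GENES) if include_rrna else [])
    assignments: list[PclAssignment] = []
    for rec in records:
        for gene in genes:
            if not rec.has_gene(gene):
                continue
            spliced = extract_coding_exons(rec, gene)
            if not spliced.introns:
                continue
            try:
                ref_cds = extract_coding_exons(reference, gene).cds
            except LookupFailure:
                logger.warning("gene %s absent from reference %s; skipped",
                               gene, reference.id)
                continue
            for site in spliced.introns:
                try:
                    ref_pos = project_insertion_site(spliced.cds, ref_cds,
                                                     site.insert_offset)
                except HomologyError as exc:
                    logger.warning("%s %s intron at %d: %s", rec.id, gene,
                                   site.insert_offset, exc)
                    continue
                assignments.append(PclAssignment(
                    genome=rec.id, gene=gene, host_offset=site.insert_offset,
                    reference_position=ref_pos, pcl_name=f"P{ref_pos}",
                ))
    if position_tolerance > 0:
        assignments = _merge_nearby(assignments, position_tolerance)
    genomes = [r.id for r in records]
    cols = sorted({(a.gene, a.reference_position) for a in assignments})
    if cols:
        index = pd.MultiIndex.from_tuples(
            [(g, f"P{p}") for g, p in cols], names=["gene", "pcl"]
        )
    else:
        index = pd.MultiIndex.from_arrays([[], []], names=["gene", "pcl"])
    table = pd.DataFrame(False, index=pd.Index(genomes, name="genome"),
                         columns=index)
    for a in assignments:
        table.loc[a.genome, (a.gene, a.pcl_name)] = True
    return PclMatrix(table=table, assignments=assignments)


def _merge_nearby(assignments: list[PclAssignment],
                  tol: int) -> list[PclAssignment]:
    """Snap reference positions within *tol* nt to the smallest member of
    their cluster (per gene)."""
    out = []
    by_gene: dict[str, list[int]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene, []).append(a.reference_position)
    canon: dict[tuple[str, int], int] = {}
    for gene, positions in by_gene.items():
        positions = sorted(set(positions))
        cluster_head = positions[0]
        for p in positions:
            if p - cluster_head > tol:
                cluster_head = p
            canon[(gene, p)] = cluster_head
    for a in assignments:
        p = canon[(a.gene, a.reference_position)]
        out.append(PclAssignment(a.genome, a.gene, a.host_offset, p, f"P{p}"))
    return out


# --------------------------------------------------------------------------
# gain/loss inference
# --------------------------------------------------------------------------


@dataclass
class GainLossEvents:
    """Per-Pcl parsimony events; branches are named by the child node (tips)
    or by the sorted tip set of the child clade (internal branches)."""

    events: dict[tuple[str, str], list[tuple[str, str]]]  # (gene, pcl) -> [(branch, event)]
    total_gains: int
    total_losses: int


def _branch_label(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return "{" + ",".join(sorted(t.name for t in node.tips())) + "}"


def _dollo_events(tree: TreeNode, present: set[str]) -> list[tuple[str, str]]:
    if not present:
        return []
    if len(present) == len(list(tree.tips())):
        mrca = tree
    elif len(present) == 1:
        mrca = tree.find(next(iter(present)))
    else:
        mrca = tree.lca([tree.find(n) for n in present])
    events = [(_branch_label(mrca), "gain")]

    def walk(node: TreeNode) -> None:
        for child in node.children:
            tips = {t.name for t in child.tips()} if not child.is_tip() else {child.name}
            if tips & present:
                walk(child)
            else:
                events.append((_branch_label(child), "loss"))

    walk(mrca)
    return events


def _fitch_events(tree: TreeNode, present: set[str]) -> list[tuple[str, str]]:
    if not present:
        return []
    # bottom-up state sets
    sets: dict[int, frozenset[int]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            sets[id(node)] = frozenset({1 if node.name in present else 0})
        else:
            inter = None
            union = frozenset()
            for c in node.children:
                s = sets[id(c)]
                inter = s if inter is None else inter & s
                union |= s
            sets[id(node)] = inter if inter else union
    # top-down: prefer the parent state; at the root prefer absence so the
    # first event along any path is a gain at the shallowest eligible branch
    events: list[tuple[str, str]] = []
    state: dict[int, int] = {}
    for node in tree.preorder(include_self=True):
        s = sets[id(node)]
        if node.is_root():
            state[id(node)] = 0 if 0 in s else 1
            if state[id(node)] == 1:
                events.append((_branch_label(node), "gain"))
        else:
            ps = state[id(node.parent)]
            mine = ps if ps in s else next(iter(sorted(s)))
            state[id(node)] = mine
            if mine != ps:
                events.append((_branch_label(node), "gain" if mine else "loss"))
    return events


def infer_gain_loss(matrix: PclMatrix, tree: str | TreeNode,
                    criterion: str = "dollo") -> GainLossEvents:
    """Most-parsimonious gain/loss reconstruction for every Pcl.

    ``dollo``: a single gain at the stem of the minimal clade containing all
    carriers, plus the minimal set of losses.  ``fitch``: unordered binary
    parsimony with deterministic tie-breaking (parent state preferred;
    absence preferred at the root).
    """
    if criterion not in ("dollo", "fitch"):
        raise MitocompError(f"unknown criterion {criterion!r}")
    if isinstance(tree, str):
        tree = TreeNode.read(_io.StringIO(tree), convert_underscores=False)
    leaf_names = {t.name for t in tree.tips()}
    missing = set(matrix.table.index) - leaf_names
    if missing:
        raise MitocompError(f"tree lacks taxa: {sorted(missing)}")
    events: dict[tuple[str, str], list[tuple[str, str]]] = {}
    gains = losses = 0
    for gene, pcl in matrix.table.columns:
        present = set(matrix.table.index[matrix.table[(gene, pcl)]])
        ev = (_dollo_events if criterion == "dollo" else _fitch_events)(tree, present)
        events[(gene, pcl)] = ev
        gains += sum(1 for _, e in ev if e == "gain")
        losses += sum(1 for _, e in ev if e == "loss")
    return GainLossEvents(events=events, total_gains=gains, total_losses=losses)


def leaf_states_from_events(tree: str | TreeNode,
                            ev: list[tuple[str, str]]) -> set[str]:
    """Replay gain/loss events down the tree; returns the set of leaves
    carrying the character (used to verify reconstructions)."""
    if isinstance(tree, str):
        tree = TreeNode.read(_io.StringIO(tree), convert_underscores=False)
    by_branch = dict(ev)
    present: set[str] = set()

    def walk(node: TreeNode, state: int) -> None:
        label = _branch_label(node)
        if label in by_branch:
            state = 1 if by_branch[label] == "gain" else 0
        if node.is_tip():
            if state:
                present.add(node.name)
        else:
            for c in node.children:
                walk(c, state)

    walk(tree, 0)
    return present


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def intron_summary(records: list[MitogenomeRecord],
                   matrix: PclMatrix | None = None,
                   common_threshold: float = 0.75) -> dict:
    """Per-gene and per-genome intron counts plus common/rare Pcl lists.

    A Pcl is "common" when present in more than ``common_threshold`` of the
    genomes and "rare" when found in exactly one.
    """
    per_genome: dict[str, int] = {}
    per_gene: dict[str, int] = {}
    for rec in records:
        count = 0
        for f in rec.features:
            if f.kind in ("core_pcg", "orf", "rRNA"):
                count += f.n_implied_introns
                per_gene[f.name] = per_gene.get(f.name, 0) + f.n_implied_introns
        per_genome[rec.id] = count
    out = {
        "per_genome": per_genome,
        "per_gene": {g: c for g, c in sorted(per_gene.items()) if c > 0},
        "host_ranking": sorted(per_gene, key=lambda g: (-per_gene[g], g)),
    }
    if matrix is not None and len(matrix.table.columns):
        n = len(matrix.table)
        counts = matrix.table.sum(axis=0)
        out["common_pcls"] = [f"{g}:{p}" for (g, p), c in counts.items()
                              if c > common_threshold * n]
        out["rare_pcls"] = [f"{g}:{p}" for (g, p), c in counts.items() if c == 1]
    else:
        out["common_pcls"] = []
        out["rare_pcls"] = []
    return out
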