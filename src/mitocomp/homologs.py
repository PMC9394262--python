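"""Clustering of free-standing non-conserved ORFs by protein similarity.

Homologs across genomes (e.g. length variants of the same RNA-polymerase
ORF) are grouped by single-linkage over all-vs-all global protein alignment,
producing a presence/absence table of ORF families.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import MitocompError
from .compstats import amino_acid
from .io_annotation import GeneFeature, MitogenomeRecord, splice

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrfCluster:
    label: str  # "orf<median protein length>", suffixed on collision
    members: tuple[tuple[str, str, int], ...]  # (genome, feature name, protein length)
    function_note: str  # majority product text


def translate_orf(feature: GeneFeature, record: MitogenomeRecord) -> str:
    """Translate an ORF under genetic code 4 (TGA = Trp), trailing stop
    removed.  An internal stop codon is an error."""
    if feature.kind not in ("orf", "intron_orf"):
        raise MitocompError(f"{feature.name}: not an ORF feature")
    cds = splice(record, feature).upper()
    if len(cds) % 3:
        raise MitocompError(f"{feature.name}: length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        aa = amino_acid(cds[i:i + 3])
        if aa == "*":
            if i == len(cds) - 3:
                break
            raise MitocompError(
                f"{feature.name}: internal stop at codon {i // 3 + 1}"
            )
        aas.append(aa)
    return "".join(aas)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global", open_gap_score=-11, extend_gap_score=-1)
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return a


def _identity_coverage(pa: str, pb: str,
                       aligner: Align.PairwiseAligner) -> tuple[float, float, float]:
    """(identity %, coverage of a %, coverage of b %) from a global alignment;
    identity is over mutually aligned columns."""
    aln = aligner.align(pa, pb)[0]
    matches = cols = 0
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        for k in range(ae - as_):
            cols += 1
            if pa[as_ + k] == pb[bs + k]:
                matches += 1
    if cols == 0:
        return 0.0, 0.0, 0.0
    return (100.0 * matches / cols, 100.0 * cols / len(pa), 100.0 * cols / len(pb))


def cluster_orfs(records: list[MitogenomeRecord], min_identity: float = 60.0,
                 min_coverage: float = 70.0
                 ) -> tuple[list[OrfCluster], pd.DataFrame]:
    """Single-linkage clusters of free-standing ORFs plus the genomes x
    clusters presence/absence matrix.

    Two ORFs link when global protein identity >= *min_identity* and the
    aligned region covers >= *min_coverage* % of both proteins.  Clustering
    is order-independent: ORFs are canonically sorted before linkage.
    """
    entries: list[tuple[str, str, str, str]] = []  # (genome, name, protein, product)
    for rec in records:
        for f in rec.features_of_kind("orf"):
            try:
                prot = translate_orf(f, rec)
            except MitocompError as exc:
                logger.warning("%s/%s skipped: %s", rec.id, f.name, exc)
                continue
            entries.append((rec.id, f.name, prot, f.product))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    n = len(entries)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aligner = _aligner()
    for i in range(n):
        for j in range(i + 1, n):
            ident, cov_a, cov_b = _identity_coverage(entries[i][2], entries[j][2],
                                                     aligner)
            if ident >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters: list[OrfCluster] = []
    used_labels: dict[str, int] = {}
    for root in sorted(groups, key=lambda r: min(groups[r])):
        idx = groups[root]
        lengths = [len(entries[i][2]) for i in idx]
        label = f"orf{round(statistics.median(lengths))}"
        if label in used_labels:
            used_labels[label] += 1
            label = f"{label}{chr(ord('a') + used_labels[label] - 1)}"
        else:
            used_labels[label] = 1
        products = [entries[i][3] for i in idx if entries[i][3]]
        note = statistics.mode(products) if products else ""
        clusters.append(OrfCluster(
            label=label,
            members=tuple((entries[i][0], entries[i][1], len(entries[i][2]))
                          for i in idx),
            function_note=note,
        ))

    genomes = [r.id for r in records]
    matrix = pd.DataFrame(False, index=pd.Index(genomes, name="genome"),
                          columns=[c.label for c in clusters])
    for c in clusters:
        for genome, _, _ in c.members:
            matrix.loc[genome, c.label] = True
    return clusters, matrix
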