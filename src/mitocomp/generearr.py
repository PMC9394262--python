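"""Circular gene-order extraction, breakpoint distance and arrangement groups.

Arrangements cover the 15 core protein-coding genes plus the two rRNAs
(tRNAs excluded).  Orders are canonicalized to start at cox1 following its
annotated transcription sense; comparison is orientation-agnostic and
treats full reversal as identity (a circular chromosome carries no intrinsic
direction without strand information).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ArrangementError
from .io_annotation import MitogenomeRecord
from .syndata import ARRANGEMENT_GENES


@dataclass(frozen=True)
class GeneOrder:
    genome: str
    order: tuple[str, ...]  # circular, first element cox1

    def canonical_key(self) -> tuple[str, ...]:
        """Reflection-invariant key: the lexicographically smaller of the
        order and its reversal (both rotated to cox1)."""
        rev = _rotate_to(self.order[::-1], "cox1")
        return min(self.order, rev)


def _rotate_to(order: tuple[str, ...], first: str) -> tuple[str, ...]:
    i = order.index(first)
    return order[i:] + order[:i]


def extract_gene_order(record: MitogenomeRecord) -> GeneOrder:
    """Canonical circular order of the 17 arrangement genes.

    Genes are sorted by the genomic start of their first transcribed segment
    and rotated so cox1 comes first; if cox1 is annotated on the minus
    strand the circle is walked in cox1's transcription sense (i.e.
    reversed).  Missing or duplicated genes raise ArrangementError.
    """
    feats = [f for f in record.features
             if f.kind in ("core_pcg", "rRNA") and f.name in ARRANGEMENT_GENES]
    names = [f.name for f in feats]
    missing = sorted(set(ARRANGEMENT_GENES) - set(names))
    dupes = sorted({n for n in names if names.count(n) > 1})
    if missing or dupes:
        raise ArrangementError(
            f"{record.id}: cannot extract arrangement"
            + (f"; missing {missing}" if missing else "")
            + (f"; duplicated {dupes}" if dupes else "")
        )
    feats.sort(key=lambda f: min(s for s, _ in f.segments))
    order = tuple(f.name for f in feats)
    cox1 = next(f for f in feats if f.name == "cox1")
    if cox1.strand == "-":
        order = order[::-1]
    return GeneOrder(genome=record.id, order=_rotate_to(order, "cox1"))


def _adjacencies(order: tuple[str, ...]) -> set[frozenset[str]]:
    n = len(order)
    return {frozenset((order[i], order[(i + 1) % n])) for i in range(n)}


def compare_orders(a: GeneOrder, b: GeneOrder) -> tuple[bool, int]:
    """(identical, breakpoint_distance).

    Breakpoint distance = number of circular adjacencies of *a* absent from
    *b* (orientation-agnostic); 0 iff the arrangements are identical up to
    rotation and reflection.
    """
    if sorted(a.order) != sorted(b.order):
        raise ArrangementError(
            f"label sets differ: {a.genome} vs {b.genome}"
        )
    shared = _adjacencies(a.order) & _adjacencies(b.order)
    distance = len(a.order) - len(shared)
    return distance == 0, distance


def group_by_arrangement(orders: list[GeneOrder]) -> dict[str, list[str]]:
    """Partition genomes into clusters of identical arrangements.

    Cluster labels are the lexicographically smallest member genome id.
    """
    if not orders:
        raise ArrangementError("no gene orders supplied")
    by_key: dict[tuple[str, ...], list[str]] = {}
    for o in orders:
        by_key.setdefault(o.canonical_key(), []).append(o.genome)
    return {min(members): sorted(members) for members in by_key.values()}


def distance_matrix(orders: list[GeneOrder]) -> pd.DataFrame:
    ids = [o.order for o in orders]
    names = [o.genome for o in orders]
    data = [[compare_orders(a, b)[1] for b in orders] for a in orders]
    return pd.DataFrame(data, index=names, columns=names)
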