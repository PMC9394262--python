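"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive and slow: exact rational arithmetic
for NG86, direct adjacency scanning for breakpoint distance, literal path
summation for additive matrices.  None of it calls into the implementation
paths it checks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
from skbio import DistanceMatrix, TreeNode

from mitocomp.compstats import amino_acid

BASES = "ACGT"


# --------------------------------------------------------------------------
# NG86 (code 4)
# --------------------------------------------------------------------------


def oracle_sites(codon):
    syn = Fraction(0)
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if amino_acid(mut) != "*" and amino_acid(mut) == amino_acid(codon):
                syn += Fraction(1, 3)
    return syn, 3 - syn


def oracle_diffs(c1, c2):
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return Fraction(0), Fraction(0)
    outcomes = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, blocked = c1, Fraction(0), Fraction(0), False
        for step_index, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if amino_acid(nxt) == "*" and step_index < len(order) - 1:
                blocked = True
            if amino_acid(cur) == amino_acid(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        outcomes.append((blocked, sd, nd))
    usable = [(s, n) for b, s, n in outcomes if not b] or \
        [(s, n) for _, s, n in outcomes]
    k = len(usable)
    return (sum(s for s, _ in usable) / k, sum(n for _, n in usable) / k)


def oracle_ka_ks(a, b):
    ca = [a[i:i + 3] for i in range(0, len(a), 3)]
    cb = [b[i:i + 3] for i in range(0, len(b), 3)]
    S = N = Sd = Nd = Fraction(0)
    for c1, c2 in zip(ca, cb):
        s1, n1 = oracle_sites(c1)
        s2, n2 = oracle_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = oracle_diffs(c1, c2)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N

    def jc(p):
        return -0.75 * math.log(1 - 4 * float(p) / 3)

    return (jc(pn) if pn else 0.0), (jc(ps) if ps else 0.0)


def random_codon_pair(rng, n_codons):
    """Two stop-free coding sequences differing at ~8% of sites."""
    non_stop = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
                if amino_acid(c) != "*"]
    a = "".join(rng.choice(non_stop) for _ in range(n_codons))
    b = list(a)
    for i in range(len(b)):
        if rng.random() < 0.08:
            b[i] = rng.choice(list(BASES))
    b = "".join(b)
    fixed = [b[i:i + 3] if amino_acid(b[i:i + 3]) != "*" else a[i:i + 3]
             for i in range(0, len(b), 3)]
    return a, "".join(fixed)


# --------------------------------------------------------------------------
# indel-divergent gene pairs with a known coordinate mapping
# --------------------------------------------------------------------------


def indel_projection_case(rng, ref_len=900, sub_rate=0.05, indel_rate=0.05):
    """(host, ref, host_position, ref_position) for one simulated gene pair.

    The host differs from the reference by per-site substitutions plus
    whole-codon insertions/deletions; the true mapping of the sampled
    reference position onto the host is tracked through the edit history.
    """
    ref = "".join(rng.choice(list(BASES), size=ref_len))
    host_sub = list(ref)
    for i in range(ref_len):
        if rng.random() < sub_rate:
            host_sub[i] = rng.choice([b for b in BASES if b != ref[i]])
    n_codons = ref_len // 3
    host_codons: list[str] = []
    ref_of_host: list[int | None] = []
    for c in range(n_codons):
        codon = "".join(host_sub[3 * c: 3 * c + 3])
        u = rng.random()
        if u < indel_rate / 2:  # deletion
            continue
        host_codons.append(codon)
        ref_of_host.append(c)
        if indel_rate / 2 <= u < indel_rate:  # insertion after this codon
            host_codons.append("".join(rng.choice(list(BASES), size=3)))
            ref_of_host.append(None)
    surviving = [c for c in ref_of_host if c is not None]
    ref_codon = int(rng.choice(surviving[1:-1]))
    within = int(rng.integers(0, 3))
    ref_position = 3 * ref_codon + within + 1
    host_codon_index = ref_of_host.index(ref_codon)
    host_position = 3 * host_codon_index + within + 1
    return "".join(host_codons), ref, host_position, ref_position


# --------------------------------------------------------------------------
# circular breakpoint distance
# --------------------------------------------------------------------------


def oracle_breakpoints(a, b):
    """Adjacencies of circular order *a* absent from *b* (either direction)."""
    n = len(a)
    b_adj = set()
    for i in range(n):
        x, y = b[i], b[(i + 1) % n]
        b_adj.add((x, y))
        b_adj.add((y, x))
    return sum(1 for i in range(n) if (a[i], a[(i + 1) % n]) not in b_adj)


# --------------------------------------------------------------------------
# additive matrices
# --------------------------------------------------------------------------


def random_additive(rng, n_taxa):
    """Random binary tree with positive branch lengths plus its exact
    leaf-to-leaf path-length matrix."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=n, length=round(float(rng.uniform(0.05, 1.0)), 4))
             for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]],
                          length=round(float(rng.uniform(0.05, 1.0)), 4))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=nodes)
    dm = np.zeros((n_taxa, n_taxa))
    tips = {t.name: t for t in root.tips()}
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            d = tips[names[x]].distance(tips[names[y]])
            dm[x, y] = dm[y, x] = d
    return root, DistanceMatrix(dm, ids=names)
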