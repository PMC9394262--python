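"""Synthetic annotated mitogenomes with planted, machine-readable ground truth.

Every downstream stage of the toolkit is exercised against cohorts built
here: circular genomes with the 15 core protein-coding genes, 2 rRNAs and 26
tRNAs, group-I/II-style introns planted at exact coding positions (optionally
carrying a homing-endonuclease ORF), free-standing ORF families, dispersed
and tandem repeats, configurable GC content and per-genome gene orders.

All sequence blocks are ancestral and evolve along a tree by a per-site
Kimura two-parameter substitution process, so pairwise distances have known
expectations and a cohort simulated at divergence 0 is a set of identical
genomes.  A single seed drives every draw; the same spec and seed reproduce
byte-identical output.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import SimSpecError
from .io_annotation import (
    CORE_PCGS,
    GeneFeature,
    MitogenomeRecord,
    RRNA_GENES,
    revcomp,
    write_genbank,
    write_gff3_fasta,
)

# --------------------------------------------------------------------------
# study-scale constants
# --------------------------------------------------------------------------

#: Default coding/gene lengths (nt); protein genes include the stop codon.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "cox1": 1593, "cox2": 750, "cox3": 810, "cob": 1182,
    "nad1": 960, "nad2": 1680, "nad3": 414, "nad4": 1470, "nad4L": 270,
    "nad5": 2010, "nad6": 630, "atp6": 768, "atp8": 147, "atp9": 225,
    "rps3": 1290, "rnl": 3000, "rns": 1500,
}

TRNA_NAMES: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG1", "trnG2", "trnH",
    "trnI1", "trnI2", "trnK", "trnL1", "trnL2", "trnM1", "trnM2", "trnN",
    "trnP", "trnQ", "trnR1", "trnR2", "trnS1", "trnS2", "trnT", "trnV",
    "trnW", "trnY",
)

#: The two circular arrangements of 15 core PCGs + 2 rRNAs observed in
#: *Ganoderma*: one shared by six mitogenomes, the other by four.
ARRANGEMENT_1: tuple[str, ...] = (
    "cox1", "nad4", "atp6", "rnl", "cox3", "nad4L", "rps3", "nad2", "nad5",
    "rns", "nad6", "atp9", "nad1", "cob", "cox2", "atp8", "nad3",
)
ARRANGEMENT_2: tuple[str, ...] = (
    "cox1", "nad4", "atp6", "rnl", "cox3", "nad4L", "nad5", "rns", "cox2",
    "rps3", "nad6", "atp8", "nad2", "nad3", "atp9", "nad1", "cob",
)

ARRANGEMENT_GENES: tuple[str, ...] = tuple(sorted(CORE_PCGS)) + RRNA_GENES

_STOPS = {"TAA", "TAG"}  # genetic code 4: TGA encodes Trp, not stop
_TRNA_LEN = 72

# base order A, G, C, T: transition partner is index ^ 1
_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"AGCT"):
    _BASE_INDEX[_b] = _i


# --------------------------------------------------------------------------
# K2P substitution process
# --------------------------------------------------------------------------


def _k2p_probs(rate: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Expected transition (P) and per-target transversion probability after
    evolving for *rate* expected substitutions per site."""
    R = ts_tv_ratio
    beta = 1.0 / (2.0 * (R + 1.0))
    alpha = R / (R + 1.0)  # alpha + 2 beta = 1: rate == expected subs/site
    t = rate
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta * t) - 0.5 * np.exp(-2 * (alpha + beta) * t)
    q_each = 0.25 - 0.25 * np.exp(-4 * beta * t)
    return float(p_ts), float(q_each)


def _mutate_arr(arr: np.ndarray, rate: float, rng: np.random.Generator,
                ts_tv_ratio: float) -> np.ndarray:
    if rate == 0:
        return arr.copy()
    idx = _BASE_INDEX[arr]
    valid = idx != 255  # leave N and friends untouched
    p_ts, q_each = _k2p_probs(rate, ts_tv_ratio)
    u = rng.random(arr.size)
    out = idx.copy()
    ts = valid & (u < p_ts)
    tv1 = valid & (u >= p_ts) & (u < p_ts + q_each)
    tv2 = valid & (u >= p_ts + q_each) & (u < p_ts + 2 * q_each)
    out[ts] ^= 1
    out[tv1] ^= 2
    out[tv2] ^= 3
    res = arr.copy()
    res[valid] = _BASES[out[valid]]
    return res


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def mutate_sequence(seq: str, rate: float, seed: int | np.random.Generator,
                    ts_tv_ratio: float = 2.0) -> str:
    """Evolve *seq* for *rate* expected substitutions per site under a K2P
    process with the given expected transition/transversion ratio.

    Multiple hits are modelled, so for small rates the proportion of changed
    sites is close to *rate* and the K2P distance estimator recovers it.
    """
    if not 0 <= rate < 0.75:
        raise SimSpecError(f"substitution rate {rate} outside [0, 0.75)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _to_str(_mutate_arr(_to_arr(seq), rate, rng, ts_tv_ratio))


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator,
                ts_tv_ratio: float) -> str:
    """Mutate a protein-coding sequence, pinning the start and stop codons and
    reverting any internal codon that a substitution turned into a stop."""
    if rate == 0:
        return cds
    arr = _mutate_arr(_to_arr(cds), rate, rng, ts_tv_ratio)
    out = _to_str(arr)
    codons = [out[i:i + 3] for i in range(0, len(out), 3)]
    parent = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    codons[0] = parent[0]
    codons[-1] = parent[-1]
    for i in range(1, len(codons) - 1):
        if codons[i] in _STOPS:
            codons[i] = parent[i]
    return "".join(codons)


# --------------------------------------------------------------------------
# random sequence construction
# --------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _to_str(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, length_nt: int, gc: float,
                start: str = "ATG", stop: str = "TAA") -> str:
    if length_nt % 3:
        raise SimSpecError(f"coding length {length_nt} not a multiple of 3")
    n_codons = length_nt // 3 - 2
    codons = []
    while len(codons) < n_codons:
        block = _random_seq(rng, 3 * (n_codons - len(codons) + 8), gc)
        for i in range(0, len(block) - 2, 3):
            c = block[i:i + 3]
            if c not in _STOPS:
                codons.append(c)
            if len(codons) == n_codons:
                break
    return start + "".join(codons) + stop


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IntronPlant:
    """Plant one intron in *genome*'s *gene* after ancestral coding position
    *position* (1-based nt count 5' of the intron)."""

    genome: str
    gene: str
    position: int
    length: int = 1500
    with_orf: bool = False


@dataclass(frozen=True)
class RepeatPlant:
    genome: str
    length: int = 100
    copies: int = 2
    tandem: bool = False
    orientation: str = "direct"  # or "inverted" (second copy reverse-complemented)
    label: str = ""


@dataclass(frozen=True)
class OrfPlant:
    """A free-standing ORF family shared (as homologs) by several genomes."""

    family: str
    genomes: tuple[str, ...]
    length_codons: int = 150
    product: str = "hypothetical protein"


@dataclass(frozen=True)
class SynthSpec:
    n_genomes: int = 3
    genome_ids: tuple[str, ...] | None = None
    genome_length_target: int = 50_000
    gc_target: float = 0.26
    divergence: float = 0.05
    ts_tv_ratio: float = 2.0
    tree: str | None = None
    gene_order: str | Mapping[str, Sequence[str]] = "shared"
    intron_plants: tuple[IntronPlant, ...] = ()
    repeat_plants: tuple[RepeatPlant, ...] = ()
    orf_plants: tuple[OrfPlant, ...] = ()
    indel_rate: float = 0.0  # per-codon whole-codon indel probability at each tip
    gene_rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    cob_gtg_start: bool = True
    minus_strand_genes: tuple[str, ...] = ()
    gene_lengths: Mapping[str, int] = field(default_factory=dict)
    reference_genome: str | None = None
    seed: int = 0

    def ids(self) -> tuple[str, ...]:
        if self.genome_ids is not None:
            return tuple(self.genome_ids)
        return tuple(f"G{i + 1:02d}" for i in range(self.n_genomes))

    def lengths(self) -> dict[str, int]:
        d = dict(DEFAULT_GENE_LENGTHS)
        d.update(self.gene_lengths)
        return d

    def order_for(self, genome: str) -> tuple[str, ...]:
        if isinstance(self.gene_order, str):
            return ARRANGEMENT_1
        return tuple(self.gene_order[genome])

    def validate(self) -> None:
        ids = self.ids()
        if len(set(ids)) != len(ids):
            raise SimSpecError("duplicate genome ids")
        lens = self.lengths()
        seen = set()
        for p in self.intron_plants:
            if p.genome not in ids:
                raise SimSpecError(f"intron plant names unknown genome {p.genome!r}")
            if p.gene not in lens:
                raise SimSpecError(f"intron plant names unknown gene {p.gene!r}")
            if not 1 <= p.position < lens[p.gene]:
                raise SimSpecError(
                    f"intron position {p.position} outside coding region of "
                    f"{p.gene} (length {lens[p.gene]})"
                )
            key = (p.genome, p.gene, p.position)
            if key in seen:
                raise SimSpecError(f"duplicate intron plant at {key}")
            seen.add(key)
            if p.with_orf and p.length < 300:
                raise SimSpecError(
                    f"intron at {key} too short ({p.length} nt) to embed an ORF"
                )
        for g in ids:
            order = self.order_for(g)
            if sorted(order) != sorted(ARRANGEMENT_GENES):
                raise SimSpecError(f"gene order for {g} is not a 17-gene permutation")


@dataclass
class SynthTruth:
    """Planted ground truth emitted beside a synthetic cohort."""

    introns: "pd.DataFrame"
    repeats: "pd.DataFrame"
    gene_orders: dict[str, tuple[str, ...]]
    tree_newick: str
    tip_depths: dict[str, float]
    pair_distances: dict[tuple[str, str], float]
    orf_members: "pd.DataFrame"

    def expected_gene_distance(self, a: str, b: str, gene: str,
                               multipliers: Mapping[str, float] | None = None) -> float:
        m = (multipliers or {}).get(gene, 1.0)
        key = (a, b) if (a, b) in self.pair_distances else (b, a)
        return self.pair_distances[key] * m

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.introns.to_csv(outdir / "truth_introns.tsv", sep="\t", index=False)
        self.repeats.to_csv(outdir / "truth_repeats.tsv", sep="\t", index=False)
        self.orf_members.to_csv(outdir / "truth_orfs.tsv", sep="\t", index=False)
        import json

        meta = {
            "gene_orders": {g: list(o) for g, o in self.gene_orders.items()},
            "tree": self.tree_newick,
            "tip_depths": self.tip_depths,
        }
        (outdir / "truth.json").write_text(json.dumps(meta, indent=1))


# --------------------------------------------------------------------------
# tree handling
# --------------------------------------------------------------------------


def _tree_for(spec: SynthSpec) -> TreeNode:
    ids = spec.ids()
    if spec.tree is None:
        nwk = "(" + ",".join(f"{g}:{spec.divergence}" for g in ids) + ");"
    else:
        nwk = spec.tree
    tree = TreeNode.read(_io.StringIO(nwk), convert_underscores=False)
    leaves = {t.name for t in tree.tips()}
    if leaves != set(ids):
        raise SimSpecError(
            f"tree leaves {sorted(leaves)} do not match genome ids {sorted(ids)}"
        )
    return tree


def _branch_rate(node: TreeNode, spec: SynthSpec) -> float:
    return spec.divergence if node.length is None else float(node.length)


def _evolve_blocks(tree: TreeNode, ancestral: dict[str, str],
                   coding: set[str], rng: np.random.Generator,
                   spec: SynthSpec) -> dict[str, dict[str, str]]:
    """Evolve every ancestral block down the tree; returns {leaf: {block: seq}}.

    Protein-coding blocks keep frame and never acquire internal stops;
    per-gene rate multipliers scale the branch rate of that gene only.
    """
    mult = dict(spec.gene_rate_multipliers)
    keys = sorted(ancestral)
    state: dict[int, dict[str, str]] = {id(tree): dict(ancestral)}
    out: dict[str, dict[str, str]] = {}
    for node in tree.preorder(include_self=True):
        if node.is_root():
            pass
        else:
            parent_seqs = state[id(node.parent)]
            rate0 = _branch_rate(node, spec)
            seqs = {}
            for k in keys:
                rate = min(rate0 * mult.get(k, 1.0), 0.7499)
                if k in coding:
                    seqs[k] = _mutate_cds(parent_seqs[k], rate, rng, spec.ts_tv_ratio)
                else:
                    seqs[k] = mutate_sequence(parent_seqs[k], rate, rng, spec.ts_tv_ratio)
            state[id(node)] = seqs
        if node.is_tip():
            out[node.name] = state[id(node)]
    return out


def _tip_depths(tree: TreeNode, spec: SynthSpec) -> dict[str, float]:
    depths = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while not node.is_root():
            d += _branch_rate(node, spec)
            node = node.parent
        depths[tip.name] = d
    return depths


def _pair_distances(tree: TreeNode, spec: SynthSpec) -> dict[tuple[str, str], float]:
    tips = sorted(t.name for t in tree.tips())
    node_of = {t.name: t for t in tree.tips()}

    def path_to_root(n: TreeNode) -> list[TreeNode]:
        out = [n]
        while not n.is_root():
            n = n.parent
            out.append(n)
        return out

    dists = {}
    for i, a in enumerate(tips):
        pa = path_to_root(node_of[a])
        anc_a = {id(x): k for k, x in enumerate(pa)}
        for b in tips[i + 1:]:
            d = 0.0
            node = node_of[b]
            while id(node) not in anc_a:
                d += _branch_rate(node, spec)
                node = node.parent
            for x in pa[: anc_a[id(node)]]:
                d += _branch_rate(x, spec)
            dists[(a, b)] = d
    return dists


# --------------------------------------------------------------------------
# indels (codon-level, with host->ancestor codon map)
# --------------------------------------------------------------------------


def _apply_codon_indels(cds: str, rng: np.random.Generator, rate: float,
                        protected: set[int], gc: float) -> tuple[str, list[int | None]]:
    """Insert/delete whole codons at probability *rate* per codon; returns the
    new sequence and, per host codon, the ancestral codon index (None for
    insertions).  The first/last codons and *protected* codons are immune."""
    n = len(cds) // 3
    out: list[str] = []
    cmap: list[int | None] = []
    for i in range(n):
        codon = cds[3 * i: 3 * i + 3]
        immune = i in protected or i == 0 or i == n - 1
        u = rng.random()
        if not immune and u < rate / 2:
            continue  # deletion
        out.append(codon)
        cmap.append(i)
        if not immune and rate / 2 <= u < rate:
            ins = _random_seq(rng, 3, gc)
            while ins in _STOPS:
                ins = _random_seq(rng, 3, gc)
            out.append(ins)
            cmap.append(None)
    return "".join(out), cmap


def _host_position(cmap: list[int | None], ref_position: int) -> int:
    """Map a 1-based ancestral coding position to the host coding position."""
    ref_codon = (ref_position - 1) // 3
    within = (ref_position - 1) % 3
    for j, r in enumerate(cmap):
        if r == ref_codon:
            return 3 * j + within + 1
    raise SimSpecError(f"reference codon {ref_codon} lost by indels")


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

_HE_PRODUCTS = ("LAGLIDADG homing endonuclease", "GIY-YIG homing endonuclease")


def generate_cohort(spec: SynthSpec) -> tuple[list[MitogenomeRecord], SynthTruth]:
    """Build the cohort: evolve ancestral blocks along the tree, plant introns
    and repeats, assemble circular genomes, and emit matching ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = spec.ids()
    lens = spec.lengths()
    tree = _tree_for(spec)
    depths = _tip_depths(tree, spec)
    # The symmetric substitution process pulls composition toward 50% GC;
    # offset the ancestral GC so leaf genomes land on gc_target.
    m = min(float(np.mean(list(depths.values()))), 0.7)
    gc = min(0.95, max(0.05, (spec.gc_target - 0.5 * m) / (1.0 - m)))

    # --- ancestral blocks -------------------------------------------------
    ancestral: dict[str, str] = {}
    coding: set[str] = set()
    for g in sorted(CORE_PCGS):
        start = "GTG" if (g == "cob" and spec.cob_gtg_start) else "ATG"
        ancestral[g] = _random_cds(rng, lens[g], gc, start=start)
        coding.add(g)
    for g in RRNA_GENES:
        ancestral[g] = _random_seq(rng, lens[g], gc)
    for t in TRNA_NAMES:
        ancestral[t] = _random_seq(rng, _TRNA_LEN, gc)
    n_gaps = len(ARRANGEMENT_1)
    base_content = sum(lens[g] for g in ARRANGEMENT_GENES) + _TRNA_LEN * len(TRNA_NAMES)
    filler_total = spec.genome_length_target - base_content
    if filler_total < 100 * n_gaps:
        raise SimSpecError(
            f"genome_length_target {spec.genome_length_target} too small for content"
        )
    gap_sizes = np.full(n_gaps, filler_total // n_gaps)
    gap_sizes[: filler_total % n_gaps] += 1
    for i in range(n_gaps):
        ancestral[f"igs{i:02d}"] = _random_seq(rng, int(gap_sizes[i]), gc)
    # orthologous intron bodies, one ancestor per distinct (gene, position)
    intron_sites = sorted({(p.gene, p.position) for p in spec.intron_plants})
    intron_len = {}
    for gene, pos in intron_sites:
        length = max(p.length for p in spec.intron_plants
                     if p.gene == gene and p.position == pos)
        intron_len[(gene, pos)] = length
        ancestral[f"intron:{gene}:{pos}"] = _random_seq(rng, length, gc)
    orf_anc_orfs: dict[str, str] = {}
    for o in spec.orf_plants:
        key = f"fsorf:{o.family}"
        ancestral[key] = _random_cds(rng, 3 * (o.length_codons + 1), gc)
        coding.add(key)
        orf_anc_orfs[o.family] = key
    # embedded homing-endonuclease ORFs inside with_orf introns
    for k, (gene, pos) in enumerate(intron_sites):
        if any(p.with_orf and p.gene == gene and p.position == pos
               for p in spec.intron_plants):
            body_len = intron_len[(gene, pos)]
            orf_nt = max(90, 3 * ((body_len - 120) // 3))
            key = f"heorf:{gene}:{pos}"
            ancestral[key] = _random_cds(rng, orf_nt, gc)
            coding.add(key)

    evolved = _evolve_blocks(tree, ancestral, coding, rng, spec)

    # --- per-genome assembly ---------------------------------------------
    ref_genome = spec.reference_genome or ids[0]
    records: list[MitogenomeRecord] = []
    truth_introns = []
    truth_repeats = []
    truth_orfs = []
    orders: dict[str, tuple[str, ...]] = {}

    trna_by_gap: dict[int, list[str]] = {}
    for j, t in enumerate(TRNA_NAMES):
        trna_by_gap.setdefault(j % n_gaps, []).append(t)

    for gid in ids:
        blocks = evolved[gid]
        order = spec.order_for(gid)
        orders[gid] = order
        plants = sorted(
            (p for p in spec.intron_plants if p.genome == gid),
            key=lambda p: (p.gene, p.position),
        )
        plants_by_gene: dict[str, list[IntronPlant]] = {}
        for p in plants:
            plants_by_gene.setdefault(p.gene, []).append(p)
        my_orfs = [o for o in spec.orf_plants if gid in o.genomes]
        my_reps = [r for r in spec.repeat_plants if r.genome == gid]
        # repeat copies to place: list of (label, seq, kind)
        rep_copies: list[tuple[str, str, str]] = []
        for ri, r in enumerate(my_reps):
            label = r.label or f"rep{ri}"
            unit = _random_seq(rng, r.length, gc)
            if r.tandem:
                rep_copies.append((label, unit * r.copies, "tandem"))
            else:
                for ci in range(r.copies):
                    s = unit if (ci == 0 or r.orientation == "direct") else revcomp(unit)
                    kind = "direct" if (ci == 0 or r.orientation == "direct") else "inverted"
                    rep_copies.append((f"{label}.{ci}", s, kind))

        parts: list[str] = []
        feats: list[GeneFeature] = []
        cursor = 0

        def emit(seq: str) -> tuple[int, int]:
            nonlocal cursor
            parts.append(seq)
            s = cursor
            cursor += len(seq)
            return s, cursor

        for slot, gene in enumerate(order):
            # --- the gene block (with introns), possibly minus strand
            gene_cds = blocks[gene]
            if gid != ref_genome and spec.indel_rate > 0 and gene in CORE_PCGS:
                protected = {(p.position - 1) // 3 for p in plants_by_gene.get(gene, [])}
                gene_cds, cmap = _apply_codon_indels(
                    gene_cds, rng, spec.indel_rate, protected, gc)
            else:
                cmap = None
            local: list[tuple[str, str, int, int, str]] = []  # (name, kind, s, e, product)
            block_parts: list[str] = []
            bcur = 0
            gplants = plants_by_gene.get(gene, [])
            host_positions = []
            for p in gplants:
                hp = p.position if cmap is None else _host_position(cmap, p.position)
                host_positions.append(hp)
            exon_bounds = [0] + sorted(host_positions) + [len(gene_cds)]
            seg_local: list[tuple[int, int]] = []
            for k in range(len(exon_bounds) - 1):
                ex = gene_cds[exon_bounds[k]: exon_bounds[k + 1]]
                block_parts.append(ex)
                seg_local.append((bcur, bcur + len(ex)))
                bcur += len(ex)
                if k < len(gplants):
                    p = sorted(gplants, key=lambda q: q.position)[k]
                    body = blocks.get(f"intron:{gene}:{p.position}",
                                      ancestral.get(f"intron:{gene}:{p.position}", ""))
                    body = body[: p.length]
                    i_s = bcur
                    if p.with_orf:
                        hekey = f"heorf:{gene}:{p.position}"
                        he = blocks[hekey]
                        body = body[:60] + he + body[60 + len(he):]
                        local.append((f"{gene}-i{k + 1}-orf", "intron_orf",
                                      bcur + 60, bcur + 60 + len(he),
                                      _HE_PRODUCTS[k % 2]))
                    block_parts.append(body)
                    bcur += len(body)
                    local.append((f"{gene}-i{k + 1}", "intron", i_s, bcur, ""))
                    truth_introns.append({
                        "genome": gid, "gene": gene, "ref_position": p.position,
                        "host_position": sorted(host_positions)[k],
                        "length": len(body), "with_orf": p.with_orf,
                    })
            block_seq = "".join(block_parts)
            strand = "-" if gene in spec.minus_strand_genes else "+"
            if strand == "-":
                B = len(block_seq)
                block_seq = revcomp(block_seq)
                seg_local = [(B - e, B - s) for s, e in seg_local]
                local = [(n_, k_, B - e_, B - s_, pr) for n_, k_, s_, e_, pr in local]
            s0, _ = emit(block_seq)
            kind = "rRNA" if gene in RRNA_GENES else "core_pcg"
            feats.append(GeneFeature(
                name=gene, kind=kind, strand=strand,
                segments=tuple((s0 + a, s0 + b) for a, b in seg_local),
            ))
            for n_, k_, a, b, pr in local:
                feats.append(GeneFeature(name=n_, kind=k_, strand=strand,
                                         segments=((s0 + a, s0 + b),), product=pr))
            # --- intergenic gap after this gene
            gap_seq = blocks[f"igs{slot:02d}"]
            third = max(len(gap_seq) // 4, 10)
            emit(gap_seq[:third])
            for tj, t in enumerate(trna_by_gap.get(slot, [])):
                ts, te = emit(blocks[t])
                feats.append(GeneFeature(name=t, kind="tRNA", strand="+",
                                         segments=((ts, te),)))
                emit(gap_seq[third + 20 * tj: third + 20 * (tj + 1)])
            for oi, o in enumerate(my_orfs):
                if oi % n_gaps == slot:
                    oseq = blocks[orf_anc_orfs[o.family]]
                    os_, oe_ = emit(oseq)
                    name = f"orf{(len(oseq) // 3) - 1}"
                    feats.append(GeneFeature(name=name, kind="orf", strand="+",
                                             segments=((os_, oe_),), product=o.product))
                    truth_orfs.append({"genome": gid, "family": o.family,
                                       "feature": name, "slot": slot})
            for ri_, (label, rseq, rkind) in enumerate(rep_copies):
                if ri_ % n_gaps == slot:
                    rs, re = emit(rseq)
                    truth_repeats.append({"genome": gid, "label": label,
                                          "start": rs, "end": re, "kind": rkind})
            emit(gap_seq[third + 20 * max(len(trna_by_gap.get(slot, [])), 0):])

        record = MitogenomeRecord(id=gid, sequence="".join(parts),
                                  features=feats, circular=True)
        record.validate()
        records.append(record)

    truth = SynthTruth(
        introns=pd.DataFrame(
            truth_introns,
            columns=["genome", "gene", "ref_position", "host_position",
                     "length", "with_orf"],
        ),
        repeats=pd.DataFrame(
            truth_repeats, columns=["genome", "label", "start", "end", "kind"]),
        gene_orders=orders,
        tree_newick=str(tree).strip(),
        tip_depths=depths,
        pair_distances=_pair_distances(tree, spec),
        orf_members=pd.DataFrame(truth_orfs,
                                 columns=["genome", "family", "feature", "slot"]),
    )
    return records, truth


def write_cohort(records: list[MitogenomeRecord], truth: SynthTruth,
                 outdir: str | Path, formats: Sequence[str] = ("genbank",)) -> None:
    """Write a cohort plus its ground truth to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        if "genbank" in formats:
            write_genbank(rec, outdir / f"{rec.id}.gb")
        if "gff3+fasta" in formats:
            write_gff3_fasta(rec, outdir / f"{rec.id}.gff3", outdir / f"{rec.id}.fasta")
    truth.write(outdir)


# --------------------------------------------------------------------------
# the 13-genome study-like cohort
# --------------------------------------------------------------------------

STUDY_GENOMES: tuple[str, ...] = (
    "G_applanatum", "G_tsugae", "G_sinense", "G_meredithae", "G_lucidum_KC",
    "G_lucidum_s26", "G_lucidum_s37", "G_lingzhi_s62", "G_lingzhi_s74",
    "G_subamboinense_s118", "G_lingzhi_s8", "G_calidophilum",
    "G_leucocontextum",
)

STUDY_TREE = (
    "((((G_lucidum_KC:0.01,(G_lucidum_s26:0.008,G_lucidum_s37:0.008):0.004):0.015,"
    "(G_lingzhi_s62:0.009,(G_lingzhi_s74:0.007,G_lingzhi_s8:0.007):0.004):0.016):0.02,"
    "(G_tsugae:0.03,G_meredithae:0.03):0.012):0.015,"
    "((G_applanatum:0.035,G_subamboinense_s118:0.035):0.01,"
    "(G_sinense:0.03,(G_calidophilum:0.025,G_leucocontextum:0.025):0.008):0.012):0.01);"
)

#: A third arrangement for the genomes outside the two main groups.
ARRANGEMENT_3: tuple[str, ...] = (
    "cox1", "nad4", "rnl", "atp6", "cox3", "nad4L", "rps3", "nad5", "nad2",
    "rns", "nad6", "atp9", "cob", "nad1", "cox2", "atp8", "nad3",
)


def study_cohort_spec(seed: int = 0, genome_length_target: int = 46_000,
                      indel_rate: float = 0.0) -> SynthSpec:
    """A 13-genome cohort emulating the study conditions: two shared gene
    arrangements (6 + 4 genomes) plus three private ones, intron position
    classes with the observed common/rare pattern (P1305 in 12/13, P209 in
    10/13, a universal nad5 site, several singletons), homing-endonuclease
    ORFs in a subset of introns, and shared free-standing ORF families."""
    g = STUDY_GENOMES
    order: dict[str, tuple[str, ...]] = {}
    for gid in g[:6]:
        order[gid] = ARRANGEMENT_1
    for gid in g[6:10]:
        order[gid] = ARRANGEMENT_2
    for gid in g[10:]:
        order[gid] = ARRANGEMENT_3
    plants: list[IntronPlant] = []
    for gid in g[:12]:  # P1305: 12 of 13
        plants.append(IntronPlant(gid, "cox1", 1305, 1400, with_orf=True))
    for gid in g[:10]:  # P209: 10 of 13
        plants.append(IntronPlant(gid, "cox1", 209, 1200))
    for gid in g:  # nad5 P426: universal
        plants.append(IntronPlant(gid, "nad5", 426, 1500, with_orf=(gid in g[:4])))
    for gid in g[2:8]:
        plants.append(IntronPlant(gid, "cob", 393, 1300))
    # rare, single-genome sites
    plants.append(IntronPlant(g[0], "cox1", 218, 1100))
    plants.append(IntronPlant(g[4], "cox1", 900, 1250))
    plants.append(IntronPlant(g[11], "cob", 597, 1350, with_orf=True))
    plants.append(IntronPlant(g[12], "cox1", 971, 1450))
    repeats = [
        RepeatPlant(g[9], length=120, copies=2, label="dup120"),
        RepeatPlant(g[9], length=45, copies=3, tandem=True, label="tand45"),
        RepeatPlant(g[4], length=80, copies=2, orientation="inverted", label="inv80"),
    ]
    orfs = [
        OrfPlant("rnapol_A", tuple(g[4:10]), 109, "RNA polymerase"),
        OrfPlant("dnapol_B", tuple(g[4:7]), 283, "DNA polymerase"),
        OrfPlant("hyp_C", (g[7], g[8], g[10]), 151, "hypothetical protein"),
    ]
    return SynthSpec(
        genome_ids=g, genome_length_target=genome_length_target,
        gc_target=0.264, tree=STUDY_TREE, gene_order=order,
        intron_plants=tuple(plants), repeat_plants=tuple(repeats),
        orf_plants=tuple(orfs), indel_rate=indel_rate,
        reference_genome="G_calidophilum", seed=seed,
    )


def pcl_benchmark_spec(seed: int = 0, indel_rate: float = 0.0) -> SynthSpec:
    """13 genomes at divergence 0.05 with 40 introns planted across cox1,
    cob and nad5 at known reference positions — the position-class recovery
    benchmark."""
    g = STUDY_GENOMES
    plants: list[IntronPlant] = []
    for gid in g[:12]:
        plants.append(IntronPlant(gid, "cox1", 1305, 500))
    for gid in g[:10]:
        plants.append(IntronPlant(gid, "cox1", 209, 450))
    for gid in g[3:8]:
        plants.append(IntronPlant(gid, "cob", 393, 480))
    for gid in g[5:13]:
        plants.append(IntronPlant(gid, "nad5", 426, 520))
    plants.append(IntronPlant(g[0], "cox1", 900, 400))
    plants.append(IntronPlant(g[2], "cob", 597, 430))
    plants.append(IntronPlant(g[4], "nad5", 1002, 460))
    plants.append(IntronPlant(g[7], "nad5", 324, 440))
    plants.append(IntronPlant(g[12], "cox1", 218, 410))
    assert len(plants) == 40
    return SynthSpec(
        genome_ids=g, genome_length_target=30_000, gc_target=0.264,
        tree=STUDY_TREE, intron_plants=tuple(plants), indel_rate=indel_rate,
        reference_genome="G_calidophilum", seed=seed,
    )
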