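"""Reading, writing and slicing annotated circular mitochondrial genomes.

The record model is deliberately small: a circular DNA sequence plus typed
gene features whose (possibly multi-segment) coordinates are stored 0-based
half-open, in transcription order.  Multi-segment CDS features imply introns;
splicing and intron insert offsets are derived from the geometry alone, so the
same code path serves GenBank flat files, GFF3+FASTA pairs and synthetic
fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, LookupFailure, ParseError

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# canonical gene sets and symbol normalization
# --------------------------------------------------------------------------

#: The 15 protein-coding genes conserved across fungal mitogenomes.
CORE_PCGS: frozenset[str] = frozenset(
    {
        "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
    }
)

#: Mitochondrial rRNA genes: large (rnl) and small (rns) subunit.
RRNA_GENES: tuple[str, str] = ("rnl", "rns")

#: Core gene symbols are case-normalized except nad4L, kept in its
#: conventional mixed case.
_CASE_CANONICAL = {g.lower(): g for g in CORE_PCGS | set(RRNA_GENES)}

_SYNONYMS = {
    "cytb": "cob", "cob1": "cob", "cytochrome_b": "cob",
    "nd4l": "nad4L", "nad4l": "nad4L",
    "lsu": "rnl", "rrnl": "rnl", "rnl_rrna": "rnl", "16s": "rnl",
    "ssu": "rns", "rrns": "rns", "12s": "rns",
    "atpase6": "atp6", "atpase8": "atp8", "atpase9": "atp9",
}


def normalize_gene_symbol(symbol: str) -> str:
    """Map a raw annotation symbol to the canonical lowercase gene name.

    Known synonyms (cob/cytb, nad4L/nd4l, rnl/LSU, rns/SSU, ...) collapse to
    the canonical symbol; unknown symbols pass through lowercased, except
    tRNA names which keep their amino-acid letter case (trnA, trnL1, ...).
    """
    s = symbol.strip()
    low = s.lower()
    if low in _SYNONYMS:
        return _SYNONYMS[low]
    if low in _CASE_CANONICAL:
        return _CASE_CANONICAL[low]
    if low.startswith("trn"):
        return "trn" + s[3:]
    return low


FeatureKind = Literal["core_pcg", "orf", "intron_orf", "tRNA", "rRNA", "intron"]

KINDS: tuple[str, ...] = ("core_pcg", "orf", "intron_orf", "tRNA", "rRNA", "intron")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# record model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with multi-segment, transcription-ordered geometry.

    ``segments`` are 0-based half-open genomic intervals listed in
    transcription order: ascending for ``+`` strand features, descending for
    ``-`` strand.  ``wraps`` marks features whose span crosses the circular
    origin (stored pre-split, so all coordinates stay inside the genome).
    """

    name: str
    kind: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    product: str = ""
    wraps: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConsistencyError(f"feature {self.name}: no segments")
        if self.kind not in KINDS:
            raise ConsistencyError(f"feature {self.name}: unknown kind {self.kind!r}")
        if self.strand not in "+-":
            raise ConsistencyError(f"feature {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def start(self) -> int:
        """Genomic start of the first transcribed segment."""
        return self.segments[0][0] if self.strand == "+" else self.segments[-1][0]

    @property
    def n_implied_introns(self) -> int:
        return len(self.segments) - 1


@dataclass
class MitogenomeRecord:
    """An annotated (by default circular) mitochondrial genome."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ParseError(f"{self.id}: disallowed sequence characters {sorted(bad)}")
        for f in self.features:
            for s, e in f.segments:
                if not (0 <= s < e <= self.length):
                    raise ConsistencyError(
                        f"{self.id}: feature {f.name} segment ({s}, {e}) "
                        f"outside [0, {self.length})"
                    )

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]

    def get_gene(self, gene: str) -> GeneFeature:
        name = normalize_gene_symbol(gene)
        for f in self.features:
            if f.name == name and f.kind in ("core_pcg", "orf", "rRNA"):
                return f
        raise LookupFailure(f"{self.id}: gene {gene!r} not annotated")

    def has_gene(self, gene: str) -> bool:
        try:
            self.get_gene(gene)
            return True
        except LookupFailure:
            return False


def normalize_coordinates(record: MitogenomeRecord) -> MitogenomeRecord:
    """Reduce all segment coordinates modulo the genome length (idempotent)."""
    n = record.length
    feats = []
    for f in record.features:
        segs = []
        for s, e in f.segments:
            if 0 <= s < e <= n:
                segs.append((s, e))
            else:
                s0 = s % n
                segs.append((s0, s0 + (e - s)))
        feats.append(replace(f, segments=tuple(segs)))
    return MitogenomeRecord(record.id, record.sequence, feats, record.circular)


# --------------------------------------------------------------------------
# splicing and intron geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IntronSite:
    """An intron implied by a multi-segment gene.

    ``insert_offset`` is the number of coding nucleotides 5' of the intron
    (1-based count), i.e. the intron sits immediately after coding position
    ``insert_offset`` of the spliced gene.
    """

    insert_offset: int
    length: int


@dataclass(frozen=True)
class SplicedGene:
    cds: str
    introns: tuple[IntronSite, ...]
    frame_ok: bool

    def __iter__(self):  # allow (cds, introns) unpacking plus the flag
        return iter((self.cds, self.introns, self.frame_ok))


def splice(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """Concatenate a feature's segments in transcription order."""
    seq = record.sequence
    if feature.strand == "+":
        return "".join(seq[s:e] for s, e in feature.segments)
    return "".join(revcomp(seq[s:e]) for s, e in feature.segments)


def extract_coding_exons(record: MitogenomeRecord, gene: str) -> SplicedGene:
    """Spliced CDS of *gene* plus its introns with coding-coordinate offsets.

    A spliced length not divisible by 3 is flagged (``frame_ok=False``) but
    not fatal — rRNA genes go through the same machinery.
    """
    feat = record.get_gene(gene)
    cds = splice(record, feat)
    n = record.length
    introns: list[IntronSite] = []
    offset = 0
    for i in range(len(feat.segments) - 1):
        s_cur, s_nxt = feat.segments[i], feat.segments[i + 1]
        offset += s_cur[1] - s_cur[0]
        if feat.strand == "+":
            gap = (s_nxt[0] - s_cur[1]) % n
        else:
            gap = (s_cur[0] - s_nxt[1]) % n
        introns.append(IntronSite(insert_offset=offset, length=gap))
    frame_ok = len(cds) % 3 == 0
    if not frame_ok and feat.kind in ("core_pcg", "orf", "intron_orf"):
        logger.warning("%s: spliced %s length %d not divisible by 3", record.id, gene, len(cds))
    return SplicedGene(cds=cds, introns=tuple(introns), frame_ok=frame_ok)


# --------------------------------------------------------------------------
# inventory
# --------------------------------------------------------------------------


def canonical_gene_inventory(record: MitogenomeRecord) -> pd.DataFrame:
    """Presence/absence and copy counts for the canonical gene set.

    One row per core PCG and rRNA gene, plus total rows for tRNA and rRNA
    counts.  Absences are data, not errors.
    """
    counts: dict[str, int] = {}
    for f in record.features:
        if f.kind in ("core_pcg", "rRNA"):
            counts[f.name] = counts.get(f.name, 0) + 1
    rows = []
    for g in sorted(CORE_PCGS) + list(RRNA_GENES):
        c = counts.get(g, 0)
        rows.append(
            {"item": g, "category": "rRNA" if g in RRNA_GENES else "core_pcg",
             "present": c > 0, "copies": c}
        )
    n_trna = len(record.features_of_kind("tRNA"))
    n_rrna = len(record.features_of_kind("rRNA"))
    rows.append({"item": "tRNA_total", "category": "total", "present": n_trna > 0, "copies": n_trna})
    rows.append({"item": "rRNA_total", "category": "total", "present": n_rrna > 0, "copies": n_rrna})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# GenBank I/O
# --------------------------------------------------------------------------

_GB_TYPE = {"core_pcg": "CDS", "orf": "CDS", "intron_orf": "CDS",
            "tRNA": "tRNA", "rRNA": "rRNA", "intron": "intron"}


def _location_for(feature: GeneFeature, genome_len: int) -> SimpleLocation | CompoundLocation:
    strand = 1 if feature.strand == "+" else -1
    parts = [SimpleLocation(s, e, strand) for s, e in feature.segments]
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def _to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    sr = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                   description=f"{record.id} mitochondrion")
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    sr.features.append(
        SeqFeature(SimpleLocation(0, record.length, 1), type="source",
                   qualifiers={"organelle": ["mitochondrion"]})
    )
    for f in record.features:
        quals: dict[str, list[str]] = {"gene": [f.name], "note": [f"kind:{f.kind}"]}
        if f.product:
            quals["product"] = [f.product]
        sr.features.append(
            SeqFeature(_location_for(f, record.length), type=_GB_TYPE[f.kind], qualifiers=quals)
        )
    return sr


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(_to_seqrecord(record), str(path), "genbank")


def _kind_from_seqfeature(ftype: str, name: str, note: str) -> str | None:
    for k in KINDS:
        if f"kind:{k}" in note:
            return k
    if ftype == "CDS":
        return "core_pcg" if name in CORE_PCGS else "orf"
    if ftype in ("tRNA", "rRNA", "intron"):
        return ftype
    return None


def _feature_from_biopython(sf: SeqFeature, genome_len: int) -> GeneFeature | None:
    quals = sf.qualifiers
    raw = (quals.get("gene") or quals.get("locus_tag") or quals.get("label") or [""])[0]
    product = (quals.get("product") or [""])[0]
    name = normalize_gene_symbol(raw) if raw else ""
    note = " ".join(quals.get("note", []))
    kind = _kind_from_seqfeature(sf.type, name, note)
    if kind is None:
        return None
    if not name:
        name = product.split()[0].lower() if product else sf.type.lower()
    try:
        parts = sf.location.parts
    except AttributeError as exc:
        raise ParseError(f"feature {name}: unreadable location") from exc
    strand = "-" if all(p.strand == -1 for p in parts) else "+"
    segments = tuple((int(p.start), int(p.end)) for p in parts)
    for s, e in segments:
        if not (0 <= s < e <= genome_len):
            raise ParseError(f"feature {name}: malformed coordinates ({s}, {e})")
    # An origin-spanning join shows up as a final segment restarting at 0.
    wraps = any(
        (strand == "+" and segments[i][1] == genome_len and segments[i + 1][0] == 0)
        or (strand == "-" and segments[i][0] == 0 and segments[i + 1][1] == genome_len)
        for i in range(len(segments) - 1)
    )
    return GeneFeature(name=name, kind=kind, strand=strand, segments=segments,
                       product=product, wraps=wraps)


def _cross_check_introns(features: list[GeneFeature], rec_id: str) -> list[GeneFeature]:
    """Explicit intron features must match CDS join gaps; joins win on conflict."""
    gaps: set[tuple[int, int]] = set()
    for f in features:
        if f.kind in ("core_pcg", "orf") and len(f.segments) > 1:
            segs = sorted(f.segments)
            for i in range(len(segs) - 1):
                gaps.add((segs[i][1], segs[i + 1][0]))
    kept = []
    for f in features:
        if f.kind == "intron" and gaps:
            iv = (f.segments[0][0], f.segments[-1][1])
            if iv not in gaps:
                logger.warning(
                    "%s: intron feature %s at %s conflicts with CDS joins; join wins",
                    rec_id, f.name, iv,
                )
                continue
        kept.append(f)
    return kept


def read_genbank(path: str | Path) -> MitogenomeRecord:
    try:
        sr = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"{path}: not a readable GenBank flat file") from exc
    seq = str(sr.seq).upper()
    features = []
    for sf in sr.features:
        if sf.type == "source":
            continue
        gf = _feature_from_biopython(sf, len(seq))
        if gf is not None:
            features.append(gf)
    features = _cross_check_introns(features, sr.id)
    rec = MitogenomeRecord(
        id=sr.id, sequence=seq, features=features,
        circular=sr.annotations.get("topology", "circular") == "circular",
    )
    rec.validate()
    return rec


# --------------------------------------------------------------------------
# GFF3 + FASTA I/O
# --------------------------------------------------------------------------

_GFF_TYPE = {"core_pcg": "CDS", "orf": "CDS", "intron_orf": "CDS",
             "tRNA": "tRNA", "rRNA": "rRNA", "intron": "intron"}


def write_gff3_fasta(record: MitogenomeRecord, gff_path: str | Path,
                     fasta_path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {record.id} 1 {record.length}"]
    circ = ";Is_circular=true" if record.circular else ""
    lines.append(
        f"{record.id}\tmitocomp\tregion\t1\t{record.length}\t.\t+\t.\tID={record.id}{circ}"
    )
    for i, f in enumerate(record.features):
        fid = f"feat{i:04d}"
        coding_before = 0
        for s, e in f.segments:  # transcription order; phase from coding length upstream
            attrs = f"ID={fid};Name={f.name};gene={f.name};kind={f.kind}"
            if f.product:
                attrs += f";product={f.product.replace(';', '%3B')}"
            if f.kind in ("core_pcg", "orf", "intron_orf"):
                phase = str((3 - (coding_before % 3)) % 3)
            else:
                phase = "."
            lines.append(
                f"{record.id}\tmitocomp\t{_GFF_TYPE[f.kind]}\t{s + 1}\t{e}\t.\t"
                f"{f.strand}\t{phase}\t{attrs}"
            )
            coding_before += e - s
    Path(gff_path).write_text("\n".join(lines) + "\n")
    SeqIO.write(SeqRecord(Seq(record.sequence), id=record.id, description=""),
                str(fasta_path), "fasta")


def _parse_attrs(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v.replace("%3B", ";")
    return out


def read_gff3_fasta(gff_path: str | Path, fasta_path: str | Path) -> MitogenomeRecord:
    try:
        sr = next(SeqIO.parse(str(fasta_path), "fasta"))
    except StopIteration as exc:
        raise ParseError(f"{fasta_path}: empty FASTA") from exc
    seq = str(sr.seq).upper()
    circular = True
    # group feature lines by ID
    grouped: dict[str, list[tuple[int, int, str, dict[str, str], str]]] = {}
    order: list[str] = []
    for ln in Path(gff_path).read_text().splitlines():
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 9:
            raise ParseError(f"{gff_path}: malformed GFF3 line: {ln[:60]!r}")
        _, _, ftype, start, end, _, strand, _, attr_col = cols
        attrs = _parse_attrs(attr_col)
        if ftype == "region":
            circular = attrs.get("Is_circular", "false") == "true"
            continue
        try:
            s, e = int(start) - 1, int(end)
        except ValueError as exc:
            raise ParseError(
                f"{gff_path}: malformed coordinates for feature "
                f"{attrs.get('Name', attrs.get('ID', '?'))}"
            ) from exc
        fid = attrs.get("ID", f"anon{len(order)}")
        if fid not in grouped:
            grouped[fid] = []
            order.append(fid)
        grouped[fid].append((s, e, strand, attrs, ftype))
    features = []
    for fid in order:
        parts = grouped[fid]
        s0, e0, strand, attrs, ftype = parts[0]
        name = normalize_gene_symbol(attrs.get("gene", attrs.get("Name", ftype)))
        kind = attrs.get("kind") or _kind_from_seqfeature(ftype, name, "")
        if kind is None:
            continue
        segs = sorted([(p[0], p[1]) for p in parts])
        if strand == "-":
            segs = segs[::-1]
        features.append(
            GeneFeature(name=name, kind=kind, strand=strand, segments=tuple(segs),
                        product=attrs.get("product", ""))
        )
    rec = MitogenomeRecord(id=sr.id, sequence=seq, features=features, circular=circular)
    rec.validate()
    return rec


def read_annotated_genome(path: str | Path, format: str = "genbank") -> MitogenomeRecord:
    """Read one annotated mitogenome.

    ``format`` is ``"genbank"`` or ``"gff3+fasta"``; in the latter case *path*
    names the GFF3 file and the FASTA is found beside it (same stem, suffix
    .fasta/.fa/.fna).
    """
    path = Path(path)
    if format == "genbank":
        return read_genbank(path)
    if format == "gff3+fasta":
        for suffix in (".fasta", ".fa", ".fna"):
            fa = path.with_suffix(suffix)
            if fa.exists():
                return read_gff3_fasta(path, fa)
        raise ParseError(f"{path}: no companion FASTA (.fasta/.fa/.fna) found")
    raise ParseError(f"unknown format {format!r}")
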