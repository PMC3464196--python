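"""Data model and readers/writers for the formats the toolkit touches.

All internal coordinates are 0-based half-open; all GFF3/text output is
1-based inclusive.  The conversion lives in :func:`to_gff_coords` /
:func:`from_gff_coords` and nowhere else.

The central record is :class:`IesRecord`: a TA-led germline insertion whose
somatic (MAC) insertion point ``p`` satisfies ``MAC[p:p+2] == "TA"`` and whose
reconstruction identity ``MAC[:p] + seq + MAC[p:]`` reproduces the germline
locus.  ``seq`` starts with the left TA and excludes the right TA, so a
canonical excision removes ``len(seq)`` bases and leaves one TA behind.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# coordinate convention


def to_gff_coords(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start0 < 0 or end0 < start0:
        raise ValueError(f"invalid interval ({start0}, {end0})")
    return start0 + 1, end0


def from_gff_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise FormatError(f"invalid GFF interval ({start1}, {end1})")
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomeSequence:
    id: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: illegal character(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its intervals in 0-based half-open scaffold coordinates.

    ``intervals`` holds (start, end, kind) with kind in {exon, intron, CDS};
    introns are derived as the gaps between consecutive exons.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    intervals: tuple[tuple[int, int, str], ...]
    cds_phases: tuple[int, ...] = ()

    def intervals_of(self, kind: str):
        return [iv for iv in self.intervals if iv[2] == kind]


@dataclass
class IesRecord:
    scaffold: str
    p: int  # 0-based offset of the T of the retained TA on the MAC
    seq: str  # starts with "TA"; excludes the right TA
    context: str = "unknown"  # exon / intron / intergenic / unknown
    gene_id: str | None = None
    support: int = 1
    flags: frozenset[str] = field(default_factory=frozenset)
    id: str | None = None

    def __post_init__(self):
        if not self.seq.startswith("TA"):
            raise ValueError(f"IES at {self.scaffold}:{self.p} does not start with TA")
        if self.p < 0:
            raise ValueError("negative insertion point")

    @property
    def length(self) -> int:
        return len(self.seq)

    def key(self) -> tuple[str, int, str]:
        return (self.scaffold, self.p, self.seq)

    def check_against_genome(self, genome: dict[str, str]) -> None:
        """Assert the MAC retains a TA at the insertion point."""
        mac = genome[self.scaffold]
        if mac[self.p : self.p + 2] != "TA":
            raise ValueError(
                f"IES {self.scaffold}:{self.p}: MAC does not carry TA at the "
                "insertion point"
            )


@dataclass(frozen=True)
class SamAlignmentRecord:
    qname: str
    flag: int
    scaffold: str
    pos: int  # 0-based mapped start
    mapq: int
    cigar: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4) or self.cigar == "*"

    @property
    def strand(self) -> str:
        return "-" if self.flag & 16 else "+"

    def cigar_ops(self) -> list[tuple[int, str]]:
        return [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]

    @property
    def end(self) -> int:
        """One past the last reference base consumed (M/D/N/=/X)."""
        ref = sum(n for n, op in self.cigar_ops() if op in "MDN=X")
        return self.pos + ref


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences are uppercased, U and other non-ACGTN
    characters rejected, record order preserved."""
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal character(s) "
                f"{sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, seq))
    return out


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def genome_dict(records) -> dict[str, str]:
    return {r.id: r.seq for r in records}


# ---------------------------------------------------------------------------
# GFF3 genes


def _gff_attributes(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path) -> list[GeneAnnotation]:
    """Read gene/exon/CDS features from GFF3 and derive introns.

    Exons and CDS are attached to their gene via Parent/ID chains (mRNA
    levels are followed one step).  Coordinates are converted to 0-based
    half-open on input.
    """
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seqid, _, ftype, s1, e1, _, strand, phase, attrs = cols[:9]
            try:
                start1, end1 = int(s1), int(e1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            start0, end0 = from_gff_coords(start1, end1)
            a = _gff_attributes(attrs)
            rows.append((lineno, seqid, ftype, start0, end0, strand, phase, a))
    for lineno, seqid, ftype, s, e, strand, phase, a in rows:
        if ftype == "gene":
            gid = a.get("ID")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: gene without ID")
            genes[gid] = dict(
                scaffold=seqid, start=s, end=e, strand=strand, exons=[], cds=[]
            )
        elif ftype == "mRNA":
            if "ID" in a and "Parent" in a:
                parent_of[a["ID"]] = a["Parent"]
    for lineno, seqid, ftype, s, e, strand, phase, a in rows:
        if ftype not in ("exon", "CDS"):
            continue
        parent = a.get("Parent")
        gid = parent_of.get(parent, parent)
        if gid not in genes:
            continue  # feature of an unannotated parent
        g = genes[gid]
        if s < g["start"] or e > g["end"]:
            raise FormatError(
                f"{path}:{lineno}: {ftype} outside gene bounds of {gid}"
            )
        if ftype == "exon":
            g["exons"].append((s, e))
        else:
            g["cds"].append((s, e, 0 if phase == "." else int(phase)))
    out = []
    for gid, g in genes.items():
        exons = sorted(g["exons"])
        for (s1_, e1_), (s2_, e2_) in zip(exons, exons[1:]):
            if s2_ < e1_:
                raise FormatError(f"gene {gid}: overlapping exons")
        intervals = [(s, e, "exon") for s, e in exons]
        intervals += [
            (e1_, s2_, "intron")
            for (s1_, e1_), (s2_, e2_) in zip(exons, exons[1:])
            if s2_ > e1_
        ]
        cds = sorted(g["cds"])
        intervals += [(s, e, "CDS") for s, e, _ in cds]
        intervals.sort()
        out.append(
            GeneAnnotation(
                gene_id=gid,
                scaffold=g["scaffold"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                intervals=tuple(intervals),
                cds_phases=tuple(ph for _, _, ph in cds),
            )
        )
    out.sort(key=lambda g: (g.scaffold, g.start))
    return out


def write_genes_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = to_gff_coords(g.start, g.end)
            fh.write(
                f"{g.scaffold}\tiescan\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.scaffold}\tiescan\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            n = 0
            phases = iter(g.cds_phases)
            for s, e, kind in g.intervals:
                if kind == "intron":
                    continue
                n += 1
                fs, fe = to_gff_coords(s, e)
                phase = "."
                if kind == "CDS":
                    phase = str(next(phases, 0))
                fh.write(
                    f"{g.scaffold}\tiescan\t{kind}\t{fs}\t{fe}\t.\t{g.strand}\t"
                    f"{phase}\tID={g.gene_id}.{kind}{n};Parent={g.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# IES GFF3


def write_ies_gff3(ies_set, path, genome: dict[str, str] | None = None) -> None:
    """One feature per IES; start/end mark the retained TA on the MAC.

    If ``genome`` is given, each record is checked for the retained-TA
    invariant before anything is written.
    """
    records = list(ies_set)
    if genome is not None:
        for rec in records:
            rec.check_against_genome(genome)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(records, 1):
            s1, e1 = to_gff_coords(rec.p, rec.p + 2)
            rid = rec.id or f"IES.{rec.scaffold}.{rec.p}"
            attrs = (
                f"ID={rid};ies_seq={rec.seq};length={rec.length};"
                f"support={rec.support}"
            )
            if rec.context != "unknown":
                attrs += f";context={rec.context}"
            if rec.gene_id:
                attrs += f";gene_id={rec.gene_id}"
            if rec.flags:
                attrs += f";flags={','.join(sorted(rec.flags))}"
            fh.write(
                f"{rec.scaffold}\tiescan\tinternal_eliminated_sequence\t"
                f"{s1}\t{e1}\t.\t.\t.\t{attrs}\n"
            )


def read_ies_gff3(path) -> list[IesRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            a = _gff_attributes(cols[8])
            p, _ = from_gff_coords(int(cols[3]), int(cols[4]))
            flags = frozenset(
                f for f in a.get("flags", "").split(",") if f
            )
            out.append(
                IesRecord(
                    scaffold=cols[0],
                    p=p,
                    seq=a["ies_seq"],
                    context=a.get("context", "unknown"),
                    gene_id=a.get("gene_id"),
                    support=int(a.get("support", 1)),
                    flags=flags,
                    id=a.get("ID"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# SAM (plain-text subset; header optional, columns 1-6 required)


def parse_sam_line(line: str) -> SamAlignmentRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 6:
        raise FormatError("SAM record with fewer than 6 columns")
    return SamAlignmentRecord(
        qname=cols[0],
        flag=int(cols[1]),
        scaffold=cols[2],
        pos=int(cols[3]) - 1,
        mapq=int(cols[4]),
        cigar=cols[5],
    )


def read_sam(path):
    """Yield mapped SamAlignmentRecords from a plain-text SAM file."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            rec = parse_sam_line(line)
            if rec.scaffold == "*":
                continue
            yield rec


def write_sam(records, path, genome: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        if genome:
            for name, seq in genome.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in records:
            fh.write(
                f"{r.qname}\t{r.flag}\t{r.scaffold}\t{r.pos + 1}\t{r.mapq}\t"
                f"{r.cigar}\t*\t0\t0\t*\t*\n"
            )
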