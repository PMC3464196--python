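"""Synthetic-data generator for the whole toolkit.

Emulates the statistical structure the detection and inference stages
assume: an AT-rich somatic (MAC) genome (28% G+C) carrying TA-bounded
germline insertions of 20% G+C whose lengths follow a ~10 bp periodic
mixture starting at 26 bp with a depleted second peak, whose ends follow a
degenerate TAYAGYNR consensus, plus error-free reads (soft-clipped at
junctions when mapped back to the MAC), germline contigs, and forward-
simulated quartet gain/loss histories.

Everything is a pure function of (config, seed).  The quartet simulator
draws explicit per-branch survival events and shares no code with
``quartets.pattern_probabilities`` — their agreement is a test, not an
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import GeneAnnotation, GenomeSequence, IesRecord, SamAlignmentRecord
from .mica import canonicalize
from .quartets import QuartetPatternCounts

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: position weight matrix approximating the degenerate 5'-TAYAGYNR-3' end
#: consensus (rows = consensus positions, columns = A, C, G, T); the
#: degenerate positions stay AT-rich, as in the genome the consensus sits in
END_CONSENSUS_PWM = np.array(
    [
        [0.00, 0.00, 0.00, 1.00],  # T
        [1.00, 0.00, 0.00, 0.00],  # A
        [0.10, 0.30, 0.05, 0.55],  # Y (C/T)
        [0.70, 0.08, 0.07, 0.15],  # A-biased
        [0.25, 0.05, 0.50, 0.20],  # G-biased
        [0.10, 0.30, 0.05, 0.55],  # Y
        [0.40, 0.10, 0.10, 0.40],  # N at AT-rich background
        [0.55, 0.05, 0.30, 0.10],  # R (A/G)
    ]
)

#: expected number of G/C bases in one PWM draw
_PWM_GC = float(END_CONSENSUS_PWM[:, 1].sum() + END_CONSENSUS_PWM[:, 2].sum())


@dataclass(frozen=True)
class SimConfig:
    seed: int
    genome_length: int = 100_000
    n_scaffolds: int = 2
    gc: float = 0.28
    n_genes: int | None = None  # default: one gene per ~2.5 kb
    n_ies: int | None = None  # default: one IES per kb
    ies_gc: float = 0.20
    # size model
    first_peak: float = 28.0
    min_len: int = 26
    peak_spacing: float = 10.2
    peak_sd: float = 1.5
    peak_decay: float = 0.65
    second_peak_factor: float = 0.05
    n_peaks: int = 12
    # placement
    end_margin: int = 600
    min_spacing: int = 300
    # reads
    read_length: int = 108
    fragment_size: int = 500
    coverage: float = 160.0
    min_anchor: int = 25
    substitution_rate: float = 0.0
    # contigs
    contig_length: int = 2000
    contig_step: int = 1000

    def __post_init__(self):
        if self.read_length > self.fragment_size:
            raise ValueError("read length exceeds fragment size")
        if not (0 <= self.gc <= 1 and 0 <= self.ies_gc <= 1):
            raise ValueError("G+C fractions must lie in [0, 1]")

    @property
    def genes_target(self) -> int:
        return (
            self.n_genes
            if self.n_genes is not None
            else self.genome_length // 2500
        )

    @property
    def ies_target(self) -> int:
        return (
            self.n_ies if self.n_ies is not None else self.genome_length // 1000
        )


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.seed])


def _random_bases(rng, n, gc) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return _BASE_CODES[codes].tobytes().decode()


@dataclass
class TruthRecord:
    scaffold: str
    p: int  # canonical MAC insertion point
    seq: str  # canonical TA-led sequence
    mic_start: int  # offset of seq within the germline (MIC) scaffold
    context: str = "unknown"

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_ies_record(self) -> IesRecord:
        return IesRecord(
            scaffold=self.scaffold, p=self.p, seq=self.seq, context=self.context
        )


@dataclass
class SimDataset:
    config: SimConfig
    mac: list[GenomeSequence]
    genes: list[GeneAnnotation]
    mic: list[GenomeSequence] = field(default_factory=list)
    truth: list[TruthRecord] = field(default_factory=list)

    def truth_by_scaffold(self) -> dict[str, list[TruthRecord]]:
        out: dict[str, list[TruthRecord]] = {}
        for t in self.truth:
            out.setdefault(t.scaffold, []).append(t)
        for lst in out.values():
            lst.sort(key=lambda t: t.mic_start)
        return out

    def write(self, outdir) -> None:
        from pathlib import Path

        from . import io as iio
        from .io import write_fasta, write_genes_gff3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.mac, outdir / "mac.fa")
        write_genes_gff3(self.genes, outdir / "genes.gff3")
        write_fasta(self.mic, outdir / "mic.fa")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("scaffold\tp\tlength\tmic_start\tcontext\tseq\n")
            for t in self.truth:
                fh.write(
                    f"{t.scaffold}\t{t.p}\t{t.length}\t{t.mic_start}\t"
                    f"{t.context}\t{t.seq}\n"
                )
        iio.write_ies_gff3(
            [t.as_ies_record() for t in self.truth],
            outdir / "truth_ies.gff3",
            genome=iio.genome_dict(self.mac),
        )


# ---------------------------------------------------------------------------
# MAC genome and gene models


def simulate_mac(cfg: SimConfig) -> SimDataset:
    """Random MAC scaffolds at the target G+C with non-overlapping genes."""
    rng = _rng(cfg, 1)
    per = cfg.genome_length // cfg.n_scaffolds
    mac = [
        GenomeSequence(f"scaffold_{i + 1}", _random_bases(rng, per, cfg.gc))
        for i in range(cfg.n_scaffolds)
    ]
    genes: list[GeneAnnotation] = []
    target = cfg.genes_target
    if target * 800 > cfg.genome_length * 0.9:
        raise ValueError("gene demand exceeds genome capacity")
    per_scaffold = [target // cfg.n_scaffolds] * cfg.n_scaffolds
    for i in range(target % cfg.n_scaffolds):
        per_scaffold[i] += 1
    gid = 0
    for rec, want in zip(mac, per_scaffold):
        cursor = 200
        made = 0
        while made < want and cursor < rec.length - 2200:
            n_exons = int(rng.integers(1, 4))
            exon_lens = rng.integers(300, 800, size=n_exons)
            intron_lens = rng.integers(20, 31, size=max(0, n_exons - 1))
            start = cursor
            exons = []
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if j < len(intron_lens):
                    pos += int(intron_lens[j])
            end = pos
            if end > rec.length - 200:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            intervals = [(s, e, "exon") for s, e in exons]
            intervals += [
                (e1, s2, "intron")
                for (s1, e1), (s2, e2) in zip(exons, exons[1:])
            ]
            # CDS == exons in this simple gene model; phases follow from
            # cumulative coding length
            phases = []
            acc = 0
            for s, e in exons:
                phases.append((3 - acc % 3) % 3)
                acc += e - s
            intervals += [(s, e, "CDS") for s, e in exons]
            intervals.sort()
            genes.append(
                GeneAnnotation(
                    gene_id=f"G{gid:05d}",
                    scaffold=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    intervals=tuple(intervals),
                    cds_phases=tuple(phases),
                )
            )
            made += 1
            cursor = end + int(rng.integers(100, 400))
    return SimDataset(config=cfg, mac=mac, genes=genes)


# ---------------------------------------------------------------------------
# IES planting


def _draw_length(cfg: SimConfig, rng) -> int:
    weights = cfg.peak_decay ** np.arange(cfg.n_peaks)
    if cfg.n_peaks > 1:
        weights = weights.copy()
        weights[1] *= cfg.second_peak_factor  # the forbidden second peak
    weights /= weights.sum()
    k = rng.choice(cfg.n_peaks, p=weights)
    length = int(round(rng.normal(cfg.first_peak + cfg.peak_spacing * k,
                                  cfg.peak_sd)))
    return max(cfg.min_len, length)


def _draw_element(cfg: SimConfig, rng, length: int) -> str:
    """TA-led element of ``length``+2 bases including both bounding TAs.

    The first and last 8 bases follow the end-consensus weight matrix (the
    right end as its reverse complement); the interior G+C is adjusted so
    the element's expected overall G+C equals the configured IES G+C.
    """
    total = length + 2
    left = "".join(
        _BASE_CODES[rng.choice(4, p=row)].tobytes().decode()
        for row in END_CONSENSUS_PWM
    )
    right_draw = "".join(
        _BASE_CODES[rng.choice(4, p=row)].tobytes().decode()
        for row in END_CONSENSUS_PWM
    )
    comp = str.maketrans("ACGT", "TGCA")
    right = right_draw.translate(comp)[::-1]
    n_middle = total - 16
    middle_gc = (cfg.ies_gc * total - 2 * _PWM_GC) / n_middle
    middle = _random_bases(rng, n_middle, min(1.0, max(0.0, middle_gc)))
    return left + middle + right


def plant_ies(dataset: SimDataset) -> SimDataset:
    """Insert IESs at existing MAC TA dinucleotides; returns a new dataset
    with germline (MIC) scaffolds and the canonical truth table."""
    cfg = dataset.config
    rng = _rng(cfg, 2)
    genome = {r.id: r.seq for r in dataset.mac}
    target = cfg.ies_target
    per_scaffold = _apportion(target, [r.length for r in dataset.mac])
    mic: list[GenomeSequence] = []
    truth: list[TruthRecord] = []
    for rec, want in zip(dataset.mac, per_scaffold):
        arr = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        ta = np.nonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))[0]
        ta = ta[(ta > cfg.end_margin) & (ta < rec.length - cfg.end_margin)]
        if len(ta) < want:
            raise ValueError(
                f"too few TA sites on {rec.id}: {len(ta)} < {want}"
            )
        chosen: list[int] = []
        occupied: dict[int, int] = {}
        for pos in rng.permutation(ta):
            b = int(pos) // cfg.min_spacing
            if any(
                abs(int(pos) - occupied[bb]) < cfg.min_spacing
                for bb in (b - 1, b, b + 1)
                if bb in occupied
            ):
                continue
            occupied[b] = int(pos)
            chosen.append(int(pos))
            if len(chosen) == want:
                break
        if len(chosen) < want:
            raise ValueError(f"could not place {want} IESs on {rec.id}")
        chosen.sort()
        pieces = []
        prev = 0
        offset = 0
        for pos in chosen:
            length = _draw_length(cfg, rng)
            element = _draw_element(cfg, rng, length)
            seq = element[:-2]  # trailing TA provided by the MAC
            canon = canonicalize(genome, rec.id, pos, seq)
            assert canon is not None  # TA-led at a MAC TA: always accepted
            pieces.append(rec.seq[prev:pos])
            pieces.append(seq)
            truth.append(
                TruthRecord(
                    scaffold=rec.id,
                    p=canon.p,
                    seq=canon.seq,
                    mic_start=canon.p + offset,
                )
            )
            offset += length
            prev = pos
        pieces.append(rec.seq[prev:])
        mic.append(GenomeSequence(rec.id, "".join(pieces)))
    out = replace(dataset)
    out.mic = mic
    out.truth = truth
    _fill_truth_contexts(out)
    return out


def _apportion(total, sizes):
    sizes = np.asarray(sizes, dtype=float)
    raw = total * sizes / sizes.sum()
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(raw - out))
    out[order[:rem]] += 1
    return out.tolist()


def _fill_truth_contexts(dataset: SimDataset) -> None:
    from .stats import classify_context

    by_scaffold: dict[str, list] = {}
    for g in dataset.genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for t in dataset.truth:
        rec = t.as_ies_record()
        ctx, _ = classify_context(rec, by_scaffold.get(t.scaffold, []))
        t.context = ctx


# ---------------------------------------------------------------------------
# reads


def simulate_reads_sam(dataset: SimDataset):
    """Error-free reads from the germline, aligned analytically to the MAC.

    Reads crossing an IES junction are soft-clipped on the junction side
    (anchored on the longer somatic match when they span a whole IES);
    reads fully inside an IES, or with less than ``min_anchor`` matching
    bases, are unmapped and skipped.  Yields SamAlignmentRecords sorted by
    scaffold then position.
    """
    cfg = dataset.config
    rng = _rng(cfg, 3)
    rl = cfg.read_length
    out = []
    truth_by = dataset.truth_by_scaffold()
    for rec in dataset.mic:
        trs = truth_by.get(rec.id, [])
        starts_ies = np.array([t.mic_start for t in trs], dtype=np.int64)
        ends_ies = starts_ies + np.array(
            [t.length for t in trs], dtype=np.int64
        )
        cum_before = np.concatenate(
            [[0], np.cumsum([t.length for t in trs])]
        )  # inserted bases before IES i / after IES i-1
        mac_p = starts_ies - cum_before[:-1]
        n_reads = int(round(cfg.coverage * rec.length / rl))
        read_starts = np.sort(rng.integers(0, rec.length - rl + 1, n_reads))
        for idx, a in enumerate(read_starts):
            a = int(a)
            b = a + rl
            i = int(np.searchsorted(ends_ies, a, side="right"))
            pos = cigar = None
            if i < len(starts_ies) and a >= starts_ies[i]:
                # read starts inside IES i
                if b <= ends_ies[i]:
                    continue  # fully internal: unmapped
                m2 = b - int(ends_ies[i])
                if m2 < cfg.min_anchor:
                    continue
                pos = int(mac_p[i])
                cigar = f"{rl - m2}S{m2}M"
            else:
                mac_a = a - int(cum_before[i])
                if i >= len(starts_ies) or b <= starts_ies[i]:
                    pos, cigar = mac_a, f"{rl}M"
                else:
                    m1 = int(starts_ies[i]) - a
                    if b <= ends_ies[i]:
                        if m1 < cfg.min_anchor:
                            continue
                        pos, cigar = mac_a, f"{m1}M{rl - m1}S"
                    else:
                        m2 = b - int(ends_ies[i])
                        if max(m1, m2) < cfg.min_anchor:
                            continue
                        if m1 >= m2:
                            pos, cigar = mac_a, f"{m1}M{rl - m1}S"
                        else:
                            pos, cigar = int(mac_p[i]), f"{rl - m2}S{m2}M"
            out.append(
                SamAlignmentRecord(
                    qname=f"r_{rec.id}_{idx}",
                    flag=0,
                    scaffold=rec.id,
                    pos=pos,
                    mapq=60,
                    cigar=cigar,
                )
            )
    out.sort(key=lambda r: (r.scaffold, r.pos))
    return out


# ---------------------------------------------------------------------------
# contigs


def simulate_contigs(dataset: SimDataset) -> list[GenomeSequence]:
    """Error-free germline contigs tiling each MIC scaffold."""
    cfg = dataset.config
    out = []
    for rec in dataset.mic:
        n = 0
        start = 0
        while start < rec.length:
            end = min(rec.length, start + cfg.contig_length)
            out.append(
                GenomeSequence(f"{rec.id}_ctg{n}", rec.seq[start:end])
            )
            n += 1
            if end == rec.length:
                break
            start += cfg.contig_step
    return out


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """simulate_mac + plant_ies in one call."""
    return plant_ies(simulate_mac(cfg))


# ---------------------------------------------------------------------------
# quartet histories


def simulate_quartet_counts(rho, s: float, n: int, seed: int) -> QuartetPatternCounts:
    """Forward-simulate ``n`` ancestral IES groups through the two WGDs.

    Each locus draws an acquisition cohort from ``rho``; survival is then
    simulated with explicit per-branch Bernoulli draws at the constant loss
    rate implied by ``s`` (an IES acquired at uniform time u within a
    period survives its remainder with probability s^(1-u)).  Loci lost in
    all four genes are discarded.
    """
    rho = np.asarray(rho, dtype=float)
    if not np.isclose(rho.sum(), 1.0):
        raise ValueError("rho must sum to 1")
    if not 0 < s <= 1:
        raise ValueError("s must be in (0, 1]")
    rng = np.random.default_rng([9, seed])
    if n == 0:
        return QuartetPatternCounts(0, 0, 0, 0, 0)
    cohort = rng.choice(3, size=n, p=rho)  # 0 -> g3, 1 -> g2, 2 -> g1
    u = rng.random(n)
    partial = s ** (1 - u)  # survival over the remainder of the period
    # branch-level survival through the inter-WGD period, then one draw per
    # terminal gene through the last period
    branch_a = rng.random(n) < s
    branch_b = rng.random(n) < s
    branch_partial = rng.random(n) < partial
    copies = rng.random((n, 4)) < s
    genes = np.zeros((n, 4), dtype=bool)
    g3 = cohort == 0
    genes[g3, 0] = branch_a[g3] & copies[g3, 0]
    genes[g3, 1] = branch_a[g3] & copies[g3, 1]
    genes[g3, 2] = branch_b[g3] & copies[g3, 2]
    genes[g3, 3] = branch_b[g3] & copies[g3, 3]
    g2 = cohort == 1
    genes[g2, 0] = branch_partial[g2] & copies[g2, 0]
    genes[g2, 1] = branch_partial[g2] & copies[g2, 1]
    g1 = cohort == 2
    genes[g1, 0] = branch_partial[g1]
    a = genes[:, 0].astype(int) + genes[:, 1]
    b = genes[:, 2].astype(int) + genes[:, 3]
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    return QuartetPatternCounts(
        int(np.sum((hi == 2) & (lo == 2))),
        int(np.sum((hi == 2) & (lo == 1))),
        int(np.sum((hi == 2) & (lo == 0))),
        int(np.sum((hi == 1) & (lo == 1))),
        int(np.sum((hi == 1) & (lo == 0))),
    )
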