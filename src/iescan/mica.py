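"""MICA: call IESs as TA-bounded insertions in germline contigs.

The pipeline compares germline-derived contigs to the somatic (MAC)
reference: contigs are filtered on G+C content, anchored to the reference by
unique k-mer chains, the gaps between anchors are realigned with an
affine-gap aligner, and an insertion is accepted as an IES iff it can be
placed (possibly after sliding within its tandem-ambiguity range) so that
the inserted sequence starts with TA and the MAC retains a TA at the
insertion point.  The accepted record is reported in leftmost-canonical
form, the convention also used for indel left-alignment.

Alignment scoring: match +2, mismatch -3, gap open -5, extend -2 (a gap of
length g costs 5 + 2g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .io import GenomeSequence, IesRecord

log = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2
MAX_REALIGN_LEN = 20_000


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    # Biopython charges the open score on the first gap column, so
    # open=-7/extend=-2 encodes cost 5+2g for a length-g gap.
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


# ---------------------------------------------------------------------------
# contig filtering


def gc_content(seq: str) -> float:
    """G+C over A+C+G+T (N ignored in the denominator)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def filter_contigs(contigs, max_gc: float = 0.5):
    """Keep contigs with average G+C strictly below ``max_gc``."""
    kept = []
    for c in contigs:
        if len(c.seq) == 0:
            log.warning("dropping zero-length contig %s", c.id)
            continue
        if gc_content(c.seq) < max_gc:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# anchor chaining


@dataclass
class AnchorChain:
    contig_id: str
    scaffold: str
    anchors: list[tuple[int, int, int]]  # (contig_start, ref_start, len)
    gaps: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )  # (ref interval, contig interval) between adjacent anchors


class KmerIndex:
    """Unique k-mer positions of a genome; ambiguous k-mers are dropped."""

    def __init__(self, genome, k: int = 21):
        self.k = k
        self.index: dict[str, tuple[str, int]] = {}
        ambiguous = set()
        for rec in genome:
            seq = rec.seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in ambiguous:
                    continue
                if kmer in self.index:
                    del self.index[kmer]
                    ambiguous.add(kmer)
                else:
                    self.index[kmer] = (rec.id, i)

    def lookup(self, kmer):
        return self.index.get(kmer)


def _longest_increasing_chain(matches):
    """Longest chain of (contig_pos, ref_pos) strictly increasing in both.

    Matches must be sorted by contig_pos; classic O(n log n) LIS on ref_pos.
    """
    import bisect

    tails: list[int] = []  # ref_pos of smallest tail for each length
    tails_idx: list[int] = []
    prev = [-1] * len(matches)
    for i, (_, r) in enumerate(matches):
        j = bisect.bisect_left(tails, r)
        if j == len(tails):
            tails.append(r)
            tails_idx.append(i)
        else:
            tails[j] = r
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(matches[i])
        i = prev[i]
    chain.reverse()
    return chain


def anchor_align_contig(
    contig: GenomeSequence, index: KmerIndex, step: int = 1
) -> AnchorChain | None:
    """Anchor a contig to the reference by its unique k-mer matches.

    Returns None (unmapped) when no unique anchors are found.  Contigs whose
    matches split over several scaffolds keep the scaffold with the most
    matches; near-ties (putative repeats) are skipped.
    """
    k = index.k
    if len(contig.seq) < k:
        return None
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    seen_in_contig: dict[str, int] = {}
    for i in range(0, len(contig.seq) - k + 1, step):
        kmer = contig.seq[i : i + k]
        seen_in_contig[kmer] = seen_in_contig.get(kmer, 0) + 1
        hit = index.lookup(kmer)
        if hit is not None:
            by_scaffold.setdefault(hit[0], []).append((i, hit[1]))
    # drop k-mers repeated within the contig itself
    for sc, lst in by_scaffold.items():
        by_scaffold[sc] = [
            (i, r)
            for i, r in lst
            if seen_in_contig[contig.seq[i : i + k]] == 1
        ]
    by_scaffold = {sc: lst for sc, lst in by_scaffold.items() if lst}
    if not by_scaffold:
        return None
    ranked = sorted(by_scaffold.items(), key=lambda kv: -len(kv[1]))
    if len(ranked) > 1 and len(ranked[1][1]) >= 0.8 * len(ranked[0][1]):
        log.info("contig %s: ambiguous multi-scaffold mapping, skipped", contig.id)
        return None
    scaffold, matches = ranked[0]
    matches.sort()
    chain = _longest_increasing_chain(matches)
    if not chain:
        return None
    # merge consecutive matches on the same diagonal into maximal anchors
    anchors: list[tuple[int, int, int]] = []
    for c, r in chain:
        if anchors:
            pc, pr, pl = anchors[-1]
            if c - pc == r - pr and c <= pc + pl:
                anchors[-1] = (pc, pr, c + k - pc)
                continue
            if c < pc + pl or r < pr + pl:
                # overlapping off-diagonal match; truncate previous anchor
                cut = max(0, min(pl, c - pc, r - pr))
                if cut == 0:
                    continue
                anchors[-1] = (pc, pr, cut)
        anchors.append((c, r, k))
    gaps = []
    for (c1, r1, l1), (c2, r2, _) in zip(anchors, anchors[1:]):
        gaps.append(((r1 + l1, r2), (c1 + l1, c2)))
    return AnchorChain(contig.id, scaffold, anchors, gaps)


# ---------------------------------------------------------------------------
# gap realignment


def realign_gap(ref_segment: str, contig_segment: str):
    """Global affine-gap alignment of two gap segments (with their flanks).

    Returns (alignment, insertion) where insertion is (ref_offset, seq) for
    the maximal contig-only run, or None when the alignment has no
    insertion.
    """
    if max(len(ref_segment), len(contig_segment)) > MAX_REALIGN_LEN:
        raise ValueError("gap segment exceeds realignment guard (20 kb)")
    aligner = make_aligner("global")
    aln = aligner.align(ref_segment, contig_segment)[0]
    ref_blocks, query_blocks = aln.aligned
    best = None  # (length, ref_offset, contig_start, contig_end)
    # contig-only runs are the gaps between consecutive aligned query blocks
    # with no reference advance
    prev_r_end = None
    prev_q_end = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        if prev_q_end is not None and qs > prev_q_end and rs == prev_r_end:
            length = qs - prev_q_end
            if best is None or length > best[0]:
                best = (length, rs, prev_q_end, qs)
        prev_r_end, prev_q_end = re_, qe
    if best is None:
        return aln, None
    _, ref_off, qs, qe = best
    return aln, (ref_off, contig_segment[qs:qe])


# ---------------------------------------------------------------------------
# boundary canonicalization


def enumerate_placements(mac: str, pos: int, ins: str):
    """All equivalent placements of inserting ``ins`` at ``pos`` in ``mac``.

    Two placements (p, s) and (p', s') are equivalent when they produce the
    same germline string mac[:p] + s + mac[p:].  Yields (p, seq) pairs in
    increasing p, including the input placement.
    """
    placements = {pos: ins}
    p, seq = pos, ins
    while p > 0 and mac[p - 1] == seq[-1]:
        seq = mac[p - 1] + seq[:-1]
        p -= 1
        placements[p] = seq
    p, seq = pos, ins
    while p < len(mac) and mac[p] == seq[0]:
        seq = seq[1:] + mac[p]
        p += 1
        placements[p] = seq
    return sorted(placements.items())


def adjust_ies_boundaries(genome: dict[str, str], scaffold: str, rough):
    """Accept a rough insertion as an IES iff a TA-bounded placement exists.

    ``rough`` is (ref_pos, inserted_seq).  Acceptance requires some
    equivalent placement (p, seq) with seq starting "TA" and the MAC
    retaining "TA" at p — i.e. germline = L + TA..seq.. + TA + R with
    MAC = L + TA + R.  The leftmost such placement is returned.

    Returns (IesRecord, None) on acceptance, (None, reason) otherwise.
    """
    ref_pos, ins = rough
    if not ins:
        return None, "empty insertion"
    mac = genome[scaffold]
    if not 0 <= ref_pos <= len(mac):
        raise ValueError(f"ref_pos {ref_pos} outside scaffold {scaffold}")
    for p, seq in enumerate_placements(mac, ref_pos, ins):
        if seq.startswith("TA") and mac[p : p + 2] == "TA":
            flags = set()
            if len(seq) < 26:
                flags.add("shorter_than_26")
            if "N" in seq:
                return None, "insertion overlaps N bases"
            return (
                IesRecord(
                    scaffold=scaffold, p=p, seq=seq, flags=frozenset(flags)
                ),
                None,
            )
    return None, "no TA-bounded placement"


def canonicalize(genome: dict[str, str], scaffold: str, pos: int, ins: str):
    """Leftmost TA-bounded placement of a known-valid insertion (or None)."""
    rec, _ = adjust_ies_boundaries(genome, scaffold, (pos, ins))
    return rec


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class MicaParams:
    max_gc: float = 0.5
    k: int = 21
    flank: int = 50
    anchor_step: int = 1
    min_insertion: int = 1


def call_ies(contigs, genome_records, params: MicaParams | None = None):
    """Run the full insertion-calling pipeline on germline contigs.

    filter_contigs -> anchor_align -> realign_gap -> adjust_ies_boundaries;
    duplicate calls at one (scaffold, p, seq) are merged with summed
    support.  Per-contig errors are logged, never fatal.
    """
    params = params or MicaParams()
    genome = {r.id: r.seq for r in genome_records}
    index = KmerIndex(genome_records, k=params.k)
    calls: dict[tuple[str, int, str], IesRecord] = {}
    for contig in filter_contigs(contigs, params.max_gc):
        try:
            chain = anchor_align_contig(contig, index, step=params.anchor_step)
        except Exception:  # pragma: no cover - defensive
            log.exception("contig %s failed anchoring", contig.id)
            continue
        if chain is None:
            log.info("contig %s unmapped", contig.id)
            continue
        mac = genome[chain.scaffold]
        for ref_iv, ctg_iv in chain.gaps:
            ref_lo, ref_hi = ref_iv
            ctg_lo, ctg_hi = ctg_iv
            if (ctg_hi - ctg_lo) - (ref_hi - ref_lo) < params.min_insertion:
                continue  # no net insertion in this gap
            f = params.flank
            if (
                ctg_lo < f
                or ctg_hi + f > len(contig.seq)
                or ref_lo < f
                or ref_hi + f > len(mac)
            ):
                # realignment needs a full anchored flank on each side;
                # overlapping contigs re-present edge-clipped gaps properly
                log.info(
                    "contig %s: gap too close to an edge for realignment",
                    contig.id,
                )
                continue
            ref_seg_lo = ref_lo - f
            ctg_seg_lo = ctg_lo - f
            ref_seg = mac[ref_seg_lo : ref_hi + f]
            ctg_seg = contig.seq[ctg_seg_lo : ctg_hi + f]
            try:
                _, insertion = realign_gap(ref_seg, ctg_seg)
            except ValueError:
                log.warning(
                    "contig %s: gap too large to realign, skipped", contig.id
                )
                continue
            if insertion is None:
                continue
            ref_off, ins = insertion
            rec, reason = adjust_ies_boundaries(
                genome, chain.scaffold, (ref_seg_lo + ref_off, ins)
            )
            if rec is None:
                log.info("contig %s: insertion rejected (%s)", contig.id, reason)
                continue
            key = rec.key()
            if key in calls:
                calls[key].support += 1
            else:
                calls[key] = rec
    out = sorted(calls.values(), key=lambda r: (r.scaffold, r.p, r.seq))
    return out


# ---------------------------------------------------------------------------
# TA-indel classification (excision errors)


@dataclass(frozen=True)
class TaIndel:
    scaffold: str
    pos: int
    seq: str
    kind: str  # residual | low_frequency
    boundary_class: str = "unclassified"


def classify_ta_indels(indels, ies_set, genome: dict[str, str]):
    """Classify TA-indels against the IES catalogue.

    exact_ies           the indel is a catalogued IES (same point, same seq)
    internal_alternative  a TA-bounded sub-segment of an IES sharing one
                          boundary TA (use of an internal alternative TA)
    external_alternative  one end on an IES boundary TA, the other at a MAC
                          TA outside the IES
    unrelated           anything else
    """
    by_scaffold: dict[str, list[IesRecord]] = {}
    for rec in ies_set:
        by_scaffold.setdefault(rec.scaffold, []).append(rec)
    out = []
    for scaffold, pos, seq, kind in indels:
        cls = "unrelated"
        mac = genome[scaffold]
        if not seq.startswith("TA"):
            if kind == "residual":
                log.warning(
                    "residual indel at %s:%d not TA-bounded", scaffold, pos
                )
            out.append(TaIndel(scaffold, pos, seq, kind, "unrelated"))
            continue
        for ies in by_scaffold.get(scaffold, []):
            if pos == ies.p and seq == ies.seq:
                cls = "exact_ies"
                break
            if pos == ies.p and len(seq) < len(ies.seq):
                # shares the left TA; internal iff the cut resumes at a TA
                m = len(seq)
                if ies.seq.startswith(seq) and ies.seq[m : m + 2] == "TA":
                    cls = "internal_alternative"
                    break
                # shares the right TA: seq equals a TA-led suffix of the IES
                m2 = len(ies.seq) - len(seq)
                if ies.seq.endswith(seq) and ies.seq[m2 : m2 + 2] == "TA":
                    cls = "internal_alternative"
                    break
            # external: left boundary TA shared, right end beyond the IES at
            # a MAC TA (seq = ies.seq + MAC[p : p+r] with TA following)
            if pos == ies.p and len(seq) > len(ies.seq) and seq.startswith(ies.seq):
                r = len(seq) - len(ies.seq)
                if (
                    seq[len(ies.seq) :] == mac[ies.p : ies.p + r]
                    and mac[ies.p + r : ies.p + r + 2] == "TA"
                ):
                    cls = "external_alternative"
                    break
            # external on the left: indel starts at an upstream MAC TA and
            # ends on the IES right boundary (seq = MAC[pos:ies.p] + ies.seq)
            if pos < ies.p and seq == mac[pos : ies.p] + ies.seq:
                if mac[pos : pos + 2] == "TA":
                    cls = "external_alternative"
                    break
        out.append(TaIndel(scaffold, pos, seq, kind, cls))
    return out
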