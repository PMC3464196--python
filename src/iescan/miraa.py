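"""MIRAA: flag candidate IES insertion sites from read-alignment anomalies.

A read that crosses a germline/somatic junction can only align partially on
the somatic (MAC) reference, so its alignment is soft-clipped at the
junction.  Positions with an excess of such clipped alignment ends — above a
threshold, away from scaffold edges, and outside high-coverage repeats — are
candidate IES insertion sites.  Only clipped terminations count: natural
read ends occur everywhere at depth-proportional rates and would swamp the
signal.

Note that both orientations pile on the same coordinate: a read entering the
insertion from the left aligns up to the insertion point p, and a read
leaving it on the right starts its alignment at p, so left- and right-clips
reinforce one another at p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BreakpointSite:
    scaffold: str
    pos: int  # 0-based
    end_count: int
    coverage: int
    has_TA: bool | None = None


@dataclass(frozen=True)
class MiraaParams:
    min_end_count: int = 15
    end_margin: int = 500
    max_coverage: int = 300
    min_end_fraction: float | None = None  # overrides min_end_count if set
    merge_distance: int = 2

    def __post_init__(self):
        if self.min_end_count <= 0 or self.end_margin <= 0 or self.max_coverage <= 0:
            raise ValueError("MIRAA thresholds must be positive")


def _scan_scaffold(length, starts, ends, left_clip, right_clip):
    """Per-position clip-end counts and coverage from parallel arrays."""
    clip_count = np.zeros(length + 1, dtype=np.int64)
    covdiff = np.zeros(length + 2, dtype=np.int64)
    np.add.at(covdiff, starts, 1)
    np.add.at(covdiff, ends, -1)
    if left_clip.any():
        np.add.at(clip_count, starts[left_clip], 1)
    if right_clip.any():
        np.add.at(clip_count, ends[right_clip], 1)
    coverage = np.cumsum(covdiff)[:length]
    return clip_count[:length], coverage


def detect_breakpoint_sites(alignments, genome, params: MiraaParams | None = None):
    """Emit breakpoint sites with an excess of clipped alignment ends.

    Parameters
    ----------
    alignments : iterable of SamAlignmentRecord
        Must be sorted by scaffold then mapped start.
    genome : dict scaffold -> sequence
    params : MiraaParams

    A site is emitted iff end_count > threshold, the position is more than
    ``end_margin`` from both scaffold ends, and local coverage is below
    ``max_coverage``.  Sites within ``merge_distance`` of each other are
    merged to the position of maximal end_count (leftmost on ties).
    """
    params = params or MiraaParams()
    per_scaffold: dict[str, list] = {}
    seen_order: list[str] = []
    last_scaffold, last_pos = None, -1
    for rec in alignments:
        if rec.is_unmapped:
            continue
        if rec.scaffold != last_scaffold:
            if rec.scaffold in per_scaffold:
                raise ValueError("alignments not sorted: scaffold revisited")
            per_scaffold[rec.scaffold] = []
            seen_order.append(rec.scaffold)
            last_scaffold, last_pos = rec.scaffold, -1
        if rec.pos < last_pos:
            raise ValueError(
                f"alignments not sorted at {rec.scaffold}:{rec.pos}"
            )
        last_pos = rec.pos
        ops = rec.cigar_ops()
        left = ops[0][1] == "S"
        right = ops[-1][1] == "S"
        per_scaffold[rec.scaffold].append((rec.pos, rec.end, left, right))

    # threshold possibly recomputed from observed mean coverage
    threshold = params.min_end_count
    if params.min_end_fraction is not None:
        total_bases = sum(
            sum(e - s for s, e, _, _ in recs) for recs in per_scaffold.values()
        )
        genome_len = sum(len(genome[sc]) for sc in per_scaffold if sc in genome)
        if genome_len:
            threshold = params.min_end_fraction * total_bases / genome_len

    sites = []
    for scaffold in seen_order:
        recs = per_scaffold[scaffold]
        if scaffold not in genome or not recs:
            continue
        length = len(genome[scaffold])
        arr = np.asarray([(s, e) for s, e, _, _ in recs], dtype=np.int64)
        left = np.asarray([l for _, _, l, _ in recs], dtype=bool)
        right = np.asarray([r for _, _, _, r in recs], dtype=bool)
        clip_count, coverage = _scan_scaffold(
            length, arr[:, 0], arr[:, 1], left, right
        )
        cand = np.nonzero(clip_count > threshold)[0]
        cand = cand[
            (cand > params.end_margin) & (length - cand > params.end_margin)
        ]
        cand = cand[coverage[cand] < params.max_coverage]
        # merge candidates within merge_distance: keep max end_count, leftmost tie
        merged = []
        group: list[int] = []
        for pos in cand:
            if group and pos - group[-1] > params.merge_distance:
                merged.append(group)
                group = []
            group.append(int(pos))
        if group:
            merged.append(group)
        for grp in merged:
            best = max(grp, key=lambda q: (clip_count[q], -q))
            sites.append(
                BreakpointSite(
                    scaffold=scaffold,
                    pos=best,
                    end_count=int(clip_count[best]),
                    coverage=int(coverage[best]),
                )
            )
    sites.sort(key=lambda s: (s.scaffold, s.pos))
    for s in sites:
        assert s.end_count > threshold
    return sites


def annotate_sites_with_ta(sites, genome):
    """Set has_TA: a TA dinucleotide starts at pos or pos-1 on the MAC."""
    out = []
    for s in sites:
        seq = genome[s.scaffold]
        lo = max(0, s.pos - 1)
        window = seq[lo : s.pos + 2]
        out.append(
            BreakpointSite(
                scaffold=s.scaffold,
                pos=s.pos,
                end_count=s.end_count,
                coverage=s.coverage,
                has_TA="TA" in window,
            )
        )
    return out


def ta_fraction(sites) -> float:
    """Fraction of annotated sites carrying a TA (summary statistic)."""
    annotated = [s for s in sites if s.has_TA is not None]
    if not annotated:
        return float("nan")
    return sum(s.has_TA for s in annotated) / len(annotated)
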