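"""IES conservation across whole-genome-duplication ohnologs, and clustering
of homologous IESs found at non-homologous genomic sites.

Two IESs in a pair of aligned ohnologous genes are called conserved when
their insertion points map to alignment columns at most 2 nt apart (the
tolerance absorbs boundary wobble from indel placement).  Homologous-IES
clustering replaces database E-value cutoffs with raw local-alignment score
thresholds, excludes pairs whose MAC flanks are themselves homologous
(segmental duplication of the site rather than element mobility), and takes
the transitive closure of the remaining similarity relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align

from .mica import make_aligner


# ---------------------------------------------------------------------------
# ohnolog pairs


@dataclass(frozen=True)
class OhnologPair:
    gene_a: str
    gene_b: str
    wgd: str  # recent | intermediate | old
    aligned_a: str  # aligned gene sequences with '-' gaps
    aligned_b: str

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global affine-gap alignment of two gene sequences (gapped strings)."""
    aligner = make_aligner("global")
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def position_to_column(aligned: str, pos: int) -> int:
    """Alignment column of the ``pos``-th ungapped base (0-based)."""
    if pos < 0:
        raise ValueError("negative position")
    seen = 0
    for col, ch in enumerate(aligned):
        if ch != "-":
            if seen == pos:
                return col
            seen += 1
    raise ValueError(f"position {pos} beyond sequence (length {seen})")


def column_to_position(aligned: str, col: int) -> int:
    """Number of ungapped bases strictly before ``col``."""
    return sum(1 for ch in aligned[:col] if ch != "-")


def conserved_pair(
    ies_a_pos: int, ies_b_pos: int, alignment: OhnologPair, tol: int = 2
) -> bool:
    """True when the two insertion points fall on alignment columns within
    ``tol`` of each other."""
    col_a = position_to_column(alignment.aligned_a, ies_a_pos)
    col_b = position_to_column(alignment.aligned_b, ies_b_pos)
    return abs(col_a - col_b) <= tol


# ---------------------------------------------------------------------------
# conservation table


def conservation_percentage(n_ies: int, n_conserved: int) -> float:
    """Percent conserved, rounded to 0.1 as reported."""
    if n_ies == 0:
        return 0.0
    return round(100.0 * n_conserved / n_ies, 1)


def conservation_table(rows):
    """Summary table from per-WGD counts.

    ``rows`` is an iterable of (wgd, genes_with_ohnolog, n_ies, n_conserved);
    the percent-conserved column is derived.  Returns a pandas DataFrame.
    """
    import pandas as pd

    out = []
    for wgd, n_genes, n_ies, n_cons in rows:
        out.append(
            dict(
                wgd=wgd,
                genes_with_ohnolog=n_genes,
                n_ies=n_ies,
                n_conserved=n_cons,
                pct_conserved=conservation_percentage(n_ies, n_cons),
            )
        )
    return pd.DataFrame(out)


def tabulate_conservation(pair_data, tol: int = 2):
    """Build the per-WGD conservation table from ohnolog pair data.

    ``pair_data`` is an iterable of (OhnologPair, ies_a_positions,
    ies_b_positions).  An IES counts as conserved when conserved_pair holds
    against at least one ohnolog.
    """
    per_wgd: dict[str, dict] = {}
    for pair, pos_a, pos_b in pair_data:
        acc = per_wgd.setdefault(
            pair.wgd, dict(genes=set(), n_ies=0, n_cons=0)
        )
        acc["genes"].update((pair.gene_a, pair.gene_b))
        for side, own, other in (
            ("a", pos_a, pos_b),
            ("b", pos_b, pos_a),
        ):
            for p in own:
                acc["n_ies"] += 1
                hit = any(
                    conserved_pair(p, q, pair, tol)
                    if side == "a"
                    else conserved_pair(q, p, pair, tol)
                    for q in other
                )
                acc["n_cons"] += bool(hit)
    rows = [
        (wgd, len(acc["genes"]), acc["n_ies"], acc["n_cons"])
        for wgd, acc in per_wgd.items()
    ]
    return conservation_table(rows)


# ---------------------------------------------------------------------------
# homologous-IES clustering


@dataclass
class IesCluster:
    members: list[str]
    pairwise_coverage: dict[tuple[str, str], float] = field(default_factory=dict)


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the dinucleotide distribution."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        counts[d] = counts.get(d, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )


def _local_best(aligner: Align.PairwiseAligner, a: str, b: str):
    if not a or not b:
        return 0.0, None
    aln = aligner.align(a, b)
    try:
        best = aln[0]
    except IndexError:
        return 0.0, None
    return float(best.score), best


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_homologous_ies(
    ies_entries,
    coverage: float = 0.85,
    min_score: float = 50.0,
    flank_score: float = 40.0,
    min_entropy: float = 1.5,
):
    """Cluster homologous IESs inserted at non-homologous sites.

    ``ies_entries`` maps IES id -> (seq, flank_left, flank_right); flanks are
    the MAC sequence (up to 500 nt) on each side of the insertion point.
    Two IESs are similar when their best local alignment covers at least
    ``coverage`` of the longer one with score >= ``min_score``; a pair is
    excluded when any flank-vs-flank local alignment reaches
    ``flank_score`` (homologous site, not an independent insertion).
    Low-complexity members (dinucleotide entropy < ``min_entropy``) are
    dropped up front.  Clusters are the transitive closure; only clusters of
    two or more are returned, sorted by member ids.
    """
    entries = {
        k: v
        for k, v in ies_entries.items()
        if dinucleotide_entropy(v[0]) >= min_entropy
    }
    aligner = make_aligner("local")
    ids = sorted(entries)
    uf = _UnionFind(ids)
    cov_record: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        seq_a, la, ra = entries[a]
        for b in ids[i + 1 :]:
            seq_b, lb, rb = entries[b]
            score, aln = _local_best(aligner, seq_a, seq_b)
            if aln is None or score < min_score:
                continue
            longer = max(len(seq_a), len(seq_b))
            blocks_a, blocks_b = aln.aligned
            span_a = blocks_a[-1][1] - blocks_a[0][0]
            span_b = blocks_b[-1][1] - blocks_b[0][0]
            span = span_a if len(seq_a) >= len(seq_b) else span_b
            cov = span / longer
            if cov < coverage:
                continue
            flank_hit = False
            for fa, fb in ((la, lb), (ra, rb), (la, rb), (ra, lb)):
                s, _ = _local_best(aligner, fa, fb)
                if s >= flank_score:
                    flank_hit = True
                    break
            if flank_hit:
                continue
            uf.union(a, b)
            cov_record[(a, b)] = cov
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(uf.find(x), []).append(x)
    clusters = [
        IesCluster(
            members=sorted(members),
            pairwise_coverage={
                k: v
                for k, v in cov_record.items()
                if k[0] in members and k[1] in members
            },
        )
        for members in groups.values()
        if len(members) >= 2
    ]
    clusters.sort(key=lambda c: c.members)
    return clusters
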