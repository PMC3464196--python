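"""Descriptive and inferential statistics on an IES catalogue.

Covers genomic context classification, base composition, the periodic size
distribution, the TA-end consensus logo (relative entropy against an AT-rich
background), the 3n/stop-codon selection test, IES density versus gene
expression, and positional uniformity along scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats as sps

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: stop codons by genetic code; ciliates (translation table 6) read TAA/TAG
#: as glutamine, leaving TGA as the only stop
STOP_CODONS = {"ciliate": {"TGA"}, "standard": {"TAA", "TAG", "TGA"}}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# context


def classify_context(ies, annotations):
    """Classify an IES by the interval containing its insertion point.

    Returns (context, gene_id) with context in {exon, intron, intergenic}.
    Intervals are half-open, so a point on an exon end boundary belongs to
    the following interval.
    """
    p = ies.p
    for gene in annotations:
        if gene.scaffold != ies.scaffold or not (gene.start <= p < gene.end):
            continue
        for s, e, kind in gene.intervals:
            if kind == "CDS":
                continue
            if s <= p < e:
                return kind, gene.gene_id
        return "intergenic", None  # inside gene bounds but unannotated gap
    return "intergenic", None


def annotate_contexts(ies_set, annotations):
    """Fill context/gene_id in place; returns the per-context fractions."""
    counts = {"exon": 0, "intron": 0, "intergenic": 0}
    by_scaffold: dict[str, list] = {}
    for g in annotations:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for rec in ies_set:
        ctx, gid = classify_context(rec, by_scaffold.get(rec.scaffold, []))
        rec.context = ctx
        rec.gene_id = gid
        counts[ctx] += 1
    n = max(1, len(list(ies_set)))
    return {k: v / n for k, v in counts.items()}


# ---------------------------------------------------------------------------
# composition


def composition(ies_set) -> dict:
    """Pooled G+C and length summary of an IES catalogue."""
    records = list(ies_set)
    if not records:
        raise ValueError("empty IES set")
    gc = at = 0
    lengths = np.array([r.length for r in records])
    for r in records:
        gc += r.seq.count("G") + r.seq.count("C")
        at += r.seq.count("A") + r.seq.count("T")
    return {
        "n": len(records),
        "gc": gc / (gc + at),
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
        "fraction_lt_150": float((lengths < 150).mean()),
    }


# ---------------------------------------------------------------------------
# size periodicity


@dataclass
class SizeHistogram:
    counts: np.ndarray  # counts per integer length over [min_len, max_len]
    min_len: int = 26
    max_len: int = 150

    @classmethod
    def from_lengths(cls, lengths, min_len: int = 26, max_len: int = 150):
        lengths = np.asarray(lengths)
        sel = lengths[(lengths >= min_len) & (lengths <= max_len)]
        counts = np.bincount(sel - min_len, minlength=max_len - min_len + 1)
        return cls(counts=counts, min_len=min_len, max_len=max_len)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)


@dataclass
class PeriodicityFit:
    period: float
    peak_positions: np.ndarray
    peak_indices: np.ndarray
    amplitude: float
    residual: float
    n_peaks: int
    first_peak_mass: float
    second_peak_ratio: float


def size_periodicity(
    hist: SizeHistogram, smooth_sigma: float = 1.5, min_peaks: int = 3
) -> PeriodicityFit:
    """Estimate the inter-peak spacing of a periodic size histogram.

    Counts are smoothed with a Gaussian kernel, local maxima detected, and
    the period taken as the least-squares slope of peak position on peak
    index.  Because the second peak of the distribution is heavily depleted
    and may escape detection, peak indices are inferred by rounding the
    distance to the first peak to the nearest multiple of the median
    inter-peak difference.
    """
    smoothed = ndimage.gaussian_filter1d(
        hist.counts.astype(float), smooth_sigma
    )
    # zero-pad so a peak on the truncated 26 bp edge keeps its prominence
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    prominence = max(5.0, 0.05 * smoothed.max())
    peaks, _ = signal.find_peaks(padded, prominence=prominence)
    peaks -= 1
    if len(peaks) < min_peaks:
        raise ValueError(
            f"insufficient periodic structure: {len(peaks)} peak(s) found"
        )
    positions = peaks + hist.min_len
    diffs = np.diff(positions)
    t0 = float(np.median(diffs))
    idx = np.round((positions - positions[0]) / t0).astype(int)
    # least-squares regression of position on inferred index
    slope, intercept = np.polyfit(idx, positions, 1)
    fitted = intercept + slope * idx
    residual = float(np.sqrt(np.mean((positions - fitted) ** 2)))
    if residual > 1.0:
        raise ValueError(
            "insufficient periodic structure: irregular peak spacing "
            f"(rms residual {residual:.2f} bp)"
        )
    # mass diagnostics
    total = hist.counts.sum()
    half = slope / 2
    first = positions[0]

    def window_mass(center):
        lo = int(np.floor(center - half)) - hist.min_len
        hi = int(np.ceil(center + half)) - hist.min_len
        return hist.counts[max(0, lo) : max(0, hi + 1)].sum()

    first_mass = window_mass(first) / total if total else 0.0
    second = window_mass(first + slope)
    neighbors = (window_mass(first) + window_mass(first + 2 * slope)) / 2
    second_ratio = float(second / neighbors) if neighbors else float("nan")
    return PeriodicityFit(
        period=float(slope),
        peak_positions=positions,
        peak_indices=idx,
        amplitude=float(smoothed[peaks].max()),
        residual=residual,
        n_peaks=len(peaks),
        first_peak_mass=float(first_mass),
        second_peak_ratio=second_ratio,
    )


# ---------------------------------------------------------------------------
# end-consensus logo


@dataclass
class ConsensusLogo:
    frequencies: pd.DataFrame  # positions x bases
    information: np.ndarray  # bits per position
    background: dict[str, float]
    n_sequences: int
    n_excluded: int = 0


def column_information(freqs, background) -> float:
    """Kullback-Leibler information (bits) of one logo column."""
    ic = 0.0
    for b, f in freqs.items():
        if f > 0:
            ic += f * np.log2(f / background[b])
    return ic


def end_logo(ies_set, n_positions: int = 8, gc: float = 0.28) -> ConsensusLogo:
    """Consensus logo of IES ends against a G+C-corrected background.

    Both ends are pooled: the left end of the TA-led element and the
    reverse complement of its right end (the element carries the retained
    TA appended, so both windows start with the invariant T, A).  The
    background is q(G)=q(C)=gc/2, q(A)=q(T)=(1-gc)/2.
    """
    background = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
                  "G": gc / 2, "C": gc / 2}
    counts = np.zeros((n_positions, 4))
    n_used = n_excluded = 0
    for rec in ies_set:
        element = rec.seq + "TA"  # both bounding TAs present
        if len(element) < 2 * n_positions:
            n_excluded += 1
            continue
        n_used += 1
        for window in (element[:n_positions], revcomp(element)[:n_positions]):
            for i, b in enumerate(window):
                if b in BASES:
                    counts[i, BASES.index(b)] += 1
    if n_used == 0:
        raise ValueError("no sequences long enough for the logo")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, columns=list(BASES),
                      index=np.arange(1, n_positions + 1))
    info = np.array(
        [
            column_information(dict(zip(BASES, row)), background)
            for row in freqs
        ]
    )
    return ConsensusLogo(
        frequencies=df,
        information=info,
        background=background,
        n_sequences=n_used,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# 3n / stop-codon bias


def classify_stop_in_frame(
    ies_seq: str,
    phase: int,
    flank_up: str = "",
    flank_down: str = "",
    code: str = "ciliate",
) -> str:
    """Classify a coding-sequence IES as stop_containing or stopless.

    ``phase`` is the offset of the insertion point within the current codon
    (0, 1 or 2), i.e. how many bases of that codon precede the IES.  All
    in-frame codons overlapping the retained IES are scanned, including the
    junction codons assembled from up to two flanking bases on each side.
    Under the ciliate code (translation table 6) only TGA is a stop.
    """
    if phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    stops = STOP_CODONS[code]
    if phase:
        lead = flank_up[len(flank_up) - phase :]
        if len(lead) < phase:
            # upstream flank missing: skip the first junction codon
            readthrough = ies_seq[3 - phase :]
        else:
            readthrough = lead + ies_seq
    else:
        readthrough = ies_seq
    tail = (-len(readthrough)) % 3
    if tail:
        down = flank_down[:tail]
        if len(down) < tail:
            # downstream flank missing: skip the last junction codon
            readthrough = readthrough[: len(readthrough) - len(readthrough) % 3]
        else:
            readthrough += down
    for i in range(0, len(readthrough) - 2, 3):
        if readthrough[i : i + 3] in stops:
            return "stop_containing"
    return "stopless"


@dataclass(frozen=True)
class BiasTestResult:
    category: str
    N: int
    n_3n: int
    n_non3n: int
    expected_3n: float
    expected_non3n: float
    chi2: float
    df: int
    p: float


def chi2_3n_bias(category_counts, null_counts, category: str = "") -> BiasTestResult:
    """Two-cell goodness-of-fit of 3n/non-3n counts against a null split.

    The expected counts are the observed total apportioned by the null
    (non-coding) 3n fraction; chi2 = sum (O-E)^2/E over the two cells with
    one degree of freedom and no continuity correction.
    """
    n3, nn = category_counts
    null3, nulln = null_counts
    if min(n3, nn, null3, nulln) < 0:
        raise ValueError("negative counts")
    N = n3 + nn
    null_total = null3 + nulln
    if N == 0 or null_total == 0:
        raise ValueError("empty category or null")
    e3 = N * null3 / null_total
    en = N * nulln / null_total
    chi2 = (n3 - e3) ** 2 / e3 + (nn - en) ** 2 / en
    p = float(sps.chi2.sf(chi2, df=1))
    return BiasTestResult(
        category=category,
        N=N,
        n_3n=n3,
        n_non3n=nn,
        expected_3n=e3,
        expected_non3n=en,
        chi2=float(chi2),
        df=1,
        p=p,
    )


# ---------------------------------------------------------------------------
# density vs expression


def density_by_expression(gene_table: pd.DataFrame, n_bins: int = 30):
    """IES density per expression bin (equal-count bins) and its OLS trend.

    ``gene_table`` needs columns gene_id, cds_kb, n_ies, expression.  Bin
    density is total IES count over total CDS kilobases in the bin; the
    slope is from an ordinary least-squares fit of density on bin rank.
    Returns (per-bin DataFrame, slope, intercept).
    """
    t = gene_table
    if t["expression"].nunique() < n_bins:
        raise ValueError(
            f"fewer than {n_bins} distinct expression values; "
            "use a smaller n_bins"
        )
    ranks = t["expression"].rank(method="first")
    bins = pd.qcut(ranks, n_bins, labels=False)
    grouped = t.groupby(bins).agg(
        n_ies=("n_ies", "sum"),
        cds_kb=("cds_kb", "sum"),
        mean_expression=("expression", "mean"),
    )
    grouped["density"] = grouped["n_ies"] / grouped["cds_kb"]
    grouped.index.name = "bin"
    x = np.arange(len(grouped))
    slope, intercept = np.polyfit(x, grouped["density"].to_numpy(), 1)
    return grouped.reset_index(), float(slope), float(intercept)


# ---------------------------------------------------------------------------
# positional uniformity


@dataclass(frozen=True)
class UniformityResult:
    verdict: str  # uniform | non_uniform | inconclusive
    statistic: float
    p: float
    n: int


def positional_uniformity(
    ies_positions, scaffold_length: int, alpha: float = 0.002
) -> UniformityResult:
    """One-sample KS test of IES positions against Uniform(0, L)."""
    positions = np.asarray(ies_positions, dtype=float)
    n = len(positions)
    if n < 10:
        return UniformityResult("inconclusive", float("nan"), float("nan"), n)
    res = sps.kstest(
        positions / scaffold_length, "uniform", mode="asymp"
    )
    verdict = "non_uniform" if res.pvalue < alpha else "uniform"
    return UniformityResult(verdict, float(res.statistic), float(res.pvalue), n)
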