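"""Quartet retention patterns and the maximum-likelihood IES gain/loss model.

A *quartet* is a gene family retained in four copies through two successive
whole-genome duplications (WGDs): the intermediate WGD split the ancestral
gene into two branches, and the recent WGD split each branch into a sibling
pair.  An IES group is the set of IESs found at one conserved position
across the four genes; its *pattern* records presence/absence, oriented so
that 1100 means both genes of one intermediate branch.

The gain/loss model assigns each ancestral IES to an acquisition cohort:

* g3 — extant at the intermediate WGD (the fraction absorbs survival
  through the pre-WGD period, which is not separately identifiable),
* g2 — acquired between the WGDs on one intermediate branch,
* g1 — acquired since the recent WGD on one terminal branch,

with a constant loss rate λ and equal period durations τ.  A full-period
survival is s = e^(−λτ); an IES acquired at a uniform time within a period
survives to its end with probability σ = (1−s)/(λτ) = (s−1)/ln s.  Cohort
fractions ρ3, ρ2, ρ1 are estimated by maximizing the multinomial likelihood
of the five observable patterns, conditioning on observation (a group is
observable only if at least one copy survives to the present).

The model is exposed statsmodels-style: ``GainLossModel(counts).fit()``
returns a :class:`GainLossResults` with estimates, standard errors and a
``summary()`` table; ``fit_gain_loss`` and ``lrt_all_ancient`` are thin
functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .conservation import conserved_pair

PATTERNS = ("1111", "1110", "1100", "1010", "1000")
COHORTS = ("g3", "g2", "g1")


@dataclass(frozen=True)
class QuartetPatternCounts:
    n1111: int
    n1110: int
    n1100: int
    n1010: int
    n1000: int

    def __post_init__(self):
        if min(self.as_array()) < 0:
            raise ValueError("negative pattern count")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.n1111, self.n1110, self.n1100, self.n1010, self.n1000],
            dtype=float,
        )

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


# ---------------------------------------------------------------------------
# model probabilities


def survival_sigma(s: float) -> float:
    """Mean survival to period end for a uniformly timed acquisition."""
    if not 0 < s <= 1:
        raise ValueError("s must be in (0, 1]")
    if s == 1.0:
        return 1.0
    return (s - 1.0) / np.log(s)


def pattern_probabilities(s: float):
    """Per-cohort probabilities of every pattern including 0000.

    For cohort g3 each intermediate branch independently ends with both
    terminal copies (s^3), exactly one (2 s^2 (1−s)), or none
    (q = 1−s + s(1−s)^2); the quartet pattern combines the two branches.
    Cohort g2 lives on a single branch with initial survival σ; cohort g1
    on a single terminal gene.  Each cohort's probabilities sum to one.
    """
    q = 1 - s + s * (1 - s) ** 2
    sig = survival_sigma(s)
    g3 = {
        "1111": s**6,
        "1110": 4 * s**5 * (1 - s),
        "1100": 2 * s**3 * q,
        "1010": 4 * s**4 * (1 - s) ** 2,
        "1000": 4 * s**2 * (1 - s) * q,
        "0000": q * q,
    }
    g2 = {
        "1111": 0.0,
        "1110": 0.0,
        "1100": sig * s**2,
        "1010": 0.0,
        "1000": 2 * sig * s * (1 - s),
        "0000": 1 - sig + sig * (1 - s) ** 2,
    }
    g1 = {
        "1111": 0.0,
        "1110": 0.0,
        "1100": 0.0,
        "1010": 0.0,
        "1000": sig,
        "0000": 1 - sig,
    }
    return {"g3": g3, "g2": g2, "g1": g1}


def observation_probabilities(s: float) -> np.ndarray:
    """P(at least one copy survives) per cohort (g3, g2, g1)."""
    q = 1 - s + s * (1 - s) ** 2
    sig = survival_sigma(s)
    return np.array([1 - q * q, sig * (1 - (1 - s) ** 2), sig])


def mixture_probabilities(s: float, weights) -> np.ndarray:
    """Observed-pattern distribution for conditional cohort weights.

    ``weights`` are the probabilities that an *observed* group belongs to
    each cohort (they sum to 1); the acquisition fractions ρ are recovered
    by dividing by the per-cohort observation probabilities.
    """
    per = pattern_probabilities(s)
    pobs = observation_probabilities(s)
    w = np.asarray(weights, dtype=float)
    out = np.zeros(len(PATTERNS))
    for j, cohort in enumerate(COHORTS):
        if pobs[j] <= 0:
            continue
        for i, pat in enumerate(PATTERNS):
            out[i] += w[j] * per[cohort][pat] / pobs[j]
    return out


def weights_to_rho(s: float, weights) -> np.ndarray:
    rho = np.asarray(weights, dtype=float) / observation_probabilities(s)
    return rho / rho.sum()


def rho_to_weights(s: float, rho) -> np.ndarray:
    w = np.asarray(rho, dtype=float) * observation_probabilities(s)
    return w / w.sum()


# ---------------------------------------------------------------------------
# pattern classification from quartet data


@dataclass(frozen=True)
class Quartet:
    """Four ohnologous genes: (a1, a2) and (b1, b2) are the recent-WGD
    sibling pairs on the two intermediate-WGD branches.  ``alignments`` maps
    unordered gene-id pairs to OhnologPair alignments; ``ies_positions``
    maps gene id to the positions of its IESs within the ungapped gene."""

    id: str
    a1: str
    a2: str
    b1: str
    b2: str
    alignments: dict
    ies_positions: dict

    @property
    def genes(self):
        return (self.a1, self.a2, self.b1, self.b2)


def _alignment_for(quartet, x, y):
    aln = quartet.alignments.get((x, y))
    if aln is not None:
        return aln, False
    aln = quartet.alignments.get((y, x))
    if aln is not None:
        return aln, True
    return None, False


def classify_quartet_patterns(quartets, tol: int = 2):
    """Group IESs by conserved position and tally retention patterns.

    IESs across the four genes of each quartet are linked when
    :func:`conserved_pair` holds for the corresponding gene-pair alignment;
    groups are connected components of that relation.  A group holding two
    IESs of the same gene is flagged ambiguous and excluded.  Patterns are
    oriented so that a group on one intermediate branch reads 1100/1000.
    Returns (QuartetPatternCounts, per-group label list).
    """
    tally = dict.fromkeys(PATTERNS, 0)
    labels = []
    for quartet in quartets:
        nodes = [
            (gene, pos)
            for gene in quartet.genes
            for pos in quartet.ies_positions.get(gene, ())
        ]
        adj = {n: set() for n in nodes}
        for i, (ga, pa) in enumerate(nodes):
            for gb, pb in nodes[i + 1 :]:
                if ga == gb:
                    continue
                aln, flipped = _alignment_for(quartet, ga, gb)
                if aln is None:
                    continue
                x, y = (pb, pa) if flipped else (pa, pb)
                if conserved_pair(x, y, aln, tol):
                    adj[(ga, pa)].add((gb, pb))
                    adj[(gb, pb)].add((ga, pa))
        seen = set()
        for start in nodes:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                n = stack.pop()
                comp.append(n)
                for m in adj[n]:
                    if m not in seen:
                        seen.add(m)
                        stack.append(m)
            genes_in = [g for g, _ in comp]
            if len(genes_in) != len(set(genes_in)):
                labels.append((quartet.id, "ambiguous"))
                continue
            present = set(genes_in)
            a = (quartet.a1 in present) + (quartet.a2 in present)
            b = (quartet.b1 in present) + (quartet.b2 in present)
            hi, lo = max(a, b), min(a, b)
            pattern = {
                (2, 2): "1111",
                (2, 1): "1110",
                (2, 0): "1100",
                (1, 1): "1010",
                (1, 0): "1000",
            }[(hi, lo)]
            tally[pattern] += 1
            labels.append((quartet.id, pattern))
    counts = QuartetPatternCounts(
        tally["1111"], tally["1110"], tally["1100"], tally["1010"], tally["1000"]
    )
    return counts, labels


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _softmax(z):
    z = np.concatenate([np.asarray(z, dtype=float), [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1 - p))


class GainLossModel:
    """Three-cohort multinomial gain/loss model for quartet IES patterns.

    Parameters
    ----------
    counts : QuartetPatternCounts or sequence of 5 ints
        Observed N1111, N1110, N1100, N1010, N1000.
    """

    def __init__(self, counts):
        if not isinstance(counts, QuartetPatternCounts):
            counts = QuartetPatternCounts(*counts)
        if counts.total < 1:
            raise ValueError("no observed patterns")
        self.counts = counts

    def loglike(self, s: float, weights) -> float:
        pr = mixture_probabilities(s, weights)
        c = self.counts.as_array()
        mask = c > 0
        if np.any(pr[mask] <= 0):
            return -np.inf
        return float(np.sum(c[mask] * np.log(pr[mask])))

    def _negll(self, theta):
        s = _expit(theta[0])
        w = _softmax(theta[1:])
        ll = self.loglike(s, w)
        return -ll if np.isfinite(ll) else 1e12

    def fit(self, tol: float = 1e-9) -> "GainLossResults":
        """Deterministic multi-start Nelder-Mead maximization."""
        c = self.counts.as_array()
        if np.count_nonzero(c) == 1:
            warnings.warn(
                "all counts in a single pattern: boundary estimate",
                RuntimeWarning,
            )
        best = None
        for s0 in (0.5, 0.8, 0.95):
            for a in (-1.0, 0.0, 1.0):
                for b in (-1.0, 0.0, 1.0):
                    res = optimize.minimize(
                        self._negll,
                        np.array([_logit(s0), a, b]),
                        method="Nelder-Mead",
                        options=dict(
                            xatol=1e-8, fatol=tol, maxiter=10_000
                        ),
                    )
                    if best is None or res.fun < best.fun:
                        best = res
        s_hat = _expit(best.x[0])
        w_hat = _softmax(best.x[1:])
        rho_hat = weights_to_rho(s_hat, w_hat)
        cov = self._theta_cov(best.x)
        return GainLossResults(
            model=self,
            params_internal=best.x.copy(),
            s=float(s_hat),
            weights=w_hat,
            rho=rho_hat,
            loglik=-float(best.fun),
            theta_cov=cov,
        )

    def _theta_cov(self, theta, eps: float = 1e-4):
        """Inverse observed information on the internal parameterization."""
        k = len(theta)
        hess = np.zeros((k, k))
        f0 = self._negll(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = eps
                ej[j] = eps
                fpp = self._negll(theta + ei + ej)
                fpm = self._negll(theta + ei - ej)
                fmp = self._negll(theta - ei + ej)
                fmm = self._negll(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
        try:
            return np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return np.full((k, k), np.nan)

    def fit_all_ancient(self):
        """Restricted fit: every IES predates the intermediate WGD."""

        def negll(z):
            s = _expit(z)
            ll = self.loglike(s, np.array([1.0, 0.0, 0.0]))
            return -ll if np.isfinite(ll) else 1e12

        res = optimize.minimize_scalar(
            negll, bounds=(-20, 20), method="bounded",
            options=dict(xatol=1e-12),
        )
        return float(_expit(res.x)), -float(res.fun)


@dataclass
class GainLossResults:
    """Estimates and diagnostics of a fitted gain/loss model."""

    model: GainLossModel
    params_internal: np.ndarray
    s: float
    weights: np.ndarray
    rho: np.ndarray
    loglik: float
    theta_cov: np.ndarray

    @property
    def sigma(self) -> float:
        return survival_sigma(self.s)

    @property
    def rho_percent(self) -> np.ndarray:
        return 100.0 * self.rho

    def rho_se(self, eps: float = 1e-5) -> np.ndarray:
        """Delta-method standard errors of the cohort fractions."""
        if not np.all(np.isfinite(self.theta_cov)):
            return np.full(3, np.nan)

        def rho_of(theta):
            return weights_to_rho(_expit(theta[0]), _softmax(theta[1:]))

        k = len(self.params_internal)
        jac = np.zeros((3, k))
        for i in range(k):
            e = np.zeros(k)
            e[i] = eps
            jac[:, i] = (
                rho_of(self.params_internal + e)
                - rho_of(self.params_internal - e)
            ) / (2 * eps)
        var = np.einsum("ij,jk,ik->i", jac, self.theta_cov, jac)
        return np.sqrt(np.clip(var, 0, None))

    def expected_counts(self) -> np.ndarray:
        pr = mixture_probabilities(self.s, self.weights)
        return pr * self.model.counts.total

    def lrt_all_ancient(self):
        """Likelihood-ratio test of H0: all IESs predate the intermediate WGD.

        Returns (statistic, df, p) with df = 2.
        """
        _, ll0 = self.model.fit_all_ancient()
        stat = max(0.0, 2 * (self.loglik - ll0))
        p = float(sps.chi2.sf(stat, df=2))
        return stat, 2, p

    def summary(self) -> str:
        se = self.rho_se()
        lines = [
            "Gain/loss model for quartet IES retention patterns",
            "=" * 52,
            f"observed groups: {self.model.counts.total}   "
            f"log-likelihood: {self.loglik:.3f}",
            f"full-period survival s     : {self.s:.4f}",
            f"partial-period survival σ  : {self.sigma:.4f}",
            "",
            "cohort   acquired                         ρ̂      s.e.",
        ]
        labels = (
            "before the intermediate WGD",
            "between the two WGDs       ",
            "since the recent WGD       ",
        )
        for name, label, r, e in zip(COHORTS, labels, self.rho, se):
            lines.append(f"{name}       {label}   {r:6.3f}   {e:.3f}")
        obs = self.model.counts.as_array().astype(int)
        exp = self.expected_counts()
        lines += ["", "pattern   observed   expected"]
        for pat, o, x in zip(PATTERNS, obs, exp):
            lines.append(f"{pat}      {o:8d}   {x:8.1f}")
        stat, df, p = self.lrt_all_ancient()
        lines += [
            "",
            f"LRT all-ancient (w2=w1=0): stat={stat:.2f}, df={df}, p={p:.3g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_gain_loss(counts):
    """Fit the gain/loss model; returns (ρ̂3, ρ̂2, ρ̂1, ŝ, loglik)."""
    res = GainLossModel(counts).fit()
    return (*res.rho, res.s, res.loglik)


def lrt_all_ancient(counts):
    """LRT of 'all IESs predate the intermediate WGD' vs the full model."""
    return GainLossModel(counts).fit().lrt_all_ancient()
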