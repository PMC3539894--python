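"""Coupling statistics.

The two bespoke randomization procedures used throughout the analysis:

* :func:`bin_permutation_test` — genes are cut into equally sized bins of
  an ordering covariate (proximal nucleosome occupancy); within each bin
  genes are split at the bin median of a second covariate (CRE) and the
  difference in mean outcome (plasticity or noise) between the two halves
  is contrasted with a within-bin permutation null (mean +/- 2 SD
  envelope).
* :func:`sliding_window` — genes are ordered by one variable (noise) and
  a second variable (translational efficiency, ribosome density, ORF
  length) is averaged in a window slid one gene at a time; the envelope
  comes from re-running the same analysis on globally shuffled data.

Plus thin, contract-checked wrappers around the standard two-sample and
contingency tests (Spearman, Fisher exact, Yates chi-square, KS,
rank-sum, Benjamini-Hochberg) so that every statistical call in the
pipeline goes through one audited surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "equal_size_bins", "bin_permutation_test", "BinPermutationResult",
    "sliding_window", "SlidingWindowResult",
    "spearman", "fisher_2x2", "chi2_2x2_yates",
    "group_location_tests", "bh_fdr",
]


# ---------------------------------------------------------------------------
# binned permutation analysis

def equal_size_bins(values, n_bins: int) -> np.ndarray:
    """Assign each element to one of ``n_bins`` contiguous rank bins.

    Elements are sorted ascending (stable in input order on ties) and
    split into contiguous groups whose sizes differ by at most one, the
    larger groups coming first.  Returns the bin index (0-based,
    increasing with value) per input element.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("equal_size_bins requires non-missing values")
    n = len(v)
    if n < n_bins:
        raise ValueError(f"cannot cut {n} values into {n_bins} bins")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    bins = np.empty(n, dtype=int)
    pos = 0
    for b, size in enumerate(sizes):
        bins[order[pos:pos + size]] = b
        pos += size
    return bins


@dataclass
class BinPermutationResult:
    """Per-bin observed median-split deltas with permutation envelopes."""

    bins: pd.DataFrame          # one row per bin
    n_bins: int
    n_perm: int
    seed: int
    envelope_sd: float = 2.0

    @property
    def significant(self) -> pd.Series:
        return self.bins["significant"]


def bin_permutation_test(binning_values, split_values, outcome_values,
                         n_bins: int = 10, n_perm: int = 10000,
                         seed: int = 0,
                         envelope_sd: float = 2.0) -> BinPermutationResult:
    """Binned median-split permutation test.

    Genes are restricted to complete cases of the three aligned vectors,
    cut into ``n_bins`` equally sized bins of ``binning_values``, and in
    each bin split at the within-bin median of ``split_values`` (values
    at the median go to the "below" side).  The observed statistic is
    mean(outcome | above) - mean(outcome | below); the null permutes the
    outcome within the bin.  A bin is significant when the observed delta
    lies outside null mean +/- ``envelope_sd`` null SD.
    """
    b = np.asarray(binning_values, dtype=float)
    s = np.asarray(split_values, dtype=float)
    o = np.asarray(outcome_values, dtype=float)
    if not (len(b) == len(s) == len(o)):
        raise ValueError("input vectors must be aligned")
    ok = ~(np.isnan(b) | np.isnan(s) | np.isnan(o))
    b, s, o = b[ok], s[ok], o[ok]
    bins = equal_size_bins(b, n_bins)
    rng = np.random.default_rng(seed)

    rows = []
    for k in range(n_bins):
        mask = bins == k
        bs, bo, bb = s[mask], o[mask], b[mask]
        med = float(np.median(bs))
        above = bs > med
        n_above, n_below = int(above.sum()), int((~above).sum())
        row = {"bin": k, "n": int(mask.sum()),
               "bin_low": float(bb.min()), "bin_high": float(bb.max()),
               "split_median": med, "n_above": n_above, "n_below": n_below}
        if n_above < 2 or n_below < 2:
            row.update(observed_delta=np.nan, null_mean=np.nan,
                       null_sd=np.nan, significant=False, degenerate=True)
            rows.append(row)
            continue
        delta = float(bo[above].mean() - bo[~above].mean())
        perm = rng.permuted(np.broadcast_to(bo, (n_perm, len(bo))).copy(), axis=1)
        d_null = perm[:, :n_above].mean(axis=1) - perm[:, n_above:].mean(axis=1)
        mu, sd = float(d_null.mean()), float(d_null.std(ddof=1))
        row.update(observed_delta=delta, null_mean=mu, null_sd=sd,
                   significant=bool(abs(delta - mu) > envelope_sd * sd),
                   degenerate=False)
        rows.append(row)

    return BinPermutationResult(bins=pd.DataFrame(rows), n_bins=n_bins,
                                n_perm=n_perm, seed=seed,
                                envelope_sd=envelope_sd)


# ---------------------------------------------------------------------------
# sliding-window randomization

@dataclass
class SlidingWindowResult:
    """Window-mean profile along an ordering with a shuffle envelope."""

    order: np.ndarray           # indices of input genes, sorted by order_values
    window_mean: np.ndarray     # one value per window start
    null_mean: np.ndarray
    null_sd: np.ndarray
    window_size: int
    n_perm: int
    seed: int

    @property
    def n_windows(self) -> int:
        return len(self.window_mean)

    def outside_envelope(self, envelope_sd: float = 2.0) -> np.ndarray:
        return np.abs(self.window_mean - self.null_mean) > envelope_sd * self.null_sd


def _window_means_exact(x: np.ndarray, w: int) -> np.ndarray:
    # per-window np.mean over a contiguous view: bit-identical to a direct
    # loop-and-mean computation, unlike cumulative-sum shortcuts
    return np.lib.stride_tricks.sliding_window_view(x, w).mean(axis=1)


def _window_means_fast(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def sliding_window(order_values, response_values, window_size: int = 100,
                   n_perm: int = 10000, seed: int = 0) -> SlidingWindowResult:
    """Sliding-window analysis with a global-shuffle null envelope.

    Genes are sorted by ``order_values`` ascending (stable on ties) and
    the mean of ``response_values`` is taken in every window of
    ``window_size`` consecutive genes (step 1).  The envelope repeats the
    identical analysis on ``n_perm`` global shuffles of the response and
    reports the per-position null mean and sample SD.
    """
    ov = np.asarray(order_values, dtype=float)
    rv = np.asarray(response_values, dtype=float)
    if len(ov) != len(rv):
        raise ValueError("input vectors must be aligned")
    ok = ~(np.isnan(ov) | np.isnan(rv))
    ov, rv = ov[ok], rv[ok]
    n = len(ov)
    if n < window_size:
        raise ValueError(f"need at least window_size={window_size} genes, got {n}")
    order = np.argsort(ov, kind="stable")
    sorted_resp = rv[order]
    observed = _window_means_exact(sorted_resp, window_size)

    rng = np.random.default_rng(seed)
    n_pos = n - window_size + 1
    s1 = np.zeros(n_pos)
    s2 = np.zeros(n_pos)
    for _ in range(n_perm):
        prof = _window_means_fast(rng.permutation(rv), window_size)
        s1 += prof
        s2 += prof * prof
    null_mean = s1 / n_perm
    var = (s2 - n_perm * null_mean ** 2) / (n_perm - 1)
    null_sd = np.sqrt(np.clip(var, 0.0, None))

    return SlidingWindowResult(order=order, window_mean=observed,
                               null_mean=null_mean, null_sd=null_sd,
                               window_size=window_size, n_perm=n_perm,
                               seed=seed)


# ---------------------------------------------------------------------------
# standard tests, contract-checked

def spearman(x, y):
    """Spearman rank correlation with pairwise deletion.

    Returns (rho, two-sided p, n complete pairs).  Average ranks on
    ties; p from the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    rho, p = sps.spearmanr(x[ok], y[ok])
    return float(rho), float(p), n


def _check_2x2(a, b, c, d):
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("all margins must be positive")
    return a, b, c, d


def fisher_2x2(a, b, c, d):
    """Two-sided Fisher exact test (minimum-likelihood method).

    Returns (odds_ratio, p).  The odds ratio is the unconditional sample
    estimate ad/bc (inf when bc = 0).
    """
    a, b, c, d = _check_2x2(a, b, c, d)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(odds), float(p)


def chi2_2x2_yates(a, b, c, d):
    """Pearson chi-square with Yates continuity correction, 1 df."""
    a, b, c, d = _check_2x2(a, b, c, d)
    stat, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=True)
    return float(stat), float(p)


def group_location_tests(values_a, values_b):
    """Two-sided KS and rank-sum p-values plus group means.

    Returns (ks_p, ranksum_p, mean_a, mean_b).  The rank-sum test is
    Wilcoxon/Mann-Whitney with average-rank tie handling.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    ks = sps.ks_2samp(a, b, alternative="two-sided")
    if np.ptp(np.concatenate([a, b])) == 0:
        ranksum_p = 1.0  # all observations tied: no evidence either way
    else:
        ranksum_p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return float(ks.pvalue), ranksum_p, float(a.mean()), float(b.mean())


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (missing p propagates)."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
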