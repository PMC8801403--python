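"""Conversion-tract statistics and the geometric tract-length model.

Given the reads x variants ternary call matrix, this module computes:

- the per-distance conversion-frequency profile (how often the variant at
  each distance from the double-strand break was incorporated),
- the conditional co-occurrence matrix P(variant j converted | variant i
  converted), which exposes the nested structure of conversion tracts
  (conversion of a far site implies conversion of nearer ones),
- clone recombination-rate reports with exact binomial confidence
  intervals, and
- a maximum-likelihood fit of a geometric tract-length model.

The tract model treats each sequenced molecule as carrying one conversion
tract of length L extending from the cut, incorporating exactly the
designed variants at distance <= L.  Under a geometric family with
per-nucleotide continuation probability p, the survival function is
S(d) = p**d, and each read contributes an interval-censored likelihood
S(d_far) - S(d_next), where d_far is its furthest converted distance
(S(0) = 1 when nothing converted) and d_next its nearest unconverted
distance (S = 0 when everything converted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .amplicon_analysis import AMBIGUOUS, CONVERTED, ReadCallMatrix, UNCONVERTED

logger = logging.getLogger(__name__)

_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # profile-likelihood drop


@dataclass
class ConversionProfile:
    """Per-variant conversion frequency ordered by tract distance."""

    table: pd.DataFrame  # variant_id, tract_distance, n_converted, n_called, frequency

    def frequency_at(self, variant_id: str) -> float:
        return float(self.table.set_index("variant_id").loc[variant_id, "frequency"])

    def min_frequency_below(self, max_distance_nt: float) -> float:
        """Minimum per-site frequency among variants closer than ``max_distance_nt``."""
        sub = self.table[self.table.tract_distance < max_distance_nt]
        sub = sub[sub.frequency.notna()]
        if sub.empty:
            raise ValueError(f"no called variants below {max_distance_nt} nt")
        return float(sub.frequency.min())

    def pooled_frequency_below(self, max_distance_nt: float) -> float:
        """Pooled conversion frequency (total converted / total called) below a distance."""
        sub = self.table[self.table.tract_distance < max_distance_nt]
        called = int(sub.n_called.sum())
        if called == 0:
            raise ValueError(f"no called variants below {max_distance_nt} nt")
        return float(sub.n_converted.sum() / called)


def conversion_profile(
    matrix: ReadCallMatrix, denominator: str = "called"
) -> ConversionProfile:
    """Fraction of reads carrying each designed variant, by tract distance.

    ``denominator='called'`` (default) divides by the non-ambiguous calls
    at each site, so truncated reads do not count as unconverted;
    ``denominator='total'`` divides by all QC-passing reads, reproducing a
    fixed-total convention.  A variant with zero non-ambiguous calls gets
    frequency NaN (undefined), never 0.
    """
    if denominator not in ("called", "total"):
        raise ValueError("denominator must be 'called' or 'total'")
    calls = matrix.calls
    if calls.empty:
        raise ValueError("empty call matrix")
    n_conv = (calls == CONVERTED).sum(axis=0)
    n_called = (calls != AMBIGUOUS).sum(axis=0)
    denom = n_called if denominator == "called" else pd.Series(
        len(calls), index=calls.columns
    )
    freq = n_conv / denom.where(denom > 0)
    table = pd.DataFrame(
        {
            "variant_id": calls.columns,
            "tract_distance": matrix.tract_distances.reindex(calls.columns).values,
            "n_converted": n_conv.values,
            "n_called": n_called.values,
            "frequency": freq.values,
        }
    ).sort_values("tract_distance", ignore_index=True)
    return ConversionProfile(table)


@dataclass
class CooccurrenceMatrix:
    """values[i, j] = P(variant j converted | variant i converted).

    Conditional frequencies are computed over reads where both calls are
    non-ambiguous; a row whose conditioning set is empty is NaN.
    """

    values: pd.DataFrame
    n_condition: pd.Series  # reads with variant i converted


def cooccurrence(matrix: ReadCallMatrix) -> CooccurrenceMatrix:
    calls = matrix.calls
    cols = list(calls.columns)
    k = len(cols)
    vals = np.full((k, k), np.nan)
    n_cond = np.zeros(k, dtype=int)
    arr = calls.to_numpy()
    conv = arr == CONVERTED
    ok = arr != AMBIGUOUS
    for i in range(k):
        n_cond[i] = int(conv[:, i].sum())
        for j in range(k):
            both = conv[:, i] & ok[:, j]
            n = int(both.sum())
            if n > 0:
                vals[i, j] = conv[both, j].sum() / n
    return CooccurrenceMatrix(
        values=pd.DataFrame(vals, index=cols, columns=cols),
        n_condition=pd.Series(n_cond, index=cols),
    )


@dataclass
class TractModelFit:
    """Geometric conversion-tract model fitted by interval-censored ML."""

    family: str
    p: float
    log_likelihood: float
    ci_low: float
    ci_high: float
    n_reads_used: int
    n_non_nested: int
    non_identifiable: bool = False

    def survival(self, d) -> np.ndarray:
        """S(d) = P(tract length >= d) = p**d."""
        return np.power(self.p, np.asarray(d, dtype=float))

    def mean_tract_nt(self) -> float:
        """Mean geometric tract length p/(1-p)."""
        return self.p / (1.0 - self.p)


def _read_intervals(
    matrix: ReadCallMatrix, non_nested: str = "exclude"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Collapse each read to its censoring interval [d_far, d_next).

    Returns (a, b) arrays where the read's tract length L satisfies
    a <= L < b, with a = furthest converted distance (0 if none) and
    b = nearest unconverted distance (inf if none).  Reads whose pattern is
    not nested (an unconverted site nearer than a converted one) are
    excluded (default) or an error, per ``non_nested``; their count is
    returned either way.
    """
    if non_nested not in ("exclude", "error"):
        raise ValueError("non_nested must be 'exclude' or 'error'")
    dist = matrix.tract_distances.reindex(matrix.calls.columns).to_numpy(dtype=float)
    arr = matrix.calls.to_numpy()
    a_list, b_list = [], []
    n_bad = 0
    for row in arr:
        conv_d = dist[row == CONVERTED]
        unconv_d = dist[row == UNCONVERTED]
        if conv_d.size == 0 and unconv_d.size == 0:
            continue  # fully ambiguous read carries no information
        a = conv_d.max() if conv_d.size else 0.0
        b = unconv_d.min() if unconv_d.size else np.inf
        if b <= a:
            n_bad += 1
            if non_nested == "error":
                raise ValueError("non-nested conversion pattern encountered")
            continue
        a_list.append(a)
        b_list.append(b)
    if n_bad:
        logger.info("excluded %d non-nested reads from tract-model fit", n_bad)
    return np.asarray(a_list), np.asarray(b_list), n_bad


def fit_tract_model(
    matrix: ReadCallMatrix,
    family: str = "geometric",
    non_nested: str = "exclude",
    tol: float = 1e-12,
) -> TractModelFit:
    """Maximum-likelihood geometric tract-length parameter with profile CI.

    Each read contributes log(p**a - p**b) for its censoring interval
    [a, b).  The 95% confidence interval is the profile-likelihood set
    {p : loglik(p) >= loglik(p_hat) - chi2(1, 0.95)/2}.  A dataset where
    the optimum sits at a boundary (e.g. a single distance with every read
    converted) is flagged non-identifiable.
    """
    if family != "geometric":
        raise ValueError(f"unknown tract model family {family!r}")
    a, b, n_bad = _read_intervals(matrix, non_nested=non_nested)
    if a.size == 0:
        raise ValueError("no informative reads for tract-model fitting")
    if np.unique(np.concatenate([a[a > 0], b[np.isfinite(b)]])).size < 1:
        raise ValueError("no finite censoring bounds; model not identifiable")

    # aggregate identical intervals: likelihood only depends on counts
    pairs, counts = np.unique(np.column_stack([a, b]), axis=0, return_counts=True)
    pa, pb = pairs[:, 0], pairs[:, 1]

    def negloglik(p: float) -> float:
        if not 0.0 < p < 1.0:
            return np.inf
        term = np.power(p, pa) - np.power(p, pb)  # p**inf == 0 for p < 1
        if np.any(term <= 0):
            return np.inf
        return -float(np.sum(counts * np.log(term)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(1e-12, 1 - 1e-12), method="bounded",
        options={"xatol": tol},
    )
    p_hat = float(res.x)
    ll_max = -float(res.fun)
    eps = 1e-9
    non_ident = p_hat > 1 - 1e-6 or p_hat < 1e-6 or not np.isfinite(ll_max)

    thresh = ll_max - _CHI2_95_HALF

    def drop(p: float) -> float:
        return -negloglik(p) - thresh

    ci_low, ci_high = 0.0, 1.0
    if not non_ident:
        if drop(eps) < 0:
            ci_low = float(optimize.brentq(drop, eps, p_hat, xtol=1e-10))
        if drop(1 - eps) < 0:
            ci_high = float(optimize.brentq(drop, p_hat, 1 - eps, xtol=1e-10))
    else:
        logger.warning("tract-model fit hit the parameter boundary (p=%.6g)", p_hat)

    return TractModelFit(
        family=family,
        p=p_hat,
        log_likelihood=ll_max,
        ci_low=ci_low,
        ci_high=ci_high,
        n_reads_used=int(a.size),
        n_non_nested=n_bad,
        non_identifiable=bool(non_ident),
    )


@dataclass
class CloneReport:
    """Recombination rate among genotyped clones with an exact binomial CI."""

    n_positive: int
    n_total: int
    rate_percent: float
    rate_percent_rounded: float  # one decimal, half-up ("21/24 -> 87.5")
    ci_low_percent: float
    ci_high_percent: float
    rate_exact: Fraction = field(repr=False, default=Fraction(0))


def clone_report(n_positive: int, n_total: int) -> CloneReport:
    """Percentage of recombination-positive clones with a Clopper-Pearson 95% CI.

    The percentage is computed in exact rational arithmetic and rounded
    half-up to one decimal for reporting (21/24 -> 87.5, 10/24 -> 41.7).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    exact = Fraction(100 * n_positive, n_total)
    rounded = float(
        (Decimal(100 * n_positive) / Decimal(n_total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    k, n = n_positive, n_total
    low = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return CloneReport(
        n_positive=k,
        n_total=n,
        rate_percent=float(exact),
        rate_percent_rounded=rounded,
        ci_low_percent=100 * low,
        ci_high_percent=100 * high,
        rate_exact=exact,
    )
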