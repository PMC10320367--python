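"""Agreement and validity statistics for multi-reader ordinal scores.

Implements the validation toolkit used for central-reading studies of
endoscopic indices:

* Spearman rank correlation with a Fisher-z confidence interval using the
  Bonett-Wright standard error ``sqrt((1 + rho^2/2) / (n - 3))`` (a
  Fieller-Hartley-Pearson variant is available behind a flag), with a 0.6
  meaningfulness threshold.
* One-way random-effects intraclass correlation (video as the random effect;
  a fully crossed two-way design does not exist when reader pairs rotate over
  a pool), estimated by the ANOVA method of moments on balanced tables and by
  REML on unbalanced ones, with the exact F confidence interval for balanced
  data and a Satterthwaite-style approximation otherwise.  Reliability bands:
  <0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good, >0.90 excellent.
* Weighted Cohen kappa (linear or quadratic weights) with the
  Fleiss-Cohen-Everitt large-sample variance, plus inverse-variance pooling
  over reader pairs.  Agreement bands: 0.41-0.60 moderate, 0.61-0.80 good,
  >0.80 very good.
* Inverse-variance-weighted pooling of stratum-level mean differences.

Missing data are handled complete-case per analysis; no multiplicity
correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPEARMAN_THRESHOLD = 0.6
POOLED = "POOLED"


class ReliabilityError(ValueError):
    """Raised when a statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# Spearman correlation


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    stratum_label: str = "overall"

    @property
    def meets_threshold(self) -> bool:
        return self.rho >= SPEARMAN_THRESHOLD


def spearman_ci(
    x: Sequence[float],
    y: Sequence[float],
    stratum_label: str = "overall",
    alpha: float = 0.05,
    se_method: str = "bonett",
) -> CorrelationResult:
    """Average-rank Spearman rho with a Fisher-z confidence interval.

    ``se_method="bonett"`` uses the Bonett-Wright standard error
    ``sqrt((1 + rho^2/2)/(n-3))``; ``"fieller"`` uses ``sqrt(1.06/(n-3))``.
    Pairs with a missing value in either vector are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ReliabilityError(f"need n >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ReliabilityError("undefined correlation: zero variance in a score vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if se_method == "bonett":
        se = np.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
    elif se_method == "fieller":
        se = np.sqrt(1.06 / (n - 3))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    zcrit = stats.norm.ppf(1 - alpha / 2)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(rho=rho, ci_low=float(lo), ci_high=float(hi), n=int(n),
                             stratum_label=stratum_label)


def change_score_correlation(pre_post: pd.DataFrame, alpha: float = 0.05) -> CorrelationResult:
    """Spearman correlation of per-patient change scores of the two indices.

    ``pre_post`` needs columns ``sema_pre, sema_post, ses_pre, ses_post``;
    patients missing any of the four are dropped (complete case).
    """
    cols = ["sema_pre", "sema_post", "ses_pre", "ses_post"]
    t = pre_post.dropna(subset=cols)
    d_sema = t["sema_post"].to_numpy(float) - t["sema_pre"].to_numpy(float)
    d_ses = t["ses_post"].to_numpy(float) - t["ses_pre"].to_numpy(float)
    return spearman_ci(d_sema, d_ses, stratum_label="change", alpha=alpha)


# ---------------------------------------------------------------------------
# Intraclass correlation (one-way random effects)

ICC_BANDS = (("poor", -np.inf, 0.50), ("moderate", 0.50, 0.75),
             ("good", 0.75, 0.90 + 1e-12), ("excellent", 0.90 + 1e-12, np.inf))


def icc_band(icc: float) -> str:
    """<0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90] good, >0.90 excellent."""
    for label, lo, hi in ICC_BANDS:
        if lo <= icc < hi:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    variance_between: float
    variance_within: float
    n_groups: int
    n_obs: int
    method: str

    @property
    def band(self) -> str:
        return icc_band(self.icc)


def _anova_components(groups: list) -> Tuple[float, float, float, float, float]:
    """One-way ANOVA mean squares and effective group size n0 (Searle)."""
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - np.sum(ns**2) / N) / (k - 1)
    return msb, msw, float(n0), float(N), float(k)


def icc_oneway(
    table: pd.DataFrame,
    group_col: str = "video_id",
    score_col: str = "score",
    alpha: float = 0.05,
) -> IccResult:
    """ICC(1) from a long (group, score) table with >=2 scores for some groups.

    Groups with a single observation are dropped (they carry no within-group
    information for ICC(1) beyond the grand mean and would otherwise make the
    moment estimator needlessly noisy on small panels).  Balanced tables use
    the ANOVA method of moments with the exact F interval
    ``(F/Fu - 1)/(F/Fu + n - 1)``; unbalanced tables use REML variance
    components with a Satterthwaite-style F interval on the ANOVA mean
    squares (effective group size n0).
    """
    t = table[[group_col, score_col]].dropna()
    sizes = t.groupby(group_col)[score_col].size()
    keep = sizes[sizes >= 2].index
    if len(keep) < 2:
        raise ReliabilityError("ICC needs >= 2 groups with >= 2 scores each")
    t = t[t[group_col].isin(keep)]
    groups = [g.to_numpy(float) for _, g in t.groupby(group_col)[score_col]]
    msb, msw, n0, N, k = _anova_components(groups)
    balanced = len({g.size for g in groups}) == 1

    if balanced:
        sigma_w = msw
        sigma_b = max(0.0, (msb - msw) / n0)
        method = "anova"
    else:
        sigma_b, sigma_w = _reml_components(t, group_col, score_col)
        if sigma_b is None:  # REML failure: fall back to moments
            sigma_w = msw
            sigma_b = max(0.0, (msb - msw) / n0)
            method = "anova"
        else:
            method = "reml"
    denom = sigma_b + sigma_w
    icc = 0.0 if denom == 0 else max(0.0, sigma_b / denom)

    # F-based interval; exact for balanced designs, Satterthwaite-style via
    # n0 for unbalanced ones.
    if msw == 0.0:
        lo = hi = 1.0 if msb > 0 else 0.0
    else:
        f = msb / msw
        df1, df2 = k - 1, N - k
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + n0 - 1)
        hi = (fu - 1) / (fu + n0 - 1)
        lo, hi = float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
    return IccResult(
        icc=float(icc),
        ci_low=lo,
        ci_high=hi,
        variance_between=float(sigma_b),
        variance_within=float(sigma_w),
        n_groups=int(k),
        n_obs=int(N),
        method=method,
    )


def _reml_components(t, group_col, score_col):
    from statsmodels.regression.mixed_linear_model import MixedLM

    endog = t[score_col].to_numpy(float)
    exog = np.ones((endog.size, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = MixedLM(endog, exog, groups=t[group_col].to_numpy()).fit(reml=True)
        except Exception:  # pragma: no cover - rare optimizer failure
            return None, None
    return float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale)


# ---------------------------------------------------------------------------
# Weighted Cohen kappa

KAPPA_BANDS = (("below_moderate", -np.inf, 0.41), ("moderate", 0.41, 0.61),
               ("good", 0.61, 0.80 + 1e-12), ("very_good", 0.80 + 1e-12, np.inf))


def kappa_band(kappa: float) -> str:
    """0.41-0.60 moderate, 0.61-0.80 good, >0.80 very good, else below_moderate."""
    for label, lo, hi in KAPPA_BANDS:
        if lo <= kappa < hi:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class KappaResult:
    reader_pair: Tuple[str, str]
    kappa: float
    ci_low: float
    ci_high: float
    variance: float
    n: int
    weight_scheme: str

    @property
    def band(self) -> str:
        return kappa_band(self.kappa)


def _agreement_weights(k: int, scheme: str) -> np.ndarray:
    i = np.arange(k)[:, None]
    j = np.arange(k)[None, :]
    d = np.abs(i - j) / (k - 1) if k > 1 else np.zeros((1, 1))
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    categories: Sequence,
    scheme: str = "linear",
    reader_pair: Tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> KappaResult:
    """Weighted Cohen kappa with its large-sample confidence interval.

    Disagreement weights are ``|i-j|/(k-1)`` (linear) or the square of that
    (quadratic); kappa = 1 - sum(w*observed)/sum(w*expected) with expected
    cell proportions from the marginal products.  The variance is the
    Fleiss-Cohen-Everitt large-sample form and the CI is normal on kappa.
    """
    cats = list(categories)
    idx = {c: i for i, c in enumerate(cats)}
    a = np.array([idx[v] for v in ratings_a])
    b = np.array([idx[v] for v in ratings_b])
    if a.size != b.size:
        raise ReliabilityError("rating vectors must have equal length")
    n = a.size
    if n == 0:
        raise ReliabilityError("empty rating vectors")
    k = len(cats)
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    p = counts / n
    pa = p.sum(axis=1)  # marginal of rater a (rows)
    pb = p.sum(axis=0)
    v = _agreement_weights(k, scheme)
    po = float(np.sum(v * p))
    pe = float(np.sum(v * np.outer(pa, pb)))
    if 1.0 - pe < 1e-12:
        raise ReliabilityError("undefined kappa: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance of weighted kappa.
    vbar_row = v @ pb  # E over b's marginal, per row category
    vbar_col = pa @ v
    term = (v * (1 - pe) - (vbar_row[:, None] + vbar_col[None, :]) * (1 - po)) ** 2
    var = (np.sum(p * term) - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    var = float(max(var, 0.0))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(var)
    return KappaResult(
        reader_pair=tuple(reader_pair),
        kappa=float(kappa),
        ci_low=float(kappa - half),
        ci_high=float(min(kappa + half, 1.0)),
        variance=var,
        n=int(n),
        weight_scheme=scheme,
    )


def pool_kappas(pair_results: Sequence[KappaResult], alpha: float = 0.05) -> KappaResult:
    """Inverse-variance-weighted pooled kappa over reader pairs.

    Pairs with zero variance (perfect agreement at every video) carry
    infinite weight; when present, the pool reduces to the mean of those
    exact pairs.
    """
    results = list(pair_results)
    if not results:
        raise ReliabilityError("no pairwise kappa results to pool")
    if len(results) == 1:
        return results[0]
    scheme = results[0].weight_scheme
    exact = [r for r in results if r.variance == 0.0]
    if exact:
        kap = float(np.mean([r.kappa for r in exact]))
        return KappaResult((POOLED, POOLED), kap, kap, kap, 0.0,
                           sum(r.n for r in exact), scheme)
    finite = [r for r in results if np.isfinite(r.variance)]
    if not finite:
        raise ReliabilityError("all pairwise kappa variances are infinite")
    w = np.array([1.0 / r.variance for r in finite])
    kap = float(np.sum(w * [r.kappa for r in finite]) / w.sum())
    var = 1.0 / float(w.sum())
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(var)
    return KappaResult(
        reader_pair=(POOLED, POOLED),
        kappa=kap,
        ci_low=kap - half,
        ci_high=min(kap + half, 1.0),
        variance=var,
        n=sum(r.n for r in finite),
        weight_scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Pooled mean differences


@dataclass(frozen=True)
class PooledDifference:
    mean_diff: float
    ci_low: float
    ci_high: float
    strata: tuple  # of (label, mean, variance_of_mean, n)


def pooled_mean_difference(strata: Sequence[Tuple[str, Sequence[float]]],
                           alpha: float = 0.05) -> PooledDifference:
    """Inverse-variance-weighted average of stratum-level mean differences.

    Each stratum supplies a vector of paired differences (fixed sign
    convention: first reader minus second reader of the pair).  Strata with
    fewer than two differences are dropped with a warning (their variance is
    not estimable).  Zero-variance strata (identical reads throughout) carry
    infinite weight and collapse the pool to their mean.
    """
    rows = []
    for label, diffs in strata:
        d = np.asarray(list(diffs), dtype=float)
        d = d[~np.isnan(d)]
        if d.size < 2:
            logger.warning("stratum %r dropped: n=%d < 2", label, d.size)
            continue
        rows.append((str(label), float(d.mean()), float(d.var(ddof=1) / d.size), int(d.size)))
    if not rows:
        raise ReliabilityError("no stratum has enough differences to pool")
    exact = [r for r in rows if r[2] == 0.0]
    if exact:
        m = float(np.mean([r[1] for r in exact]))
        return PooledDifference(m, m, m, tuple(rows))
    w = np.array([1.0 / r[2] for r in rows])
    m = float(np.sum(w * [r[1] for r in rows]) / w.sum())
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(float(w.sum()))
    return PooledDifference(m, m - half, m + half, tuple(rows))
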