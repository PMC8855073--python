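"""Per-gene moderated differential expression for two-group contrasts.

The model: each gene's log2-normalized expression is compared between a
knockout group and its control with an ordinary pooled two-sample linear
model, then the per-gene residual variances are shrunk toward a global prior
estimated across genes (empirical Bayes, scaled-F model for the variances).
The moderated t-statistic uses the posterior variance and gains the prior
degrees of freedom:

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)
    t_mod   = beta / (sqrt(s2_post) * u),   df_total = d0 + df

with ``u = sqrt(1/n_ko + 1/n_ctrl)`` the unscaled standard deviation of the
group-difference estimator. Two-sided p-values come from the t distribution
with ``df_total`` degrees of freedom and are Benjamini-Hochberg adjusted
within the contrast's gene family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

#: cap used for the prior degrees of freedom when the observed spread of
#: log-variances is at or below the value implied by d0 -> infinity
D0_CAP = 1e6


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the count-matrix contract: unique ids, nonnegative integers."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    vals = counts.to_numpy()
    if np.any(vals < 0):
        raise ValueError("counts must be nonnegative")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integral")


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-group map plus the (knockout, control) contrast of interest."""

    groups: dict  # sample id -> group label
    contrast: tuple  # (knockout group, control group)

    def samples_in(self, group: str) -> list:
        return [s for s, g in self.groups.items() if g == group]

    def validate(self, counts: pd.DataFrame) -> None:
        missing = [s for s in self.groups if s not in counts.columns]
        if missing:
            raise ValueError(f"samples not in count matrix: {missing}")
        for g in self.contrast:
            if len(self.samples_in(g)) < 2:
                raise ValueError(f"contrast group {g!r} has fewer than 2 samples")


@dataclass
class NormalizedMatrix:
    """Gene x sample log2 expression with the size factors that produced it."""

    values: pd.DataFrame
    size_factors: pd.Series
    prior_count: float
    method: str


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValueError("require d0 >= 0 and s0_sq > 0")


@dataclass(frozen=True)
class DECallConfig:
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.5  # linear scale
    exclude_genes: tuple = ()

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")


def normalize_counts(
    counts: pd.DataFrame,
    method: str = "cpm_log2",
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """Normalize raw counts to log2 scale.

    ``cpm_log2``: ``log2((count + prior_count) * 1e6 / library)`` with
    ``library`` the sample's total raw counts; the size factor reported is
    ``library / 1e6``. ``median_of_ratios_log2``: size factors are the
    per-sample median across genes of count / geometric-mean-count, computed
    over genes with no zero count; values are
    ``log2((count + prior_count) / size_factor)``.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    validate_counts(counts)
    libs = counts.sum(axis=0)
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    if method == "cpm_log2":
        sf = libs / 1e6
    elif method == "median_of_ratios_log2":
        vals = counts.to_numpy(dtype=float)
        allpos = np.all(vals > 0, axis=1)
        if not allpos.any():
            raise ValueError("median-of-ratios needs at least one gene with no zeros")
        ref = vals[allpos]
        log_geomean = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geomean[:, None]
        sf = pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    values = np.log2((counts + prior_count).div(sf, axis=1))
    return NormalizedMatrix(values=values, size_factors=sf, prior_count=prior_count, method=method)


def filter_low_counts(
    counts: pd.DataFrame, design: SampleDesign, min_total: int = 10
) -> pd.DataFrame:
    """Drop genes with fewer than ``min_total`` counts across the contrast's samples."""
    if min_total <= 0:
        return counts
    samples = design.samples_in(design.contrast[0]) + design.samples_in(design.contrast[1])
    keep = counts[samples].sum(axis=1) >= min_total
    return counts.loc[keep]


def fit_gene_models(norm: NormalizedMatrix, design: SampleDesign) -> pd.DataFrame:
    """Pooled two-group fit per gene for the design's contrast.

    Returns a frame indexed by gene with columns ``beta`` (log2FC, knockout
    minus control), ``s2`` (pooled residual variance), ``df_residual`` and
    ``stdev_unscaled`` (u such that SE = s * u).
    """
    design.validate(norm.values)
    ko, ctrl = design.contrast
    x_ko = norm.values[design.samples_in(ko)].to_numpy()
    x_ctrl = norm.values[design.samples_in(ctrl)].to_numpy()
    n1, n2 = x_ko.shape[1], x_ctrl.shape[1]
    beta = x_ko.mean(axis=1) - x_ctrl.mean(axis=1)
    ss = ((x_ko - x_ko.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_ctrl - x_ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df
    u = np.sqrt(1.0 / n1 + 1.0 / n2)
    return pd.DataFrame(
        {
            "beta": beta,
            "s2": s2,
            "df_residual": float(df),
            "stdev_unscaled": u,
        },
        index=norm.values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone Newton step on the inverse scale; converges in a
    handful of iterations for any y > 0. Very small y (flat trigamma) maps
    to a large x, capped by the caller.
    """
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: Sequence[float], df: Sequence[float] | float) -> VariancePrior:
    """Method-of-moments fit of the scaled-F variance prior on log variances.

    Under the model s2_g ~ s0^2 * chi^2_df / df scaled by an F with d0 prior
    df, log s2_g has known mean/variance offsets in terms of digamma and
    trigamma functions; matching the observed mean and variance of log s2_g
    yields (d0, s0^2). When the observed spread is at or below the d0->inf
    value, d0 is capped at ``D0_CAP``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, D0_CAP)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess spread beyond chi-square sampling noise: infinite-shrinkage
        # limit, where the pooled mean variance is the natural scale estimate
        d0 = D0_CAP
        s0_sq = s2.mean()
    return VariancePrior(d0=float(d0), s0_sq=float(s0_sq))


def moderate(fit: pd.DataFrame, prior: VariancePrior) -> pd.DataFrame:
    """Apply variance moderation and compute moderated t, p and BH q per gene.

    ``prior.d0 = 0`` is the no-shrinkage limit and reproduces the ordinary
    pooled two-sample t-test. A gene with zero posterior variance and nonzero
    beta gets an infinite t (sign of beta) and p = 0.
    """
    beta = fit["beta"].to_numpy()
    s2 = fit["s2"].to_numpy()
    df = fit["df_residual"].to_numpy()
    u = fit["stdev_unscaled"].to_numpy()
    d0 = prior.d0
    s2_post = (d0 * prior.s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post) * u
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    df_total = d0 + df
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
        },
        index=fit.index,
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1; ties share the
    adjusted value of their rank position.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def call_de_genes(results: pd.DataFrame, cfg: DECallConfig = DECallConfig()) -> pd.DataFrame:
    """Threshold moderated results into up/down/ns calls.

    A gene is "up" when q < fdr_threshold and beta >= log2(fc_threshold),
    "down" when q < fdr_threshold and beta <= -log2(fc_threshold) (fold-change
    boundary inclusive, FDR boundary exclusive), otherwise "ns". Genes whose
    names fully match an exclude pattern are removed before calling.
    """
    if "q" not in results.columns:
        raise ValueError("results must carry BH q-values")
    out = results
    if cfg.exclude_genes:
        pats = [re.compile(p) for p in cfg.exclude_genes]
        keep = [g for g in out.index if not any(p.fullmatch(str(g)) for p in pats)]
        out = out.loc[keep]
    lfc = np.log2(cfg.fc_threshold)
    out = out.copy()
    sig = out["q"] < cfg.fdr_threshold
    call = np.where(
        sig & (out["beta"] >= lfc), "up", np.where(sig & (out["beta"] <= -lfc), "down", "ns")
    )
    out["call"] = call
    return out


def run_contrast(
    counts: pd.DataFrame,
    design: SampleDesign,
    norm_method: str = "cpm_log2",
    prior_count: float = 0.5,
    min_count: int = 10,
    call_cfg: DECallConfig = DECallConfig(),
) -> pd.DataFrame:
    """Full DE pass for one contrast: filter, normalize, fit, moderate, call.

    Normalization size factors use all supplied samples; fitting and the
    variance prior use only the contrast's samples and the genes passing the
    low-count filter.
    """
    design.validate(counts)
    filtered = filter_low_counts(counts, design, min_total=min_count)
    norm = normalize_counts(filtered, method=norm_method, prior_count=prior_count)
    fit = fit_gene_models(norm, design)
    prior = estimate_prior(fit["s2"], fit["df_residual"])
    res = moderate(fit, prior)
    return call_de_genes(res, call_cfg)
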