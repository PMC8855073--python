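"""Two-contrast dependence classification.

Given per-gene statistics from two independent knockout-vs-control contrasts
(A: receptor knockout with the downstream factor intact; B: the same receptor
knockout on a factor-null background), genes are partitioned into:

* **dependent** — the contrast-A log2 fold change is statistically greater
  than ``factor`` (default 2) times the contrast-B log2 fold change, in the
  sign-aligned direction. The downstream factor mediates the response.
* **independent** — both contrasts moved the gene in the same direction and
  the smaller of the two |t| statistics (the min-t intersection statistic) is
  larger than expected under a null of two independent central t variates.
* **neither** — everything else.

The dependent test is a one-sided contrast z = h*(beta_A - factor*beta_B) /
sqrt(se_A^2 + factor^2 * se_B^2) with h = sign(beta_A), referred to a t
distribution with Satterthwaite-combined degrees of freedom; the two fits
come from different mouse lines and are treated as independent. The min-t
statistic m = min(|t_A|, |t_B|) is set to 0 when the signs disagree; its
p-value is the closed form 2*S(m)^2 when df_A = df_B and otherwise the
(r+1)/(n+1) tail fraction of a seeded Monte-Carlo null. Both families of
p-values are Benjamini-Hochberg adjusted; "dependent" takes precedence so the
categories are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr


@dataclass(frozen=True)
class ClassifierConfig:
    dependence_factor: float = 2.0
    n_sim: int = 1_000_000
    seed: int = 20240101
    fdr_threshold: float = 0.05
    restrict_to: tuple | None = None  # gene ids; None = all genes in the pair table

    def __post_init__(self):
        if self.dependence_factor <= 0:
            raise ValueError("dependence_factor must be positive")
        if self.n_sim < 10_000:
            raise ValueError("n_sim must be at least 10^4")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")


def build_contrast_pairs(res_a: pd.DataFrame, res_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two per-contrast moderated result tables into a pair table.

    Requires columns beta, se, t, df_total in each input; genes are matched
    by id (inner join).
    """
    need = {"beta", "se", "t", "df_total"}
    for name, res in (("A", res_a), ("B", res_b)):
        missing = need - set(res.columns)
        if missing:
            raise ValueError(f"contrast {name} results missing columns: {sorted(missing)}")
    a = res_a[["beta", "se", "t", "df_total"]].rename(
        columns={"beta": "beta_A", "se": "se_A", "t": "t_A", "df_total": "df_A"}
    )
    b = res_b[["beta", "se", "t", "df_total"]].rename(
        columns={"beta": "beta_B", "se": "se_B", "t": "t_B", "df_total": "df_B"}
    )
    return a.join(b, how="inner")


def dependent_test(
    beta_a, se_a, df_a, beta_b, se_b, df_b, factor: float = 2.0
) -> np.ndarray:
    """One-sided p-value for H1: sign-aligned beta_A exceeds factor*beta_B.

    With h = sign(beta_A) the statistic is

        z = h * (beta_A - factor*beta_B) / sqrt(se_A^2 + factor^2 * se_B^2)

    referred to a t distribution whose df combine the two contrasts by
    Satterthwaite. beta_A = 0 has no direction to align and returns p = 1.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    se_a = np.asarray(se_a, dtype=float)
    se_b = np.asarray(se_b, dtype=float)
    df_a = np.asarray(df_a, dtype=float)
    df_b = np.asarray(df_b, dtype=float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("standard errors must be positive")
    va = se_a**2
    vb = factor**2 * se_b**2
    var = va + vb
    df = var**2 / (va**2 / df_a + vb**2 / df_b)
    h = np.sign(beta_a)
    z = h * (beta_a - factor * beta_b) / np.sqrt(var)
    p = stats.t.sf(z, df)
    p = np.where(beta_a == 0, 1.0, p)
    return p if p.ndim else float(p)


def min_t_statistic(t_a, t_b) -> np.ndarray:
    """m = min(|t_A|, |t_B|) when signs agree and both are nonzero, else 0."""
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    same_sign = (np.sign(t_a) == np.sign(t_b)) & (t_a != 0) & (t_b != 0)
    m = np.where(same_sign, np.minimum(np.abs(t_a), np.abs(t_b)), 0.0)
    return m if m.ndim else float(m)


class MinTNull:
    """Empirical null distribution of the min-t statistic.

    Holds sorted Monte-Carlo draws; ``pvalue(m)`` is the tail fraction with
    the (r+1)/(n+1) continuity correction, and 1 exactly at m = 0 (an
    opposite-sign gene can never be significant).
    """

    def __init__(self, draws: np.ndarray):
        self.draws = np.sort(np.asarray(draws, dtype=float))
        self.n = len(self.draws)

    def pvalue(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        if np.any(m < 0):
            raise ValueError("m must be nonnegative")
        r = self.n - np.searchsorted(self.draws, m, side="left")
        p = (r + 1.0) / (self.n + 1.0)
        p = np.where(m == 0, 1.0, np.minimum(p, 1.0))
        return p if p.ndim else float(p)


def _t_draws(df: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if np.isinf(df):
        return rng.standard_normal(n)
    return rng.standard_t(df, n)


def simulate_min_t_null(
    df_a: float, df_b: float, n_sim: int = 1_000_000, seed: int = 20240101
) -> MinTNull:
    """Monte-Carlo null of min-t from independent central t pairs."""
    if n_sim < 10_000:
        raise ValueError("n_sim must be at least 10^4")
    rng = np.random.default_rng(seed)
    ta = _t_draws(float(df_a), n_sim, rng)
    tb = _t_draws(float(df_b), n_sim, rng)
    return MinTNull(min_t_statistic(ta, tb))


def analytic_min_t_pvalue(m, df: float) -> np.ndarray:
    """Closed-form null p-value of min-t when both contrasts share df.

    P(min(|T_A|,|T_B|) >= m, signs agree) = 2*S(m)^2 with S the upper-tail
    t probability: both statistics must exceed m with a common sign and the
    two sign configurations are disjoint. p = 1 at m = 0.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("m must be nonnegative")
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    s = stats.norm.sf(m) if np.isinf(df) else stats.t.sf(m, df)
    p = np.where(m == 0, 1.0, 2.0 * s**2)
    return p if p.ndim else float(p)


def classify_genes(pairs: pd.DataFrame, cfg: ClassifierConfig = ClassifierConfig()) -> pd.DataFrame:
    """Classify every gene in the pair table as dependent / independent / neither.

    Both tests run on the restriction set (``cfg.restrict_to`` if given,
    typically the genes DE in contrast A); BH adjustment is within that
    family. Genes listed in the restriction but missing from the pair table
    are reported with category ``missing`` rather than aborting the run.
    """
    if pairs.empty:
        raise ValueError("pair table is empty")
    missing_idx = []
    sub = pairs
    if cfg.restrict_to is not None:
        wanted = list(cfg.restrict_to)
        present = [g for g in wanted if g in pairs.index]
        missing_idx = [g for g in wanted if g not in pairs.index]
        sub = pairs.loc[present]
    if sub.empty:
        raise ValueError("no genes left after restriction")

    p_dep = dependent_test(
        sub["beta_A"], sub["se_A"], sub["df_A"],
        sub["beta_B"], sub["se_B"], sub["df_B"],
        factor=cfg.dependence_factor,
    )
    q_dep = bh_fdr(p_dep)

    m = min_t_statistic(sub["t_A"], sub["t_B"])
    p_indep = np.empty(len(sub))
    seeds = np.random.SeedSequence(cfg.seed)
    df_pairs = list(zip(sub["df_A"].to_numpy(), sub["df_B"].to_numpy()))
    unique_pairs = sorted(set(df_pairs))
    child_seeds = seeds.spawn(len(unique_pairs))
    for (dfa, dfb), child in zip(unique_pairs, child_seeds):
        mask = np.array([dp == (dfa, dfb) for dp in df_pairs])
        if dfa == dfb:
            p_indep[mask] = analytic_min_t_pvalue(m[mask], dfa)
        else:
            null = simulate_min_t_null(
                dfa, dfb, n_sim=cfg.n_sim, seed=child.generate_state(1)[0] % (2**31)
            )
            p_indep[mask] = null.pvalue(m[mask])
    q_indep = bh_fdr(p_indep)

    category = np.where(
        q_dep < cfg.fdr_threshold,
        "dependent",
        np.where(q_indep < cfg.fdr_threshold, "independent", "neither"),
    )
    out = pd.DataFrame(
        {
            "category": category,
            "p_dep": p_dep,
            "q_dep": q_dep,
            "m": m,
            "p_indep": p_indep,
            "q_indep": q_indep,
            "direction": np.sign(sub["beta_A"].to_numpy()),
        },
        index=sub.index,
    )
    if missing_idx:
        miss = pd.DataFrame(
            {
                "category": "missing",
                "p_dep": np.nan,
                "q_dep": np.nan,
                "m": np.nan,
                "p_indep": np.nan,
                "q_indep": np.nan,
                "direction": np.nan,
            },
            index=pd.Index(missing_idx, name=pairs.index.name),
        )
        out = pd.concat([out, miss])
    return out
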