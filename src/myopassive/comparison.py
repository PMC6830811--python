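"""Extra-sum-of-squares F-test between separate and pooled nonlinear fits.

Following Motulsky & Ransnas, two groups fitted separately (RSS_sep =
RSS₁ + RSS₂, ν_sep = ν₁ + ν₂) are compared against a single pooled fit
of their union (RSS_pool, ν_pool) through

    F = [(RSS_pool − RSS_sep) / (ν_pool − ν_sep)] · [ν_sep / RSS_sep]

referred to the F distribution with (ν_pool − ν_sep, ν_sep) degrees of
freedom.  A small p-value means the groups need separate parameter
sets — e.g. bundles are stiffer than fibres beyond what one shared
curve can express.  For nonlinear regressions the test is approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import DomainError
from .fitting import FitResult

__all__ = ["FTestResult", "extra_ss_f_test", "f_critical"]


@dataclass(frozen=True)
class FTestResult:
    rss_sep: float
    rss_pool: float
    nu_sep: int
    nu_pool: int
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    significant_at_0_05: bool


def extra_ss_f_test(fit_group1: FitResult, fit_group2: FitResult,
                    fit_pooled: FitResult, alpha: float = 0.05) -> FTestResult:
    """Compare two separate fits against the pooled fit of their union.

    All three fits must use the same law and the pooled fit must cover
    exactly the union of the two groups' records.
    """
    if not (fit_group1.law == fit_group2.law == fit_pooled.law):
        raise DomainError("all three fits must use the same law")
    if fit_pooled.n_exp != fit_group1.n_exp + fit_group2.n_exp:
        raise DomainError(
            "pooled fit must use exactly the union of the two groups "
            f"({fit_group1.n_exp} + {fit_group2.n_exp} != {fit_pooled.n_exp})")
    rss_sep = fit_group1.rss + fit_group2.rss
    nu_sep = fit_group1.nu + fit_group2.nu
    nu_pool = fit_pooled.nu
    rss_pool = fit_pooled.rss
    df_num = nu_pool - nu_sep
    if df_num < 1:
        raise DomainError("pooled fit must have more degrees of freedom "
                          "than the separate fits combined")
    if rss_sep <= 0:
        # perfect separate fits: any pooled excess is infinitely significant
        f_stat = float("inf") if rss_pool > 0 else 0.0
    else:
        f_stat = max(0.0, (rss_pool - rss_sep) / df_num * nu_sep / rss_sep)
    p_value = float(stats.f.sf(f_stat, df_num, nu_sep))
    return FTestResult(
        rss_sep=rss_sep, rss_pool=rss_pool, nu_sep=nu_sep, nu_pool=nu_pool,
        f_stat=f_stat, df_num=df_num, df_den=nu_sep, p_value=p_value,
        significant_at_0_05=bool(p_value < alpha),
    )


def f_critical(df_num: int, df_den: int, alpha: float = 0.05) -> float:
    """Upper-tail critical value of the F distribution."""
    if df_num < 1 or df_den < 1:
        raise DomainError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    return float(stats.f.isf(alpha, df_num, df_den))
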