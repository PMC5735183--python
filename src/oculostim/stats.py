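"""Statistical procedures for the oculomotor stimulation analyses.

Covers the full inferential toolkit the pipeline needs: the reciprocal
(rate) transform of saccadic latencies, pooled-variance and Welch t tests,
Wilcoxon rank-sum, an exact-arithmetic Fisher test with odds ratio, a
two-factor ANOVA for circular data (Harrison–Kanji scheme, with a seeded
permutation companion p-value), a two-way linear ANOVA with Type-II sums of
squares, Bonferroni adjustment and circular descriptives.

Conventions: all tests are two-sided unless stated; angle arguments are in
degrees; every stochastic procedure takes an explicit seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .errors import InvalidArgumentError, UnsupportedDesignError

__all__ = [
    "TestResult",
    "CircAnovaResult",
    "reciprocal_transform",
    "latency_test",
    "fisher_exact",
    "hk_circ_anova",
    "twoway_linear_anova",
    "bonferroni_alpha",
    "circ_descriptives",
    "watson_williams",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: float | tuple | None
    p_value: float
    effect_estimate: float
    method: str
    sidedness: str = "two-sided"
    n: tuple = ()
    flags: tuple = ()
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": _f(self.statistic),
            "df": list(self.df) if isinstance(self.df, tuple) else _f(self.df),
            "p_value": _f(self.p_value),
            "effect_estimate": _f(self.effect_estimate),
            "method": self.method,
            "sidedness": self.sidedness,
            "n": list(self.n),
            "flags": list(self.flags),
            "extras": {k: _f(v) for k, v in self.extras.items()},
        }


def _f(v):
    if v is None:
        return None
    v = float(v)
    return v


# ---------------------------------------------------------------------------
# reciprocal (rate) transform
# ---------------------------------------------------------------------------

def reciprocal_transform(latencies_ms) -> np.ndarray:
    """Saccadic latencies (ms) to rates (1/s): ``rate = 1000 / latency``.

    The transform normalizes right-skewed reaction-time distributions toward
    Gaussian and is strictly order-reversing.
    """
    lat = np.asarray(latencies_ms, dtype=float)
    if lat.size and np.nanmin(lat) <= 0:
        raise InvalidArgumentError("latencies must be strictly positive")
    return 1000.0 / lat


# ---------------------------------------------------------------------------
# group comparisons on latencies
# ---------------------------------------------------------------------------

def latency_test(
    group_a,
    group_b,
    method: str = "t",
    paired: bool = False,
    transform: bool = True,
    equal_var: bool = True,
) -> TestResult:
    """Two-sided comparison of two latency samples.

    With ``transform`` (the default, and the primary analysis) the test is
    run on reciprocal-transformed latencies; raw-millisecond effect
    estimates are reported alongside either way.  ``method='t'`` uses the
    pooled-variance Student test (Welch via ``equal_var=False``);
    ``method='ranksum'`` uses the Wilcoxon rank-sum (Mann-Whitney) test,
    exact for small tie-free samples and normal-approximated with tie
    correction otherwise; paired data use the paired t or signed-rank test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    if paired and a.size != b.size:
        raise InvalidArgumentError("paired test requires equal-length groups")
    xa = reciprocal_transform(a) if transform else a
    xb = reciprocal_transform(b) if transform else b

    flags: list[str] = []
    extras = {
        "mean_diff_ms": float(np.mean(a) - np.mean(b)),
        "median_diff_ms": float(np.median(a) - np.median(b)),
        "mean_diff_transformed": float(np.mean(xa) - np.mean(xb)),
    }
    effect = extras["mean_diff_transformed"] if transform else extras["mean_diff_ms"]

    if method == "t":
        if paired:
            d = xa - xb
            if np.std(d, ddof=1) == 0 or a.size < 2:
                return TestResult(
                    float("nan"), a.size - 1, float("nan"), effect,
                    "paired-t" + ("-reciprocal" if transform else ""),
                    n=(a.size, b.size), flags=("zero-variance",), extras=extras,
                )
            res = sps.ttest_rel(xa, xb)
            df = a.size - 1
            tag = "paired-t"
        else:
            if (np.std(xa, ddof=0) == 0 and np.std(xb, ddof=0) == 0) or (
                a.size + b.size < 3
            ):
                p = 1.0 if np.mean(xa) == np.mean(xb) else float("nan")
                return TestResult(
                    float("nan") if np.isnan(p) else 0.0,
                    a.size + b.size - 2, p, effect,
                    "t" + ("-reciprocal" if transform else ""),
                    n=(a.size, b.size), flags=("zero-variance",), extras=extras,
                )
            res = sps.ttest_ind(xa, xb, equal_var=equal_var)
            df = float(res.df)
            tag = "t" if equal_var else "welch-t"
        if transform:
            tag += "-reciprocal"
        return TestResult(
            float(res.statistic), df, float(res.pvalue), effect, tag,
            n=(a.size, b.size), flags=tuple(flags), extras=extras,
        )

    if method == "ranksum":
        if paired:
            d = xa - xb
            if np.all(d == 0):
                return TestResult(
                    0.0, None, 1.0, effect, "signed-rank",
                    n=(a.size, b.size), flags=("all-zero-differences",),
                    extras=extras,
                )
            res = sps.wilcoxon(xa, xb)
            tag = "signed-rank"
        else:
            small = max(a.size, b.size) <= 25
            ties = np.unique(np.concatenate([xa, xb])).size < a.size + b.size
            how = "exact" if (small and not ties) else "asymptotic"
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=how)
            tag = f"rank-sum-{how}"
        if transform:
            tag += "-reciprocal"
        return TestResult(
            float(res.statistic), None, float(res.pvalue), effect, tag,
            n=(a.size, b.size), flags=tuple(flags), extras=extras,
        )

    raise InvalidArgumentError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Fisher's exact test (exact rational arithmetic)
# ---------------------------------------------------------------------------

def _hypergeom_pmf_frac(k: int, r1: int, r2: int, c1: int) -> Fraction:
    return Fraction(
        math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(r1 + r2, c1)
    )


def fisher_exact(table_2x2) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The p-value sums the hypergeometric probabilities of all tables with the
    same margins that are at most as likely as the observed one (with a 1e-7
    relative slack on the comparison, so exact ties in floating point are
    included).  Probabilities are accumulated in exact rational arithmetic.
    The effect estimate is the sample cross-product odds ratio
    ``(a d) / (b c)``, reported as 0 or inf when a zero cell makes it
    degenerate.
    """
    tab = np.asarray(table_2x2)
    if tab.shape != (2, 2):
        raise InvalidArgumentError("table must be 2x2")
    if not np.issubdtype(tab.dtype, np.integer):
        if not np.all(np.asarray(tab, float) == np.round(np.asarray(tab, float))):
            raise InvalidArgumentError("cells must be non-negative integers")
        tab = tab.astype(int)
    if (tab < 0).any():
        raise InvalidArgumentError("cells must be non-negative integers")
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 + r2 == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
        raise InvalidArgumentError("table margins must be positive")

    p_obs = _hypergeom_pmf_frac(a, r1, r2, c1)
    slack = Fraction(1, 10**7)
    cutoff = p_obs * (1 + slack)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p = Fraction(0)
    for k in range(lo, hi + 1):
        pk = _hypergeom_pmf_frac(k, r1, r2, c1)
        if pk <= cutoff:
            p += pk
    p_value = min(float(p), 1.0)

    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        statistic=float(a),
        df=None,
        p_value=p_value,
        effect_estimate=odds,
        method="fisher-exact",
        n=(r1, r2),
        extras={"odds_ratio": odds},
    )


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

@dataclass
class CircDescriptives:
    mean_direction_deg: float
    resultant_length: float
    undefined: bool = False


def circ_descriptives(angles_deg) -> CircDescriptives:
    """Mean direction and resultant length of a set of angles (degrees).

    The mean direction is the angle of the summed unit vectors; the
    resultant length R lies in [0, 1] and measures concentration.  When
    R is (numerically) zero the mean direction is undefined and flagged.
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if ang.size < 1:
        raise InvalidArgumentError("need at least one angle")
    C, S = np.cos(ang).sum(), np.sin(ang).sum()
    R = float(np.hypot(C, S) / ang.size)
    if R < 1e-12:
        return CircDescriptives(float("nan"), 0.0, undefined=True)
    mean = float(np.rad2deg(np.arctan2(S, C)) % 360.0)
    return CircDescriptives(mean, R)


def _circ_kappa(rbar: float) -> float:
    """Maximum-likelihood-style concentration estimate from the mean
    resultant length (standard piecewise approximation)."""
    r = float(rbar)
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


@dataclass
class CircAnovaTerm:
    statistic: float
    df: int
    p_value: float
    p_permutation: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": _f(self.statistic),
            "df": self.df,
            "p_value": _f(self.p_value),
            "p_permutation": _f(self.p_permutation),
        }


@dataclass
class CircAnovaResult:
    """Two-factor circular ANOVA decomposition."""

    factor_a: CircAnovaTerm
    factor_b: CircAnovaTerm
    interaction: CircAnovaTerm
    kappa_hat: float
    regime: str               # "F" (high concentration) or "chi2" (low)
    low_kappa_warning: bool
    n_cells: int
    n: int

    def to_dict(self) -> dict:
        return {
            "factor_a": self.factor_a.to_dict(),
            "factor_b": self.factor_b.to_dict(),
            "interaction": self.interaction.to_dict(),
            "kappa_hat": _f(self.kappa_hat),
            "regime": self.regime,
            "low_kappa_warning": self.low_kappa_warning,
            "n_cells": self.n_cells,
            "n": self.n,
        }


def _hk_sums(cos_a, sin_a, cell_idx, a_of_cell, b_of_cell, n_a, n_b, cell_n):
    """Squared-resultant sums for the Harrison-Kanji decomposition.

    Returns (SS_a, SS_b, SS_int, SS_res, SS_tot) given per-observation unit
    vectors and their cell assignment.
    """
    n = cos_a.size
    n_cells = n_a * n_b
    Cc = np.bincount(cell_idx, weights=cos_a, minlength=n_cells)
    Sc = np.bincount(cell_idx, weights=sin_a, minlength=n_cells)
    R2_cell = Cc**2 + Sc**2

    Ca = np.bincount(a_of_cell, weights=Cc, minlength=n_a)
    Sa = np.bincount(a_of_cell, weights=Sc, minlength=n_a)
    na = np.bincount(a_of_cell, weights=cell_n, minlength=n_a)
    Cb = np.bincount(b_of_cell, weights=Cc, minlength=n_b)
    Sb = np.bincount(b_of_cell, weights=Sc, minlength=n_b)
    nb = np.bincount(b_of_cell, weights=cell_n, minlength=n_b)

    Rt2 = Cc.sum() ** 2 + Sc.sum() ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_term = np.where(cell_n > 0, R2_cell / np.maximum(cell_n, 1), 0.0).sum()
        a_term = ((Ca**2 + Sa**2) / na).sum()
        b_term = ((Cb**2 + Sb**2) / nb).sum()
    tot_term = Rt2 / n
    ss_a = a_term - tot_term
    ss_b = b_term - tot_term
    ss_int = cell_term - a_term - b_term + tot_term
    ss_res = n - cell_term
    ss_tot = n - tot_term
    return ss_a, ss_b, ss_int, ss_res, ss_tot


def hk_circ_anova(
    angles_deg,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed: int | None = None,
) -> CircAnovaResult:
    """Two-way ANOVA for circular data (Harrison-Kanji two-factor scheme).

    Decomposes squared-resultant variation of the angles into factor A,
    factor B and interaction terms.  The concentration parameter kappa is
    estimated from the overall resultant length; for kappa > 2 the terms are
    referred to F distributions against the residual, otherwise to
    chi-squared approximations with the kappa-dependent scale factor
    ``2 / (1 - rho^2)`` where ``rho = I1(kappa)/I0(kappa)``.  Because the
    approximations degrade at low concentration, a ``low_kappa_warning`` is
    raised when kappa < 2 and a permutation p-value (joint shuffling of the
    cell labels, ``n_perm`` permutations, seeded) is always reported as a
    companion for every term.

    A factor with a single level collapses its term (df 0, p 1) rather than
    failing; empty cells in a crossed design are unsupported.
    """
    ang = np.asarray(angles_deg, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (ang.size == fa.size == fb.size):
        raise InvalidArgumentError("angles and factors must have equal length")
    if ang.size < 4:
        raise InvalidArgumentError("need at least 4 observations")
    ua, ai = np.unique(fa, return_inverse=True)
    ub, bi = np.unique(fb, return_inverse=True)
    n_a, n_b = ua.size, ub.size
    if n_a < 2:
        raise InvalidArgumentError("factor A needs at least 2 levels")
    n = ang.size
    cell_idx = ai * n_b + bi
    cell_n = np.bincount(cell_idx, minlength=n_a * n_b).astype(float)
    if (cell_n == 0).any():
        raise UnsupportedDesignError(
            "empty cells in the crossed design are not supported"
        )
    if (cell_n < 2).any():
        raise InvalidArgumentError("every cell needs at least 2 observations")

    df_a = n_a - 1
    df_b = n_b - 1
    df_int = (n_a - 1) * (n_b - 1)
    df_res = n - n_a * n_b

    rad = np.deg2rad(ang)
    cos_a, sin_a = np.cos(rad), np.sin(rad)
    a_of_cell = np.repeat(np.arange(n_a), n_b)
    b_of_cell = np.tile(np.arange(n_b), n_a)

    rbar = float(np.hypot(cos_a.sum(), sin_a.sum()) / n)
    kappa = _circ_kappa(rbar)
    high = kappa > 2.0

    def stats_tuple(c, s):
        ss_a, ss_b, ss_int, ss_res, _ = _hk_sums(
            c, s, cell_idx, a_of_cell, b_of_cell, n_a, n_b, cell_n
        )
        if high:
            ms_res = ss_res / df_res if df_res > 0 else np.nan
            st_a = (ss_a / df_a) / ms_res if df_a > 0 else np.nan
            st_b = (ss_b / df_b) / ms_res if df_b > 0 else np.nan
            st_i = (ss_int / df_int) / ms_res if df_int > 0 else np.nan
        else:
            rho = special.i1(kappa) / special.i0(kappa)
            f = 2.0 / (1.0 - rho**2)
            st_a = f * ss_a
            st_b = f * ss_b
            st_i = f * ss_int
        return st_a, st_b, st_i

    st_a, st_b, st_i = stats_tuple(cos_a, sin_a)

    def parametric_p(stat, df):
        if df == 0 or not np.isfinite(stat):
            return 1.0
        if high:
            return float(sps.f.sf(stat, df, df_res))
        return float(sps.chi2.sf(stat, df))

    p_a = parametric_p(st_a, df_a)
    p_b = parametric_p(st_b, df_b)
    p_i = parametric_p(st_i, df_int)

    p_perm = (None, None, None)
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = np.zeros(3)
        obs = np.array([st_a, st_b, st_i], dtype=float)
        obs = np.where(np.isfinite(obs), obs, np.inf)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ps = np.array(stats_tuple(cos_a[perm], sin_a[perm]), dtype=float)
            hits += np.nan_to_num(ps, nan=-np.inf) >= obs - 1e-12
        p_perm = tuple((1.0 + h) / (n_perm + 1.0) for h in hits)

    def term(stat, df, p, pp):
        if df == 0:
            return CircAnovaTerm(float("nan"), 0, 1.0, None)
        return CircAnovaTerm(float(stat), int(df), p, pp)

    return CircAnovaResult(
        factor_a=term(st_a, df_a, p_a, p_perm[0]),
        factor_b=term(st_b, df_b, p_b, p_perm[1]),
        interaction=term(st_i, df_int, p_i, p_perm[2]),
        kappa_hat=float(kappa),
        regime="F" if high else "chi2",
        low_kappa_warning=bool(kappa < 2.0),
        n_cells=int(n_a * n_b),
        n=int(n),
    )


def watson_williams(angles_deg, groups) -> TestResult:
    """One-way test for equal mean directions across groups
    (Watson-Williams F with the standard 1 + 3/(8 kappa) correction).

    Suitable at moderate-to-high concentration; used here as an independent
    one-way cross-check of the two-factor circular ANOVA.
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    g = np.asarray(groups)
    if ang.size != g.size:
        raise InvalidArgumentError("angles and groups must have equal length")
    ug, gi = np.unique(g, return_inverse=True)
    p = ug.size
    if p < 2:
        raise InvalidArgumentError("need at least 2 groups")
    n = ang.size
    C = np.bincount(gi, weights=np.cos(ang), minlength=p)
    S = np.bincount(gi, weights=np.sin(ang), minlength=p)
    Ri = np.hypot(C, S)
    R = float(np.hypot(C.sum(), S.sum()))
    rbar = R / n
    kappa = _circ_kappa(rbar)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (Ri.sum() - R) / (p - 1)
    den = (n - Ri.sum()) / (n - p)
    F = correction * num / den if den > 0 else float("inf")
    pval = float(sps.f.sf(F, p - 1, n - p))
    return TestResult(
        statistic=float(F),
        df=(p - 1, n - p),
        p_value=pval,
        effect_estimate=float(rbar),
        method="watson-williams",
        n=tuple(int(c) for c in np.bincount(gi, minlength=p)),
        flags=("low-kappa",) if kappa < 1.0 else (),
    )


# ---------------------------------------------------------------------------
# linear two-way ANOVA
# ---------------------------------------------------------------------------

def twoway_linear_anova(y, factor_a, factor_b, ss_type: int = 2) -> dict:
    """Fixed-effects two-way ANOVA with interaction on a linear response.

    Uses an OLS fit with Type-II sums of squares by default (appropriate for
    unbalanced cell counts without an a-priori factor ordering; Type I/III
    available via ``ss_type``).  On balanced designs this reduces to the
    classical decomposition.

    Returns a dict with keys ``factor_a``, ``factor_b``, ``interaction``
    mapping to :class:`TestResult`, plus ``residual_df``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(y, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise InvalidArgumentError("y and factors must have equal length")
    if np.unique(fa).size < 2:
        raise InvalidArgumentError("factor A needs at least 2 levels")
    flags = ()
    if np.allclose(y, y[0]):
        flags = ("constant-response",)
    df = pd.DataFrame({"y": y, "a": fa.astype(str), "b": fb.astype(str)})
    has_b = df["b"].nunique() > 1
    formula = "y ~ C(a) * C(b)" if has_b else "y ~ C(a)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=ss_type)

    def grab(row_name) -> TestResult:
        if row_name not in table.index:
            return TestResult(float("nan"), 0, 1.0, float("nan"),
                              f"anova2-type{ss_type}", flags=("collapsed",))
        row = table.loc[row_name]
        return TestResult(
            statistic=float(row["F"]),
            df=(float(row["df"]), float(table.loc["Residual", "df"])),
            p_value=float(row["PR(>F)"]),
            effect_estimate=float(row["sum_sq"]),
            method=f"anova2-type{ss_type}",
            n=(int(y.size),),
            flags=flags,
        )

    return {
        "factor_a": grab("C(a)"),
        "factor_b": grab("C(b)"),
        "interaction": grab("C(a):C(b)"),
        "residual_df": float(table.loc["Residual", "df"]),
    }


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance level, ``alpha / n_tests``."""
    if n_tests < 1:
        raise InvalidArgumentError("n_tests must be >= 1")
    return alpha / n_tests
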