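"""Statistical layer: depletion percentages, ANOVA + Dunnett, binned KS,
concentration-response R^2, and weighted 1/x quadratic calibration curves.

Dunnett's many-to-one comparison is computed from the multivariate-t
formulation: under the null the treatment-vs-control t statistics are
jointly t-distributed with the equal-correlation structure
``rho_ij = lambda_i * lambda_j``, ``lambda_i = sqrt(n_i / (n_i + n_0))``,
on the pooled-variance degrees of freedom ``N - k``.  The familywise
adjusted p-value ``P(max_j |T_j| >= |t_i|)`` is evaluated by conditioning
on the shared pooled-SD factor and the common latent normal, reducing the
integral to a product of univariate normal probabilities under a double
Gauss quadrature — deterministic and accurate to well below the 1e-6
tolerance used here.  For a single treatment group this reduces exactly to
the two-sided pooled-variance t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import special, stats as sps

__all__ = [
    "DepletionResult",
    "DunnettResult",
    "CalibrationCurve",
    "BackCalcResult",
    "depletion_percent",
    "anova_dunnett",
    "dunnett_pvalue",
    "ks_binned",
    "concentration_response_r2",
    "fit_calibration",
    "back_calculate",
    "analyze_cohort",
]

PLX3397_LLOQ_UM = 0.0073  # default lower limit of quantitation, uM


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = {"animal_id", "group", "region", "density"}


def _check_cohort(table: pd.DataFrame, control: str, region: str) -> pd.DataFrame:
    missing = _COHORT_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    sub = table[table["region"] == region]
    if sub.empty:
        raise ValueError(f"no rows for region {region!r}")
    if control not in set(sub["group"]):
        raise ValueError(f"control group {control!r} absent in region {region!r}")
    return sub


@dataclass(frozen=True)
class DepletionResult:
    """Percent depletion of a group relative to the control mean.

    ``percent_depletion = 100 * (1 - mean_group / mean_control)``; negative
    values indicate densities above control (repopulation direction).
    ``se`` is a delta-method standard error from the two group-mean SEs.
    """

    group: str
    region: str
    percent_depletion: float
    se: float
    mean_group: float
    mean_control: float
    n_group: int
    n_control: int


def depletion_percent(
    table: pd.DataFrame, control: str, region: str
) -> list[DepletionResult]:
    """Depletion of every non-control group vs control, in one region."""
    sub = _check_cohort(table, control, region)
    ctrl = sub.loc[sub["group"] == control, "density"].to_numpy(float)
    m0 = ctrl.mean()
    if m0 == 0:
        raise ZeroDivisionError("control mean density is zero; ratio undefined")
    se0 = ctrl.std(ddof=1) / math.sqrt(len(ctrl)) if len(ctrl) > 1 else 0.0
    out = []
    for g, gdf in sub.groupby("group", sort=False):
        if g == control:
            continue
        y = gdf["density"].to_numpy(float)
        mg = y.mean()
        seg = y.std(ddof=1) / math.sqrt(len(y)) if len(y) > 1 else 0.0
        # delta method on f(mg, m0) = 100 (1 - mg/m0)
        var = (100.0 / m0) ** 2 * seg**2 + (100.0 * mg / m0**2) ** 2 * se0**2
        out.append(
            DepletionResult(
                group=str(g),
                region=region,
                percent_depletion=100.0 * (1.0 - mg / m0),
                se=math.sqrt(var),
                mean_group=mg,
                mean_control=m0,
                n_group=len(y),
                n_control=len(ctrl),
            )
        )
    return out


# ---------------------------------------------------------------------------
# One-way ANOVA with Dunnett's post-hoc test
# ---------------------------------------------------------------------------

_GH_X, _GH_W = hermgauss(96)
_GL_X, _GL_W = leggauss(120)


def _prob_max_abs_below(t: float, lambdas: np.ndarray, df: float) -> float:
    """P(max_j |T_j| < t) for Dunnett-correlated t statistics.

    Conditions on W = s/sigma (chi_df / sqrt(df)) and the shared latent
    standard normal U; the treatment statistics are then independent with
    ``Z_j = lambda_j U + sqrt(1 - lambda_j^2) e_j``.
    """
    if t <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    s = np.sqrt(1.0 - lam**2)
    # inner integral over U via Gauss-Hermite: u = sqrt(2) x
    u = math.sqrt(2.0) * _GH_X  # (nu,)

    def inner(w: np.ndarray) -> np.ndarray:
        # w: (nw,) -> P(max |Z| < t w) averaged over U
        tw = t * np.asarray(w)[:, None, None]  # (nw,1,1)
        uu = u[None, :, None]  # (1,nu,1)
        a = (tw + lam[None, None, :] * uu) / s[None, None, :]
        b = (-tw + lam[None, None, :] * uu) / s[None, None, :]
        prod = np.prod(special.ndtr(a) - special.ndtr(b), axis=2)  # (nw,nu)
        return prod @ _GH_W / math.sqrt(math.pi)

    # outer over W: density of sqrt(chi2_df / df)
    chi = sps.chi(df)
    lo, hi = chi.ppf(1e-14) / math.sqrt(df), chi.isf(1e-14) / math.sqrt(df)
    w = 0.5 * (hi - lo) * _GL_X + 0.5 * (hi + lo)
    fw = chi.pdf(w * math.sqrt(df)) * math.sqrt(df)
    val = 0.5 * (hi - lo) * np.sum(_GL_W * fw * inner(w))
    return float(min(max(val, 0.0), 1.0))


def dunnett_pvalue(
    t: float, n_treat: Sequence[int], n_control: int, df: float
) -> float:
    """Two-sided familywise-adjusted p for |T| = ``t`` against ``len(n_treat)``
    many-to-one comparisons with the standard Dunnett correlation."""
    lam = np.sqrt(np.asarray(n_treat, float) / (np.asarray(n_treat, float) + n_control))
    return 1.0 - _prob_max_abs_below(abs(t), lam, df)


def dunnett_critical_value(
    alpha: float, n_treat: Sequence[int], n_control: int, df: float
) -> float:
    """Two-sided critical value c with P(max |T_j| > c) = alpha."""
    from scipy.optimize import brentq

    lam = np.sqrt(np.asarray(n_treat, float) / (np.asarray(n_treat, float) + n_control))
    return float(
        brentq(lambda c: 1.0 - _prob_max_abs_below(c, lam, df) - alpha, 1e-6, 50.0)
    )


@dataclass(frozen=True)
class DunnettResult:
    """One-way ANOVA with Dunnett's many-to-one post-hoc comparisons."""

    groups: tuple[str, ...]  # treatment group names, control excluded
    estimates: np.ndarray  # mean_i - mean_control
    t_statistics: np.ndarray
    p_adjusted: np.ndarray
    f_statistic: float
    f_pvalue: float
    df_resid: int


def anova_dunnett(
    table: pd.DataFrame, control: str, region: str
) -> DunnettResult:
    """One-way ANOVA over all groups in a region plus Dunnett's post-hoc.

    Uses the pooled residual variance on ``N - k`` degrees of freedom for
    every comparison.  Every group must have at least two observations.
    """
    sub = _check_cohort(table, control, region)
    names = [g for g in sub["group"].unique()]
    samples = {g: sub.loc[sub["group"] == g, "density"].to_numpy(float) for g in names}
    for g, y in samples.items():
        if len(y) < 2:
            raise ValueError(f"group {g!r} has < 2 observations in {region!r}")
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = {g: len(y) for g, y in samples.items()}
    means = {g: y.mean() for g, y in samples.items()}
    N = sum(ns.values())
    grand = np.concatenate(list(samples.values())).mean()
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    ss_within = sum(((samples[g] - means[g]) ** 2).sum() for g in names)
    df_b, df_w = k - 1, N - k
    ms_within = ss_within / df_w
    f_stat = (ss_between / df_b) / ms_within if ms_within > 0 else np.inf
    f_p = float(sps.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0

    treat = [g for g in names if g != control]
    n0 = ns[control]
    est = np.array([means[g] - means[control] for g in treat])
    se = np.array([math.sqrt(ms_within * (1.0 / ns[g] + 1.0 / n0)) for g in treat])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    n_treat = [ns[g] for g in treat]
    p_adj = np.array(
        [dunnett_pvalue(abs(t), n_treat, n0, df_w) if np.isfinite(t) else 0.0
         for t in tstats]
    )
    return DunnettResult(
        groups=tuple(treat),
        estimates=est,
        t_statistics=tstats,
        p_adjusted=p_adj,
        f_statistic=float(f_stat),
        f_pvalue=f_p,
        df_resid=df_w,
    )


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov on binned histograms
# ---------------------------------------------------------------------------


def ks_binned(hist_a, hist_b) -> tuple[float, float]:
    """Two-sample KS on identically-binned histograms.

    ``D`` is the maximum CDF gap evaluated at the bin boundaries; ``p`` is
    the asymptotic Kolmogorov distribution with the effective sample size
    ``n_a n_b / (n_a + n_b)``.  Exact within-bin values are never
    reconstructed, so D is the binned statistic, not the underlying one.
    """
    ea, eb = np.asarray(hist_a.bin_edges), np.asarray(hist_b.bin_edges)
    if ea.shape != eb.shape or not np.array_equal(ea, eb):
        raise ValueError("histograms must share identical bin edges")
    ca, cb = np.asarray(hist_a.counts, float), np.asarray(hist_b.counts, float)
    na, nb = ca.sum(), cb.sum()
    if na == 0 or nb == 0:
        raise ValueError("both histograms must be non-empty")
    d = float(np.max(np.abs(np.cumsum(ca) / na - np.cumsum(cb) / nb)))
    n_eff = na * nb / (na + nb)
    p = float(special.kolmogorov(math.sqrt(n_eff) * d))
    return d, p


# ---------------------------------------------------------------------------
# Concentration-response R^2
# ---------------------------------------------------------------------------


def concentration_response_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """R^2 of a simple ordinary-least-squares linear fit of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired points")
    if np.var(y) == 0:
        raise ValueError("zero variance in y: R^2 undefined")
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


# ---------------------------------------------------------------------------
# LC-MS calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted 1/x quadratic calibration: response ratio vs concentration.

    ``coefficients`` are (intercept, linear, quadratic); ``valid_range`` is
    the calibrated concentration span in uM and ``lloq`` the lower limit of
    quantitation (default 0.0073 uM).
    """

    coefficients: tuple[float, float, float]
    valid_range: tuple[float, float]
    lloq: float = PLX3397_LLOQ_UM
    monotone: bool = True

    def predict(self, conc: float | np.ndarray) -> np.ndarray:
        a, b, c = self.coefficients
        x = np.asarray(conc, float)
        return a + b * x + c * x**2


@dataclass(frozen=True)
class BackCalcResult:
    """A back-calculated concentration with its LLOQ flag."""

    concentration: float
    below_lloq: bool


def fit_calibration(
    concentrations: Sequence[float],
    ratios: Sequence[float],
    lloq: float = PLX3397_LLOQ_UM,
) -> CalibrationCurve:
    """Fit ``ratio = a + b x + c x^2`` minimizing ``sum (y - f)^2 / x``.

    Standards must be at >= 4 distinct, strictly positive concentrations
    (the 1/x weight is undefined at zero).  A non-monotone fit over the
    calibrated range triggers a warning and is flagged on the curve.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(ratios, float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive (1/x weights)")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 standards at distinct concentrations")
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    X = np.column_stack([np.ones_like(x), x, x**2])
    w = 1.0 / x
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    a, b, c = (float(v) for v in beta)
    lo, hi = float(x.min()), float(x.max())
    # monotone iff derivative b + 2 c x keeps one sign on [lo, hi]
    d_lo, d_hi = b + 2 * c * lo, b + 2 * c * hi
    monotone = (d_lo >= 0 and d_hi >= 0) or (d_lo <= 0 and d_hi <= 0)
    if not monotone:
        warnings.warn(
            "calibration curve is not monotone over the calibrated range",
            stacklevel=2,
        )
    return CalibrationCurve(
        coefficients=(a, b, c), valid_range=(lo, hi), lloq=lloq, monotone=monotone
    )


def back_calculate(curve: CalibrationCurve, ratio: float) -> BackCalcResult:
    """Invert the calibration curve: response ratio -> concentration (uM).

    Solves the quadratic for its real root inside the calibrated range
    (with a small extrapolation margin); no in-range real root is an
    out-of-range error.  Concentrations below the LLOQ are flagged.
    """
    a, b, c = curve.coefficients
    lo, hi = curve.valid_range
    margin = 0.05 * (hi - lo)
    if c == 0.0:
        if b == 0:
            raise ValueError("degenerate calibration curve")
        roots = np.array([(ratio - a) / b])
    else:
        disc = b * b - 4 * c * (a - ratio)
        if disc < 0:
            raise ValueError("response ratio outside the calibrated response range")
        # cancellation-free quadratic formula: one root via q, one via Vieta
        q = -0.5 * (b + math.copysign(math.sqrt(disc), b if b != 0 else 1.0))
        roots = [q / c]
        if q != 0:
            roots.append((a - ratio) / q)
        roots = np.array(roots)
    in_range = roots[(roots >= lo - margin) & (roots <= hi + margin)]
    if len(in_range) == 0:
        raise ValueError(
            f"no real root in the calibrated range [{lo:g}, {hi:g}] uM"
        )
    conc = float(in_range[np.argmin(np.abs(in_range - 0.5 * (lo + hi)))])
    return BackCalcResult(concentration=conc, below_lloq=conc < curve.lloq)


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------


def analyze_cohort(
    table: pd.DataFrame, control: str, by_sex: bool = False
) -> pd.DataFrame:
    """Depletion and Dunnett statistics for every region of a cohort table.

    Returns a tidy frame with one row per (region, treatment group):
    percent depletion +/- delta-method SE, the Dunnett-adjusted p, and the
    region's overall ANOVA F and p.  With ``by_sex`` the same analysis is
    repeated within each sex (no interaction model is fitted).
    """
    frames = []
    strata = [("pooled", table)]
    if by_sex and "sex" in table.columns:
        strata += [(s, table[table["sex"] == s]) for s in sorted(table["sex"].unique())]
    for stratum, tab in strata:
        for region in tab["region"].unique():
            dep = {d.group: d for d in depletion_percent(tab, control, region)}
            try:
                dun = anova_dunnett(tab, control, region)
            except ValueError:
                if stratum == "pooled":
                    raise
                continue  # a sex stratum without replication is skipped
            for g, t, p in zip(dun.groups, dun.t_statistics, dun.p_adjusted):
                d = dep[g]
                frames.append(
                    {
                        "stratum": stratum,
                        "region": region,
                        "group": g,
                        "percent_depletion": d.percent_depletion,
                        "se": d.se,
                        "mean_density": d.mean_group,
                        "control_mean_density": d.mean_control,
                        "t_statistic": t,
                        "p_adjusted": p,
                        "anova_f": dun.f_statistic,
                        "anova_p": dun.f_pvalue,
                    }
                )
    return pd.DataFrame(frames)
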