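"""Four-parameter logistic (4PL) competition fitting for site-level
dose-response data.

For a site covalently labeled by the probe, pre-incubation with a
competing inhibitor reduces the labeled-peptide intensity dose-dependently.
The response (log2 site intensity) as a function of inhibitor concentration
``c`` is modeled as

    y(c) = bottom + (top − bottom) / (1 + (c / IC50)^h)

with ``top`` the uninhibited plateau, ``bottom`` the fully competed plateau,
``h > 0`` the Hill slope, and the apparent IC50 in concentration units (nM).
The model is fitted in concentration space, so the vehicle control (dose 0)
participates naturally as an exact top-plateau anchor: y(0) = top. The fit
is parameterized internally by log10(IC50), on which the asymptotic 95%
confidence interval is computed and back-transformed — hence intervals that
are asymmetric in nM, as dose-response intervals should be.

A site is called *competed* when the 4PL explains the data significantly
better than a flat line (extra-sum-of-squares F-test, p < 0.05), the fitted
drop is at least one log2 unit (a two-fold intensity loss), and the IC50
falls within a decade of the tested concentration range; *stable* when the
F-test is not significant; *ambiguous* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseSeries",
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "ic50_confidence_interval",
    "classify_site",
    "fit_all_sites",
    "plot_dose_response",
]

#: Hill-slope bounds; the variable-slope model with a physically plausible
#: slope range.
HILL_BOUNDS = (0.1, 10.0)

#: Calls
COMPETED, STABLE, AMBIGUOUS, NOT_FIT = "competed", "stable", "ambiguous", "not_fit"


@dataclass
class DoseSeries:
    """Observed responses across inhibitor doses for one site and protease.

    ``doses`` (nM, 0 = vehicle control) and ``responses`` are parallel
    arrays with one entry per replicate measurement; missing measurements
    are simply absent. At least four distinct dose levels are required to
    attempt a four-parameter fit.
    """

    doses: np.ndarray
    responses: np.ndarray
    protease: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must be parallel arrays")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(~np.isfinite(self.responses)):
            raise ValueError("responses must be finite (drop missing values)")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.doses))


@dataclass
class FourPLFit:
    """Result of a 4PL fit: parameters, uncertainty, diagnostics, call."""

    top: float = np.nan
    bottom: float = np.nan
    hill: float = np.nan
    ic50: float = np.nan
    log10_ic50: float = np.nan
    log10_ic50_se: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    rss: float = np.nan
    rss_null: float = np.nan
    f_pvalue: float = np.nan
    n_points: int = 0
    converged: bool = False
    call: str = NOT_FIT
    flags: list[str] = field(default_factory=list)

    @property
    def amplitude(self) -> float:
        """Fitted drop, top − bottom (log2 units when fitting log2 data)."""
        return self.top - self.bottom


def four_pl(c, top, bottom, log10_ic50, hill):
    """Model value; c = 0 evaluates to ``top`` exactly."""
    c = np.asarray(c, dtype=float)
    ratio = np.zeros_like(c)
    pos = c > 0
    ratio[pos] = (c[pos] / 10.0**log10_ic50) ** hill
    return bottom + (top - bottom) / (1.0 + ratio)


def _four_pl_jac(c, top, bottom, log10_ic50, hill):
    """Analytic Jacobian of the model w.r.t. (top, bottom, log10_ic50, hill)."""
    c = np.asarray(c, dtype=float)
    n = len(c)
    r = np.zeros(n)
    logx = np.zeros(n)  # ln(c / ic50) where defined
    pos = c > 0
    logx[pos] = np.log(c[pos]) - np.log(10.0) * log10_ic50
    r[pos] = np.exp(hill * logx[pos])
    g = 1.0 / (1.0 + r)
    amp = top - bottom
    dg = -amp * r / (1.0 + r) ** 2  # d model / d r * r  (log-derivative helper)
    jac = np.empty((n, 4))
    jac[:, 0] = g
    jac[:, 1] = 1.0 - g
    jac[:, 2] = -dg * hill * np.log(10.0)  # d r / d q = -h ln10 · r
    jac[:, 3] = dg * logx  # d r / d h = ln(c/ic50) · r
    return jac


def _null_rss(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2))


def fit_4pl(series: DoseSeries, min_levels: int = 4) -> FourPLFit:
    """Least-squares 4PL fit with deterministic multi-start initialization.

    Starts place log10(IC50) at every tested positive dose (plus slope
    variations at the geometric mid-dose); plateau starts come from the mean
    responses at the extreme doses. The best-RSS converged solution wins.
    Fewer than ``min_levels`` distinct doses yields a ``not_fit`` result;
    an optimizer failure from every start is reported as not converged,
    never silently accepted.
    """
    c, y = series.doses, series.responses
    n = len(y)
    fit = FourPLFit(n_points=n)
    if series.n_levels < min_levels:
        fit.flags.append("too_few_dose_levels")
        return fit
    fit.rss_null = _null_rss(y)
    if fit.rss_null == 0.0:
        # perfectly flat data: constant model is exact, IC50 undefined
        fit.top = fit.bottom = float(y[0])
        fit.hill = np.nan
        fit.rss = 0.0
        fit.converged = True
        fit.call = STABLE
        fit.flags.append("flat")
        return fit

    pos = np.unique(c[c > 0])
    q_lo, q_hi = np.log10(pos.min()) - 4.0, np.log10(pos.max()) + 4.0
    lo = np.array([-np.inf, -np.inf, q_lo, HILL_BOUNDS[0]])
    hi = np.array([np.inf, np.inf, q_hi, HILL_BOUNDS[1]])

    top0 = float(y[c == c.min()].mean())
    bottom0 = float(y[c == c.max()].mean())
    q_mid = float(np.log10(pos).mean())
    starts = [(float(np.log10(d)), 1.0) for d in pos]
    starts += [(q_mid, 0.3), (q_mid, 3.0)]

    def residuals(theta):
        return four_pl(c, *theta) - y

    def jacobian(theta):
        return _four_pl_jac(c, *theta)

    # coarse multi-start, then a single high-precision polish of the winner;
    # an iteration-capped start with a usable minimum is still a candidate
    # (a flat response surface makes top≈bottom fits converge slowly in the
    # unidentifiable IC50/Hill directions)
    best = None
    best_success = False
    for q0, h0 in starts:
        theta0 = np.clip([top0, bottom0, q0, h0], lo, hi)
        try:
            res = optimize.least_squares(
                residuals, theta0, jac=jacobian, bounds=(lo, hi),
                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=150,
            )
        except Exception:  # numerical failure from this start
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
            best_success = bool(res.success)
    if best is None:
        fit.flags.append("optimizer_failed")
        return fit
    try:
        polished = optimize.least_squares(
            residuals, best[1].x, jac=jacobian, bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=600,
        )
        if 2.0 * polished.cost <= best[0] + 1e-12:
            best = (float(2.0 * polished.cost), polished)
            best_success = best_success or bool(polished.success)
    except Exception:
        pass
    if not best_success:
        fit.flags.append("iteration_capped")

    rss, res = best
    top, bottom, q, h = res.x
    fit.top, fit.bottom = float(top), float(bottom)
    fit.hill = float(h)
    fit.log10_ic50 = float(q)
    fit.ic50 = float(10.0**q)
    fit.rss = rss
    fit.converged = True
    if not (pos.min() <= fit.ic50 <= pos.max()):
        fit.flags.append("extrapolated")

    # asymptotic covariance on the fit scale, residual-variance scaled
    dof = n - 4
    if dof > 0:
        jac = res.jac
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof)
            se = float(np.sqrt(max(cov[2, 2], 0.0)))
            fit.log10_ic50_se = se
        except np.linalg.LinAlgError:
            fit.flags.append("singular_covariance")
            fit.log10_ic50_se = np.inf
    else:
        fit.flags.append("zero_dof")
        fit.log10_ic50_se = np.inf
    fit.ci95 = ic50_confidence_interval(fit)
    return fit


def ic50_confidence_interval(fit: FourPLFit, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic confidence interval for the IC50, in nM.

    A t-interval on log10(IC50) using the residual-variance-scaled parameter
    covariance, back-transformed to concentration units — asymmetric around
    the IC50, as printed dose-response intervals are. A singular covariance
    yields an unbounded (0, inf) interval, flagged on the fit.
    """
    if not fit.converged or not np.isfinite(fit.log10_ic50):
        return (np.nan, np.nan)
    dof = fit.n_points - 4
    if dof <= 0 or not np.isfinite(fit.log10_ic50_se):
        return (0.0, np.inf)
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    half = tq * fit.log10_ic50_se
    lo = fit.log10_ic50 - half
    hi = fit.log10_ic50 + half
    # a half-width beyond ~300 decades is numerically unbounded
    return (
        0.0 if lo < -300 else float(10.0**lo),
        np.inf if hi > 300 else float(10.0**hi),
    )


def classify_site(
    fit: FourPLFit,
    series: DoseSeries,
    alpha: float = 0.05,
    min_drop: float = 1.0,
    range_factor: float = 10.0,
) -> str:
    """Competed / stable / ambiguous call for a fitted site.

    *Competed* requires (i) the 4PL to beat the constant model in an
    extra-sum-of-squares F-test at ``alpha``, (ii) a fitted drop of at least
    ``min_drop`` response units (1 log2 unit = two-fold), and (iii) an IC50
    within ``range_factor`` of the tested dose range. A non-significant
    F-test is *stable*; anything else (significant but shallow or
    out-of-range) is *ambiguous*. The call is stored on the fit and
    returned.
    """
    if not fit.converged:
        fit.call = NOT_FIT
        return fit.call
    if "flat" in fit.flags:
        fit.call = STABLE
        return fit.call
    n = fit.n_points
    df1, df2 = 3, n - 4  # 4PL adds 3 parameters over the constant model
    if df2 <= 0:
        fit.call = NOT_FIT
        fit.flags.append("zero_dof")
        return fit.call
    if fit.rss <= 0.0:
        pval = 0.0
    else:
        f_stat = ((fit.rss_null - fit.rss) / df1) / (fit.rss / df2)
        pval = float(stats.f.sf(max(f_stat, 0.0), df1, df2))
    fit.f_pvalue = pval
    if pval >= alpha:
        fit.call = STABLE
        return fit.call
    pos = series.doses[series.doses > 0]
    in_range = (
        np.isfinite(fit.ic50)
        and pos.min() / range_factor <= fit.ic50 <= pos.max() * range_factor
    )
    if fit.amplitude >= min_drop and in_range:
        fit.call = COMPETED
    else:
        fit.call = AMBIGUOUS
    return fit.call


def fit_all_sites(
    matrix,
    annotation,
    use_log2: bool = True,
    alpha: float = 0.05,
    min_drop: float = 1.0,
    range_factor: float = 10.0,
) -> "pd.DataFrame":
    """Fit every site × protease series in a site quantification matrix.

    Fits are independent per protease — evidence from different proteases is
    never pooled into one curve. Rows are emitted in deterministic
    (site, protease) order; every site with any data for a protease receives
    a call (``not_fit`` when fewer than four dose levels survive).

    Returns a tidy table: site, protease, call, ic50_nM, ci_low_nM,
    ci_high_nM, hill, top, bottom, rss, f_pvalue, n_points, converged, flags.
    """
    import pandas as pd

    data = matrix.log2 if use_log2 else matrix.intensity
    rows = []
    for protease in sorted(annotation["protease"].unique()):
        sub = annotation[annotation["protease"] == protease]
        samples = [s for s in sub.index if s in data.columns]
        doses = sub.loc[samples, "dose_nM"].to_numpy(dtype=float)
        for site in data.index:
            values = data.loc[site, samples].to_numpy(dtype=float)
            ok = np.isfinite(values)
            if not ok.any():
                continue
            series = DoseSeries(doses[ok], values[ok], protease=protease)
            fit = fit_4pl(series)
            classify_site(fit, series, alpha=alpha, min_drop=min_drop,
                          range_factor=range_factor)
            rows.append(
                {
                    "site": site,
                    "protease": protease,
                    "call": fit.call,
                    "ic50_nM": fit.ic50,
                    "ci_low_nM": fit.ci95[0],
                    "ci_high_nM": fit.ci95[1],
                    "hill": fit.hill,
                    "top": fit.top,
                    "bottom": fit.bottom,
                    "rss": fit.rss,
                    "f_pvalue": fit.f_pvalue,
                    "n_points": fit.n_points,
                    "converged": fit.converged,
                    "flags": ";".join(fit.flags),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["site", "protease"], kind="stable").reset_index(drop=True)
    return out


def plot_dose_response(series: DoseSeries, fit: FourPLFit, ax=None, label: str = ""):
    """Dose vs mean ± SEM with the fitted curve, on a log concentration axis.

    The vehicle control (dose 0) is drawn at a tick one decade below the
    lowest tested dose, a display convention only — the fit itself treats
    dose 0 exactly.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    pos = np.unique(series.doses[series.doses > 0])
    zero_pos = pos.min() / 10.0
    means, sems, xs = [], [], []
    for d in np.unique(series.doses):
        vals = series.responses[series.doses == d]
        xs.append(zero_pos if d == 0 else d)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
    ax.errorbar(xs, means, yerr=sems, fmt="o", capsize=3, label=label or None)
    if fit.converged and "flat" not in fit.flags:
        grid = np.geomspace(zero_pos, pos.max(), 200)
        ax.plot(grid, four_pl(grid, fit.top, fit.bottom, fit.log10_ic50, fit.hill))
    ax.set_xscale("log")
    ax.set_xlabel("inhibitor (nM)")
    ax.set_ylabel("log2 intensity")
    if label:
        ax.legend(frameon=False)
    return ax
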