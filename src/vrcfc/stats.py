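"""Statistical layer: paired tests, effect sizes, Bonferroni, KS, and
the linear mixed-effects extinction model.

Within-subject contrasts (shock-paired vs neutral context) use the
two-sided paired t-test with a t-distribution 95% confidence interval
of the mean difference, and the paired effect size d_z =
mean(diff)/sd(diff) (the averaged-variance variant d_av is available by
option).  Extinction across recall days is modelled per context as

    freezing ~ C(day, reference = pre-conditioning baseline) + (1 | mouse)

fit by REML with normal-approximation (Wald) p-values, reporting one
estimate ± SE and p per recall day relative to the day-0 baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "PairedTestResult",
    "paired_test",
    "cohens_d_paired",
    "bonferroni",
    "ks_two_sample",
    "LMEResult",
    "fit_lme_freezing",
    "simulate_extinction_table",
]


@dataclass
class PairedTestResult:
    t: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False  # all differences identical


def paired_test(a, b, ci: float = 0.95) -> PairedTestResult:
    """Two-sided paired t-test of ``b - a`` with a 95% CI of the mean.

    With identical differences across subjects the test statistic is
    undefined (zero variance); the result is flagged ``degenerate``
    with ``t=0, p=1`` when the common difference is 0 and NaN stats
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired test requires n >= 2")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t, p = (0.0, 1.0) if mean == 0.0 else (float("nan"), float("nan"))
        return PairedTestResult(t, p, mean, mean, mean, n, degenerate=True)
    res = sps.ttest_rel(b, a)
    half = sps.t.ppf(0.5 + ci / 2.0, n - 1) * sd / np.sqrt(n)
    return PairedTestResult(
        float(res.statistic), float(res.pvalue), mean,
        mean - half, mean + half, n,
    )


def cohens_d_paired(a, b, variant: str = "dz") -> float:
    """Paired Cohen's d of ``b - a``.

    ``dz`` (default) is mean(diff)/sd(diff), the natural within-subject
    effect size; ``av`` divides by the average of the two condition
    standard deviations instead.  Zero-variance differences give NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired effect size requires equal-length samples, n >= 2")
    d = b - a
    if variant == "dz":
        denom = d.std(ddof=1)
    elif variant == "av":
        denom = 0.5 * (a.std(ddof=1) + b.std(ddof=1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(d.mean() / denom) if denom > 0 else float("nan")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-tailed two-sample Kolmogorov-Smirnov statistic and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# extinction LME
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    """Per-day fixed effects of the extinction model.

    ``days`` has columns ``day, estimate, se, p`` (days relative to the
    baseline); ``intercept`` is the baseline mean.  ``singular`` flags a
    degenerate random-intercept variance (estimates still returned).
    """

    days: pd.DataFrame
    intercept: float
    intercept_se: float
    random_intercept_var: float
    residual_var: float
    converged: bool
    singular: bool
    context: str
    metric: str
    n_mice: int

    def estimate(self, day: str) -> float:
        return float(self.days.set_index("day").loc[day, "estimate"])


def fit_lme_freezing(
    table: pd.DataFrame,
    context: str,
    metric: str = "average",
    baseline: str = "Day0",
) -> LMEResult:
    """Fit the extinction mixed model for one context and metric.

    ``table`` is long-format with columns ``mouse_id, vr_context, day,
    metric, freezing_pct``.  Recall days enter as categorical fixed
    effects with the pre-conditioning day-0 measurement as the
    reference level and a random intercept per mouse; REML estimates
    with Wald (normal-approximation) p-values.
    """
    sub = table[(table["vr_context"] == context)]
    if "metric" in sub.columns:
        sub = sub[sub["metric"] == metric]
    sub = sub[sub["day"] != "Habituation"].copy()
    days_present = sub["day"].unique()
    if baseline not in days_present:
        raise ValueError(f"baseline day {baseline!r} absent from table")
    if len(days_present) < 2:
        raise ValueError("need >= 2 days to model extinction")
    if sub["mouse_id"].nunique() < 3:
        raise ValueError("need >= 3 mice for the mixed model")
    formula = f"freezing_pct ~ C(day, Treatment('{baseline}'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, sub, groups=sub["mouse_id"])
        fit = model.fit(reml=True)
    prefix = f"C(day, Treatment('{baseline}'))[T."
    rows = []
    for name, est in fit.params.items():
        if name.startswith(prefix):
            day = name[len(prefix):-1]
            rows.append(
                {
                    "day": day,
                    "estimate": float(est),
                    "se": float(fit.bse[name]),
                    "p": float(fit.pvalues[name]),
                }
            )
    days = pd.DataFrame(rows, columns=["day", "estimate", "se", "p"])
    re_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    return LMEResult(
        days=days,
        intercept=float(fit.params["Intercept"]),
        intercept_se=float(fit.bse["Intercept"]),
        random_intercept_var=re_var,
        residual_var=float(fit.scale),
        converged=bool(fit.converged),
        singular=bool(re_var < 1e-8),
        context=context,
        metric=metric,
        n_mice=int(sub["mouse_id"].nunique()),
    )


def simulate_extinction_table(
    n_mice: int = 20,
    day_effects: dict[str, float] | None = None,
    baseline_mean: float = 15.0,
    mouse_sd: float = 3.0,
    resid_sd: float = 4.0,
    context: str = "cfc",
    metric: str = "average",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Long-format freezing table with known fixed effects.

    Each mouse contributes one observation per day: baseline mean, plus
    the day's fixed effect, plus a mouse-level random intercept
    (``mouse_sd``) and i.i.d. residual noise (``resid_sd``).  Used for
    parameter-recovery and null-calibration checks of the extinction
    model.
    """
    rng = np.random.default_rng(rng)
    if day_effects is None:
        day_effects = {"Recall1": 10.0, "Recall2": 3.0, "Recall3": 1.0,
                       "Recall4": 0.0}
    days = ["Day0", *day_effects.keys()]
    effects = {"Day0": 0.0, **day_effects}
    rows = []
    for mouse in range(n_mice):
        intercept = rng.normal(0.0, mouse_sd)
        for day in days:
            rows.append(
                {
                    "mouse_id": mouse,
                    "vr_context": context,
                    "day": day,
                    "metric": metric,
                    "freezing_pct": baseline_mean + effects[day] + intercept
                    + rng.normal(0.0, resid_sd),
                }
            )
    return pd.DataFrame(rows)
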