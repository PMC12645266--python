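"""Descriptive behavioral summaries and default-prior Bayesian tests.

Provides the per-subject, per-recipient summaries (work-choice rate, choice
RT, force AUC, success rate), the JZS paired-sample Bayes factor with the
default Cauchy prior on the standardized effect (r scale 0.707), and the
default-prior Pearson-correlation Bayes factor (stretched-beta prior on the
correlation, width 1).  All Bayes factors are reported as BF01 — evidence
for the null over the alternative — with the conventional evidence bands
(3-10 moderate null, >10 strong null; 0.3-0.1 moderate alternative,
<0.1 strong alternative).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "summarize_behavior",
    "jzs_paired_bf",
    "pearson_bf",
    "bf_category",
]


def summarize_behavior(data: pd.DataFrame):
    """Per-subject x recipient behavioral summaries plus group means/SDs.

    Rates are computed over responded trials only; force AUC and success
    only over work-choice trials.  Returns ``(per_subject, group, flags)``
    where ``flags`` lists subject x recipient cells with no responded
    trials (their rates are reported as missing rather than propagated).
    """
    required = {"subject_id", "recipient", "choice", "rt_s", "force_auc", "success"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    bad = ~data["choice"].isin(["work", "rest", "nonresponse"])
    if bad.any():
        rows = data.index[bad].tolist()[:5]
        raise ValueError(f"invalid choice values at rows {rows}")

    rows = []
    flags = []
    for (sid, rec), grp in data.groupby(["subject_id", "recipient"], sort=True):
        responded = grp[grp["choice"] != "nonresponse"]
        n_nonresp = int((grp["choice"] == "nonresponse").sum())
        if responded.empty:
            flags.append({"subject_id": sid, "recipient": rec,
                          "reason": "no responded trials"})
            rows.append((sid, rec, np.nan, np.nan, np.nan, np.nan, n_nonresp))
            continue
        work = responded[responded["choice"] == "work"]
        work_rate = len(work) / len(responded)
        mean_rt = responded["rt_s"].mean()
        mean_force = work["force_auc"].mean() if len(work) else np.nan
        succ = work["success"].astype("boolean")
        success_rate = float(succ.mean()) if len(work) else np.nan
        rows.append((sid, rec, work_rate, mean_rt, mean_force, success_rate, n_nonresp))
    per_subject = pd.DataFrame(
        rows,
        columns=["subject_id", "recipient", "work_choice_rate", "mean_rt_s",
                 "mean_force_auc", "success_rate", "n_nonresponse"],
    )
    group = (
        per_subject.groupby("recipient")[
            ["work_choice_rate", "mean_rt_s", "mean_force_auc", "success_rate"]
        ]
        .agg(["mean", "std"])
    )
    return per_subject, group, flags


# ---------------------------------------------------------------------------
# JZS paired-sample Bayes factor


def jzs_paired_bf(x, y, rscale: float = 0.707) -> float:
    """BF01 of the paired default-prior Bayesian t-test (JZS).

    The test is the one-sample default-prior t-test on the paired
    differences: under H1 the standardized effect has a Cauchy(0, rscale)
    prior, equivalently the Zellner-Siow g-prior with g ~ InverseGamma(1/2,
    rscale^2/2).  BF01 > 1 favors the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in length: {x.size} vs {y.size}")
    d = x - y
    n = d.size
    if n < 3:
        raise ValueError("paired Bayes factor requires n >= 3")
    if not np.all(np.isfinite(d)):
        raise ValueError("paired differences contain non-finite values")
    if n < 5:
        warnings.warn(f"n = {n} pairs is very small; the Bayes factor is fragile",
                      stacklevel=2)
    sd = d.std(ddof=1)
    if sd == 0.0 and d.mean() == 0.0:
        t = 0.0
    elif sd == 0.0:
        return 0.0  # infinitely strong evidence against the null
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
    return jzs_bf01_from_t(t, n, rscale=rscale)


def jzs_bf01_from_t(t: float, n: int, rscale: float = 0.707) -> float:
    """BF01 from a one-sample t statistic via the JZS g-prior integral."""
    nu = n - 1

    def integrand(g):
        # marginal likelihood under H1 relative to H0, up to shared factors
        return (
            (1.0 + n * g) ** -0.5
            * (1.0 + t**2 / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * _invgamma_half_pdf(g, rscale)
        )

    num, _ = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-10, limit=200)
    den = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    bf10 = num / den
    return float(1.0 / bf10)


def _invgamma_half_pdf(g, rscale):
    """InverseGamma(1/2, rscale^2/2) density (the Cauchy prior's g-mixture)."""
    s2 = rscale**2
    return (s2 / 2.0) ** 0.5 / special.gamma(0.5) * g ** -1.5 * np.exp(-s2 / (2.0 * g))


# ---------------------------------------------------------------------------
# default-prior correlation Bayes factor


def _r_density_ratio(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Sampling density of the observed correlation at rho, relative to rho=0.

    Uses the exact small-sample density of Pearson's r; factors free of rho
    cancel in the Bayes-factor ratio.
    """
    term = (1.0 - rho**2) ** ((n - 1) / 2.0) * (1.0 - rho * r) ** (1.5 - n)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    hyp0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return term * hyp / hyp0


def pearson_bf(x, y, width: float = 1.0) -> tuple[float, float]:
    """Sample Pearson correlation plus its default-prior BF01.

    Under H1 the population correlation has a stretched-beta prior of width
    ``width`` (width 1 is uniform on (-1, 1), the JASP default).  Returns
    ``(r, BF01)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in length: {x.size} vs {y.size}")
    n = x.size
    if n < 4:
        raise ValueError("correlation Bayes factor requires n >= 4")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])

    a = 1.0 / width  # stretched Beta(1/width, 1/width) on (-1, 1)

    def prior(rho):
        return ((1.0 - rho**2) ** (a - 1.0)
                / (special.beta(a, a) * 2.0 ** (2.0 * a - 1.0)))

    with warnings.catch_warnings():
        # near |r| = 1 the integrand is a boundary spike; quad still reaches
        # the achievable accuracy but emits a roundoff warning
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        bf10, _ = integrate.quad(
            lambda rho: _r_density_ratio(r, rho, n) * prior(rho),
            -1.0, 1.0, epsrel=1e-10, limit=400, points=[r],
        )
    return r, float(1.0 / bf10)


def bf_category(bf01: float) -> str:
    """Evidence band of a BF01 value (null vs. alternative)."""
    if bf01 > 10.0:
        return "strong null"
    if bf01 >= 3.0:
        return "moderate null"
    if bf01 < 0.1:
        return "strong alternative"
    if bf01 <= 0.3:
        return "moderate alternative"
    return "anecdotal"
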