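"""PSIS-LOO model comparison and per-subject best-model attribution.

Implements Pareto-smoothed importance sampling leave-one-out
cross-validation from the pointwise log-likelihood matrix: per observation,
the upper ~20% of importance ratios is replaced by quantiles of a
generalized Pareto distribution fitted with the Zhang-Stephens (2009)
posterior-weighted estimator, weights are truncated at the raw maximum, and
the smoothed ratios give the leave-one-out predictive density.  LOOIC is
``-2 * elpd_loo``; lower is better.

Subject-level LOOIC sums each subject's pointwise contributions from the
joint hierarchical fit (no per-subject refits); ties in best-model
attribution go to the model with fewer subject-level parameter components.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference.fit import FitResult
from .value_models import ModelSpec

__all__ = [
    "LooResult",
    "ComparisonTable",
    "psis_loo",
    "compare_models",
    "per_subject_best_model",
]

PARETO_K_WARN = 0.7


@dataclasses.dataclass
class LooResult:
    elpd_loo: float
    se: float
    looic: float
    pointwise: np.ndarray   # per-observation elpd contributions
    pareto_k: np.ndarray    # per-observation GPD shape diagnostics

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Zhang-Stephens (2009) empirical-Bayes generalized-Pareto fit.

    ``x`` are sorted exceedances over the tail cutoff.  Returns the shape
    ``k`` (with the weak prior pulling it toward 0.5, as in the loo package)
    and scale ``sigma`` in the parameterization used by :func:`_gpd_quantiles`.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    m = 30 + int(np.sqrt(n))
    prior_bs, prior_k = 3.0, 10.0
    j = np.arange(1, m + 1, dtype=float)
    b = 1.0 - np.sqrt(m / (j - 0.5))
    b = b / (prior_bs * x[int(n / 4 + 0.5) - 1]) + 1.0 / x[-1]
    k = np.mean(np.log1p(-b[:, None] * x), axis=1)       # profile of the shape
    log_lik = n * (np.log(-b / k) - k - 1.0)
    weights = 1.0 / np.exp(log_lik - log_lik[:, None]).sum(axis=1)
    keep = weights >= 10 * np.finfo(float).eps
    weights = weights[keep] / weights[keep].sum()
    b_post = float(np.sum(b[keep] * weights))
    k_post = float(np.mean(np.log1p(-b_post * x)))
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    """Inverse CDF of the generalized Pareto distribution (location 0)."""
    if sigma <= 0:
        return np.full_like(p, np.nan)
    if abs(k) < np.finfo(float).eps:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def _psis_smooth_one(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one observation's log importance ratios; returns (log weights, k)."""
    s = log_ratios.size
    lw = log_ratios - log_ratios.max()
    order = np.argsort(lw)
    cutoff_ind = -int(np.ceil(min(s / 5.0, 3.0 * np.sqrt(s)))) - 1
    cutoff = max(lw[order[cutoff_ind]], np.log(np.finfo(float).tiny))
    tail_ids = np.flatnonzero(lw > cutoff)
    n_tail = tail_ids.size
    if n_tail <= 4:
        return lw, np.inf
    tail_order = np.argsort(lw[tail_ids])
    exceed = np.exp(lw[tail_ids][tail_order]) - np.exp(cutoff)
    if np.ptp(exceed) <= 0.0:
        return lw, np.inf
    try:
        with np.errstate(all="ignore"):
            k, sigma = _gpd_fit(exceed)
    except (ZeroDivisionError, FloatingPointError):
        return lw, np.inf
    if np.isfinite(k) and sigma > 0:
        q = (np.arange(n_tail) + 0.5) / n_tail
        smoothed = np.log(_gpd_quantiles(q, k, sigma) + np.exp(cutoff))
        lw = lw.copy()
        lw[tail_ids[tail_order]] = smoothed
        lw[lw > 0] = 0.0            # truncate at the raw maximum
    return lw, k


def psis_loo(pointwise_ll: np.ndarray) -> LooResult:
    """PSIS-LOO from an (observations x posterior draws) log-likelihood matrix."""
    ll = np.asarray(pointwise_ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_ll must be a 2-D (observations x draws) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_ll contains non-finite values")
    n_obs, n_draws = ll.shape
    if n_draws < 100:
        raise ValueError(f"psis_loo requires >= 100 draws, got {n_draws}")
    pointwise = np.empty(n_obs)
    pareto_k = np.empty(n_obs)
    for i in range(n_obs):
        lw, k = _psis_smooth_one(-ll[i])
        lw = lw - logsumexp(lw)
        pointwise[i] = logsumexp(lw + ll[i])
        pareto_k[i] = k
    n_high = int(np.sum(pareto_k > PARETO_K_WARN))
    if n_high:
        warnings.warn(
            f"{n_high} of {n_obs} observations have Pareto k > {PARETO_K_WARN}; "
            "their PSIS-LOO contributions may be unreliable",
            stacklevel=2,
        )
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n_obs * np.var(pointwise)))
    return LooResult(
        elpd_loo=elpd, se=se, looic=-2.0 * elpd, pointwise=pointwise, pareto_k=pareto_k
    )


@dataclasses.dataclass
class ComparisonTable:
    table: pd.DataFrame                # one row per model, sorted by group LOOIC
    subject_looic: pd.DataFrame        # subjects x models
    best_model_per_subject: dict
    proportions: dict[str, float]
    parsimony_note: str | None

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "subject_looic": self.subject_looic.reset_index().to_dict(orient="records"),
            "best_model_per_subject": {str(k): v for k, v in self.best_model_per_subject.items()},
            "proportions": self.proportions,
            "parsimony_note": self.parsimony_note,
        }


def per_subject_best_model(subject_looic: pd.DataFrame) -> tuple[dict, dict[str, float]]:
    """Assign each subject the model minimizing their LOOIC contribution.

    ``subject_looic`` is a subjects-by-models table.  Ties go to the model
    with fewer subject-level parameter components.  Returns (assignment,
    share of subjects per model).
    """
    if subject_looic.shape[1] < 1:
        raise ValueError("no models to attribute")
    complexity = {name: ModelSpec.from_name(name).n_free_components
                  for name in subject_looic.columns}
    best = {}
    for sid, row in subject_looic.iterrows():
        lo = row.min()
        candidates = [m for m in subject_looic.columns if np.isclose(row[m], lo, atol=1e-9)]
        best[sid] = min(candidates, key=lambda m: (complexity[m], m))
    n = len(best)
    shares = {m: sum(1 for v in best.values() if v == m) / n for m in subject_looic.columns}
    return best, shares


def compare_models(fits: list[FitResult]) -> ComparisonTable:
    """Rank fitted models by group LOOIC and attribute a best model per subject.

    All fits must be over the identical retained trial set; a parsimony note
    is added when the top two models differ by less than one standard error
    of their pointwise difference.
    """
    if not fits:
        raise ValueError("no fits to compare")
    key_cols = ["subject_id", "trial", "recipient", "effort_level", "work_shocks", "choice"]
    ref = fits[0].data[key_cols].reset_index(drop=True)
    for f in fits[1:]:
        other = f.data[key_cols].reset_index(drop=True)
        if len(other) != len(ref) or not other.equals(ref):
            raise ValueError(
                f"fit for model {f.model.name} covers a different retained trial "
                f"set than {fits[0].model.name}; comparison would be invalid"
            )
    names = [f.model.name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names in comparison: {names}")

    loos = {}
    rows = []
    subj_ids = ref["subject_id"].to_numpy()
    subject_tables = {}
    for f in fits:
        res = psis_loo(f.pointwise_loglik())
        loos[f.model.name] = res
        rows.append(
            {
                "model": f.model.name,
                "looic": res.looic,
                "looic_se": 2.0 * res.se,
                "elpd_loo": res.elpd_loo,
                "elpd_se": res.se,
                "n_pareto_k_high": res.n_high_k,
            }
        )
        contrib = pd.Series(res.pointwise).groupby(subj_ids).sum() * -2.0
        subject_tables[f.model.name] = contrib
    table = pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)
    subject_looic = pd.DataFrame(subject_tables)
    subject_looic.index.name = "subject_id"

    best, shares = per_subject_best_model(subject_looic)

    note = None
    if len(table) >= 2:
        a, b = table.loc[0, "model"], table.loc[1, "model"]
        diff_pw = loos[a].pointwise - loos[b].pointwise
        se_diff = float(np.sqrt(diff_pw.size * np.var(diff_pw)))
        delta = abs(float(table.loc[0, "elpd_loo"] - table.loc[1, "elpd_loo"]))
        if delta < se_diff:
            note = (
                f"models {a} and {b} differ by {2 * delta:.1f} LOOIC, less than "
                f"one SE of their difference ({2 * se_diff:.1f}); prefer the "
                "more parsimonious model"
            )
    return ComparisonTable(
        table=table,
        subject_looic=subject_looic,
        best_model_per_subject=best,
        proportions=shares,
        parsimony_note=note,
    )
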