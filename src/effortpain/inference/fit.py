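"""Model fitting, convergence diagnostics and fit serialization.

``fit_model`` runs four (by default) independent NUTS chains of 1000
warmup + 1000 sampling iterations each, yielding 4000 posterior draws, and
attaches rank-normalized split R-hat diagnostics for every group-level and
subject-level parameter.  A fit is flagged converged when all R-hat values
are below 1.01; subjects whose subject-level parameters exceed R-hat 1.05
can be excluded with :func:`exclude_nonconvergent_subjects` (the refit is
the caller's responsibility).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd
from scipy import stats

from ..value_models import ModelSpec
from .model import ChoiceModel, prepare_choice_data
from .nuts import NutsConfig, nuts_sample

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "FitResult",
    "fit_model",
    "compute_rhat",
    "compute_hdi",
    "exclude_nonconvergent_subjects",
    "save_fit",
    "load_fit",
]

RHAT_CONVERGED = 1.01
RHAT_EXCLUDE = 1.05


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Standard-normal group-location priors; half-normal group scales."""

    mu_scale: float = 1.0
    sigma_scale: float = 1.0


@dataclasses.dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int | None = None
    target_accept: float = 0.95

    @property
    def n_total_draws(self) -> int:
        return self.n_chains * self.n_samples


# ---------------------------------------------------------------------------
# diagnostics


def _split(x: np.ndarray) -> np.ndarray:
    """Split each chain in half: (m, n) -> (2m, n//2)."""
    m, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)


def _rhat_classic(x: np.ndarray) -> float:
    m, n = x.shape
    if n < 2:
        return float("nan")
    means = x.mean(axis=1)
    within = x.var(axis=1, ddof=1).mean()
    between = n * means.var(ddof=1)
    if within == 0.0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, axis=None).reshape(x.shape)
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def compute_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat (max of bulk and tail/folded variants).

    ``chains`` has shape (n_chains, n_draws); at least 2 chains with at
    least 2 draws each are required.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("compute_rhat requires a (chains >= 2, draws) array")
    if chains.shape[1] < 2:
        raise ValueError("compute_rhat requires at least 2 draws per chain")
    if np.ptp(chains) == 0.0:
        return 1.0
    split = _split(chains)
    bulk = _rhat_classic(_rank_normalize(split))
    folded = _rhat_classic(_rank_normalize(np.abs(split - np.median(split))))
    return max(bulk, folded)


def compute_hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (empirical HDI)."""
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"compute_hdi requires >= 100 draws, got {n}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# ---------------------------------------------------------------------------
# fit result


@dataclasses.dataclass
class FitResult:
    model: ModelSpec
    theta: np.ndarray                 # (chains, draws, dim) unconstrained draws
    param_names: list[str]
    subject_ids: list
    rhat: dict[str, float]
    data: pd.DataFrame                # retained (responded) trials used in the fit
    n_nonresponse_dropped: int
    sampler: SamplerConfig
    diagnostics: dict

    def __post_init__(self) -> None:
        self._model_cache: ChoiceModel | None = None

    @property
    def choice_model(self) -> ChoiceModel:
        if self._model_cache is None:
            self._model_cache = ChoiceModel(self.data, self.model)
        return self._model_cache

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_CONVERGED

    def flat_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def subject_param_draws(self) -> dict[str, np.ndarray]:
        """Constrained subject-level draws: name -> (n_draws, n_subjects)."""
        cm = self.choice_model
        flat = self.flat_theta()
        out = {k: np.empty((flat.shape[0], cm.n_subjects))
               for k in ("kappa_self", "kappa_other", "beta_self", "beta_other")}
        for d in range(flat.shape[0]):
            params = cm.subject_parameters(flat[d])
            for k, v in params.items():
                out[k][d] = v
        return out

    def subject_param_means(self) -> pd.DataFrame:
        """Posterior-mean subject parameters, with |kappa| convenience columns."""
        draws = self.subject_param_draws()
        df = pd.DataFrame({k: v.mean(axis=0) for k, v in draws.items()})
        df.insert(0, "subject_id", self.subject_ids)
        df["abs_kappa_self"] = df["kappa_self"].abs()
        df["abs_kappa_other"] = df["kappa_other"].abs()
        return df

    def group_param_draws(self) -> dict[str, np.ndarray]:
        """Group-level derived draws (each a flat vector of length n_draws).

        ``group_abs_kappa_*`` are posteriors of the across-subject mean of
        |kappa|; ``group_beta`` of the across-subject mean beta;
        ``delta_abs_kappa`` is |kappa_self| - |kappa_other| averaged over
        subjects (the self-vs-other discounting contrast).
        """
        sub = self.subject_param_draws()
        return {
            "group_abs_kappa_self": np.abs(sub["kappa_self"]).mean(axis=1),
            "group_abs_kappa_other": np.abs(sub["kappa_other"]).mean(axis=1),
            "group_beta": sub["beta_self"].mean(axis=1),
            "group_beta_other": sub["beta_other"].mean(axis=1),
            "delta_abs_kappa": (np.abs(sub["kappa_self"]) - np.abs(sub["kappa_other"])).mean(axis=1),
        }

    def pointwise_loglik(self, dtype=np.float32) -> np.ndarray:
        """Per-trial log-likelihood matrix (retained trials x posterior draws)."""
        return self.choice_model.pointwise_loglik(self.flat_theta(), dtype=dtype)

    def summary(self) -> pd.DataFrame:
        rows = []
        flat = self.flat_theta()
        for j, name in enumerate(self.param_names):
            lo, hi = compute_hdi(flat[:, j]) if flat.shape[0] >= 100 else (np.nan, np.nan)
            rows.append((name, flat[:, j].mean(), flat[:, j].std(ddof=1),
                         lo, hi, self.rhat.get(name, np.nan)))
        return pd.DataFrame(rows, columns=["param", "mean", "sd", "hdi_2.5", "hdi_97.5", "rhat"])


def _initial_point(cm: ChoiceModel, rng: np.random.Generator) -> np.ndarray:
    theta = np.empty(cm.dim)
    theta[cm._mu_sl] = rng.normal(0.0, 0.5, cm.n_comp)
    theta[cm._ls_sl] = rng.normal(-1.0, 0.3, cm.n_comp)
    theta[cm._z_off:] = rng.normal(0.0, 0.2, cm.dim - cm._z_off)
    return theta


def fit_model(
    data: pd.DataFrame,
    model: ModelSpec,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
) -> FitResult:
    """Fit one candidate model to trial-level choice data by NUTS.

    Non-response trials are removed (the count is logged in the result);
    both recipients and at least two subjects must be present.  The fit is
    fully reproducible from ``sampler.seed``.
    """
    sampler = sampler or SamplerConfig()
    priors = priors or PriorSpec()
    n_dropped = int((data["choice"] == "nonresponse").sum())
    cells = prepare_choice_data(data)
    cm = ChoiceModel(cells, model, mu_scale=priors.mu_scale, sigma_scale=priors.sigma_scale)
    retained = data[data["choice"] != "nonresponse"].reset_index(drop=True)

    nuts_cfg = NutsConfig(
        n_warmup=sampler.n_warmup,
        n_samples=sampler.n_samples,
        target_accept=sampler.target_accept,
    )
    seed_seq = np.random.SeedSequence(sampler.seed)
    chain_seeds = seed_seq.spawn(sampler.n_chains)
    theta = np.empty((sampler.n_chains, sampler.n_samples, cm.dim))
    chain_diag = []
    for c in range(sampler.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        res = nuts_sample(cm.log_posterior_grad, _initial_point(cm, rng), nuts_cfg, rng)
        theta[c] = res["draws"]
        chain_diag.append(
            {
                "step_size": res["step_size"],
                "accept_rate": res["accept_rate"],
                "mean_treedepth": res["mean_treedepth"],
                "n_divergent": res["n_divergent"],
            }
        )

    rhat = _all_rhats(cm, theta)
    fit = FitResult(
        model=model,
        theta=theta,
        param_names=cm.param_names(),
        subject_ids=cm.subject_ids,
        rhat=rhat,
        data=retained,
        n_nonresponse_dropped=n_dropped,
        sampler=sampler,
        diagnostics={"chains": chain_diag},
    )
    return fit


def _all_rhats(cm: ChoiceModel, theta: np.ndarray) -> dict[str, float]:
    """R-hat for every unconstrained parameter and derived subject parameter."""
    names = cm.param_names()
    rhat = {}
    for j, name in enumerate(names):
        rhat[name] = compute_rhat(theta[:, :, j])
    n_chains, n_draws, _ = theta.shape
    derived = {k: np.empty((n_chains, n_draws, cm.n_subjects))
               for k in ("kappa_self", "kappa_other", "beta_self", "beta_other")}
    for c in range(n_chains):
        for d in range(n_draws):
            params = cm.subject_parameters(theta[c, d])
            for k, v in params.items():
                derived[k][c, d] = v
    for k, arr in derived.items():
        for i, sid in enumerate(cm.subject_ids):
            rhat[f"{k}[{sid}]"] = compute_rhat(arr[:, :, i])
    return rhat


def exclude_nonconvergent_subjects(
    fit: FitResult, threshold: float = RHAT_EXCLUDE
) -> tuple[pd.DataFrame, list[dict]]:
    """Flag subjects whose subject-level parameters have R-hat > ``threshold``.

    Returns the data restricted to retained subjects plus an exclusion log
    recording, for each removed subject, the offending R-hat and their
    per-recipient work-choice rates (extreme, near-degenerate choice
    patterns are the typical cause).  Refitting is the caller's job.
    """
    flagged: dict = {}
    for name, value in fit.rhat.items():
        if "[" not in name or not name.split("[")[0] in (
            "kappa_self", "kappa_other", "beta_self", "beta_other"
        ):
            continue
        sid_str = name[name.index("[") + 1 : -1]
        if value > threshold:
            sid = _coerce_sid(sid_str, fit.subject_ids)
            flagged[sid] = max(flagged.get(sid, 0.0), value)

    log = []
    for sid, worst in sorted(flagged.items(), key=lambda kv: str(kv[0])):
        sub = fit.data[fit.data["subject_id"] == sid]
        rates = {}
        for rec in ("self", "other"):
            cond = sub[sub["recipient"] == rec]
            rates[rec] = float((cond["choice"] == "work").mean()) if len(cond) else float("nan")
        log.append(
            {
                "subject_id": sid,
                "max_rhat": worst,
                "work_rate_self": rates["self"],
                "work_rate_other": rates["other"],
            }
        )
    keep = ~fit.data["subject_id"].isin(list(flagged))
    return fit.data[keep].reset_index(drop=True), log


def _coerce_sid(sid_str: str, subject_ids: list):
    for sid in subject_ids:
        if str(sid) == sid_str:
            return sid
    raise KeyError(f"unknown subject id {sid_str!r}")


# ---------------------------------------------------------------------------
# serialization (text formats only: CSV draws + JSON metadata)


def save_fit(fit: FitResult, directory) -> None:
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n_chains, n_draws, dim = fit.theta.shape
    frame = pd.DataFrame(fit.flat_theta(), columns=fit.param_names)
    frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
    frame.insert(1, "draw", np.tile(np.arange(n_draws), n_chains))
    frame.to_csv(d / "draws.csv", index=False, float_format="%.10g")
    fit.data.to_csv(d / "data.csv", index=False)
    meta = {
        "model": fit.model.name,
        "subject_ids": list(fit.subject_ids),
        "rhat": fit.rhat,
        "max_rhat": fit.max_rhat,
        "converged": fit.converged,
        "n_nonresponse_dropped": fit.n_nonresponse_dropped,
        "sampler": dataclasses.asdict(fit.sampler),
        "diagnostics": fit.diagnostics,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2, default=str))


def load_fit(directory) -> FitResult:
    d = pathlib.Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    draws = pd.read_csv(d / "draws.csv")
    data = pd.read_csv(d / "data.csv")
    param_names = [c for c in draws.columns if c not in ("chain", "draw")]
    n_chains = draws["chain"].nunique()
    n_draws = draws["draw"].nunique()
    theta = draws[param_names].to_numpy().reshape(n_chains, n_draws, len(param_names))
    sampler = SamplerConfig(**{
        k: v for k, v in meta["sampler"].items()
        if k in {f.name for f in dataclasses.fields(SamplerConfig)}
    })
    return FitResult(
        model=ModelSpec.from_name(meta["model"]),
        theta=theta,
        param_names=param_names,
        subject_ids=meta["subject_ids"],
        rhat={k: float(v) for k, v in meta["rhat"].items()},
        data=data,
        n_nonresponse_dropped=meta["n_nonresponse_dropped"],
        sampler=sampler,
        diagnostics=meta.get("diagnostics", {}),
    )
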