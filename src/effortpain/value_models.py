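"""Subjective-value discounting functions, softmax choice rule and model catalog.

Offers are valued in shock-count units.  The work offer's shock count is
coded negatively (-5..-1), effort as its level 1..5, and the rest offer has
a fixed value of -6.  Three discount shapes are supported:

* linear:     SV = shock + kappa * effort
* parabolic:  SV = shock + kappa * effort**2
* hyperbolic: SV = shock / (1 + kappa * effort)

with kappa <= 0 throughout (effort makes the work offer worse), and a
logistic ("softmax" over two options) choice rule
``P(work) = 1 / (1 + exp(-beta * (SV_work - SV_rest)))``.

Twelve candidate models arise from crossing the three shapes with shared
vs. recipient-specific kappa and beta ("1k1b" .. "2k2b").
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np

__all__ = [
    "SHAPES",
    "ModelSpec",
    "ParameterSet",
    "OfferValues",
    "MODEL_GRID",
    "subjective_value",
    "choice_probability",
    "trial_loglik",
    "HYPERBOLIC_KAPPA_MIN",
    "SV_REST",
]

SHAPES = ("linear", "parabolic", "hyperbolic")
SV_REST = -6.0
#: hyperbolic kappa must exceed -1/5 so the denominator stays positive for effort <= 5
HYPERBOLIC_KAPPA_MIN = -0.2


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One of the 12 candidate models: shape x kappa-sharing x beta-sharing."""

    shape: str
    separate_kappa: bool
    separate_beta: bool

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")

    @property
    def name(self) -> str:
        k = "2k" if self.separate_kappa else "1k"
        b = "2b" if self.separate_beta else "1b"
        return f"{self.shape}_{k}{b}"

    @property
    def n_free_components(self) -> int:
        """Number of subject-level parameter components (used for tie-breaking)."""
        return 1 + int(self.separate_kappa) + 1 + int(self.separate_beta)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            shape, code = name.rsplit("_", 1)
            if shape not in SHAPES or code not in {"1k1b", "2k1b", "1k2b", "2k2b"}:
                raise ValueError
        except ValueError:
            raise ValueError(
                f"invalid model name {name!r}; expected e.g. 'parabolic_2k1b'"
            ) from None
        return cls(shape=shape, separate_kappa=code[0] == "2", separate_beta=code[2] == "2")


MODEL_GRID: tuple[ModelSpec, ...] = tuple(
    ModelSpec(shape, sk, sb)
    for shape, sk, sb in itertools.product(SHAPES, (False, True), (False, True))
)


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """Subject-level parameters with self/other effect coding.

    ``kappa_other = kappa_self + kappa_effect`` and, when betas are
    recipient-specific, ``beta_other = beta * exp(log_beta_effect)``.
    """

    kappa_self: float
    kappa_effect: float = 0.0
    beta: float = 1.0
    log_beta_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.kappa_self > 0 or self.kappa_other > 0:
            raise ValueError("kappa parameters must be <= 0")

    @property
    def kappa_other(self) -> float:
        return self.kappa_self + self.kappa_effect

    @property
    def beta_other(self) -> float:
        return self.beta * float(np.exp(self.log_beta_effect))

    def kappa_for(self, recipient) -> float:
        rec = getattr(recipient, "value", recipient)
        return self.kappa_self if rec == "self" else self.kappa_other

    def beta_for(self, recipient) -> float:
        rec = getattr(recipient, "value", recipient)
        return self.beta if rec == "self" else self.beta_other


@dataclasses.dataclass(frozen=True)
class OfferValues:
    sv_work: float
    sv_rest: float = SV_REST


def subjective_value(shape: str, kappa, shock, effort):
    """Subjective value of a work offer (vectorized over numpy inputs).

    ``shock`` is the negatively coded shock count (-5..-1) and ``effort``
    the coded level (1..5).
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}")
    shock = np.asarray(shock, dtype=float)
    effort = np.asarray(effort, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(shock < -5) or np.any(shock > -1):
        raise ValueError("shock must be coded in -5..-1")
    if np.any(effort < 1) or np.any(effort > 5):
        raise ValueError("effort must be coded in 1..5")
    if shape == "linear":
        sv = shock + kappa * effort
    elif shape == "parabolic":
        sv = shock + kappa * effort**2
    else:
        denom = 1.0 + kappa * effort
        if np.any(denom <= 0):
            raise ValueError(
                "hyperbolic discounting requires 1 + kappa*effort > 0 "
                f"(kappa > {HYPERBOLIC_KAPPA_MIN} for effort <= 5)"
            )
        sv = shock / denom
    return sv if sv.shape else float(sv)


def choice_probability(values: OfferValues | tuple, beta: float):
    """Probability of choosing the work offer under the two-option softmax."""
    if isinstance(values, OfferValues):
        sv_work, sv_rest = values.sv_work, values.sv_rest
    else:
        sv_work, sv_rest = values
    if np.any(np.asarray(beta) < 0):
        raise ValueError("beta must be >= 0")
    x = np.asarray(beta, dtype=float) * (np.asarray(sv_work, dtype=float) - sv_rest)
    p = _sigmoid(x)
    return p if p.shape else float(p)


def _sigmoid(x):
    """Overflow-safe logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))


def trial_loglik(params: ParameterSet, trial, choice: str, model: ModelSpec) -> float:
    """Log-probability of the observed choice on one trial under ``model``.

    ``trial`` needs ``recipient``, ``effort_level`` and ``work_shocks``
    attributes (a ``TrialSpec`` works); ``choice`` is "work" or "rest".
    """
    if choice not in ("work", "rest"):
        raise ValueError(f"choice must be 'work' or 'rest', got {choice!r}")
    recipient = getattr(trial.recipient, "value", trial.recipient)
    kappa = params.kappa_self
    beta = params.beta
    if recipient == "other":
        if model.separate_kappa:
            kappa = params.kappa_other
        if model.separate_beta:
            beta = params.beta_other
    sv_work = subjective_value(model.shape, kappa, -trial.work_shocks, trial.effort_level)
    x = beta * (sv_work - SV_REST)
    return float(_log_sigmoid(x) if choice == "work" else _log_sigmoid(-x))


def dataset_loglik(params_by_subject, records, model: ModelSpec) -> float:
    """Total log-likelihood of a trial-record table (responded trials only).

    ``records`` is an iterable of objects with ``subject_id``, ``recipient``,
    ``effort_level``, ``work_shocks`` and ``choice`` attributes; non-response
    trials contribute nothing.
    """
    total = 0.0
    for rec in records:
        if rec.choice == "nonresponse":
            continue
        total += trial_loglik(params_by_subject[rec.subject_id], rec, rec.choice, model)
    return total
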