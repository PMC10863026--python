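"""Latent-class generative label model over a matrix of LF votes.

A visit's latent outcome is y ~ Bernoulli(pi).  Conditionally on y, each
LF j independently emits a vote value v in {-1, 0, 1} (abstain / control /
case) from a class-conditional categorical distribution:

    theta_j(v | y) = P(lambda_j = v | y)

    P(row_i) = sum_y P(y) * prod_j theta_j(lambda_ij | y)

Modelling the full emission distribution (rather than a single
class-independent casting probability) matters because most of the 14 LFs
are *one-sided* — they emit only one non-abstain value, so all of their
information lives in the class-conditional decision to cast a vote at all.
LF correlations are deliberately not modelled; overlap and conflict are
surfaced through diagnostics instead.

The interpretable summaries used throughout the pipeline are derived from
theta and the prior:

* propensity  beta_j  = P(vote != abstain),
* accuracy    alpha_j = P(vote = y | vote != abstain),
* learned weight      = log(alpha_j / (1 - alpha_j)),

the last being the scale-free quantity ranked by the expert partial order
during hyperparameter selection.

Fitting is EM with closed-form M-steps and a symmetric Dirichlet
(pseudocount gamma) smoothing each emission row, i.e. MAP-EM whose
penalized objective is non-decreasing by construction; the marginal
log-likelihood history is stored as well.  Responsibilities are
initialized from the majority vote of each row at confidence
``init_accuracy``, which anchors the latent classes and breaks the
label-switching symmetry.
"""

from __future__ import annotations

import graphlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import yaml

from .errors import ConfigError, FitError, OirdlabError
from .labeling import ABSTAIN, LabelMatrix

_EPS = 1e-12
# vote value -> index into the emission axis
_VAL_IDX = {-1: 0, 0: 1, 1: 2}


@dataclass
class LabelModelHyper:
    prior_mode: str = "learned"  # "learned" | "fixed"
    prior_init: float = 0.5  # pi_0; the fixed value when prior_mode == "fixed"
    smoothing_pseudocount: float = 1.0
    init_accuracy: float = 0.7  # confidence of the majority-vote initialization
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.prior_mode not in ("learned", "fixed"):
            raise ConfigError("prior_mode", f"unknown mode {self.prior_mode!r}")
        if not (0.0 < self.prior_init < 1.0):
            raise ConfigError("prior_init", "must be in (0, 1)")
        if self.smoothing_pseudocount < 0:
            raise ConfigError("smoothing_pseudocount", "must be >= 0")
        if not (0.5 < self.init_accuracy < 1.0):
            raise ConfigError("init_accuracy", "must be in (0.5, 1)")
        if self.tol <= 0:
            raise ConfigError("tol", "must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter", "must be >= 1")

    @property
    def hyper_id(self) -> str:
        return (
            f"prior={self.prior_mode}({self.prior_init:g})"
            f",gamma={self.smoothing_pseudocount:g},a0={self.init_accuracy:g}"
        )


@dataclass
class GenerativeModel:
    """Fitted class prior and per-LF emission parameters.

    ``theta`` has shape (n_lf, 3, 2): value axis ordered (abstain, control,
    case), class axis ordered (y=0, y=1).
    """

    lf_ids: List[str]
    prior: float
    theta: np.ndarray
    n_iter: int = 0
    loglik: float = float("nan")
    loglik_history: List[float] = field(default_factory=list)
    hyper_id: str = ""

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.lf_ids), 3, 2):
            raise OirdlabError("theta must have shape (n_lf, 3, 2)")

    @classmethod
    def from_simple_params(
        cls,
        lf_ids: Sequence[str],
        prior: float,
        propensity: Sequence[float],
        accuracy: Sequence[float],
    ) -> "GenerativeModel":
        """Build a model with class-independent casting: each LF casts with
        probability beta and, conditional on casting, votes the true class
        with probability alpha (the textbook accuracy parameterization)."""
        beta = np.asarray(propensity, float)
        alpha = np.asarray(accuracy, float)
        theta = np.empty((len(lf_ids), 3, 2))
        theta[:, 0, :] = (1.0 - beta)[:, None]
        theta[:, 1, 0] = beta * alpha  # control vote, y=0 correct
        theta[:, 1, 1] = beta * (1.0 - alpha)
        theta[:, 2, 0] = beta * (1.0 - alpha)
        theta[:, 2, 1] = beta * alpha  # case vote, y=1 correct
        return cls(list(lf_ids), float(prior), theta)

    # ---- derived, interpretable parameters ---------------------------
    @property
    def propensity(self) -> np.ndarray:
        """beta_j = P(vote != abstain) under the fitted model."""
        cast = 1.0 - self.theta[:, 0, :]
        return (1.0 - self.prior) * cast[:, 0] + self.prior * cast[:, 1]

    @property
    def accuracy(self) -> np.ndarray:
        """alpha_j = P(vote = y | vote != abstain) under the fitted model."""
        pi = self.prior
        correct = (1.0 - pi) * self.theta[:, 1, 0] + pi * self.theta[:, 2, 1]
        cast = np.maximum(self.propensity, _EPS)
        return np.clip(correct / cast, _EPS, 1.0 - _EPS)

    @property
    def learned_weights(self) -> Dict[str, float]:
        """Accuracy log-odds per LF."""
        a = self.accuracy
        w = np.log(a) - np.log1p(-a)
        return {lf: float(x) for lf, x in zip(self.lf_ids, w)}

    # ---- inference ---------------------------------------------------
    def _log_theta(self) -> np.ndarray:
        return np.log(np.maximum(self.theta, _EPS))

    def posterior(self, row: Sequence[int]) -> float:
        """P(y=1 | votes) for one row of votes in {-1, 0, 1}."""
        return float(self.posterior_many(np.asarray(row, dtype=np.int8)[None, :])[0])

    def posterior_many(self, votes: np.ndarray) -> np.ndarray:
        votes = np.asarray(votes)
        if votes.ndim != 2 or votes.shape[1] != len(self.lf_ids):
            raise OirdlabError("vote array shape does not match the model's LF count")
        lt = self._log_theta()
        logit = math.log(self.prior) - math.log1p(-self.prior)
        acc = np.full(votes.shape[0], logit)
        for v, k in _VAL_IDX.items():
            mask = votes == v
            acc += mask @ (lt[:, k, 1] - lt[:, k, 0])
        return 1.0 / (1.0 + np.exp(-np.clip(acc, -700, 700)))

    def loglik_of(self, votes: np.ndarray) -> float:
        """Marginal log-likelihood of a vote matrix under this model."""
        lt = self._log_theta()
        l0 = np.zeros(votes.shape[0])
        l1 = np.zeros(votes.shape[0])
        for v, k in _VAL_IDX.items():
            mask = votes == v
            l0 += mask @ lt[:, k, 0]
            l1 += mask @ lt[:, k, 1]
        l0 += math.log1p(-self.prior)
        l1 += math.log(self.prior)
        hi = np.maximum(l0, l1)
        return float(np.sum(hi + np.log(np.exp(l0 - hi) + np.exp(l1 - hi))))

    # ---- serialization ----------------------------------------------
    def to_yaml(self, path) -> None:
        beta, alpha, w = self.propensity, self.accuracy, self.learned_weights
        d = {
            "prior": float(self.prior),
            "n_iter": int(self.n_iter),
            "loglik": float(self.loglik),
            "hyper_id": self.hyper_id,
            "lfs": {
                lf: {
                    "propensity": float(beta[j]),
                    "accuracy": float(alpha[j]),
                    "weight": float(w[lf]),
                    "theta": [[float(x) for x in col] for col in self.theta[j]],
                }
                for j, lf in enumerate(self.lf_ids)
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        lf_ids = list(d["lfs"])
        theta = np.array([d["lfs"][lf]["theta"] for lf in lf_ids], dtype=float)
        return cls(
            lf_ids=lf_ids,
            prior=float(d["prior"]),
            theta=theta,
            n_iter=int(d.get("n_iter", 0)),
            loglik=float(d.get("loglik", float("nan"))),
            hyper_id=d.get("hyper_id", ""),
        )


def majority_vote(row: Sequence[int]) -> int:
    """Majority of non-abstain votes; ties and all-abstain default to 0
    (control), the sensible default for a rare outcome."""
    row = np.asarray(row)
    ones = int(np.sum(row == 1))
    zeros = int(np.sum(row == 0))
    return 1 if ones > zeros else 0


def fit_label_model(matrix: LabelMatrix, hyper: LabelModelHyper) -> GenerativeModel:
    """EM fit of the generative label model on an m x n vote matrix.

    Raises :class:`~oirdlab.errors.FitError` when every LF abstains
    everywhere (no evidence to fit on — revise the labeling functions).
    """
    hyper.validate()
    V = matrix.votes
    if V.size == 0:
        raise FitError("empty label matrix")
    if not (V != ABSTAIN).any():
        raise FitError(
            "every LF abstained on every visit; revise the labeling functions "
            "before fitting a label model"
        )
    m, n = V.shape
    masks = [(V == v).astype(float) for v in (-1, 0, 1)]  # abstain, control, case
    gamma = hyper.smoothing_pseudocount

    # initialize responsibilities from the majority vote at the configured
    # confidence; this anchors class 1 to case votes
    mv = masks[2].sum(axis=1) > masks[1].sum(axis=1)
    r = np.where(mv, hyper.init_accuracy, 1.0 - hyper.init_accuracy)
    pi = hyper.prior_init

    def m_step(r):
        w1 = r.sum()
        w0 = m - w1
        theta = np.empty((n, 3, 2))
        for k, mask in enumerate(masks):
            theta[:, k, 1] = (gamma + r @ mask) / (3.0 * gamma + w1 + _EPS)
            theta[:, k, 0] = (gamma + (1.0 - r) @ mask) / (3.0 * gamma + w0 + _EPS)
        # guard against zero-probability cells when gamma == 0
        theta = np.maximum(theta, _EPS)
        theta /= theta.sum(axis=1, keepdims=True)
        return theta

    theta = m_step(r)
    if hyper.prior_mode == "learned":
        pi = float(np.clip(r.mean(), _EPS, 1.0 - _EPS))

    history: List[float] = []
    penalized_prev = -np.inf
    model = GenerativeModel(list(matrix.lf_ids), pi, theta)
    for it in range(1, hyper.max_iter + 1):
        model = GenerativeModel(list(matrix.lf_ids), pi, theta)
        r = model.posterior_many(V)
        ll = model.loglik_of(V)
        penalty = gamma * float(np.sum(np.log(np.maximum(theta, _EPS))))
        penalized = ll + penalty
        history.append(ll)
        if penalized + 1e-8 * (abs(penalized_prev) + 1.0) < penalized_prev:
            raise FitError(
                f"EM objective decreased at iteration {it} "
                f"({penalized_prev:.6f} -> {penalized:.6f})"
            )
        if it > 1 and abs(penalized - penalized_prev) <= hyper.tol * (
            abs(penalized_prev) + 1.0
        ):
            break
        penalized_prev = penalized
        theta = m_step(r)
        if hyper.prior_mode == "learned":
            pi = float(np.clip(r.mean(), _EPS, 1.0 - _EPS))

    model.n_iter = len(history)
    model.loglik = history[-1]
    model.loglik_history = history
    model.hyper_id = hyper.hyper_id
    return model


def posterior(model: GenerativeModel, row: Sequence[int]) -> float:
    """Bayes posterior P(y=1 | one row of votes)."""
    return model.posterior(row)


@dataclass
class ExpertPartialOrder:
    """Constraint pairs (lf_hi, lf_lo): lf_hi's learned weight must exceed
    lf_lo's.  Encodes clinical face validity (e.g. a naloxone-response rule
    outranks an altered-mental-status rule)."""

    pairs: List[Tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        graph: Dict[str, set] = {}
        for hi, lo in self.pairs:
            graph.setdefault(hi, set()).add(lo)
            graph.setdefault(lo, set())
        try:
            tuple(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as e:
            raise ConfigError("pairs", f"expert order contains a cycle: {e.args[1]}")

    def score(self, weights: Mapping[str, float]) -> float:
        """Fraction of satisfied constraints (1.0 when the pair list is empty)."""
        if not self.pairs:
            return 1.0
        ok = sum(1 for hi, lo in self.pairs if weights[hi] > weights[lo])
        return ok / len(self.pairs)


def tune_by_weight_order(
    matrix: LabelMatrix,
    hyper_grid: Sequence[LabelModelHyper],
    order: ExpertPartialOrder,
) -> Tuple[LabelModelHyper, GenerativeModel, List[float]]:
    """Select hyperparameters by expert rank agreement of learned weights.

    Each candidate is fitted; its score is the fraction of expert
    constraint pairs satisfied by the learned weights.  Ties break by
    higher final marginal log-likelihood, then grid order.
    """
    if not hyper_grid:
        raise OirdlabError("hyper grid must be non-empty")
    order.validate()
    fits: List[GenerativeModel] = []
    scores: List[float] = []
    for hyper in hyper_grid:
        try:
            model = fit_label_model(matrix, hyper)
        except FitError as e:
            raise FitError(f"hyper {hyper.hyper_id}: {e}") from e
        fits.append(model)
        scores.append(order.score(model.learned_weights))
    best = max(range(len(hyper_grid)), key=lambda i: (scores[i], fits[i].loglik, -i))
    return hyper_grid[best], fits[best], scores
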