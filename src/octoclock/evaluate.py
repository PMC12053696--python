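"""Model comparison and predictive evaluation.

PSIS-LOO approximates exact leave-one-out cross-validation from a pointwise
log-likelihood matrix by Pareto-smoothing the importance ratios of each
observation (tail fit on roughly the top 20% of ratios); the expected log
pointwise predictive density (ELPD) sums the per-observation contributions
and a Pareto shape k below 0.7 marks reliable smoothing.  ELPD differences
between models fitted to the same observations carry a standard error from
the pointwise-difference variance.  Bayesian stacking chooses simplex weights
over candidate models maximizing the combined LOO predictive density.
ROC/AUC compares ranking scores (e.g. Body Clock vs. the frailty index) on
binary endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

__all__ = [
    "LooResult",
    "StackingWeights",
    "PPCheckResult",
    "psis_loo",
    "compare_elpd",
    "stacking_weights",
    "pp_check",
    "roc_auc",
]


@dataclass
class LooResult:
    elpd: float
    se: float
    pointwise: np.ndarray  # per-observation elpd contributions
    pareto_k: np.ndarray
    frac_k_ok: float  # fraction of observations with k < 0.7

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)


def _flatten_loglik(loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:  # (chains, draws, obs)
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, obs)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    return ll


def psis_loo(pointwise_loglik: np.ndarray, k_threshold: float = 0.7) -> LooResult:
    """Pareto-smoothed importance-sampling LOO from a (draws, obs) matrix."""
    import arviz as az

    ll = _flatten_loglik(pointwise_loglik)
    S, n = ll.shape
    if S < 400:
        warnings.warn(
            f"only {S} posterior draws; PSIS-LOO is noisy below ~400",
            UserWarning,
            stacklevel=2,
        )
    # importance ratios 1/p(y_i | theta_s); psislw smooths and normalizes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll.T, reff=1.0)  # (n, S), (n,)
    lw = np.asarray(lw)
    k = np.asarray(k, dtype=float)
    # zero-variance ratios make the Pareto shape undefined, but importance
    # sampling is then exact; mark those observations as perfectly reliable
    k = np.where(np.ptp(ll, axis=0) == 0, 0.0, k)
    pointwise = logsumexp(lw + ll.T, axis=1)
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * np.var(pointwise)))
    n_bad = int((k > k_threshold).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad}/{n} observations have Pareto k > {k_threshold}",
            UserWarning,
            stacklevel=2,
        )
    return LooResult(
        elpd=elpd,
        se=se,
        pointwise=pointwise,
        pareto_k=k,
        frac_k_ok=float((k < k_threshold).mean()),
    )


def compare_elpd(reference: LooResult, other: LooResult) -> tuple[float, float]:
    """(ELPD_DIFF, DIFF_SE) of ``other`` relative to ``reference``.

    Negative means ``other`` predicts worse than the reference; a model
    compared with itself gives (0, 0).
    """
    if reference.n_obs != other.n_obs:
        raise ValueError("models were evaluated on different observation counts")
    d = other.pointwise - reference.pointwise
    return float(d.sum()), float(np.sqrt(len(d) * np.var(d)))


@dataclass
class StackingWeights:
    weights: np.ndarray
    model_names: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.model_names, map(float, self.weights)))


def stacking_weights(
    pointwise_elpds, model_names: tuple[str, ...] | None = None
) -> StackingWeights:
    """LOO stacking weights maximizing sum_i log sum_k w_k exp(elpd_ik).

    ``pointwise_elpds`` is an (n_obs, n_models) array of per-observation LOO
    log predictive densities (or a list of LooResults).  The optimization is
    deterministic (softmax parameterization from the barycenter); exactly
    symmetric inputs therefore return equal weights.
    """
    if isinstance(pointwise_elpds, (list, tuple)) and isinstance(
        pointwise_elpds[0], LooResult
    ):
        mat = np.column_stack([r.pointwise for r in pointwise_elpds])
    else:
        mat = np.asarray(pointwise_elpds, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need an (n_obs, n_models >= 2) matrix")
    n, K = mat.shape
    names = model_names or tuple(f"model_{k}" for k in range(K))
    if len(names) != K:
        raise ValueError("model_names length mismatch")
    # stabilize rows: weights are invariant to adding a constant per observation
    mat = mat - mat.max(axis=1, keepdims=True)

    def objective(theta):
        w = softmax(theta)
        lse = logsumexp(mat + np.log(np.clip(w, 1e-300, None))[None, :], axis=1)
        grad_w = np.exp(mat - lse[:, None]).sum(axis=0) / n
        # d/dtheta of -mean(lse) through softmax
        grad_theta = -(w * (grad_w - w @ grad_w))
        return -float(lse.mean()), grad_theta

    res = minimize(objective, np.zeros(K), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"stacking optimization failed: {res.message}")
    w = softmax(res.x)
    return StackingWeights(weights=w, model_names=tuple(names))


@dataclass
class PPCheckResult:
    """Observed vs. replicated outcome frequencies with a TV discrepancy."""

    observed_freq: np.ndarray
    replicated_freq: np.ndarray  # mean over replicates
    tv_observed: float  # total variation: observed vs. replicate mean
    tv_band95: float  # 95th pct of replicate-vs-replicate-mean TV
    n_replicates: int

    @property
    def within_band(self) -> bool:
        return self.tv_observed <= self.tv_band95


def pp_check(fit, data, n_rep: int = 200, seed: int = 0,
             group_mode: str = "auto") -> PPCheckResult:
    """Posterior predictive check of an ordinal fit against observed outcomes.

    ``fit`` must expose ``sample_replicates`` and a categorical outcome scale;
    ``data`` is a ModelFrame (or DataFrame with the outcome column).
    """
    from .scores import ModelFrame

    if isinstance(data, ModelFrame):
        y = data.outcome
        newdata = data.data
    else:
        y = np.asarray(data["bodn_next"], dtype=int)
        newdata = data
    K = fit.spec.n_thresholds
    reps = fit.sample_replicates(newdata, n_rep=n_rep, seed=seed, group_mode=group_mode)
    cats = np.arange(K + 1)
    obs_freq = np.bincount(y, minlength=K + 1) / len(y)
    rep_freq = np.stack(
        [np.bincount(r, minlength=K + 1) / reps.shape[1] for r in reps]
    )
    mean_rep = rep_freq.mean(axis=0)
    tv_obs = 0.5 * float(np.abs(obs_freq - mean_rep).sum())
    tv_reps = 0.5 * np.abs(rep_freq - mean_rep[None, :]).sum(axis=1)
    band = float(np.quantile(tv_reps, 0.95))
    assert abs(obs_freq.sum() - 1) < 1e-9 and np.allclose(rep_freq.sum(axis=1), 1)
    del cats
    return PPCheckResult(
        observed_freq=obs_freq,
        replicated_freq=mean_rep,
        tv_observed=tv_obs,
        tv_band95=band,
        n_replicates=n_rep,
    )


def roc_auc(score, outcome) -> float:
    """AUC of a ranking score for a binary outcome (midranks under ties).

    Equals the probability that a random positive outranks a random negative.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(outcome)
    if len(np.unique(y)) != 2:
        raise ValueError("need both outcome classes present")
    return float(roc_auc_score(y, np.asarray(score, dtype=float)))
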