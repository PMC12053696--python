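"""Cumulative multilevel ordinal regression with monotonic ordinal predictors.

The observed ordinal outcome ``Y`` (BODN, categories ``0..K``) arises by
thresholding a continuous latent variable at ordered cut-points
``tau_1 < ... < tau_K``:

    P(Y = k) = F(tau_{k+1} - eta) - F(tau_k - eta),   F = logistic CDF,

with ``tau_0 = -inf`` and ``tau_{K+1} = +inf``.  The linear predictor ``eta``
combines, for every disease, a monotonic effect of its ordinal severity level
— a total (maximum) effect ``b_max`` distributed over level transitions by a
simplex ``zeta`` — plus linear covariates (time since the anchor visit) and a
Gaussian random intercept per individual:

    eta = sum_d b_d * sum_{j < level_d} zeta_{d,j} + X beta + u_i,
    u_i ~ Normal(0, sigma_u).

Weakly-informative defaults: thresholds Student-t(3, 0, 2.5), ``b_max``
Normal(0, 2), ``zeta`` Dirichlet(1, ..., 1), ``sigma_u`` half-Student-t(3, 0,
2.5).  Sampling is adaptive Metropolis-within-Gibbs (see ``_mcmc``); the fit
stores posterior draws, convergence diagnostics and the pointwise
log-likelihood matrix used by model comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._mcmc import HierarchicalModel, MCMCConfig, run_mwg, t_logpdf
from .scores import ModelFrame, SchemaError

__all__ = [
    "CumulativeSpec",
    "MonotonicEffect",
    "PriorSet",
    "OrdinalFit",
    "monotonic_contribution",
    "category_probs",
    "fit_ordinal",
]


@dataclass(frozen=True)
class CumulativeSpec:
    """Cumulative-link specification: K+1 categories split by K thresholds."""

    n_categories: int
    thresholds: np.ndarray | None = None  # latent-scale cut-points, length K
    link: str = "logit"

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("need >= 2 ordinal categories")
        if self.link != "logit":
            raise NotImplementedError("only the logit link is supported")
        if self.thresholds is not None:
            tau = np.asarray(self.thresholds, dtype=float)
            if tau.shape != (self.n_categories - 1,):
                raise ValueError(
                    f"need {self.n_categories - 1} thresholds, got {tau.shape}"
                )
            if not np.all(np.diff(tau) > 0):
                raise ValueError("thresholds must be strictly increasing")
            object.__setattr__(self, "thresholds", tau)

    @classmethod
    def from_codex(cls, codex) -> "CumulativeSpec":
        """BODN scale for a codex: categories 0..n_systems, n_systems thresholds."""
        return cls(n_categories=codex.n_systems + 1)

    @property
    def n_thresholds(self) -> int:
        return self.n_categories - 1


@dataclass(frozen=True)
class MonotonicEffect:
    """Total latent effect ``b_max`` split over level steps by a simplex."""

    b_max: float
    zeta: tuple[float, ...]  # D - 1 non-negative increments summing to 1

    def __post_init__(self) -> None:
        z = np.asarray(self.zeta, dtype=float)
        if z.ndim != 1 or len(z) < 1:
            raise ValueError("zeta must be a non-empty vector")
        if (z < -1e-12).any() or abs(z.sum() - 1.0) > 1e-8:
            raise ValueError("zeta must be a simplex (non-negative, sum 1)")
        object.__setattr__(self, "zeta", tuple(float(v) for v in z))

    @property
    def n_levels(self) -> int:
        return len(self.zeta) + 1


def monotonic_contribution(level, effect: MonotonicEffect):
    """Latent-scale contribution of an ordinal severity level.

    ``contribution(1) = 0`` (reference), ``contribution(D) = b_max``, and in
    between ``b_max * sum_{j < level} zeta_j`` — non-decreasing in the level
    whenever the simplex is valid and ``b_max >= 0``.
    """
    lev = np.asarray(level)
    D = effect.n_levels
    if np.any(lev < 1) or np.any(lev > D):
        raise ValueError(f"level out of range 1..{D}")
    cum = np.concatenate([[0.0], np.cumsum(effect.zeta)])
    out = effect.b_max * cum[lev - 1]
    return float(out) if np.isscalar(level) else out


def category_probs(eta, spec: CumulativeSpec) -> np.ndarray:
    """Probability vector over the K+1 categories for latent predictor eta."""
    if spec.thresholds is None:
        raise ValueError("spec carries no thresholds")
    tau = spec.thresholds
    scalar = np.ndim(eta) == 0
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cum = expit(tau[None, :] - eta[:, None])  # P(Y <= k), k = 0..K-1
    ones = np.ones((len(eta), 1))
    zeros = np.zeros((len(eta), 1))
    probs = np.diff(np.concatenate([zeros, cum, ones], axis=1), axis=1)
    return probs[0] if scalar else probs


@dataclass(frozen=True)
class PriorSet:
    threshold_df: float = 3.0
    threshold_scale: float = 2.5
    b_sd: float = 2.0
    linear_sd: float = 2.0
    sigma_u_df: float = 3.0
    sigma_u_scale: float = 2.5


class _CumulativeMonotonicModel(HierarchicalModel):
    """Unconstrained parameterization of the cumulative-monotonic likelihood.

    Layout of ``z``: tau_1, log-increments of tau_2..tau_K, then per disease
    b_max followed by (D-1) log-Gamma(1,1) variables whose normalization gives
    the Dirichlet(1) simplex (omitted for binary diseases where zeta == (1,)),
    then one coefficient per linear covariate, then log sigma_u when grouped.
    """

    def __init__(self, frame: ModelFrame, monotonic, linear, priors: PriorSet,
                 with_groups: bool = True):
        self.priors = priors
        self.K = frame.n_categories - 1
        self.y = frame.outcome
        self.lev = frame.data[list(monotonic)].to_numpy(dtype=int) - 1  # 0-based
        self.n_levels = [frame.n_levels[d] for d in monotonic]
        self.monotonic = tuple(monotonic)
        self.linear_names = tuple(linear)
        self.X = (
            frame.data[list(linear)].to_numpy(dtype=float)
            if linear
            else np.zeros((len(frame), 0))
        )
        self.n_rows = len(frame)

        if with_groups:
            gidx, glabels = frame.groups()
            self.group_idx = gidx
            self.group_labels = glabels
            self.n_groups = len(glabels)
        else:
            self.group_idx = None
            self.group_labels = np.array([])
            self.n_groups = 0

        names: list[str] = [f"tau_{k + 1}" if k == 0 else f"log_dtau_{k + 1}"
                            for k in range(self.K)]
        self._slices: dict[str, slice] = {"tau": slice(0, self.K)}
        pos = self.K
        for d, D in zip(self.monotonic, self.n_levels):
            names.append(f"b[{d}]")
            self._slices[f"b[{d}]"] = slice(pos, pos + 1)
            pos += 1
            nz = D - 1
            if nz > 1:
                self._slices[f"zeta[{d}]"] = slice(pos, pos + nz)
                names += [f"log_g[{d}]{j}" for j in range(nz)]
                pos += nz
        for c in self.linear_names:
            names.append(f"beta[{c}]")
            self._slices[f"beta[{c}]"] = slice(pos, pos + 1)
            pos += 1
        if self.n_groups:
            names.append("log_sigma_u")
            self._slices["log_sigma_u"] = slice(pos, pos + 1)
            self.sigma_param_index = pos
            pos += 1
        self.n_params = pos
        self.param_names = tuple(names)

    # --- transforms -----------------------------------------------------
    def thresholds(self, z: np.ndarray) -> np.ndarray:
        t = z[: self.K]
        return np.concatenate([[t[0]], t[0] + np.cumsum(np.exp(t[1:]))])

    def zeta(self, z: np.ndarray, disease: str, D: int) -> np.ndarray:
        if D - 1 == 1:
            return np.ones(1)
        g = np.exp(z[self._slices[f"zeta[{disease}]"]])
        return g / g.sum()

    def u_sd(self, z: np.ndarray) -> float:
        return float(np.exp(z[self._slices["log_sigma_u"]][0]))

    # --- target ---------------------------------------------------------
    def log_prior(self, z: np.ndarray) -> float:
        p = self.priors
        tau = self.thresholds(z)
        lp = float(t_logpdf(tau, p.threshold_df, p.threshold_scale).sum())
        lp += float(z[1 : self.K].sum())  # Jacobian of the log-increments
        for d, D in zip(self.monotonic, self.n_levels):
            b = z[self._slices[f"b[{d}]"]][0]
            lp += -0.5 * (b / p.b_sd) ** 2
            if D - 1 > 1:
                zg = z[self._slices[f"zeta[{d}]"]]
                lp += float((zg - np.exp(zg)).sum())  # Gamma(1,1) on exp(zg) + Jacobian
        for c in self.linear_names:
            beta = z[self._slices[f"beta[{c}]"]][0]
            lp += -0.5 * (beta / p.linear_sd) ** 2
        if self.n_groups:
            ls = z[self._slices["log_sigma_u"]][0]
            if abs(ls) > 12:
                return -np.inf
            sigma = np.exp(ls)
            lp += float(t_logpdf(sigma, p.sigma_u_df, p.sigma_u_scale)) + ls
            # half-t on sigma via symmetry, plus the log Jacobian
        return lp

    def eta(self, z: np.ndarray, u: np.ndarray | None) -> np.ndarray:
        eta = np.zeros(self.n_rows)
        for j, (d, D) in enumerate(zip(self.monotonic, self.n_levels)):
            b = z[self._slices[f"b[{d}]"]][0]
            cum = np.concatenate([[0.0], np.cumsum(self.zeta(z, d, D))])
            eta += b * cum[self.lev[:, j]]
        for c in self.linear_names:
            eta += z[self._slices[f"beta[{c}]"]][0] * self.X[:, self.linear_names.index(c)]
        if self.n_groups and u is not None:
            eta += u[self.group_idx]
        return eta

    def loglik_rows(self, z: np.ndarray, u: np.ndarray | None) -> np.ndarray:
        tau = self.thresholds(z)
        eta = self.eta(z, u)
        hi = np.where(self.y >= self.K, 1.0, expit(tau[np.minimum(self.y, self.K - 1)] - eta))
        lo = np.where(self.y == 0, 0.0, expit(tau[np.maximum(self.y - 1, 0)] - eta))
        return np.log(np.clip(hi - lo, 1e-300, None))

    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        z = np.zeros(self.n_params)
        counts = np.bincount(self.y, minlength=self.K + 1) + 0.5
        cum = np.cumsum(counts)[:-1] / counts.sum()
        tau0 = np.log(cum / (1 - cum))
        z[0] = tau0[0]
        z[1 : self.K] = np.log(np.clip(np.diff(tau0), 0.05, None))
        if self.n_groups:
            z[self._slices["log_sigma_u"]] = np.log(0.5)
        return z


@dataclass
class OrdinalFit:
    """Posterior draws and metadata of a cumulative-monotonic fit."""

    spec: CumulativeSpec
    thresholds: np.ndarray  # (S, K)
    b: dict[str, np.ndarray]  # disease -> (S,)
    zeta: dict[str, np.ndarray]  # disease -> (S, D-1)
    beta: dict[str, np.ndarray]  # covariate -> (S,)
    sigma_u: np.ndarray | None  # (S,)
    u: np.ndarray | None  # (S, G)
    group_labels: np.ndarray
    pointwise_loglik: np.ndarray  # (S, n_obs)
    n_levels: dict[str, int]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    codex_hash: str = ""
    dropped_diseases: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.thresholds.shape[0]

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.b)

    @property
    def linear_covariates(self) -> tuple[str, ...]:
        return tuple(self.beta)

    def monotonic_effect(self, disease: str, draw: int) -> MonotonicEffect:
        return MonotonicEffect(
            b_max=float(self.b[disease][draw]),
            zeta=tuple(self.zeta[disease][draw]),
        )

    # --- prediction -----------------------------------------------------
    def _eta_draws(self, newdata: pd.DataFrame, seed: int,
                   group_mode: str = "auto") -> np.ndarray:
        """(S, n_rows) latent predictors for new data.

        Individuals seen in training reuse their intercept draws; new
        individuals get intercepts drawn from Normal(0, sigma_u) per draw
        (``group_mode='auto'``).  ``group_mode='population'`` forces the
        marginal treatment for every row.
        """
        S = self.n_draws
        n = len(newdata)
        for d in self.diseases:
            if d not in newdata.columns:
                raise SchemaError(f"newdata lacks disease column {d!r}")
            lev = newdata[d].to_numpy(dtype=int)
            if (lev < 1).any() or (lev > self.n_levels[d]).any():
                raise SchemaError(f"severity outside fitted range for {d!r}")
        eta = np.zeros((S, n))
        for d in self.diseases:
            lev = newdata[d].to_numpy(dtype=int) - 1
            cz = np.concatenate(
                [np.zeros((S, 1)), np.cumsum(self.zeta[d], axis=1)], axis=1
            )
            eta += self.b[d][:, None] * cz[:, lev]
        for c, bdraws in self.beta.items():
            if c not in newdata.columns:
                raise SchemaError(f"newdata lacks covariate column {c!r}")
            eta += bdraws[:, None] * newdata[c].to_numpy(dtype=float)[None, :]
        if self.sigma_u is not None:
            rng = np.random.default_rng(seed)
            ids = newdata["individual_id"].to_numpy() if "individual_id" in newdata else None
            label_pos = {lab: i for i, lab in enumerate(self.group_labels)}
            if group_mode == "population" or ids is None:
                codes = pd.factorize(ids)[0] if ids is not None else np.arange(n)
                n_new = codes.max() + 1
                u_new = rng.standard_normal((S, n_new)) * self.sigma_u[:, None]
                eta += u_new[:, codes]
            else:
                known = np.array([label_pos.get(i, -1) for i in ids])
                seen = known >= 0
                if seen.any():
                    eta[:, seen] += self.u[:, known[seen]]
                if (~seen).any():
                    new_codes = pd.factorize(ids[~seen])[0]
                    u_new = rng.standard_normal((S, new_codes.max() + 1))
                    u_new *= self.sigma_u[:, None]
                    eta[:, ~seen] += u_new[:, new_codes]
        return eta

    def predict(self, newdata, summarize: str = "mean", seed: int = 0,
                group_mode: str = "auto") -> np.ndarray:
        """Posterior-predicted expected category value per row.

        ``summarize='mean'`` returns the posterior mean of ``E[Y | draw]``
        (a continuous value on the outcome scale, within ``[0, K]``);
        ``'median'`` the posterior median of the same per-draw expectations;
        ``'draws'`` the full (S, n_rows) matrix of per-draw expectations.
        """
        if isinstance(newdata, ModelFrame):
            newdata = newdata.data
        eta = self._eta_draws(newdata, seed=seed, group_mode=group_mode)
        K = self.spec.n_thresholds
        kvals = np.arange(K + 1, dtype=float)
        exp_draws = np.empty_like(eta)
        for s in range(self.n_draws):  # draw-wise keeps memory flat
            cum = expit(self.thresholds[s][None, :] - eta[s][:, None])
            probs = np.diff(
                np.concatenate(
                    [np.zeros((eta.shape[1], 1)), cum, np.ones((eta.shape[1], 1))],
                    axis=1,
                ),
                axis=1,
            )
            exp_draws[s] = probs @ kvals
        if summarize == "draws":
            return exp_draws
        if summarize == "median":
            return np.median(exp_draws, axis=0)
        if summarize == "mean":
            return exp_draws.mean(axis=0)
        raise ValueError(f"unknown summarize {summarize!r}")

    def sample_replicates(self, newdata, n_rep: int = 200, seed: int = 0,
                          group_mode: str = "auto") -> np.ndarray:
        """(n_rep, n_rows) replicated ordinal outcomes for predictive checks."""
        if isinstance(newdata, ModelFrame):
            newdata = newdata.data
        rng = np.random.default_rng(seed)
        eta = self._eta_draws(newdata, seed=seed + 1, group_mode=group_mode)
        idx = rng.integers(0, self.n_draws, size=n_rep)
        n = eta.shape[1]
        out = np.empty((n_rep, n), dtype=int)
        for r, s in enumerate(idx):
            cum = expit(self.thresholds[s][None, :] - eta[s][:, None])
            cum = np.concatenate([cum, np.ones((n, 1))], axis=1)
            out[r] = (rng.random((n, 1)) > cum[:, :-1]).sum(axis=1)
        return out

    # --- serialization --------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "n_categories": self.spec.n_categories,
            "diseases": list(self.diseases),
            "n_levels": self.n_levels,
            "linear": list(self.beta),
            "rhat": self.rhat,
            "ess": self.ess,
            "converged": self.converged,
            "codex_hash": self.codex_hash,
            "dropped": list(self.dropped_diseases),
        }
        arrays = {"thresholds": self.thresholds, "loglik": self.pointwise_loglik}
        for d in self.diseases:
            arrays[f"b::{d}"] = self.b[d]
            arrays[f"zeta::{d}"] = self.zeta[d]
        for c in self.beta:
            arrays[f"beta::{c}"] = self.beta[c]
        if self.sigma_u is not None:
            arrays["sigma_u"] = self.sigma_u
            arrays["u"] = self.u
            arrays["group_labels"] = np.asarray(self.group_labels).astype(str)
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "OrdinalFit":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            b = {d: z[f"b::{d}"] for d in meta["diseases"]}
            zeta = {d: z[f"zeta::{d}"] for d in meta["diseases"]}
            beta = {c: z[f"beta::{c}"] for c in meta["linear"]}
            has_u = "sigma_u" in z
            return cls(
                spec=CumulativeSpec(n_categories=meta["n_categories"]),
                thresholds=z["thresholds"],
                b=b,
                zeta=zeta,
                beta=beta,
                sigma_u=z["sigma_u"] if has_u else None,
                u=z["u"] if has_u else None,
                group_labels=z["group_labels"] if has_u else np.array([]),
                pointwise_loglik=z["loglik"],
                n_levels={k: int(v) for k, v in meta["n_levels"].items()},
                rhat=meta["rhat"],
                ess=meta["ess"],
                converged=meta["converged"],
                codex_hash=meta["codex_hash"],
                dropped_diseases=tuple(meta["dropped"]),
            )


class DegenerateOutcomeError(ValueError):
    """Fewer than two outcome categories observed."""


def fit_ordinal(
    frame: ModelFrame,
    monotonic: tuple[str, ...] | None = None,
    linear: tuple[str, ...] | None = None,
    priors: PriorSet | None = None,
    sampler: MCMCConfig | None = None,
    with_groups: bool = True,
    codex_hash: str = "",
) -> OrdinalFit:
    """Sample the cumulative multilevel ordinal model on a lagged frame.

    ``monotonic`` defaults to every disease column of the frame; ``linear``
    to the frame's linear covariates (time).  Zero-variance monotonic
    predictors are dropped with a warning.  Non-convergence (rhat/ess beyond
    the sampler thresholds) flags the fit rather than failing.
    """
    if len(frame) == 0:
        raise ValueError("empty model frame")
    y = frame.outcome
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome has a single observed category")
    priors = priors or PriorSet()
    sampler = sampler or MCMCConfig()
    monotonic = tuple(monotonic if monotonic is not None else frame.disease_cols)
    linear = tuple(linear if linear is not None else frame.linear_cols)

    dropped = []
    kept = []
    for d in monotonic:
        if frame.data[d].nunique() < 2:
            dropped.append(d)
        else:
            kept.append(d)
    if dropped:
        warnings.warn(
            f"dropping zero-variance predictors: {dropped}", UserWarning, stacklevel=2
        )

    model = _CumulativeMonotonicModel(frame, kept, linear, priors, with_groups)
    draws = run_mwg(model, sampler)
    zf = draws.z_flat()

    S = zf.shape[0]
    thresholds = np.empty((S, model.K))
    for s in range(S):
        thresholds[s] = model.thresholds(zf[s])
    b = {}
    zeta = {}
    for d, D in zip(model.monotonic, model.n_levels):
        b[d] = zf[:, model._slices[f"b[{d}]"]][:, 0]
        if D - 1 > 1:
            g = np.exp(zf[:, model._slices[f"zeta[{d}]"]])
            zeta[d] = g / g.sum(axis=1, keepdims=True)
        else:
            zeta[d] = np.ones((S, 1))
    beta = {c: zf[:, model._slices[f"beta[{c}]"]][:, 0] for c in model.linear_names}
    if model.n_groups:
        sigma_u = np.exp(zf[:, model._slices["log_sigma_u"]][:, 0])
        u = draws.u_flat()
    else:
        sigma_u, u = None, None

    return OrdinalFit(
        spec=CumulativeSpec(n_categories=frame.n_categories),
        thresholds=thresholds,
        b=b,
        zeta=zeta,
        beta=beta,
        sigma_u=sigma_u,
        u=u,
        group_labels=model.group_labels,
        pointwise_loglik=draws.loglik_flat(),
        n_levels={d: frame.n_levels[d] for d in kept},
        rhat=draws.rhat,
        ess=draws.ess,
        converged=draws.converged,
        codex_hash=codex_hash,
        dropped_diseases=tuple(dropped),
    )
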