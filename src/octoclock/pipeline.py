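"""Orchestration of the eight clock/age metrics from a panel and codex.

The eight metric families: Body Clock (posterior-predicted BODN from the
full model with every disease as a monotonic predictor), the system-specific
clocks (BSC, one ordinal fit per bodily system), their Gamma log-link age
mappings (Body Age, BSA), the walking-speed pair (Speed-Body Clock from the
distributional Gaussian model, Speed-Body Age), and the disability pair
(Disability-Body Clock from the ZIBB model on the count scale,
Disability-Body Age).  Chronological age is never a predictor in any
clock-producing model — it enters only as the *outcome* of the age
regressions; this is asserted structurally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import MCMCConfig
from .codex import DiseaseCodex
from .glm import fit_di, fit_gamma_age, fit_speed
from .ordinal import OrdinalFit, PriorSet, fit_ordinal
from .scores import ModelFrame, build_model_frame, disability_counts

__all__ = [
    "ClockTable",
    "bsc_columns",
    "run_body_clock",
    "run_bsc",
    "run_ages",
    "run_disability",
    "run_octo",
    "transfer_predict",
]

#: columns a clock-producing ordinal model may use as linear covariates
_CLOCK_SAFE_LINEAR = ("time",)


def _assert_no_age(linear_cols) -> None:
    banned = {"chronological_age", "age"}
    leaked = banned & set(linear_cols)
    if leaked:
        raise AssertionError(
            f"chronological age must not feed a clock-producing model: {leaked}"
        )


@dataclass
class ClockTable:
    """Per individual-visit metric table aligned with the model-frame rows."""

    data: pd.DataFrame  # individual_id, outcome_visit + metric columns
    systems: tuple[str, ...]

    def metric_columns(self) -> list[str]:
        return [
            c for c in self.data.columns if c not in ("individual_id", "outcome_visit")
        ]


def bsc_columns(codex: DiseaseCodex) -> list[str]:
    """Names of the system-specific clock columns (13 for the default codex)."""
    return [f"bsc_{s}" for s in codex.systems]


def _clock_fit(
    frame: ModelFrame,
    monotonic,
    sampler: MCMCConfig | None,
    priors: PriorSet | None,
    codex_hash: str,
) -> OrdinalFit:
    _assert_no_age(frame.linear_cols)
    return fit_ordinal(
        frame,
        monotonic=monotonic,
        linear=_CLOCK_SAFE_LINEAR,
        priors=priors,
        sampler=sampler,
        codex_hash=codex_hash,
    )


def run_body_clock(
    panel: pd.DataFrame,
    codex: DiseaseCodex,
    anchor: str = "lag1",
    sampler: MCMCConfig | None = None,
    priors: PriorSet | None = None,
    summarize: str = "mean",
) -> tuple[pd.Series, OrdinalFit, ModelFrame]:
    """Full-model Body Clock: every disease as a monotonic predictor + time
    + individual intercept, posterior prediction summarized per row."""
    frame = build_model_frame(panel, codex, anchor)
    fit = _clock_fit(frame, None, sampler, priors, codex.content_hash())
    clock = fit.predict(frame, summarize=summarize)
    return pd.Series(clock, index=frame.data.index, name="body_clock"), fit, frame


def run_bsc(
    panel: pd.DataFrame,
    codex: DiseaseCodex,
    system: str,
    anchor: str = "lag1",
    sampler: MCMCConfig | None = None,
    priors: PriorSet | None = None,
    frame: ModelFrame | None = None,
) -> tuple[pd.Series, OrdinalFit]:
    """System-specific clock: ordinal fit restricted to one system's diseases
    (outcome remains full BODN)."""
    names = tuple(d.name for d in codex.diseases_of(system))
    if frame is None:
        frame = build_model_frame(panel, codex, anchor)
    varying = [d for d in names if frame.data[d].nunique() > 1]
    if not varying:
        warnings.warn(
            f"system {system!r} shows no severity variation; its clock reduces "
            "to the time trend",
            UserWarning,
            stacklevel=2,
        )
    fit = _clock_fit(frame.subset_diseases(names), names, sampler, priors,
                     codex.content_hash())
    clock = fit.predict(frame)
    return pd.Series(clock, index=frame.data.index, name=f"bsc_{system}"), fit


def run_ages(
    clock_columns: pd.DataFrame,
    chronological_age,
    height=None,
    speed_clock_col: str = "speed_body_clock",
    seed: int = 0,
    n_steps: int = 1500,
) -> pd.DataFrame:
    """Gamma log-link age mapping for every clock column.

    Each column ``c`` yields an age column (``body_clock -> body_age``,
    ``bsc_X -> bsa_X``, ...).  The walking-speed clock is additionally
    adjusted for height when ``height`` is given.  Predictions are
    per-individual posterior means; no ceiling is applied, so ages may exceed
    the oldest observed human age.
    """
    age = np.asarray(chronological_age, dtype=float)
    out = {}
    for j, col in enumerate(clock_columns.columns):
        x = clock_columns[col].to_numpy(dtype=float)
        if col == speed_clock_col and height is not None:
            X = np.column_stack([x, np.asarray(height, dtype=float)])
            fit = fit_gamma_age(age, X, predictor_names=(col, "height"),
                                seed=seed + j, n_steps=n_steps)
            pred = fit.predict(X)
        else:
            fit = fit_gamma_age(age, x, predictor_names=(col,), seed=seed + j,
                                n_steps=n_steps)
            pred = fit.predict(x)
        out[_age_name(col)] = pred
    return pd.DataFrame(out, index=clock_columns.index)


def _age_name(clock_col: str) -> str:
    if clock_col.startswith("bsc_"):
        return "bsa_" + clock_col[4:]
    if clock_col.endswith("_clock"):
        return clock_col[: -len("_clock")] + "_age"
    return clock_col + "_age"


def run_disability(
    events,
    trials,
    body_clock,
    group_ids=None,
    sampler: MCMCConfig | None = None,
):
    """Disability Index (intercept-only ZIBB, proportion scale) and
    Disability-Body Clock (ZIBB on the Body Clock, posterior-mean predicted
    event count)."""
    di_fit = fit_di(events, trials, group_ids=group_ids, sampler=sampler)
    gcodes = None
    if group_ids is not None:
        gcodes = pd.factorize(pd.Series(group_ids))[0]
    di = di_fit.predict_proportion(group_codes=gcodes)
    dbc_fit = fit_di(events, trials, group_ids=group_ids,
                     covariate=np.asarray(body_clock, dtype=float), sampler=sampler)
    dbc = dbc_fit.predict_count(x=np.asarray(body_clock, dtype=float),
                                group_codes=gcodes)
    return di, dbc, di_fit, dbc_fit


def run_octo(
    panel: pd.DataFrame,
    codex: DiseaseCodex,
    anchor: str = "lag1",
    sampler: MCMCConfig | None = None,
    priors: PriorSet | None = None,
    seed: int = 0,
) -> tuple[ClockTable, dict]:
    """All eight metric families on one panel; returns the table and the fits."""
    clock, body_fit, frame = run_body_clock(panel, codex, anchor, sampler, priors)
    out = frame.data[["individual_id", "outcome_visit"]].copy()
    out["body_clock"] = clock.to_numpy()
    fits: dict = {"body_clock": body_fit}

    for s in codex.systems:
        bsc, fit_s = run_bsc(panel, codex, s, anchor, sampler, priors, frame=frame)
        out[f"bsc_{s}"] = bsc.to_numpy()
        fits[f"bsc_{s}"] = fit_s

    # align panel covariates with the frame's outcome visits
    key = panel.set_index(["individual_id", "visit_index"])
    idx = list(zip(out["individual_id"], out["outcome_visit"]))
    aligned = key.loc[idx]
    age = aligned["chronological_age"].to_numpy(dtype=float)
    height = aligned["height"].to_numpy(dtype=float)
    speed = aligned["walking_speed"].to_numpy(dtype=float)

    speed_fit = fit_speed(speed, out["body_clock"].to_numpy(), height, seed=seed)
    out["speed_body_clock"] = speed_fit.predict(out["body_clock"].to_numpy(), height)
    fits["speed"] = speed_fit

    counts = disability_counts(aligned.reset_index())
    di, dbc, di_fit, dbc_fit = run_disability(
        counts["events"].to_numpy(),
        counts["trials"].to_numpy(),
        out["body_clock"].to_numpy(),
        group_ids=out["individual_id"].to_numpy(),
        sampler=sampler,
    )
    out["disability_index"] = di
    out["disability_body_clock"] = dbc
    fits["di"] = di_fit
    fits["disability_body_clock"] = dbc_fit

    clock_cols = ["body_clock"] + bsc_columns(codex) + [
        "speed_body_clock", "disability_body_clock",
    ]
    ages = run_ages(out[clock_cols], age, height=height, seed=seed)
    out = pd.concat([out, ages], axis=1)
    return ClockTable(data=out, systems=codex.systems), fits


def transfer_predict(
    fit: OrdinalFit,
    panel_b: pd.DataFrame,
    codex: DiseaseCodex,
    anchor: str = "lag1",
    seed: int = 0,
) -> tuple[pd.Series, ModelFrame]:
    """Predict the Body Clock on a new cohort with a fit trained elsewhere.

    New individuals draw their intercept from the fitted population
    distribution per posterior draw.  The codex must match the training
    codex (checked by content hash when recorded).
    """
    if fit.codex_hash and fit.codex_hash != codex.content_hash():
        raise ValueError("codex mismatch between training fit and new panel")
    frame = build_model_frame(panel_b, codex, anchor)
    clock = fit.predict(frame, seed=seed, group_mode="auto")
    return pd.Series(clock, index=frame.data.index, name="body_clock_transfer"), frame
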