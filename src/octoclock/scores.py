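"""Deterministic multimorbidity scores and lagged model frames.

BODN (body organ disease number) counts the bodily systems with at least one
disease above the healthy reference level; it is the ordinal outcome of the
clock models.  The frailty index (FI) expands every non-reference severity
level into a separate binary deficit item and reports the proportion present.
``build_model_frame`` turns a longitudinal panel into the lagged regression
frame: disease severities observed at an earlier visit predict BODN at a later
visit, with a time covariate and the individual id for the random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codex import DiseaseCodex

__all__ = [
    "ModelFrame",
    "SchemaError",
    "compute_bodn",
    "compute_fi",
    "build_model_frame",
    "disability_counts",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Panel does not match the codex-derived schema."""


def _severity_matrix(panel: pd.DataFrame, codex: DiseaseCodex) -> np.ndarray:
    missing = [d.name for d in codex.diseases if d.name not in panel.columns]
    if missing:
        raise SchemaError(f"panel lacks severity columns: {missing}")
    sev = panel[list(codex.disease_names)].to_numpy(dtype=float)
    if np.isnan(sev).any():
        raise SchemaError("severity columns contain missing values")
    sev = sev.astype(int)
    for j, d in enumerate(codex.diseases):
        col = sev[:, j]
        bad = (col < 1) | (col > d.n_levels)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"severity out of range for {d.name!r} at row {row}: "
                f"{col[bad][0]} not in 1..{d.n_levels}"
            )
    return sev


def compute_bodn(panel: pd.DataFrame, codex: DiseaseCodex) -> pd.Series:
    """Number of bodily systems with >= 1 disease above the reference level.

    Range ``0..n_systems``; order of severity columns and of rows is
    irrelevant.
    """
    sev = _severity_matrix(panel, codex)
    systems = codex.systems
    sys_idx = {s: i for i, s in enumerate(systems)}
    affected = np.zeros((len(panel), len(systems)), dtype=bool)
    for j, d in enumerate(codex.diseases):
        affected[:, sys_idx[d.system]] |= sev[:, j] >= 2
    return pd.Series(affected.sum(axis=1), index=panel.index, name="bodn")


def compute_fi(panel: pd.DataFrame, codex: DiseaseCodex) -> pd.Series:
    """Frailty index: proportion of binary deficit items present, in [0, 1].

    Every non-reference level of every disease is one deficit item (an
    individual at level ``x`` of a disease has ``x - 1`` of that disease's
    items), so FI = 0 exactly when BODN = 0.
    """
    total = codex.n_deficit_items()
    if total == 0:
        raise SchemaError("codex defines zero deficit items")
    sev = _severity_matrix(panel, codex)
    present = (sev - 1).sum(axis=1)
    return pd.Series(present / total, index=panel.index, name="fi")


def disability_counts(
    panel: pd.DataFrame, trials_default: int = 47
) -> pd.DataFrame:
    """Validated (events, trials) disability counts.

    Zero-event rows are retained: the zero-inflated beta-binomial downstream
    absorbs excess zeros rather than requiring their removal.
    """
    if "disability_events" not in panel.columns:
        raise SchemaError("panel lacks 'disability_events'")
    events = panel["disability_events"].to_numpy(dtype=int)
    if "disability_trials" in panel.columns:
        trials = panel["disability_trials"].to_numpy(dtype=int)
    else:
        trials = np.full(len(panel), trials_default, dtype=int)
    if (events < 0).any():
        raise SchemaError("negative disability event count")
    bad = events > trials
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"disability events exceed trials at row {row}: "
            f"{events[bad][0]} > {trials[bad][0]}"
        )
    return pd.DataFrame(
        {"events": events, "trials": trials}, index=panel.index
    )


@dataclass
class ModelFrame:
    """Lagged regression frame for the ordinal clock models.

    ``data`` holds one row per (individual, outcome visit): the ordinal
    outcome (BODN at the later visit), lagged severity predictors, the time
    covariate, and bookkeeping columns (chronological age is carried through
    for age-only comparison models but is never a clock predictor).
    """

    data: pd.DataFrame
    disease_cols: tuple[str, ...]
    n_levels: dict[str, int]
    n_categories: int  # K + 1 ordinal categories, outcomes in 0..K
    outcome_col: str = "bodn_next"
    group_col: str = "individual_id"
    time_col: str = "time"
    linear_cols: tuple[str, ...] = field(default=("time",))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.outcome_col].to_numpy(dtype=int)

    def severity(self) -> np.ndarray:
        return self.data[list(self.disease_cols)].to_numpy(dtype=int)

    def linear(self) -> np.ndarray:
        if not self.linear_cols:
            return np.zeros((len(self.data), 0))
        return self.data[list(self.linear_cols)].to_numpy(dtype=float)

    def groups(self) -> tuple[np.ndarray, np.ndarray]:
        """(group index per row, unique group labels)."""
        codes, labels = pd.factorize(self.data[self.group_col])
        return codes, np.asarray(labels)

    def subset_diseases(self, names) -> "ModelFrame":
        names = tuple(names)
        unknown = set(names) - set(self.disease_cols)
        if unknown:
            raise SchemaError(f"unknown diseases: {sorted(unknown)}")
        return ModelFrame(
            data=self.data,
            disease_cols=names,
            n_levels={k: self.n_levels[k] for k in names},
            n_categories=self.n_categories,
            outcome_col=self.outcome_col,
            group_col=self.group_col,
            time_col=self.time_col,
            linear_cols=self.linear_cols,
        )


def build_model_frame(
    panel: pd.DataFrame,
    codex: DiseaseCodex,
    anchor: str = "lag1",
) -> ModelFrame:
    """Pair lagged severity predictors with later BODN outcomes.

    anchor
        ``"baseline"``: predictors fixed at each individual's first visit for
        all later outcomes; ``"second_visit"``: fixed at the second visit,
        outcomes from the third visit on; ``"lag1"``: rolling visit pairs.
        The time covariate is years from the anchor visit to the outcome
        visit.  Individuals without any valid (predictor, outcome) pair are
        dropped with a warning.
    """
    if anchor not in ("baseline", "second_visit", "lag1"):
        raise ValueError(f"unknown anchor {anchor!r}")
    required = {"individual_id", "visit_index", "time_since_baseline"}
    missing = required - set(panel.columns)
    if missing:
        raise SchemaError(f"panel lacks columns: {sorted(missing)}")

    panel = panel.sort_values(["individual_id", "visit_index"]).reset_index(drop=True)
    bodn = compute_bodn(panel, codex)

    rows = []
    dropped = 0
    for _, g in panel.groupby("individual_id", sort=False):
        idx = g.index.to_numpy()
        if anchor == "lag1":
            pairs = [(idx[t], idx[t + 1]) for t in range(len(idx) - 1)]
        elif anchor == "baseline":
            pairs = [(idx[0], idx[t]) for t in range(1, len(idx))]
        else:  # second_visit
            pairs = [(idx[1], idx[t]) for t in range(2, len(idx))] if len(idx) >= 2 else []
        if not pairs:
            dropped += 1
            continue
        for pred_i, out_i in pairs:
            rec = {
                "individual_id": panel.at[out_i, "individual_id"],
                "outcome_visit": panel.at[out_i, "visit_index"],
                "bodn_next": int(bodn.iloc[out_i]),
                "time": float(
                    panel.at[out_i, "time_since_baseline"]
                    - panel.at[pred_i, "time_since_baseline"]
                ),
            }
            if "chronological_age" in panel.columns:
                rec["chronological_age"] = float(panel.at[pred_i, "chronological_age"])
            for d in codex.disease_names:
                rec[d] = int(panel.at[pred_i, d])
            rows.append(rec)
    if dropped:
        msg = f"dropped {dropped} individuals without a lagged (predictor, outcome) pair"
        log.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    data = pd.DataFrame(
        rows,
        columns=["individual_id", "outcome_visit", "bodn_next", "time"]
        + (["chronological_age"] if "chronological_age" in panel.columns else [])
        + list(codex.disease_names),
    )
    return ModelFrame(
        data=data,
        disease_cols=codex.disease_names,
        n_levels=codex.levels_per_disease(),
        n_categories=codex.n_systems + 1,
    )
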