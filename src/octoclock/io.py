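"""Panel CSV schema, run manifests, and shared file handling.

Panels are plain CSV with a versioned comment header recording the schema and
units (times in years since baseline, ages in years, heights in meters,
speeds in m/s).  Manifests are JSON documents carrying the run configuration,
seeds, fit hashes and software versions, protected by a content hash so a
tampered manifest fails verification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codex import DiseaseCodex
from .scores import SchemaError, _severity_matrix

__all__ = ["PanelSchema", "read_panel", "write_panel", "write_manifest", "verify_manifest"]

SCHEMA_VERSION = "octoclock-panel/1"
_UNITS = "time_since_baseline=years chronological_age=years height=m walking_speed=m/s"

_BASE_COLUMNS = [
    "individual_id",
    "visit_index",
    "time_since_baseline",
    "chronological_age",
    "sex",
    "height",
    "walking_speed",
    "disability_events",
    "disability_trials",
    "death_indicator",
    "censor_time",
]


@dataclass(frozen=True)
class PanelSchema:
    """Ordered column specification for a cohort panel CSV."""

    codex: DiseaseCodex
    version: str = SCHEMA_VERSION

    @property
    def columns(self) -> list[str]:
        return _BASE_COLUMNS + list(self.codex.disease_names)


def write_panel(panel: pd.DataFrame, path, codex: DiseaseCodex) -> None:
    schema = PanelSchema(codex)
    missing = [c for c in schema.columns if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel lacks columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# {schema.version} codex={codex.content_hash()} {_UNITS}\n")
        panel[schema.columns].to_csv(fh, index=False)


def read_panel(path, codex: DiseaseCodex, strict: bool = False) -> pd.DataFrame:
    """Read and validate a cohort panel.

    Severity codes are coerced to integers and range-checked against the
    codex; visit times must be strictly increasing per individual.  In strict
    mode unknown columns are rejected.  Rows come back canonically sorted by
    (individual, visit).
    """
    panel = pd.read_csv(path, comment="#")
    schema = PanelSchema(codex)
    missing = [c for c in schema.columns if c not in panel.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if strict:
        unknown = [c for c in panel.columns if c not in schema.columns]
        if unknown:
            raise SchemaError(f"{path}: unknown columns in strict mode: {unknown}")
    for d in codex.disease_names:
        panel[d] = pd.to_numeric(panel[d], errors="raise").astype(int)
    _severity_matrix(panel, codex)  # row/column-level range errors
    panel = panel.sort_values(["individual_id", "visit_index"]).reset_index(drop=True)
    for iid, g in panel.groupby("individual_id", sort=False):
        t = g["time_since_baseline"].to_numpy(dtype=float)
        if (np.diff(t) <= 0).any():
            raise SchemaError(f"non-monotone visit times for individual {iid!r}")
    return panel


def _content_hash(doc: dict) -> str:
    payload = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def write_manifest(path, config: dict, seeds: dict, fit_hashes: dict | None = None) -> dict:
    """Write a JSON run manifest sufficient to re-execute bit-identically."""
    import arviz
    import emcee
    import scipy
    import sklearn

    doc = {
        "schema": "octoclock-manifest/1",
        "config": config,
        "seeds": seeds,
        "fit_hashes": fit_hashes or {},
        "versions": {
            "octoclock": _pkg_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "arviz": arviz.__version__,
            "emcee": emcee.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    doc["content_hash"] = _content_hash({k: v for k, v in doc.items()})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
    return doc


def verify_manifest(path) -> bool:
    with open(path) as fh:
        doc = json.load(fh)
    stored = doc.pop("content_hash", None)
    return stored == _content_hash(doc)


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("octoclock")
    except PackageNotFoundError:
        return "0.0.0+local"
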