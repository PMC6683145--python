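"""Readers/writers for the pipeline's tabular and model formats.

CSV dialect: comma-separated, UTF-8, "NA" as the sole missing marker.
Weeks are 0-based everywhere, including files (baseline = week 0).
Model JSON round-trips every float bit-exactly (Python's shortest-repr
decimal serialization).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .mixture import FitDiagnostics, MixtureComponent, MixtureModel
from .prep import Cohort, DESIGN_WEEKS, RatingSeries
from .synthetic import ClinicalTable

MISSING = "NA"
MODEL_SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# Ratings
# --------------------------------------------------------------------------

def read_ratings(path, design: str = "MARS") -> Cohort:
    """Read a long-format ratings CSV (patient_id, week, score).

    Missing scores are the literal "NA".  Malformed rows raise with their
    line number; duplicate (patient_id, week) pairs are hard errors.
    """
    path = Path(path)
    series_data: dict = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header.split(",")[:3] != ["patient_id", "week", "score"]:
            raise ValueError(f"{path}: expected header 'patient_id,week,score'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            pid, week_s, score_s = parts
            try:
                week = int(week_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer week {week_s!r}") from None
            if week < 0:
                raise ValueError(f"{path}:{lineno}: negative week {week}")
            if score_s == MISSING:
                score = float("nan")
            else:
                try:
                    score = float(int(score_s))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer score {score_s!r}") from None
                if score < 0:
                    raise ValueError(f"{path}:{lineno}: negative score")
            rec = series_data.setdefault(pid, {})
            if week in rec:
                raise ValueError(f"{path}:{lineno}: duplicate (patient_id, week) = ({pid}, {week})")
            rec[week] = score
    series = []
    for pid, rec in series_data.items():
        weeks = np.array(sorted(rec), dtype=int)
        raw = np.array([rec[w] for w in weeks], dtype=float)
        series.append(RatingSeries(pid, weeks, raw))
    return Cohort(series, design)


def write_ratings(cohort: Cohort, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("patient_id,week,score\n")
        for s in cohort.series:
            for w, r in zip(s.weeks, s.raw):
                val = MISSING if np.isnan(r) else (repr(int(r)) if float(r).is_integer() else repr(float(r)))
                fh.write(f"{s.patient_id},{int(w)},{val}\n")


# --------------------------------------------------------------------------
# Clinical table
# --------------------------------------------------------------------------

def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, na_rep=MISSING)
    meta = Path(path).with_suffix(Path(path).suffix + ".types.json")
    meta.write_text(json.dumps(table.item_types, indent=1, sort_keys=True), encoding="utf-8")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, index_col="patient_id", na_values=[MISSING], keep_default_na=False)
    meta = Path(path).with_suffix(Path(path).suffix + ".types.json")
    if meta.exists():
        item_types = json.loads(meta.read_text(encoding="utf-8"))
    else:
        item_types = {c: "numerical" for c in df.columns}
    return ClinicalTable(df, item_types)


# --------------------------------------------------------------------------
# Model JSON
# --------------------------------------------------------------------------

def write_model(model: MixtureModel, path, diagnostics: Optional[FitDiagnostics] = None,
                meta: Optional[dict] = None) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "k": model.k,
        "components": [
            {"intercept": c.intercept, "slope": c.slope,
             "residual_sd": c.residual_sd, "weight": c.weight}
            for c in model.components
        ],
        "sort_order": "ascending_slope",
    }
    if diagnostics is not None:
        doc["diagnostics"] = dataclasses.asdict(diagnostics)
    if meta is not None:
        doc["meta"] = meta
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_model(path):
    """Load a model JSON; returns (model, diagnostics-or-None, meta-or-None)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {doc.get('schema_version')!r}")
    if not isinstance(doc.get("k"), int) or doc["k"] < 1:
        raise ValueError("model JSON: k must be a positive integer")
    comps = [MixtureComponent(c["intercept"], c["slope"], c["residual_sd"], c["weight"])
             for c in doc["components"]]
    if len(comps) != doc["k"]:
        raise ValueError("model JSON: component count disagrees with k")
    model = MixtureModel(comps)
    model.validate()
    diag = None
    if "diagnostics" in doc:
        diag = FitDiagnostics(**doc["diagnostics"])
    return model, diag, doc.get("meta")


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    design: str = "MARS"
    k_min: int = 4
    k_max: int = 10
    n_restarts: int = 200
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    rf_trees: int = 2000
    rf_n_perm: int = 1000
    importance_n_perm: int = 10000

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")
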