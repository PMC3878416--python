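"""CSV schemas and fit-result serialisation.

All tables are RFC-4180 CSV with a header row, UTF-8.  Readers validate
the schema and report offending rows; unknown columns are preserved.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import FIELD_COLUMNS_SCHEMA, LAB_COLUMNS_SCHEMA, FieldDesign, LabDesign
from .simulate import PHENOTYPE_COLUMNS

WELL_KEY = ["trial", "block", "plate", "plate_row", "plate_column"]


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_well_key(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=WELL_KEY, keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]  # 1-based + header
        raise SchemaError(f"{path}: duplicated well key {WELL_KEY} at rows {rows}")


def read_cultivar_list(path) -> list[str]:
    """Plain-text cultivar ids, one per line, blank lines ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_cultivar_list(cultivars, path) -> None:
    Path(path).write_text("\n".join(cultivars) + "\n", encoding="utf-8")


def write_field_design(design: FieldDesign, path) -> None:
    design.table.to_csv(path, index=False)


def read_field_design(path) -> FieldDesign:
    df = pd.read_csv(path, dtype={"cultivar": str})
    _require_columns(df, FIELD_COLUMNS_SCHEMA, path)
    trials = df["trial"].unique()
    if len(trials) != 1:
        raise SchemaError(f"{path}: field design must hold a single trial, got {list(trials)}")
    n_rows = int(df["field_row"].max())
    n_blocks = int(df["block"].max())
    width = int(df["field_column"].max()) // n_blocks
    return FieldDesign(
        trial=str(trials[0]),
        n_rows=n_rows,
        n_blocks=n_blocks,
        block_width=width,
        table=df[FIELD_COLUMNS_SCHEMA],
    )


def write_lab_design(design: LabDesign, path) -> None:
    design.table.to_csv(path, index=False)


def read_lab_design(path, plates_per_day: int = 4) -> LabDesign:
    df = pd.read_csv(path, dtype={"cultivar": str})
    _require_columns(df, LAB_COLUMNS_SCHEMA, path)
    _check_well_key(df, path)
    trials = df["trial"].unique()
    if len(trials) != 1:
        raise SchemaError(f"{path}: lab design must hold a single trial, got {list(trials)}")
    df["is_standard"] = df["is_standard"].astype(bool)
    dups: dict[int, list[str]] = {}
    for b, sub in df[~df["is_standard"]].groupby("block"):
        samples = sub.drop_duplicates(subset=["plate", "plate_plot"])
        counts = samples.groupby("cultivar")["copy"].count()
        dups[int(b)] = sorted(counts.index[counts > 1])
    return LabDesign(
        trial=str(trials[0]),
        plates_per_day=plates_per_day,
        duplicates=dups,
        table=df[LAB_COLUMNS_SCHEMA],
    )


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cultivar": str})
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    sugar = pd.to_numeric(df["sugar"], errors="coerce")
    bad = df.index[sugar.isna() & df["sugar"].notna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric sugar at rows {(bad + 2).tolist()[:10]}")
    if sugar.isna().any():
        raise SchemaError(f"{path}: missing sugar values")
    df["sugar"] = sugar
    df["is_standard"] = df["is_standard"].astype(bool)
    for col in ("field_row", "field_column"):
        df[col] = df[col].astype("Int64")
    _check_well_key(df, path)
    return df


def write_fit(fit, path_json, path_eblups=None) -> None:
    """Structured fit summary (JSON) plus an optional EBLUP CSV."""
    from .mixed_model import avg_pev, heritability, variance_table

    herit = {}
    for t in fit.trials:
        try:
            herit[t] = heritability(fit, t)
        except ValueError:
            herit[t] = None
    payload = {
        "kind": fit.spec.kind,
        "trials": list(fit.trials),
        "loglik": fit.loglik,
        "n_params": fit.spec.n_params,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "fixed_estimates": {str(k): v for k, v in fit.fixed_estimates.items()},
        "estimates": fit.params.as_dict(),
        "dropped_terms": [list(k) for k in fit.dropped_terms],
        "heritability": herit,
        "avg_pev": avg_pev(fit),
        "variance_tables": {
            t: variance_table(fit, t).to_dict(orient="records") for t in fit.trials
        },
    }
    Path(path_json).write_text(json.dumps(payload, indent=2, default=float), encoding="utf-8")
    if path_eblups is not None:
        from .ranking import _trial_values

        df = fit.eblup_frame()
        values = np.full(len(df), np.nan)
        for trial in fit.trials:
            v = _trial_values(fit, trial)
            mask = df["trial"] == trial
            values[mask.to_numpy()] = df.loc[mask, "cultivar"].map(v).to_numpy()
        df["value"] = values
        df.to_csv(path_eblups, index=False)


def read_fit(path_json) -> dict:
    return json.loads(Path(path_json).read_text(encoding="utf-8"))
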