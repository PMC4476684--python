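"""CSV dataset loading and report writing.

Input is RFC-4180 CSV with a header row.  Columns are inferred discrete
vs. continuous by a numeric-majority heuristic (numeric with more than 10
distinct values => continuous), overridable with a plain-text schema
sidecar of ``name<TAB>kind`` lines.  Default missing markers: empty cell,
``?``, ``NA``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DiscreteDataset, SchemaError
from .preprocess import CutPointSet, apply_cuts, learn_cuts

DEFAULT_MISSING = ("", "?", "NA")

__all__ = ["read_csv_frame", "read_csv_dataset", "infer_kinds",
           "write_predictions", "write_report", "read_schema_sidecar"]


def read_schema_sidecar(path) -> dict:
    kinds = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, kind = line.rstrip("\n").split("\t")
                if kind not in ("discrete", "continuous"):
                    raise SchemaError(f"bad kind {kind!r} for {name!r}")
                kinds[name] = kind
    return kinds


def infer_kinds(df: pd.DataFrame, overrides: dict | None = None) -> dict:
    """Numeric-majority heuristic, per column."""
    kinds = {}
    for c in df.columns:
        col = df[c].dropna()
        as_num = pd.to_numeric(col, errors="coerce")
        numeric_frac = 1.0 if len(col) == 0 else as_num.notna().mean()
        kinds[c] = ("continuous"
                    if numeric_frac >= 0.9 and as_num.nunique() > 10
                    else "discrete")
    if overrides:
        kinds.update(overrides)
    return kinds


def read_csv_frame(path, missing_markers=DEFAULT_MISSING) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=False)
    markers = set(missing_markers)
    for c in df.columns:
        df[c] = df[c].map(lambda v: None if v in markers else v)
    if len(df) == 0:
        import warnings

        warnings.warn(f"{path}: header-only file, 0 rows", stacklevel=2)
    return df


def read_csv_dataset(
    path,
    target: str,
    positive=None,
    missing_markers=DEFAULT_MISSING,
    schema_path=None,
    discretize: str = "error",
):
    """Load a CSV into a :class:`DiscreteDataset`.

    ``discretize`` controls continuous columns: ``"error"`` (default)
    rejects them so the caller can run per-fold discretization;
    ``"global"`` learns MDL cuts on the whole file and returns
    ``(dataset, CutPointSet)`` instead of just the dataset.
    """
    df = read_csv_frame(path, missing_markers)
    if target not in df.columns:
        raise SchemaError(f"target column {target!r} absent")
    overrides = read_schema_sidecar(schema_path) if schema_path else None
    kinds = infer_kinds(df.drop(columns=[target]), overrides)
    continuous = [c for c, k in kinds.items() if k == "continuous"]
    for c in continuous:
        bad = df[c].notna() & pd.to_numeric(df[c], errors="coerce").isna()
        if bad.any():
            raise SchemaError(f"unparseable numeric in continuous column {c!r}")
    if continuous and discretize == "error":
        raise SchemaError(
            f"continuous columns present ({continuous}); discretize first "
            "or pass discretize='global'"
        )
    cuts = None
    if continuous:
        cuts = learn_cuts(df, target, continuous)
        df = apply_cuts(df, cuts)
    ds = DiscreteDataset.from_dataframe(df, target, positive=positive,
                                        missing_markers=missing_markers)
    return (ds, cuts) if discretize == "global" else ds


def write_predictions(records, path, threshold: float = 0.5) -> None:
    """Predictions CSV: id, method, fold, probability, label, true."""
    rows = [
        {
            "individual": r.individual,
            "method": r.method,
            "fold": r.fold,
            "probability": f"{r.probability:.6f}",
            "label_at_threshold": int(r.probability >= threshold),
            "true_positive": int(r.is_positive),
        }
        for r in records
    ]
    cols = ["individual", "method", "fold", "probability",
            "label_at_threshold", "true_positive"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_report(table: pd.DataFrame, path) -> None:
    """Tab-separated metric table plus a flat key/value twin (.kv)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    kv_path = str(path) + ".kv"
    with open(kv_path, "w") as fh:
        for _, row in table.iterrows():
            prefix = f"{row['dataset']}.{row['method']}"
            for col in table.columns:
                if col in ("dataset", "method"):
                    continue
                v = row[col]
                if isinstance(v, float) and np.isnan(v):
                    continue
                fh.write(f"{prefix}.{col}\t{v:.6f}\n" if isinstance(v, float)
                         else f"{prefix}.{col}\t{v}\n")
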