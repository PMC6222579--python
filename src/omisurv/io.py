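"""Reading and writing the delimited formats the pipeline exchanges.

Clinical tables are CSV/TSV with one row per patient; omic matrices are
delimited with a sample-id first column and feature ids in the header; gene
sets use GMT-style text (name, description, tab-separated gene ids).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CENSOR_COL, TIME_COL, Cohort, OmicMatrix, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_CLINICAL = ("sample_id", "time", "censor")


def read_clinical(path, column_map: dict | None = None, sep: str | None = None) -> Cohort:
    """Read a clinical table into a :class:`Cohort`.

    ``column_map`` renames file columns onto the required schema, e.g.
    ``{"patient": "sample_id", "os_months": "time"}``. Rows with missing
    time or censor are dropped (count logged); non-positive times and
    duplicate ids raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise SchemaError(f"{path}: empty clinical file")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["censor"] = pd.to_numeric(df["censor"], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["time", "censor"])
    if len(df) < n0:
        logger.info("read_clinical: dropped %d rows with missing time/censor", n0 - len(df))
    bad = df.index[df["time"] <= 0]
    if len(bad):
        rows = df.loc[bad, "sample_id"].tolist()[:5]
        raise SchemaError(f"{path}: non-positive follow-up time for rows {rows}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise SchemaError(f"{path}: duplicate sample ids {dups}")
    df = df.set_index("sample_id")
    df = df.rename(columns={"time": TIME_COL, "censor": CENSOR_COL})
    # object columns with few levels become categoricals
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype("category")
    return Cohort(df)


def read_omic_matrix(path, kind: str, sep: str | None = None,
                     feature_meta: pd.Series | None = None) -> OmicMatrix:
    """Read a samples-x-features matrix; non-numeric cells become missing."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty omic matrix file")
    try:
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: ragged or malformed matrix ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty omic matrix file") from exc
    if df.empty:
        raise SchemaError(f"{path}: empty omic matrix file")
    df = df.apply(pd.to_numeric, errors="coerce")
    return OmicMatrix(df, kind, feature_meta)


def write_omic_matrix(m: OmicMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="sample_id")


def write_clinical(cohort: Cohort, path) -> None:
    cohort.data.to_csv(path, index_label="sample_id")


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read GMT-style gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"malformed gene-set line: {line[:60]!r}")
        name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise SchemaError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
    if not sets:
        raise SchemaError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
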