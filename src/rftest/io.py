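"""Readers and writers: TSV tables, metadata, JSON results, fixtures."""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import TestResult
from .simulate import synth_community

__all__ = [
    "read_table",
    "write_table",
    "read_metadata",
    "write_result",
    "read_result",
    "write_fixtures",
]


def read_table(path, taxa_as_rows: bool = False) -> pd.DataFrame:
    """Read a samples x taxa abundance table from tab-separated text.

    The first column holds sample identifiers and the header row taxon
    identifiers; ``taxa_as_rows=True`` reads the transposed dialect.
    Entries must be numeric, non-missing and non-negative.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if taxa_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate taxon identifiers: {dups[:5]}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric abundance at sample {row!r}, taxon {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise ValueError(f"missing abundance at sample {row!r}, taxon {col!r}")
        neg = vals < 0
        if neg.any():
            row = df.index[neg.argmax()]
            raise ValueError(
                f"negative abundance at sample {row!r}, taxon {col!r}: "
                f"{vals[neg].iloc[0]}"
            )
        df[col] = vals
    return df


def write_table(table: pd.DataFrame, path, taxa_as_rows: bool = False) -> None:
    out = table.T if taxa_as_rows else table
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(
    path,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    sample_ids=None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Read outcome and covariates from a tab-separated metadata file.

    Rows are joined to ``sample_ids`` (the table's samples) by
    identifier, so row order is irrelevant. The outcome is coded 0/1
    when it has exactly two distinct values (levels sorted, mapping
    attached as ``y.attrs['mapping']``); categorical covariates are
    one-hot encoded with the first level dropped.
    """
    covariate_cols = covariate_cols or []
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if outcome_col in covariate_cols:
        raise ValueError(f"outcome column {outcome_col!r} also listed as covariate")
    for col in [outcome_col, *covariate_cols]:
        if col not in meta.columns:
            raise ValueError(
                f"column {col!r} not in metadata (has: {list(meta.columns)})"
            )
    if sample_ids is not None:
        wanted = pd.Index([str(s) for s in sample_ids])
        missing = wanted.difference(meta.index)
        if len(missing):
            raise ValueError(
                f"metadata lacks rows for samples: {sorted(missing)[:10]}"
            )
        meta = meta.loc[wanted]
    y_raw = meta[outcome_col]
    if y_raw.isna().any():
        bad = y_raw.index[y_raw.isna()].tolist()
        raise ValueError(f"missing outcome values for samples: {bad[:10]}")
    levels = pd.unique(y_raw)
    if len(levels) == 2:
        ordered = sorted(levels.tolist(), key=str)
        mapping = {ordered[0]: 0, ordered[1]: 1}
        y = y_raw.map(mapping).astype(float)
        y.attrs["mapping"] = {str(k): v for k, v in mapping.items()}
    else:
        y = pd.to_numeric(y_raw, errors="raise").astype(float)
        y.attrs["mapping"] = None
    if not covariate_cols:
        return y, None
    Z_parts = []
    for col in covariate_cols:
        series = meta[col]
        if series.isna().any():
            bad = series.index[series.isna()].tolist()
            raise ValueError(f"missing covariate {col!r} for samples: {bad[:10]}")
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().all():
            Z_parts.append(numeric.to_frame(col))
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
            Z_parts.append(dummies.astype(float))
    Z = pd.concat(Z_parts, axis=1)
    return y, Z


def write_result(result: TestResult, path, timestamp: bool = True) -> None:
    """Serialize a test result (plus version stamp) as JSON."""
    payload = result.to_dict()
    payload["version"] = __version__
    if timestamp:
        payload["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_result(path) -> TestResult:
    with open(path) as fh:
        payload = json.load(fh)
    return TestResult.from_dict(payload)


def write_fixtures(
    out_dir, n: int = 30, p: int = 40, depth: int = 500, seed: int = 0
) -> dict[str, Path]:
    """Write a small synthetic Newick + TSV fixture set for tests/demos."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    community = synth_community(n=n, p=p, depth=depth, seed=seed)
    tree_path = out / "tree.nwk"
    tree_path.write_text(community.tree.to_newick() + "\n")
    table_path = out / "table.tsv"
    write_table(community.table, table_path)
    rng = np.random.default_rng(seed + 1)
    lin = community.lineages["A"]
    sig = community.table[list(lin.taxa)].sum(axis=1).to_numpy(dtype=float)
    sig = (sig - sig.mean()) / sig.std(ddof=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * sig))).astype(int)
    meta = pd.DataFrame(
        {
            "outcome": np.where(y == 1, "case", "control"),
            "age": rng.normal(50, 10, n).round(1),
        },
        index=community.table.index,
    )
    meta_path = out / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    return {"tree": tree_path, "table": table_path, "metadata": meta_path}
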