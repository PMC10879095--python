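"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are TSV/CSV with genes in rows (canonical orientation,
auto-detected with an override); survival tables carry (sample, time_months,
event); gene sets come from GMT files; single-cell matrices round-trip
through MatrixMarket + label TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_expression", "read_survival", "read_gmt", "write_gmt",
           "write_expression", "write_survival", "write_single_cell",
           "read_single_cell"]

_TIME_FACTORS = {"months": 1.0, "days": 1.0 / 30.44, "years": 12.0}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    return df


def read_expression(path, orientation: str = "auto") -> pd.DataFrame:
    """Read an expression matrix; returns genes x samples.

    ``orientation``: 'genes' (rows are genes), 'samples' (rows are samples,
    transposed on read) or 'auto' (genes in rows when the table is taller
    than wide, which matches the canonical layout).  Duplicate gene ids are
    collapsed by the per-sample maximum, with a logged count.
    """
    df = _read_table(path)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"{path}: non-numeric values; wrong orientation or malformed "
            "table (expected a gene-ID index column)") from exc
    if orientation not in {"auto", "genes", "samples"}:
        raise ValueError("orientation must be 'auto', 'genes' or 'samples'")
    if orientation == "samples" or (orientation == "auto"
                                    and df.shape[0] < df.shape[1] / 5):
        df = df.T
    dup = df.index.duplicated().sum()
    if dup:
        logger.warning("%s: collapsed %d duplicate gene id(s) by max", path, dup)
        df = df.groupby(level=0).max()
    df.index = df.index.astype(str)
    return df


def read_survival(path, time_unit: str = "months") -> pd.DataFrame:
    """Read a survival table with columns (sample, time_months|time, event)."""
    df = _read_table(path).reset_index()
    cols = {c.lower(): c for c in df.columns}
    sample_col = cols.get("sample", df.columns[0])
    time_col = next((cols[c] for c in ("time_months", "time", "os_time")
                     if c in cols), None)
    event_col = next((cols[c] for c in ("event", "status", "os_event")
                      if c in cols), None)
    if time_col is None or event_col is None:
        raise ValueError(f"{path}: need time and event columns")
    out = pd.DataFrame({
        "time_months": pd.to_numeric(df[time_col], errors="raise").to_numpy()
        * _TIME_FACTORS[time_unit],
        "event": df[event_col].to_numpy(),
    }, index=pd.Index(df[sample_col].astype(str), name="sample"))
    if (out["time_months"] < 0).any():
        raise ValueError(f"{path}: negative follow-up times")
    ev = set(pd.unique(out["event"]))
    if not ev <= {0, 1}:
        raise ValueError(f"{path}: event values outside {{0,1}}: {sorted(ev - {0, 1})}")
    out["event"] = out["event"].astype(int)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if not parts or not parts[0]:
                continue
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                logger.warning("%s line %d: set %s has no genes; skipped",
                               path, ln, name)
                continue
            sets[name] = list(dict.fromkeys(genes))
    if not sets:
        raise ValueError(f"{path}: no usable gene sets")
    return sets


def write_gmt(sets, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample")


def write_single_cell(counts: pd.DataFrame, labels: pd.Series, prefix) -> None:
    """Write counts as MatrixMarket plus gene/cell/label TSVs."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(str(prefix) + ".genes.tsv",
                                   sep="\t", index=False, header=False)
    labels.rename("cell_type").to_csv(str(prefix) + ".labels.tsv",
                                      sep="\t", index_label="cell")


def read_single_cell(prefix):
    from scipy.io import mmread

    prefix = Path(prefix)
    mat = mmread(str(prefix) + ".mtx").toarray()
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t",
                        header=None)[0].astype(str)
    labels = pd.read_csv(str(prefix) + ".labels.tsv", sep="\t", index_col=0)
    counts = pd.DataFrame(np.asarray(mat), index=genes,
                          columns=labels.index.astype(str))
    return counts, labels["cell_type"]
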