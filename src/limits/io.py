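"""Readers and writers for the on-disk formats.

Abundance tables are TSV: first column the species label, remaining columns
named ``t<i>`` (single replicate) or ``t<i>_r<j>``; a JSON sidecar
(``<table>.meta.json``) records whether values are absolute or relative,
the timestep, and free-form provenance.  Interaction matrices travel as
3-column edge lists (source, target, coefficient) with a header comment
fixing the sign convention, plus an equilibrium TSV; inferred networks can
additionally be exported to GraphML for graph tooling.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dlv_sim import AbundanceTimeseries, InteractionMatrix
from .limits_core import InferredNetwork

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_edge_list",
    "write_edge_list",
    "write_equilibrium",
    "read_equilibrium",
    "write_graphml",
    "select_top_taxa",
]

def _repr_float(v) -> str:
    return repr(float(v))


_COLUMN_RE = re.compile(r"^t(\d+)(?:_r(\d+))?$")

SIGN_CONVENTION = (
    "# sign convention: coefficient > 0 means `source` benefits `target` "
    "(directed edge source -> target; entry c[target, source])"
)


def _parse_columns(columns) -> list[tuple[int, int]]:
    pairs = []
    for name in columns:
        m = _COLUMN_RE.match(str(name))
        if not m:
            raise ValueError(
                f"column {name!r} does not match 't<i>' or 't<i>_r<j>'"
            )
        pairs.append((int(m.group(1)), int(m.group(2) or 0)))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (timepoint, replicate) columns")
    return pairs


def write_abundance_table(
    ts: AbundanceTimeseries, path, provenance: dict | None = None
) -> None:
    """Write a timeseries as TSV plus its JSON metadata sidecar.

    Values are written with full float repr so a read-back is bit-identical.
    """
    path = Path(path)
    m, T, R = ts.values.shape
    columns = [
        f"t{t}_r{r}" if R > 1 else f"t{t}" for r in range(R) for t in range(T)
    ]
    data = ts.values.transpose(0, 2, 1).reshape(m, T * R)
    df = pd.DataFrame(data, index=ts.labels, columns=columns)
    df.index.name = "species"
    df.to_csv(path, sep="\t", float_format=_repr_float)  # shortest round-trip repr
    meta = {"kind": ts.kind, "dt": ts.dt, "provenance": provenance or {}}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )


def read_abundance_table(path, kind: str | None = None) -> AbundanceTimeseries:
    """Read and validate an abundance TSV.

    ``kind`` overrides the sidecar; without either, absolute is assumed.
    Errors name the offending row/column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):  # pandas would mangle duplicates
        raise ValueError(f"{path}: duplicate column names in header")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty abundance table")
    pairs = _parse_columns(df.columns)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(df[c].dtype, np.number) for c in df.columns]
        ][0]
        raise ValueError(f"{path}: non-numeric values in column {bad!r}")
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        r, c = np.argwhere(~np.isfinite(values) | (values < 0))[0]
        raise ValueError(
            f"{path}: invalid value {values[r, c]!r} at species "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    dt = 1.0
    if kind is None:
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            kind = meta.get("kind", "absolute")
            dt = float(meta.get("dt", 1.0))
        else:
            kind = "absolute"

    timepoints = sorted({t for t, _ in pairs})
    replicates = sorted({r for _, r in pairs})
    t_pos = {t: i for i, t in enumerate(timepoints)}
    r_pos = {r: i for i, r in enumerate(replicates)}
    if len(pairs) != len(timepoints) * len(replicates):
        raise ValueError(f"{path}: timepoint/replicate grid is incomplete")
    out = np.empty((values.shape[0], len(timepoints), len(replicates)))
    for col, (t, r) in enumerate(pairs):
        out[:, t_pos[t], r_pos[r]] = values[:, col]
    return AbundanceTimeseries(
        values=out, kind=kind, dt=dt, labels=[str(s) for s in df.index]
    )


def write_edge_list(model, path, zero_tol: float = 0.0, include_diagonal: bool = True) -> None:
    """Serialize a coefficient matrix as a source/target/coefficient TSV.

    Diagonal (self-limitation) terms are included by default and marked by
    ``source == target``.  Entries with ``|c| <= zero_tol`` are omitted.
    """
    c = np.asarray(model.coefficients, dtype=float)
    labels = model.labels
    lines = [SIGN_CONVENTION, "source\ttarget\tcoefficient"]
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            if i == j and not include_diagonal:
                continue
            if abs(c[i, j]) > zero_tol or (i == j and include_diagonal and c[i, j] != 0):
                lines.append(f"{labels[j]}\t{labels[i]}\t{float(c[i, j])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path, labels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Read an edge-list TSV back into a dense coefficient matrix."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if not {"source", "target", "coefficient"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns source, target, coefficient")
    if not np.all(np.isfinite(df["coefficient"])):
        raise ValueError(f"{path}: non-finite coefficient")
    if labels is None:
        labels = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    pos = {s: i for i, s in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)))
    for _, row in df.iterrows():
        c[pos[str(row["target"])], pos[str(row["source"])]] = row["coefficient"]
    return c, list(labels)


def write_equilibrium(model: InteractionMatrix, path) -> None:
    df = pd.DataFrame({"species": model.labels, "equilibrium": model.equilibrium})
    df.to_csv(path, sep="\t", index=False, float_format=_repr_float)


def read_equilibrium(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df["equilibrium"].to_numpy(dtype=float), [str(s) for s in df["species"]]


def write_graphml(inferred: InferredNetwork, path, median_abundance=None) -> None:
    """Export an inferred network to GraphML.

    Node attribute ``median_abundance`` (the equilibrium estimate unless
    overridden) and edge attribute ``coefficient``; self-loops carry the
    self-limitation terms.
    """
    c = inferred.coefficients
    abund = (
        np.asarray(median_abundance, dtype=float)
        if median_abundance is not None
        else inferred.equilibrium_estimate
    )
    g = nx.DiGraph()
    for j, label in enumerate(inferred.labels):
        g.add_node(label, median_abundance=float(abund[j]))
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            if c[i, j] != 0:
                g.add_edge(
                    inferred.labels[j], inferred.labels[i], coefficient=float(c[i, j])
                )
    nx.write_graphml(g, path)


def select_top_taxa(tables: list[AbundanceTimeseries], n: int) -> list[str]:
    """Union of each table's top-``n`` species by median relative abundance.

    Pooling abundant taxa across subjects keeps the regression problem small
    enough for the available timepoints while covering every subject's
    dominant community members.  Returns labels sorted by first appearance
    in the tables' label lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    selected: list[str] = []
    for table in tables:
        values = table.values
        if table.kind == "absolute":
            totals = values.sum(axis=0)
            totals = np.where(totals > 0, totals, np.nan)
            values = values / totals[None, :, :]
        medians = np.nanmedian(values.reshape(table.n_species, -1), axis=1)
        if n >= table.n_species:
            if n > table.n_species:
                warnings.warn(
                    f"requested top {n} of {table.n_species} species; taking all"
                )
            top = list(range(table.n_species))
        else:
            top = list(np.argsort(-medians, kind="stable")[:n])
        for idx in sorted(top):
            label = table.labels[idx]
            if label not in selected:
                selected.append(label)
    return selected
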