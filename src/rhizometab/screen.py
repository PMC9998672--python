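"""Index-metabolite correlation screening, sign partitioning and the
bipartite interaction network.

Every soil/microbial index is correlated with every metabolite across
samples (replicate level, n = 9 in the 3x3 design). Metabolites significant
for at least one index are partitioned into positively and negatively
correlated sets by a consensus over the signs of their significant
correlations, with the fungal count's sign inverted first — fungi is the one
index that moves against the pH gradient, so a metabolite rising with pH
correlates positively with eight indexes and negatively with fungi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import INDEX_COLUMNS

__all__ = [
    "ScreenResult",
    "correlate_all",
    "partition_significant",
    "build_network",
    "write_sif",
    "read_sif",
]

#: Indexes whose sign is inverted before consensus voting (anti-gradient).
INVERTED_INDEXES = frozenset({"fungi"})


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def correlate_all(
    index_table: pd.DataFrame,
    matrix: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.05,
    correction: str = "none",
    transform: str = "log",
    index_columns: tuple = INDEX_COLUMNS,
) -> pd.DataFrame:
    """Correlate each index with each metabolite.

    Parameters
    ----------
    index_table
        Per-sample index table (rows = sample ids).
    matrix
        Feature x sample intensity matrix. NaN cells trigger a
        pairwise-complete computation for the affected features; impute
        upstream for the fast dense path.
    method
        "pearson" (default) or "spearman" (Pearson on ranks).
    correction
        "none" (raw two-sided p, default) or "bh" (Benjamini–Hochberg over
        all computed records; ``p_adj`` is reported alongside and drives
        ``significant``).
    transform
        "log" (default) correlates log(1 + intensity) — peak areas are
        heavy-tailed and Pearson's t-based p-value is calibrated on the log
        scale, not the raw scale; "none" correlates raw intensities.
        Irrelevant for Spearman.

    Returns
    -------
    DataFrame with one row per (index, metabolite) pair: index_name,
    metabolite_id, n, r, p, p_adj, significant, sign — ordered by index then
    metabolite id. Constant metabolite rows (or pairs with fewer than 3
    complete observations) are skipped and listed in ``df.attrs["skipped"]``.
    """
    cols = [c for c in index_columns if c in index_table.columns]
    sample_ids = list(matrix.columns)
    missing = set(map(str, sample_ids)) - set(map(str, index_table.index))
    if missing:
        raise ValueError(f"samples absent from index table: {sorted(missing)}")
    X = index_table.loc[sample_ids, cols].to_numpy(dtype=float)  # n x k
    Y = matrix.to_numpy(dtype=float)  # m x n
    if transform == "log":
        with np.errstate(invalid="ignore"):
            Y = np.log1p(Y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    ids = np.asarray(matrix.index.astype(str))
    order = np.argsort(ids, kind="stable")

    records: list[pd.DataFrame] = []
    skipped: list[tuple[str, str, str]] = []
    has_nan = np.isnan(Y).any()

    for j, name in enumerate(cols):
        x = X[:, j]
        if has_nan:
            r, p, n_used, skip = _correlate_pairwise(x, Y, ids, method)
        else:
            r, p, n_used, skip = _correlate_dense(x, Y, ids, method)
        skipped.extend((name, mid, why) for mid, why in skip)
        ok = ~np.isnan(r)
        rec = pd.DataFrame(
            {
                "index_name": name,
                "metabolite_id": ids[order][ok[order]],
                "n": n_used[order][ok[order]],
                "r": r[order][ok[order]],
                "p": p[order][ok[order]],
            }
        )
        records.append(rec)

    out = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["index_name", "metabolite_id", "n", "r", "p"]
    )
    if correction == "bh" and len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    elif correction == "none":
        out["p_adj"] = out["p"] if len(out) else pd.Series(dtype=float)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p_adj"] < alpha
    out["sign"] = np.where(out["r"] >= 0, "+", "-")
    out.attrs["skipped"] = skipped
    out.attrs["alpha"] = alpha
    out.attrs["method"] = method
    out.attrs["correction"] = correction
    return out


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r of x against every row of Y, with two-sided p."""
    n = len(x)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xss = (xc**2).sum()
    yss = (Yc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / np.sqrt(xss * yss)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def _correlate_dense(x, Y, ids, method):
    n = Y.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    const = np.ptp(Y, axis=1) == 0.0
    if method == "spearman":
        x = _rank(x)
        Y = _rank(Y, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r, p = _pearson_with_p(x, Y)
    r[const] = np.nan
    p[const] = np.nan
    skip = [(ids[i], "constant") for i in np.where(const)[0]]
    return r, p, np.full(len(ids), n), skip


def _correlate_pairwise(x, Y, ids, method):
    m, n = Y.shape
    r = np.full(m, np.nan)
    p = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    skip = []
    for i in range(m):
        mask = ~np.isnan(Y[i])
        k = int(mask.sum())
        n_used[i] = k
        if k < 3:
            skip.append((ids[i], "fewer than 3 complete pairs"))
            continue
        y = Y[i, mask]
        if np.ptp(y) == 0.0 or np.ptp(x[mask]) == 0.0:
            skip.append((ids[i], "constant"))
            continue
        xi, yi = (x[mask], y)
        if method == "spearman":
            xi, yi = _rank(xi), _rank(yi)
        ri, pi = _pearson_with_p(xi, yi[None, :])
        r[i], p[i] = ri[0], pi[0]
    return r, p, n_used, skip


@dataclass(frozen=True)
class ScreenResult:
    """Sign-partitioned outcome of the correlation screen.

    ``positive_set`` / ``negative_set`` hold metabolites whose significant
    correlations agree (after inverting fungi) on a positive / negative
    association with the pH gradient; metabolites with tied or inconsistent
    votes land in ``conflicted_set`` — never silently dropped.
    """

    positive_set: frozenset
    negative_set: frozenset
    conflicted_set: frozenset
    alpha: float
    records: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_significant(self) -> int:
        return len(self.positive_set) + len(self.negative_set) + len(self.conflicted_set)

    def sign_of(self, metabolite_id: str) -> str | None:
        if metabolite_id in self.positive_set:
            return "+"
        if metabolite_id in self.negative_set:
            return "-"
        if metabolite_id in self.conflicted_set:
            return "?"
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            [(m, "positive") for m in self.positive_set]
            + [(m, "negative") for m in self.negative_set]
            + [(m, "conflicted") for m in self.conflicted_set]
        )
        return pd.DataFrame(rows, columns=["metabolite_id", "partition"])


def partition_significant(
    records: pd.DataFrame,
    require: str = "any",
    anchor: str = "majority",
) -> ScreenResult:
    """Partition metabolites by the consensus sign of their significant
    correlations.

    Parameters
    ----------
    records
        Output of :func:`correlate_all`.
    require
        "any": a metabolite qualifies if significant for at least one index
        (default). "all": significance with every tested index is required.
    anchor
        "majority" (default): majority vote over the signs of the
        metabolite's significant correlations, fungi inverted; ties →
        conflicted. "ph": when pH itself is significant its sign decides;
        majority only as fallback.
    """
    alpha = records.attrs.get("alpha", 0.05)
    sig = records.loc[records["significant"]].copy()
    if require == "all":
        n_indexes = records["index_name"].nunique()
        counts = sig.groupby("metabolite_id")["index_name"].nunique()
        keep = set(counts.index[counts == n_indexes])
        sig = sig.loc[sig["metabolite_id"].isin(keep)]
    elif require != "any":
        raise ValueError(f"unknown require mode {require!r}")

    if len(sig):
        flip = sig["index_name"].isin(INVERTED_INDEXES)
        sig["vote"] = np.where(
            flip, np.where(sig["r"] >= 0, -1, 1), np.where(sig["r"] >= 0, 1, -1)
        )

    pos, neg, conflicted = set(), set(), set()
    for mid, grp in sig.groupby("metabolite_id"):
        decided = None
        if anchor == "ph":
            ph_rows = grp.loc[grp["index_name"] == "ph"]
            if len(ph_rows):
                decided = int(ph_rows["vote"].iloc[0])
        elif anchor != "majority":
            raise ValueError(f"unknown anchor mode {anchor!r}")
        if decided is None:
            total = int(grp["vote"].sum())
            decided = 0 if total == 0 else int(np.sign(total))
        if decided > 0:
            pos.add(mid)
        elif decided < 0:
            neg.add(mid)
        else:
            conflicted.add(mid)

    return ScreenResult(
        positive_set=frozenset(pos),
        negative_set=frozenset(neg),
        conflicted_set=frozenset(conflicted),
        alpha=alpha,
        records=records,
    )


def build_network(
    result: ScreenResult,
    annotations: pd.DataFrame | None = None,
    graphml_path: str | Path | None = None,
    sif_path: str | Path | None = None,
) -> nx.Graph:
    """Bipartite index-metabolite network of significant correlations.

    One edge per significant (index, metabolite) record whose metabolite was
    partitioned into the positive or negative set; edges carry ``sign``
    ("+"/"-") and ``weight`` = |r|. Node attributes: ``kind`` ("index" or
    "metabolite") and, when annotations are given, the metabolite
    ``superclass``. Optionally exported as GraphML and SIF.
    """
    g = nx.Graph()
    partitioned = result.positive_set | result.negative_set
    records = result.records
    edges = records.loc[records["significant"] & records["metabolite_id"].isin(partitioned)]
    superclass = {}
    if annotations is not None:
        superclass = dict(zip(annotations["metabolite_id"].astype(str), annotations["superclass"]))
    for row in edges.itertuples(index=False):
        if row.index_name not in g:
            g.add_node(row.index_name, kind="index", bipartite=0)
        if row.metabolite_id not in g:
            g.add_node(
                row.metabolite_id,
                kind="metabolite",
                bipartite=1,
                partition=result.sign_of(row.metabolite_id),
                **({"superclass": superclass[row.metabolite_id]} if row.metabolite_id in superclass else {}),
            )
        g.add_edge(row.index_name, row.metabolite_id, sign=row.sign, weight=float(abs(row.r)))
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if sif_path is not None:
        write_sif(g, sif_path)
    return g


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: source <tab> relation <tab> target."""
    lines = [
        f"{u}\t{'pos' if d.get('sign') == '+' else 'neg'}\t{v}"
        for u, v, d in sorted(g.edges(data=True))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_sif(path: str | Path) -> set[tuple[str, str, str]]:
    """Edge multiset of a SIF file as {(source, relation, target)}."""
    edges = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            s, rel, t = line.split("\t")
            edges.add((s, rel, t))
    return edges
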