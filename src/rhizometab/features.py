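"""Characteristic-compound selection and trend classification.

Characteristic compounds are the smallest content-ranked prefix of a signed
metabolite set (positively or negatively pH-correlated) whose cumulative
content reaches a coverage threshold, 90% by default — the construction
behind abundance "bubble map" summaries. Trends classify the shape of a
quantity across the three ordered pH groups: monotone up or down, up-then-
down, down-then-up, or flat on exact ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .qc import _group_map, impute

__all__ = [
    "TrendPattern",
    "CharacteristicSet",
    "select_characteristic",
    "classify_trend",
    "aggregate_by_category",
    "characteristic_report",
]


class TrendPattern(str, Enum):
    """Shape of a quantity across three ordered groups."""

    UP = "UP"
    DOWN = "DOWN"
    UP_DOWN = "UP_DOWN"
    DOWN_UP = "DOWN_UP"
    FLAT = "FLAT"


@dataclass(frozen=True)
class CharacteristicSet:
    """Content-ranked compound subset reaching a cumulative-content coverage.

    ``selected`` is ordered by descending content (ties broken
    lexicographically by id); ``cumulative_share`` gives the running content
    fraction after each selected compound. The set is minimal: dropping its
    last member would fall below ``coverage_threshold``.
    """

    selected: tuple
    cumulative_share: tuple
    coverage_threshold: float
    source_set: str
    total_content: float

    @property
    def achieved_share(self) -> float:
        return self.cumulative_share[-1] if self.cumulative_share else 0.0

    def __len__(self) -> int:
        return len(self.selected)


def select_characteristic(
    content: pd.Series,
    coverage: float = 0.90,
    source_set: str = "positive",
) -> CharacteristicSet:
    """Smallest content-ranked prefix covering ``coverage`` of total content.

    Parameters
    ----------
    content
        Per-compound content (mean imputed intensity over all samples),
        indexed by metabolite id, restricted to one signed set.
    coverage
        Required cumulative content share, in (0, 1].

    An empty input yields an empty result rather than an error.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    if len(content) == 0:
        return CharacteristicSet((), (), coverage, source_set, 0.0)
    if (content < 0).any():
        raise ValueError("content must be non-negative")
    df = content.rename("content").rename_axis("metabolite_id").reset_index()
    df["metabolite_id"] = df["metabolite_id"].astype(str)
    df = df.sort_values(["content", "metabolite_id"], ascending=[False, True])
    total = float(df["content"].sum())
    if total == 0.0:
        # all-zero content: coverage unattainable; return everything
        ids = tuple(df["metabolite_id"])
        return CharacteristicSet(ids, (0.0,) * len(ids), coverage, source_set, 0.0)
    share = np.cumsum(df["content"].to_numpy()) / total
    k = int(np.searchsorted(share, coverage - 1e-12)) + 1
    k = min(k, len(df))
    return CharacteristicSet(
        selected=tuple(df["metabolite_id"].iloc[:k]),
        cumulative_share=tuple(share[:k]),
        coverage_threshold=coverage,
        source_set=source_set,
        total_content=total,
    )


def classify_trend(
    group_means,
    replicate_values=None,
    alpha: float = 0.05,
    rel_tol: float = 1e-9,
) -> tuple[TrendPattern, bool]:
    """Classify the shape of three ordered group means.

    UP: m1 < m2 < m3; DOWN: m1 > m2 > m3; UP_DOWN: middle above both ends;
    DOWN_UP: middle below both ends; FLAT on any tie (within ``rel_tol``
    relative tolerance). ``significant`` is a one-way ANOVA across groups on
    ``replicate_values`` (list of per-group arrays) at ``alpha``; the pattern
    label is assigned regardless of significance.
    """
    means = [float(v) for v in group_means]
    if len(means) != 3:
        raise ValueError(f"exactly 3 ordered groups required, got {len(means)}")
    m1, m2, m3 = means

    def close(a, b):
        return math.isclose(a, b, rel_tol=rel_tol, abs_tol=0.0)

    if close(m1, m2) or close(m2, m3) or close(m1, m3):
        pattern = TrendPattern.FLAT
    elif m1 < m2 < m3:
        pattern = TrendPattern.UP
    elif m1 > m2 > m3:
        pattern = TrendPattern.DOWN
    elif m2 > m1 and m2 > m3:
        pattern = TrendPattern.UP_DOWN
    else:
        pattern = TrendPattern.DOWN_UP

    significant = False
    if replicate_values is not None:
        arrays = [np.asarray(v, dtype=float) for v in replicate_values]
        if (
            len(arrays) == 3
            and all(a.size > 1 for a in arrays)
            and np.ptp(np.concatenate(arrays)) > 0.0
        ):
            with np.errstate(invalid="ignore", divide="ignore"):
                p = stats.f_oneway(*arrays).pvalue
            significant = bool(p < alpha) if np.isfinite(p) else False
    return pattern, significant


def aggregate_by_category(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    meta: pd.DataFrame,
    level: str = "superclass",
    alpha: float = 0.05,
    impute_mode: str = "half-min",
    drop_unannotated: bool = False,
) -> pd.DataFrame:
    """Per-category content across groups with a trend label per category.

    Category content per sample is the sum of member intensities (imputed);
    per-group values are means over replicates. Returns one row per category,
    sorted by label: category, n_members, mean content per group, trend,
    significant.
    """
    if level not in ("superclass", "class"):
        raise ValueError(f"level must be 'superclass' or 'class', got {level!r}")
    ann = annotations.set_index("metabolite_id")[level]
    unannotated = matrix.index.difference(ann.index)
    if len(unannotated):
        if not drop_unannotated:
            raise ValueError(f"unannotated features: {list(unannotated[:5])}...")
        matrix = matrix.loc[matrix.index.intersection(ann.index)]
    filled = impute(matrix, impute_mode)
    labels = ann.reindex(filled.index)
    per_cat = filled.groupby(labels, observed=True).sum()  # category x sample
    groups = _group_map(meta)

    rows = []
    for cat in sorted(map(str, per_cat.index)):
        sample_vals = per_cat.loc[cat]
        reps = [sample_vals[ids].to_numpy() for ids in groups.values()]
        means = [r.mean() for r in reps]
        pattern, significant = classify_trend(means, reps, alpha=alpha)
        row = {"category": cat, "n_members": int((labels == cat).sum())}
        for g, m in zip(groups, means):
            row[f"mean_{g}"] = m
        row["trend"] = pattern.value
        row["significant"] = significant
        rows.append(row)
    return pd.DataFrame(rows)


def characteristic_report(
    pos_set: CharacteristicSet,
    neg_set: CharacteristicSet,
    annotations: pd.DataFrame,
    matrix: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    alpha: float = 0.05,
    impute_mode: str = "half-min",
) -> dict:
    """Merge the positive- and negative-derived characteristic sets.

    Returns the annotated union table grouped by class, the number of
    distinct classes, and — when the matrix and metadata are supplied —
    per-class trend labels with counts of upward vs downward classes.
    Overlapping sets violate the upstream disjoint partition and raise.
    """
    overlap = set(pos_set.selected) & set(neg_set.selected)
    if overlap:
        raise ValueError(f"characteristic sets overlap: {sorted(overlap)[:5]}")
    rows = [(m, "positive") for m in pos_set.selected] + [
        (m, "negative") for m in neg_set.selected
    ]
    table = pd.DataFrame(rows, columns=["metabolite_id", "source_set"])
    ann = annotations.set_index("metabolite_id")[["name", "superclass", "class"]]
    table = table.join(ann, on="metabolite_id").sort_values(
        ["class", "metabolite_id"]
    ).reset_index(drop=True)

    out = {
        "table": table,
        "n_compounds": len(table),
        "n_categories": int(table["class"].nunique()),
    }
    if matrix is not None and meta is not None and len(table):
        sub = matrix.loc[matrix.index.intersection(table["metabolite_id"])]
        trends = aggregate_by_category(
            sub,
            annotations,
            meta,
            level="class",
            alpha=alpha,
            impute_mode=impute_mode,
        )
        out["category_trends"] = trends
        out["n_categories_up"] = int((trends["trend"] == "UP").sum())
        out["n_categories_down"] = int((trends["trend"] == "DOWN").sum())
    return out
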