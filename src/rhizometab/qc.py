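"""Feature-table quality control: missing-rate filtering, detection sets,
imputation and content totals.

The filter mirrors common untargeted-LC-MS practice: a peak is dropped when
its within-group missing ("deletion") rate exceeds 50%. By default a feature
is removed only when it exceeds the threshold in *every* group — a peak
reliably present in any one group is kept; ``any_group=True`` applies the
stricter reading (drop if any group exceeds the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DetectionSummary",
    "filter_by_missing_rate",
    "detection_summary",
    "impute",
    "content_totals",
]

VENN_REGIONS_3 = (
    ("P1",),
    ("P2",),
    ("P3",),
    ("P1", "P2"),
    ("P1", "P3"),
    ("P2", "P3"),
    ("P1", "P2", "P3"),
)


def _group_map(meta: pd.DataFrame) -> dict[str, list[str]]:
    """group label -> ordered list of sample ids."""
    out: dict[str, list[str]] = {}
    for g in meta["group_id"].cat.categories:
        out[str(g)] = meta.loc[meta["group_id"] == g, "sample_id"].tolist()
    return out


def filter_by_missing_rate(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float = 0.5,
    any_group: bool = False,
) -> pd.DataFrame:
    """Drop features whose within-group missing rate exceeds ``threshold``.

    A feature is removed iff its missing fraction is strictly greater than
    ``threshold`` in every group (or in at least one group when
    ``any_group``). Exactly-at-threshold features are retained. Idempotent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    groups = _group_map(meta)
    missing = {str(s) for s in matrix.columns} - {s for ids in groups.values() for s in ids}
    if missing:
        raise ValueError(f"samples without group assignment: {sorted(missing)}")
    rates = pd.DataFrame(
        {g: matrix[ids].isna().mean(axis=1) for g, ids in groups.items()}
    )
    exceeds = rates > threshold
    drop = exceeds.any(axis=1) if any_group else exceeds.all(axis=1)
    return matrix.loc[~drop]


@dataclass(frozen=True)
class DetectionSummary:
    """Per-group detection sets and the 3-set Venn decomposition.

    ``min_shared_percent`` divides the shared count by the *largest*
    per-group count — the most conservative of the possible percentages.
    """

    detected: dict
    region_counts: dict
    per_group_counts: dict
    shared_count: int
    min_shared_percent: float


def detection_summary(
    matrix: pd.DataFrame, meta: pd.DataFrame, min_detect: int = 1
) -> DetectionSummary:
    """Detection sets per group and all Venn regions.

    A feature is detected in a group when observed (non-missing) in at least
    ``min_detect`` of that group's replicates.
    """
    groups = _group_map(meta)
    detected = {
        g: set(matrix.index[(~matrix[ids].isna()).sum(axis=1) >= min_detect])
        for g, ids in groups.items()
    }
    labels = list(detected)
    region_counts: dict[tuple, int] = {}
    for k in range(1, len(labels) + 1):
        for members in combinations(labels, k):
            inside = set(matrix.index)
            for g in members:
                inside &= detected[g]
            for g in labels:
                if g not in members:
                    inside -= detected[g]
            region_counts[members] = len(inside)
    shared = set(matrix.index)
    for g in labels:
        shared &= detected[g]
    per_group = {g: len(s) for g, s in detected.items()}
    denom = max(per_group.values()) if per_group else 0
    pct = 100.0 * len(shared) / denom if denom else 0.0
    return DetectionSummary(
        detected=detected,
        region_counts=region_counts,
        per_group_counts=per_group,
        shared_count=len(shared),
        min_shared_percent=pct,
    )


def impute(matrix: pd.DataFrame, mode: str = "half-min") -> pd.DataFrame:
    """Fill missing cells.

    "half-min" replaces missing cells of each feature with half of that
    feature's minimum observed value (rows with no observed value fall back
    to half the global minimum); "zero" fills with 0; "none" returns the
    matrix unchanged.
    """
    if mode == "none":
        return matrix
    if mode == "zero":
        return matrix.fillna(0.0)
    if mode != "half-min":
        raise ValueError(f"unknown imputation mode {mode!r}")
    row_min = matrix.min(axis=1, skipna=True)
    global_min = np.nanmin(matrix.to_numpy()) if matrix.size else 0.0
    fill = (row_min.fillna(global_min) / 2.0).to_numpy()[:, None]
    values = matrix.to_numpy(dtype=float, copy=True)
    mask = np.isnan(values)
    values[mask] = np.broadcast_to(fill, values.shape)[mask]
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def content_totals(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    impute_mode: str = "half-min",
) -> dict:
    """Per-sample total content and per-group mean ± sd, with a one-way test.

    "Content" is the sum of (imputed) peak areas per sample; no normalization
    by sample mass is applied, so totals are relative. The one-way ANOVA
    p-value across groups supports the increasing-total-content claim.
    """
    filled = impute(matrix, impute_mode)
    per_sample = filled.sum(axis=0)
    groups = _group_map(meta)
    by_group = {g: per_sample[ids].to_numpy() for g, ids in groups.items()}
    group_stats = pd.DataFrame(
        {
            "group_id": list(by_group),
            "mean_total": [v.mean() if v.size else np.nan for v in by_group.values()],
            "sd_total": [v.std(ddof=1) if v.size > 1 else np.nan for v in by_group.values()],
            "n": [v.size for v in by_group.values()],
        }
    )
    arrays = [v for v in by_group.values() if v.size]
    if len(arrays) >= 2 and all(v.size > 1 for v in arrays) and len(matrix):
        anova_p = float(stats.f_oneway(*arrays).pvalue)
    else:
        anova_p = float("nan")
    return {
        "per_sample": per_sample,
        "per_group": group_stats,
        "anova_p": anova_p,
    }
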