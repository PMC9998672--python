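"""End-to-end orchestration: QC -> totals -> screen -> network ->
characteristic selection -> trends -> PCA, with a machine-readable report.

The report is deterministic for fixed inputs and configuration: keys are
sorted, floats serialized verbatim, and the configuration (plus its hash)
embedded, so identical reruns produce byte-identical ``report.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .features import aggregate_by_category, characteristic_report, select_characteristic
from .qc import content_totals, detection_summary, filter_by_missing_rate, impute
from .screen import build_network, correlate_all, partition_significant
from .soil_indices import index_correlation_matrix
from .synthetic import read_dataset

__all__ = ["PipelineConfig", "pca_scores", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run; serialized verbatim into the report."""

    data_dir: str
    out_dir: str
    alpha: float = 0.05
    coverage: float = 0.90
    method: str = "pearson"
    correction: str = "none"
    impute_mode: str = "half-min"
    missing_threshold: float = 0.5
    any_group: bool = False
    require: str = "any"
    anchor: str = "majority"
    pca_log: bool = True
    pca_scale: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def pca_scores(
    matrix: pd.DataFrame,
    log: bool = True,
    scale: bool = False,
    impute_mode: str = "half-min",
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample ordination by PCA of the feature matrix.

    Samples are rows of the decomposed table (features are variables).
    Defaults: half-min imputation, log(x+1) transform, feature centering;
    ``scale`` adds unit feature scaling. Returns per-sample scores and the
    explained-variance fractions (non-increasing, summing to <= 1).
    """
    filled = impute(matrix, impute_mode)
    X = filled.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if log:
        X = np.log1p(X)
    if np.ptp(X) == 0.0:
        raise ValueError("degenerate input: matrix is constant")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd == 0.0, 1.0, sd)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on the dataset under ``cfg.data_dir``.

    Writes all stage tables plus ``report.json`` into ``cfg.out_dir`` and
    returns the report dict. Reruns with identical inputs and configuration
    are byte-identical.
    """
    data = read_dataset(cfg.data_dir)
    matrix, meta, annotations, indexes = (
        data["matrix"],
        data["samples"],
        data["annotations"],
        data["indexes"],
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # QC
    filtered = filter_by_missing_rate(
        matrix, meta, threshold=cfg.missing_threshold, any_group=cfg.any_group
    )
    detect = detection_summary(filtered, meta)
    totals = content_totals(filtered, meta, impute_mode=cfg.impute_mode)
    filled = impute(filtered, cfg.impute_mode)

    # index-index correlations
    idx_corr = index_correlation_matrix(indexes, method=cfg.method)
    idx_corr.to_long().to_csv(out / "index_corr.tsv", sep="\t", index=False)

    # screen + partition + network
    records = correlate_all(
        indexes, filled, method=cfg.method, alpha=cfg.alpha, correction=cfg.correction
    )
    records.to_csv(out / "screen.tsv", sep="\t", index=False)
    screen = partition_significant(records, require=cfg.require, anchor=cfg.anchor)
    screen.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
    build_network(
        screen,
        annotations,
        graphml_path=out / "network.graphml",
        sif_path=out / "network.sif",
    )

    # characteristic selection on each signed set
    content = filled.mean(axis=1)
    pos_sel = select_characteristic(
        content.loc[content.index.intersection(screen.positive_set)],
        coverage=cfg.coverage,
        source_set="positive",
    )
    neg_sel = select_characteristic(
        content.loc[content.index.intersection(screen.negative_set)],
        coverage=cfg.coverage,
        source_set="negative",
    )
    for sel, name in ((pos_sel, "characteristic_pos"), (neg_sel, "characteristic_neg")):
        pd.DataFrame(
            {"metabolite_id": sel.selected, "cumulative_share": sel.cumulative_share}
        ).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    report_chars = characteristic_report(
        pos_sel, neg_sel, annotations, matrix=filled, meta=meta, alpha=cfg.alpha
    )
    report_chars["table"].to_csv(out / "characteristic_merged.tsv", sep="\t", index=False)

    # category trends at both taxonomy levels
    trend_counts = {}
    for level in ("superclass", "class"):
        cat = aggregate_by_category(
            filled, annotations, meta, level=level, alpha=cfg.alpha, impute_mode="none"
        )
        cat.to_csv(out / f"category_trends_{level}.tsv", sep="\t", index=False)
        trend_counts[level] = {
            "n_categories": int(len(cat)),
            **{t: int((cat["trend"] == t).sum()) for t in ("UP", "DOWN", "UP_DOWN", "DOWN_UP", "FLAT")},
        }

    # ordination
    scores, evr = pca_scores(filtered, log=cfg.pca_log, scale=cfg.pca_scale, impute_mode=cfg.impute_mode)
    scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")

    totals["per_sample"].rename("total").to_csv(out / "totals.tsv", sep="\t")
    venn = pd.DataFrame(
        {"region": ["&".join(k) for k in detect.region_counts], "count": list(detect.region_counts.values())}
    )
    venn.to_csv(out / "venn.tsv", sep="\t", index=False)

    report = {
        "provenance": {
            "config": cfg.to_dict(),
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "version": __version__,
        },
        "detection": {
            "per_group_counts": detect.per_group_counts,
            "shared_count": detect.shared_count,
            "min_shared_percent": detect.min_shared_percent,
            "n_features_input": int(len(matrix)),
            "n_features_filtered": int(len(filtered)),
        },
        "totals": {
            "per_group_mean": {
                str(g): float(m)
                for g, m in zip(totals["per_group"]["group_id"], totals["per_group"]["mean_total"])
            },
            "anova_p": totals["anova_p"],
        },
        "screen": {
            "alpha": cfg.alpha,
            "n_significant": screen.n_significant,
            "n_positive": len(screen.positive_set),
            "n_negative": len(screen.negative_set),
            "n_conflicted": len(screen.conflicted_set),
        },
        "characteristic": {
            "n_positive_selected": len(pos_sel),
            "n_negative_selected": len(neg_sel),
            "n_total": report_chars["n_compounds"],
            "n_categories": report_chars["n_categories"],
            "n_categories_up": report_chars.get("n_categories_up"),
            "n_categories_down": report_chars.get("n_categories_down"),
            "positive_share": pos_sel.achieved_share,
            "negative_share": neg_sel.achieved_share,
        },
        "category_trends": trend_counts,
        "pca": {"explained_variance_ratio": [float(v) for v in evr]},
    }
    report = _jsonable(report)
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return report
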