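"""Seeded synthetic datasets emulating a 3-level soil-pH gradient study.

The generator reproduces the statistical structure the downstream analysis
assumes: three pH groups (P1 < P2 < P3) with three replicates each, nine
physicochemical/microbial soil indexes whose group means follow the gradient
(all increasing with pH except the fungal count, which decreases), and an
untargeted LC-MS style metabolite matrix with log-normal intensities, planted
signed pH associations, a two-level chemical taxonomy and missing cells.

Every random draw is derived from a single master seed through
``numpy.random.SeedSequence`` substreams, so identical configurations produce
identical tables (and identical bytes on disk via :func:`write_dataset`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "INDEX_COLUMNS",
    "DEFAULT_PH_ANCHORS",
    "DEFAULT_INDEX_ANCHORS",
    "DEFAULT_TAXONOMY",
    "SimConfig",
    "GroundTruth",
    "make_sample_meta",
    "generate_index_table",
    "generate_metabolome",
    "write_dataset",
    "read_dataset",
]

#: Ordered pH groups, lowest pH first.
GROUPS = ("P1", "P2", "P3")

#: The nine soil/microbial index columns, in reporting order.
INDEX_COLUMNS = (
    "ph",
    "organic_matter",
    "cec",
    "mbc",
    "mbn",
    "respiration",
    "bacteria",
    "fungi",
    "actinomyces",
)

#: Group-mean pH of the three plantations (strongly acidified -> suitable).
DEFAULT_PH_ANCHORS = (3.29, 4.74, 5.32)

#: (value at lowest pH, value at highest pH) for each remaining index.
#: All increase with pH except the fungal count, which decreases.
DEFAULT_INDEX_ANCHORS = {
    "organic_matter": (8.32, 17.96),  # g/kg
    "cec": (7.26, 22.48),  # mmol/kg
    "mbc": (131.25, 218.52),  # mg/kg
    "mbn": (42.37, 78.49),  # mg/kg
    "respiration": (7.16, 18.25),  # mg CO2/kg.h
    "bacteria": (7.65, 15.42),  # 1e9 cells/g
    "fungi": (7.43, 2.48),  # 1e9 cells/g, decreasing
    "actinomyces": (2.65, 7.52),  # 1e9 cells/g
}

#: Two-level chemical taxonomy: 11 superclasses containing 60 classes total.
DEFAULT_TAXONOMY = {
    "Benzenoids": [
        "Benzene and substituted derivatives",
        "Naphthalenes",
        "Phenols",
        "Anthracenes",
        "Indanes",
        "Anilides",
    ],
    "Lipids and lipid-like molecules": [
        "Fatty acyls",
        "Prenol lipids",
        "Steroids and steroid derivatives",
        "Glycerolipids",
        "Glycerophospholipids",
        "Sphingolipids",
        "Saccharolipids",
    ],
    "Organic acids and derivatives": [
        "Carboxylic acids and derivatives",
        "Hydroxy acids and derivatives",
        "Keto acids and derivatives",
        "Organic sulfonic acids and derivatives",
        "Peptidomimetics",
        "Vinylogous acids",
    ],
    "Organic nitrogen compounds": [
        "Organonitrogen compounds",
        "Amines",
        "Quaternary ammonium salts",
        "Imines",
    ],
    "Organic oxygen compounds": [
        "Organooxygen compounds",
        "Carbohydrates and carbohydrate conjugates",
        "Alcohols and polyols",
        "Carbonyl compounds",
        "Ethers",
    ],
    "Organoheterocyclic compounds": [
        "Azoles",
        "Diazines",
        "Piperidines",
        "Pyridines and derivatives",
        "Lactams",
        "Azolidines",
        "Diazinanes",
        "Benzothiazoles",
        "Imidazopyrimidines",
        "Quinolines and derivatives",
        "Furans",
        "Pyrroles",
        "Indoles and derivatives",
    ],
    "Organohalogen compounds": [
        "Aryl halides",
        "Alkyl halides",
        "Organofluorides",
    ],
    "Organosulfur compounds": [
        "Thioethers",
        "Sulfoxides",
        "Thiols",
        "Sulfones",
    ],
    "Nucleosides, nucleotides, and analogues": [
        "Purine nucleotides",
        "Pyrimidine nucleotides",
        "Purine nucleosides",
        "Pyrimidine nucleosides",
    ],
    "Phenylpropanoids and polyketides": [
        "Flavonoids",
        "Coumarins and derivatives",
        "Cinnamic acids and derivatives",
        "Isoflavonoids",
    ],
    "Hydrocarbons": [
        "Saturated hydrocarbons",
        "Unsaturated hydrocarbons",
        "Cyclic hydrocarbons",
        "Polycyclic hydrocarbons",
    ],
}


class InvalidConfigError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study.

    Parameters
    ----------
    seed
        Master seed; every table derives its own substream from it.
    n_groups, n_reps
        Design size. The pH-gradient study is 3 groups x 3 replicates.
    n_metabolites
        Number of metabolite features to simulate.
    n_pos, n_neg
        Number of features planted with a positive / negative association
        with pH (on the log-intensity scale). The remainder are null.
    effect_size
        Planted log-intensity slope per pH unit (unitless on the log scale).
    noise_sd
        Replicate noise s.d. on the log-intensity scale.
    missing_rate
        Fraction of cells removed. ``missing_mode`` "mcar" removes cells
        completely at random; "censor" removes the globally lowest
        intensities, emulating limit-of-detection dropout.
    index_noise_frac
        Replicate noise s.d. for each soil index, as a fraction of that
        index's anchor range.
    ph_anchors
        Group-mean pH values, strictly increasing, one per group.
    index_anchors
        Mapping index name -> (value at first group, value at last group);
        intermediate groups are interpolated linearly along the pH anchors.
    taxonomy
        Superclass -> list-of-classes vocabulary for feature annotation.
    """

    seed: int = 0
    n_groups: int = 3
    n_reps: int = 3
    n_metabolites: int = 2370
    n_pos: int = 55
    n_neg: int = 166
    effect_size: float = 0.8
    noise_sd: float = 0.4
    missing_rate: float = 0.05
    missing_mode: str = "mcar"
    index_noise_frac: float = 0.05
    ph_anchors: tuple = DEFAULT_PH_ANCHORS
    index_anchors: dict = field(default_factory=lambda: dict(DEFAULT_INDEX_ANCHORS))
    taxonomy: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TAXONOMY.items()})

    def __post_init__(self):
        if len(self.ph_anchors) != self.n_groups:
            raise InvalidConfigError(
                f"need {self.n_groups} pH anchors, got {len(self.ph_anchors)}"
            )
        if not all(a < b for a, b in zip(self.ph_anchors, self.ph_anchors[1:])):
            raise InvalidConfigError("ph_anchors must be strictly increasing")
        if self.n_pos + self.n_neg > self.n_metabolites:
            raise InvalidConfigError("n_pos + n_neg exceeds n_metabolites")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1]")
        if self.missing_mode not in ("mcar", "censor"):
            raise InvalidConfigError(f"unknown missing_mode {self.missing_mode!r}")

    def group_labels(self) -> list[str]:
        if self.n_groups == len(GROUPS):
            return list(GROUPS)
        return [f"P{i + 1}" for i in range(self.n_groups)]

    def _streams(self) -> dict[str, np.random.Generator]:
        """Named substreams of the master seed, in a fixed order."""
        names = ("indexes", "baseline", "noise", "missing", "taxonomy")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass(frozen=True)
class GroundTruth:
    """Planted association sets; a disjoint partition of all feature ids."""

    planted_positive: frozenset
    planted_negative: frozenset
    null_set: frozenset
    effect_size: float
    noise_sd: float

    def label(self, metabolite_id: str) -> str:
        if metabolite_id in self.planted_positive:
            return "positive"
        if metabolite_id in self.planted_negative:
            return "negative"
        return "null"

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            [(m, "positive") for m in self.planted_positive]
            + [(m, "negative") for m in self.planted_negative]
            + [(m, "null") for m in self.null_set]
        )
        return pd.DataFrame(rows, columns=["metabolite_id", "truth"])


def make_sample_meta(cfg: SimConfig) -> pd.DataFrame:
    """Sample metadata: one row per (group, replicate), ordered by group."""
    rows = [
        {"sample_id": f"{g}_{r}", "group_id": g, "replicate": r}
        for g in cfg.group_labels()
        for r in range(1, cfg.n_reps + 1)
    ]
    meta = pd.DataFrame(rows)
    meta["group_id"] = pd.Categorical(meta["group_id"], categories=cfg.group_labels(), ordered=True)
    return meta


def generate_index_table(cfg: SimConfig) -> pd.DataFrame:
    """Per-sample physicochemical and microbial index table.

    Group means interpolate each index's (low-pH, high-pH) anchors linearly
    along the pH anchors, so on noiseless data every index is an exact affine
    function of group pH — increasing for all indexes except fungi.
    Gaussian replicate noise with s.d. ``index_noise_frac * |range|`` is added
    around the group means.
    """
    rng = cfg._streams()["indexes"]
    meta = make_sample_meta(cfg)
    ph = np.asarray(cfg.ph_anchors, dtype=float)
    frac = (ph - ph[0]) / (ph[-1] - ph[0])  # position of each group along the gradient

    group_means = {"ph": ph}
    for name, (lo, hi) in cfg.index_anchors.items():
        group_means[name] = lo + frac * (hi - lo)

    table = meta.copy()
    gidx = meta["group_id"].cat.codes.to_numpy()
    for name in INDEX_COLUMNS:
        if name == "ph":
            lo, hi = ph[0], ph[-1]
        else:
            lo, hi = cfg.index_anchors[name]
        sd = cfg.index_noise_frac * abs(hi - lo)
        vals = group_means[name][gidx] + rng.normal(0.0, sd, size=len(meta))
        table[name] = np.maximum(vals, 0.0)
    return table.set_index("sample_id")


def generate_metabolome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Metabolite intensity matrix, feature annotations and planted truth.

    Returns
    -------
    matrix
        ``n_metabolites x (n_groups * n_reps)`` DataFrame of non-negative
        peak areas (NaN = missing), rows indexed by metabolite id, columns by
        sample id in metadata order.
    annotations
        One row per feature: metabolite_id, name, superclass, class.
    truth
        The planted positive/negative/null partition.

    The intensity model is log-normal: each feature has a baseline log-mean
    drawn once, planted features add ``±effect_size * (pH_g − mean pH)`` on
    the log scale, and replicate noise is Gaussian on the log scale. Planted
    group means are therefore exactly monotone in group pH in the noiseless
    limit, and raw intensities are heavy-tailed.
    """
    streams = cfg._streams()
    meta = make_sample_meta(cfg)
    ids = np.array([f"M{i + 1:05d}" for i in range(cfg.n_metabolites)])

    # signed slope per feature: first n_pos positive, next n_neg negative
    beta = np.zeros(cfg.n_metabolites)
    beta[: cfg.n_pos] = cfg.effect_size
    beta[cfg.n_pos : cfg.n_pos + cfg.n_neg] = -cfg.effect_size

    ph = np.asarray(cfg.ph_anchors, dtype=float)
    ph_c = ph - ph.mean()
    gidx = meta["group_id"].cat.codes.to_numpy()

    mu = streams["baseline"].normal(np.log(1e5), 1.5, size=cfg.n_metabolites)
    log_int = (
        mu[:, None]
        + beta[:, None] * ph_c[gidx][None, :]
        + streams["noise"].normal(0.0, cfg.noise_sd, size=(cfg.n_metabolites, len(meta)))
    )
    values = np.exp(log_int)

    if cfg.missing_rate > 0:
        if cfg.missing_mode == "mcar":
            mask = streams["missing"].random(values.shape) < cfg.missing_rate
        else:  # censor: drop the globally lowest intensities
            cutoff = np.quantile(values, cfg.missing_rate)
            mask = values <= cutoff
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(ids, name="metabolite_id"), columns=meta["sample_id"])

    # uniform taxonomy assignment over the class vocabulary
    pairs = [(sc, cl) for sc, classes in cfg.taxonomy.items() for cl in classes]
    choice = streams["taxonomy"].integers(0, len(pairs), size=cfg.n_metabolites)
    annotations = pd.DataFrame(
        {
            "metabolite_id": ids,
            "name": [f"Compound_{i + 1:05d}" for i in range(cfg.n_metabolites)],
            "superclass": [pairs[c][0] for c in choice],
            "class": [pairs[c][1] for c in choice],
        }
    )

    truth = GroundTruth(
        planted_positive=frozenset(ids[: cfg.n_pos]),
        planted_negative=frozenset(ids[cfg.n_pos : cfg.n_pos + cfg.n_neg]),
        null_set=frozenset(ids[cfg.n_pos + cfg.n_neg :]),
        effect_size=cfg.effect_size,
        noise_sd=cfg.noise_sd,
    )
    return matrix, annotations, truth


def write_dataset(
    directory: str | Path,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    annotations: pd.DataFrame,
    index_table: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write all study tables as TSV; returns the written paths.

    Missing matrix cells are written as empty fields. Round-trips losslessly
    through :func:`read_dataset` (float values to full repr precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "samples": directory / "samples.tsv",
        "annotations": directory / "annotations.tsv",
        "indexes": directory / "indexes.tsv",
    }
    matrix.to_csv(paths["matrix"], sep="\t", na_rep="", float_format="%.17g")
    meta.to_csv(paths["samples"], sep="\t", index=False)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    index_table.to_csv(paths["indexes"], sep="\t", float_format="%.17g")
    if truth is not None:
        paths["truth"] = directory / "truth.tsv"
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_dataset(directory: str | Path) -> dict:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    matrix = pd.read_csv(directory / "matrix.tsv", sep="\t", index_col="metabolite_id")
    meta = pd.read_csv(directory / "samples.tsv", sep="\t")
    groups = sorted(meta["group_id"].unique())
    meta["group_id"] = pd.Categorical(meta["group_id"], categories=groups, ordered=True)
    indexes = pd.read_csv(directory / "indexes.tsv", sep="\t", index_col="sample_id")
    if "group_id" in indexes.columns:
        indexes["group_id"] = pd.Categorical(indexes["group_id"], categories=groups, ordered=True)
    out = {
        "matrix": matrix,
        "samples": meta,
        "annotations": pd.read_csv(directory / "annotations.tsv", sep="\t"),
        "indexes": indexes,
    }
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        # keep_default_na: the literal label "null" must not parse as NaN
        df = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
        out["truth"] = GroundTruth(
            planted_positive=frozenset(df.loc[df["truth"] == "positive", "metabolite_id"]),
            planted_negative=frozenset(df.loc[df["truth"] == "negative", "metabolite_id"]),
            null_set=frozenset(df.loc[df["truth"] == "null", "metabolite_id"]),
            effect_size=float("nan"),
            noise_sd=float("nan"),
        )
    return out
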