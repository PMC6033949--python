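"""Logistic non-essentiality classification of genes from insertion features.

Each gene is described by two features — the Gene Insertion Index (GII) and
the read density — standardized against a labelled training set of known
essential and non-essential genes.  An L2-regularized logistic regression
(C = 10) maps the standardized features (x1 = GII, x2 = read density) to the
non-essentiality probability

    NEP = 1 / (1 + exp(-(b1*x1 + b2*x2 + b0))),

with NEP near 0 meaning essential and near 1 non-essential.  The model fitted
on the original glucose-grown Pichia pastoris libraries, b1 = 5.737,
b2 = 0.082, b0 = 2.098, ships as a built-in so classification can run without
retraining.  Genes are then assigned to four categories:

    NEP < 0.03            putatively essential
    0.03 <= NEP < 0.5     ambig1  (growth-advantageous / condition-essential)
    0.5  <= NEP <= 0.9    ambig2  (uncertain, includes small genes)
    NEP > 0.9             putatively non-essential

Genes with fewer than 15 TA sites carry too little signal and are excluded,
as is the transposon's selection-marker gene (HIS4 in the original screen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .stats import GeneInsertionStats

__all__ = [
    "LogisticModel",
    "TrainingSet",
    "EssentialityRecord",
    "published_model",
    "standardize",
    "train_model",
    "nep",
    "categorize",
    "classify",
    "validate_against_labels",
    "category_counts",
    "records_frame",
    "CATEGORIES",
]

PUBLISHED_BETA_GII = 5.737
PUBLISHED_BETA_DENSITY = 0.082
PUBLISHED_INTERCEPT = 2.098

CATEGORIES = (
    "putatively_essential",
    "ambig1",
    "ambig2",
    "putatively_non_essential",
)

LABEL_NON_ESSENTIAL = "non_essential"
LABEL_ESSENTIAL = "essential"


@dataclass
class LogisticModel:
    """Two-feature logistic model with its standardization parameters."""

    beta_gii: float
    beta_density: float
    intercept: float
    feature_means: tuple[float, float] | None = None
    feature_sds: tuple[float, float] | None = None
    published: bool = False

    def __post_init__(self) -> None:
        for v in (self.beta_gii, self.beta_density, self.intercept):
            if not np.isfinite(v):
                raise ValueError("model coefficients must be finite")
        if self.feature_sds is not None and any(s <= 0 for s in self.feature_sds):
            raise ValueError("feature standard deviations must be positive")

    def to_json(self, path: str) -> None:
        with open(path, "w") as out:
            json.dump(
                {
                    "beta_gii": self.beta_gii,
                    "beta_density": self.beta_density,
                    "intercept": self.intercept,
                    "feature_means": self.feature_means,
                    "feature_sds": self.feature_sds,
                    "published": self.published,
                },
                out,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "LogisticModel":
        with open(path) as handle:
            d = json.load(handle)
        means = tuple(d["feature_means"]) if d.get("feature_means") else None
        sds = tuple(d["feature_sds"]) if d.get("feature_sds") else None
        return cls(
            d["beta_gii"], d["beta_density"], d["intercept"], means, sds,
            bool(d.get("published", False)),
        )


def published_model(
    feature_means: tuple[float, float] | None = None,
    feature_sds: tuple[float, float] | None = None,
) -> LogisticModel:
    """The coefficients fitted on the original glucose Tn-seq training set.

    The original standardization parameters were not released, so they must
    be supplied (or computed from a labelled training set) before raw GII /
    read-density values can be scored; standardized (x1, x2) can be scored
    directly.
    """
    return LogisticModel(
        PUBLISHED_BETA_GII,
        PUBLISHED_BETA_DENSITY,
        PUBLISHED_INTERCEPT,
        feature_means,
        feature_sds,
        published=True,
    )


@dataclass
class TrainingSet:
    """Labelled (GII, read density) features; class 1 = non-essential."""

    gene_ids: list[str]
    features: np.ndarray  # (n, 2) raw [gii, read_density]
    labels: np.ndarray  # (n,) 1 = non_essential, 0 = essential

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape != (len(self.gene_ids), 2):
            raise ValueError("features must be (n_genes, 2)")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @classmethod
    def from_labels(
        cls, labels: dict[str, str], stats: list[GeneInsertionStats]
    ) -> "TrainingSet":
        """Join gene_id -> {essential, non_essential} labels to computed stats."""
        by_id = {s.gene_id: s for s in stats}
        gene_ids, feats, y = [], [], []
        for gene_id, label in labels.items():
            if label not in (LABEL_ESSENTIAL, LABEL_NON_ESSENTIAL):
                raise ValueError(f"unknown label {label!r} for {gene_id}")
            s = by_id.get(gene_id)
            if s is None or not s.defined:
                continue
            gene_ids.append(gene_id)
            feats.append([s.gii, s.read_density])
            y.append(1 if label == LABEL_NON_ESSENTIAL else 0)
        return cls(gene_ids, np.array(feats), np.array(y))

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            LABEL_ESSENTIAL: int((self.labels == 0).sum()),
            LABEL_NON_ESSENTIAL: int((self.labels == 1).sum()),
        }


@dataclass
class EssentialityRecord:
    gene_id: str
    gii: float
    read_density: float
    x1: float
    x2: float
    nep: float
    category: str
    exclusion_reason: str = "none"  # low_ta | marker_gene | undefined_features | none


def _training_standardization(training: TrainingSet) -> tuple[tuple, tuple]:
    means = training.features.mean(axis=0)
    sds = training.features.std(axis=0, ddof=0)
    for name, sd in zip(("gii", "read_density"), sds):
        if sd <= 0:
            raise ValueError(f"zero standard deviation in feature {name!r}")
    return tuple(means), tuple(sds)


def standardize(
    stats: list[GeneInsertionStats],
    model_or_training: LogisticModel | TrainingSet,
) -> dict[str, tuple[float, float]]:
    """Map raw (gii, read_density) to standardized (x1, x2) per gene.

    The means/sds come from the labelled training set (directly, or as stored
    on a trained model) and the same transform is applied genome-wide.
    """
    if isinstance(model_or_training, TrainingSet):
        means, sds = _training_standardization(model_or_training)
    else:
        if model_or_training.feature_means is None or model_or_training.feature_sds is None:
            raise ValueError("model carries no standardization parameters")
        means, sds = model_or_training.feature_means, model_or_training.feature_sds
    out = {}
    for s in stats:
        out[s.gene_id] = (
            (s.gii - means[0]) / sds[0],
            (s.read_density - means[1]) / sds[1],
        )
    return out


def train_model(
    training: TrainingSet,
    C: float = 10.0,
    test_fraction: float = 0.30,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[LogisticModel, list[float]]:
    """Fit the L2 logistic model with repeated held-out evaluation.

    Features are standardized with training-set means/sds; ``repeats``
    stratified splits (seeded seed, seed+1, ...) give per-repeat held-out
    accuracies; the returned model is refit on all data and carries the
    standardization parameters.
    """
    if len(training.gene_ids) < 10:
        raise ValueError("need at least 10 training genes")
    counts = training.class_counts
    if min(counts.values()) == 0:
        raise ValueError("both classes must be present")
    means, sds = _training_standardization(training)
    X = (training.features - np.array(means)) / np.array(sds)
    y = training.labels

    accuracies: list[float] = []
    for r in range(repeats):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=seed + r
        )
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
        clf.fit(X_tr, y_tr)
        if clf.n_iter_[0] >= 1000:
            raise RuntimeError(f"logistic fit did not converge (repeat {r})")
        accuracies.append(float(clf.score(X_te, y_te)))

    final = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    final.fit(X, y)
    model = LogisticModel(
        beta_gii=float(final.coef_[0, 0]),
        beta_density=float(final.coef_[0, 1]),
        intercept=float(final.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
    )
    return model, accuracies


def nep(model: LogisticModel, x1, x2):
    """Non-essentiality probability at standardized features (x1, x2).

    Numerically saturates to 0/1 at extreme arguments; strictly monotone in
    each feature for positive coefficients.
    """
    from scipy.special import expit

    z = (
        model.beta_gii * np.asarray(x1, dtype=float)
        + model.beta_density * np.asarray(x2, dtype=float)
        + model.intercept
    )
    out = expit(z)
    if np.ndim(out) == 0:
        return float(out)
    return out


def categorize(p: float, thresholds: tuple[float, float, float] = (0.03, 0.5, 0.9)) -> str:
    """Category for a NEP value: < t1 essential; [t1, t2) ambig1; [t2, t3]
    ambig2; > t3 non-essential (t2 and t3 land in ambig2 by convention)."""
    t1, t2, t3 = thresholds
    if not (0.0 < t1 < t2 < t3 < 1.0):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    if p < t1:
        return "putatively_essential"
    if p < t2:
        return "ambig1"
    if p <= t3:
        return "ambig2"
    return "putatively_non_essential"


def classify(
    stats: list[GeneInsertionStats],
    model: LogisticModel,
    thresholds: tuple[float, float, float] = (0.03, 0.5, 0.9),
    min_ta: int = 15,
    marker_genes: frozenset | set = frozenset(),
) -> list[EssentialityRecord]:
    """Assign every gene a category (or an exclusion reason).

    Boundary conventions: NEP < t1 essential; t1 <= NEP < t2 ambig1;
    t2 <= NEP <= t3 ambig2; NEP > t3 non-essential.  Genes with fewer than
    ``min_ta`` TA sites, marker genes, and genes with undefined features are
    excluded with a reason.  The result partitions the input genes.
    """
    t1, t2, t3 = thresholds
    if not (0.0 < t1 < t2 < t3 < 1.0):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    x = standardize([s for s in stats if s.defined], model)
    records: list[EssentialityRecord] = []
    for s in stats:
        if s.gene_id in marker_genes:
            records.append(
                EssentialityRecord(s.gene_id, s.gii, s.read_density,
                                   float("nan"), float("nan"), float("nan"),
                                   "excluded", "marker_gene")
            )
            continue
        if not s.defined:
            records.append(
                EssentialityRecord(s.gene_id, s.gii, s.read_density,
                                   float("nan"), float("nan"), float("nan"),
                                   "excluded", "undefined_features")
            )
            continue
        if s.ta_full < min_ta:
            records.append(
                EssentialityRecord(s.gene_id, s.gii, s.read_density,
                                   float("nan"), float("nan"), float("nan"),
                                   "excluded", "low_ta")
            )
            continue
        x1, x2 = x[s.gene_id]
        p = nep(model, x1, x2)
        records.append(
            EssentialityRecord(s.gene_id, s.gii, s.read_density, x1, x2, p,
                               categorize(p, thresholds))
        )
    return records


def category_counts(records: list[EssentialityRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES + ("excluded",)}
    for r in records:
        counts[r.category] += 1
    return counts


def validate_against_labels(
    records: list[EssentialityRecord], labels: dict[str, str]
) -> pd.DataFrame:
    """Cross-tabulate known labels against predicted categories."""
    by_id = {r.gene_id: r for r in records}
    rows = []
    for gene_id, label in labels.items():
        r = by_id.get(gene_id)
        if r is not None:
            rows.append({"label": label, "category": r.category})
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return pd.crosstab(df["label"], df["category"])


def records_frame(records: list[EssentialityRecord]) -> pd.DataFrame:
    """Tabular classification output (gene_id ... nep, category, reason)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "gii": [r.gii for r in records],
            "read_density": [r.read_density for r in records],
            "x1": [r.x1 for r in records],
            "x2": [r.x2 for r in records],
            "nep": [r.nep for r in records],
            "category": [r.category for r in records],
            "exclusion_reason": [r.exclusion_reason for r in records],
        }
    )
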