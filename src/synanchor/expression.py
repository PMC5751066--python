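"""Expression-stage analysis: sample QC, DE-set filtering and group assignment.

Differential-expression model fitting is out of scope — the stage consumes a
precomputed per-feature table (log2 fold change, p, adjusted p) and applies
the study thresholds (padj < 0.005 strictly, |log2FC| > 2 strictly),
partitioning significant features by direction.  QC works on
log2(count + 1)-transformed columns: Euclidean sample-to-sample distances, a
mean-distance z-score outlier rule, and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .formats_io import DERecord, ValidationError

__all__ = [
    "CountMatrix",
    "DEConfig",
    "DEPartition",
    "filter_de",
    "assign_de_to_groups",
    "sample_distance_matrix",
    "detect_outlier_samples",
    "pca_qc",
]


@dataclass
class CountMatrix:
    """A features x samples matrix of non-negative integer read counts."""

    features: list[str]
    samples: list[str]
    conditions: list[str]  # per-sample condition label, e.g. "A"/"B"
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} != "
                f"({len(self.features)}, {len(self.samples)})"
            )
        if len(self.conditions) != len(self.samples):
            raise ValidationError("one condition label per sample required")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    def log_transformed(self) -> np.ndarray:
        """log2(count + 1), the variance-compressing transform used for QC."""
        return np.log2(self.counts.astype(float) + 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    @classmethod
    def from_tsv(cls, path, conditions: list[str] | None = None) -> "CountMatrix":
        """Read a TSV with a feature-id first column; sample columns may be
        named ``name:condition`` when ``conditions`` is not given."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        samples = [str(c) for c in df.columns]
        if conditions is None:
            if not all(":" in s for s in samples):
                raise ValidationError(
                    "sample columns must be 'name:condition' when conditions not given"
                )
            names = [s.split(":")[0] for s in samples]
            conditions = [s.split(":", 1)[1] for s in samples]
            samples = names
        return cls(
            features=[str(i) for i in df.index],
            samples=samples,
            conditions=conditions,
            counts=df.to_numpy(),
        )


@dataclass(frozen=True)
class DEConfig:
    """Significance thresholds, both applied strictly."""

    alpha: float = 0.005
    min_abs_lfc: float = 2.0
    positive_direction_label: str = "A"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if self.min_abs_lfc < 0:
            raise ValidationError("min_abs_lfc must be >= 0")


@dataclass(frozen=True)
class DEPartition:
    """Significant features split by direction; positive log2FC -> ``up_in_a``."""

    up_in_a: frozenset[str]
    up_in_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.up_in_a & self.up_in_b:
            raise ValidationError("direction sets must be disjoint")

    @property
    def total_significant(self) -> int:
        return len(self.up_in_a) + len(self.up_in_b)

    @property
    def significant(self) -> frozenset[str]:
        return self.up_in_a | self.up_in_b


def filter_de(records: list[DERecord], cfg: DEConfig | None = None) -> DEPartition:
    """Apply the DE thresholds: significant iff padj present, padj < alpha
    and |log2FC| > min_abs_lfc (both strict).  The fold-change sign routes
    each feature to its direction set."""
    cfg = cfg or DEConfig()
    up_a: set[str] = set()
    up_b: set[str] = set()
    for r in records:
        if r.p_adjusted is None:
            continue
        if r.p_adjusted < cfg.alpha and abs(r.log2_fold_change) > cfg.min_abs_lfc:
            (up_a if r.log2_fold_change > 0 else up_b).add(r.feature_id)
    return DEPartition(up_in_a=frozenset(up_a), up_in_b=frozenset(up_b))


def assign_de_to_groups(
    partition: DEPartition, placements: dict[str, str]
) -> pd.DataFrame:
    """Count each direction set per in silico group.

    ``placements`` maps feature id -> group label (e.g. from
    ``map_transcripts_to_groups``).  Features without a placement land in the
    ``unplaced`` row; per-group totals plus the unplaced row sum to the
    partition total.
    """
    rows: dict[str, list[int]] = {}
    for fid in sorted(partition.up_in_a):
        g = placements.get(fid, "unplaced")
        rows.setdefault(g, [0, 0])[0] += 1
    for fid in sorted(partition.up_in_b):
        g = placements.get(fid, "unplaced")
        rows.setdefault(g, [0, 0])[1] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["up_in_a", "up_in_b"])
    df.index.name = "group"
    df["total"] = df["up_in_a"] + df["up_in_b"]
    return df.sort_index()


def sample_distance_matrix(m: CountMatrix) -> pd.DataFrame:
    """Euclidean sample-to-sample distances on log2(count+1) columns."""
    if len(m.samples) < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    d = squareform(pdist(m.log_transformed().T, metric="euclidean"))
    return pd.DataFrame(d, index=m.samples, columns=m.samples)


def detect_outlier_samples(d: pd.DataFrame, k: float = 2.0) -> list[str]:
    """Flag samples unusually far from the rest, by mean Euclidean distance.

    Sample i is flagged iff its mean distance to the other samples exceeds
    the grand mean of those per-sample means by more than ``k`` sample
    standard deviations.  Needs at least 3 samples for a dispersion estimate.
    """
    arr = np.asarray(d, dtype=float)
    n = arr.shape[0]
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValidationError("need >= 3 samples to estimate dispersion")
    means = arr.sum(axis=1) / (n - 1)
    cutoff = means.mean() + k * means.std(ddof=1)
    labels = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    return [labels[i] for i in range(n) if means[i] > cutoff]


@dataclass(frozen=True)
class PCAResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray


def pca_qc(m: CountMatrix) -> PCAResult:
    """Principal components of the centered log2(count+1) sample matrix.

    Variance fractions are non-increasing and sum to 1 over all components;
    a constant matrix yields all-zero scores with uniform fractions.
    """
    if len(m.samples) < 2:
        raise ValidationError("need >= 2 samples for PCA")
    x = m.log_transformed().T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0.0:
        k = len(s)
        fractions = np.full(k, 1.0 / k)
        scores = np.zeros((len(m.samples), k))
    else:
        fractions = var / total
        scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.samples, columns=cols),
        variance_fractions=fractions,
    )
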