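"""Alpha and beta diversity on count tables.

Alpha: observed richness S, Shannon entropy H (natural log by default) and
Pielou's evenness J = H / ln(S), reported as missing when S <= 1. Beta:
Jaccard distance on presence/absence and Bray-Curtis dissimilarity on counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd

from .table_ops import FeatureTable

logger = logging.getLogger(__name__)

METRICS = ("jaccard", "bray_curtis")


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy of a count vector, in units of log ``base``."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return float("nan")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def alpha_diversity(table: FeatureTable, base: float = math.e) -> pd.DataFrame:
    """Per-sample richness_S, shannon_H and pielou_J (NaN when S <= 1)."""
    rows = []
    for sid in table.sample_ids:
        col = table.df[sid].to_numpy(dtype=float)
        s = int((col > 0).sum())
        if s == 0:
            logger.warning("sample %s is empty; alpha diversity missing", sid)
            rows.append({"sample_id": sid, "richness_S": 0,
                         "shannon_H": np.nan, "pielou_J": np.nan})
            continue
        h = shannon(col, base=base)
        j = h / (math.log(s) / math.log(base)) if s > 1 else np.nan
        rows.append({"sample_id": sid, "richness_S": s, "shannon_H": h, "pielou_J": j})
    return pd.DataFrame(rows).set_index("sample_id")


def beta_distance(a, b, metric: str) -> float:
    """Pairwise dissimilarity in [0, 1] between two count vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must share the same feature universe")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("beta distance undefined for two empty samples")
    if metric == "jaccard":
        return float(ssd.jaccard(a > 0, b > 0))
    if metric == "bray_curtis":
        return float(ssd.braycurtis(a, b))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    sample_ids: list[str]
    metric: str
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> pd.Series:
        """Unordered-pair series keyed by 'a|b' with a < b (pairing key for
        treatment comparisons)."""
        ids = self.sample_ids
        out = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = sorted((ids[i], ids[j]))
                out[f"{a}|{b}"] = self.values[i, j]
        return pd.Series(out, name=self.metric)


def distance_matrix(table: FeatureTable, metric: str) -> DistanceMatrix:
    """All pairwise beta distances between the table's samples."""
    ids = table.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.df.to_numpy(dtype=float).T  # samples x features
    if metric == "jaccard":
        cond = ssd.pdist(x > 0, metric="jaccard")
    elif metric == "bray_curtis":
        cond = ssd.pdist(x, metric="braycurtis")
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return DistanceMatrix(sample_ids=ids, metric=metric, values=ssd.squareform(cond))
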