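"""Feature-importance ranking from trained networks by Ruck saliency.

The saliency of input feature j is the aggregated magnitude of the trained
network's output partial derivatives with respect to that input, summed over
both output nodes and averaged over the sampled input points (here, the
normalized training points). Per-fold saliency vectors are aggregated two
ways: as mean proportions of summed saliency, and as mean ordinal ranks
(1 = most salient, ties sharing mid-ranks). The two aggregations answer
different questions — dominance magnitude vs. consistency of ordering — and
may legitimately disagree; the report exposes both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .learning import TrainedClassifier


@dataclass
class SaliencyReport:
    feature_names: tuple[str, ...]
    mean_saliency_proportion: np.ndarray
    mean_ordinal_rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_name": self.feature_names,
                "mean_saliency_proportion": self.mean_saliency_proportion,
                "mean_ordinal_rank": self.mean_ordinal_rank,
            }
        )

    def top_by_proportion(self, n: int = 5) -> pd.DataFrame:
        return self.to_frame().sort_values(
            "mean_saliency_proportion", ascending=False
        ).head(n)

    def top_by_rank(self, n: int = 5) -> pd.DataFrame:
        return self.to_frame().sort_values("mean_ordinal_rank").head(n)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ruck_saliency(ann: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    """Per-feature saliency: mean over input points of the summed absolute
    output-vs-input derivatives. Non-negative; zero for a disconnected input."""
    if ann.kind != "ANN":
        raise ValueError("Ruck saliency is defined for the ANN kind only")
    x = np.asarray(x, dtype=float)
    grads = ann.model.input_gradients(x)  # (n, n_in, 2)
    return np.abs(grads).sum(axis=2).mean(axis=0)


def aggregate_saliency(
    fold_saliencies: list[np.ndarray], feature_names: tuple[str, ...] | None = None
) -> SaliencyReport:
    """Aggregate per-fold saliency vectors into the two omnibus rankings.

    Proportions are normalized within each fold before averaging (so every
    fold contributes equal total weight); ordinal ranks are computed per fold
    with mid-rank ties and then averaged.
    """
    mat = np.asarray(fold_saliencies, dtype=float)
    if mat.ndim != 2:
        raise ValueError("fold saliency vectors must share one length")
    n_feat = mat.shape[1]
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(n_feat))
    if len(feature_names) != n_feat:
        raise ValueError("feature name count mismatch")
    sums = mat.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("each fold must have positive total saliency")
    proportions = mat / sums
    ranks = np.stack([rankdata(-row, method="average") for row in mat])
    return SaliencyReport(
        feature_names=feature_names,
        mean_saliency_proportion=proportions.mean(axis=0),
        mean_ordinal_rank=ranks.mean(axis=0),
    )
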