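"""SMOTE-style minority oversampling with replica provenance.

The acidemic class (7 cases) is augmented at the feature-table level by the
classic two-step construction: for a minority case ``p``, take the difference
to one of its nearest minority neighbours ``q``, scale it by a uniform random
``lambda`` in [0, 1], and add it to ``p`` — a random point on the segment
between the two cases.  Each original seeds ``n_synthetic_per_original``
replicas (default 6, growing 7 originals to 49 minority cases against 54
majority, 103 in total), and every replica records which original seeded it
so cross-validation can hold an original out together with all its replicas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import META_COLUMNS


@dataclass(frozen=True)
class AugmentationPlan:
    n_synthetic_per_original: int = 6
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_synthetic_per_original < 0 or self.k_neighbors < 1:
            raise ValueError("counts must be non-negative (k_neighbors >= 1)")


def smote_augment(minority: pd.DataFrame, plan: AugmentationPlan) -> pd.DataFrame:
    """Generate synthetic minority feature rows.

    ``minority`` holds the original minority rows (feature columns plus
    optional metadata).  Returns only the synthetic rows, indexed
    ``<seed_id>_r<j>`` with ``origin = "replica:<seed_id>"``.
    """
    feature_cols = [c for c in minority.columns if c not in META_COLUMNS]
    X = minority[feature_cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority rows (no neighbour)")
    if plan.k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the minority count")
    rng = np.random.default_rng(plan.seed)
    nn = NearestNeighbors(n_neighbors=plan.k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbours = idx[:, 1:]  # drop self

    rows, index = [], []
    for i, seed_id in enumerate(minority.index):
        for j in range(plan.n_synthetic_per_original):
            q = X[rng.choice(neighbours[i])]
            lam = rng.uniform(0.0, 1.0)
            rows.append(X[i] + lam * (q - X[i]))
            index.append(f"{seed_id}_r{j}")
    synthetic = pd.DataFrame(rows, index=index, columns=feature_cols)
    if "group" in minority.columns:
        synthetic["group"] = minority["group"].iloc[0]
    synthetic["origin"] = [f"replica:{i.rsplit('_r', 1)[0]}" for i in index]
    return synthetic


def augment_table(table: pd.DataFrame, minority_label: str,
                  plan: AugmentationPlan) -> pd.DataFrame:
    """Append synthetic minority rows to a full feature table.

    Original rows are never altered; the returned table has exactly
    ``n_minority * (1 + n_synthetic_per_original)`` minority rows.
    """
    minority = table[table["group"] == minority_label]
    synthetic = smote_augment(minority, plan)
    return pd.concat([table, synthetic[table.columns]])
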