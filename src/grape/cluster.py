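"""Clustering of validated stabilizing mutations on their feature vectors.

Mutations are grouped by k-means on standardized features (ΔTm, hydrogen-
bond change, hydrophobic-contact change, entropy flag, Cα position) so that
combination experiments can accumulate mutations within structurally and
mechanistically coherent groups. Because the features mix °C, counts, a
binary flag and Å, every numeric column is z-scored before clustering; the
three Cα coordinate columns are additionally multiplied by a joint
``coordinate_weight`` so the spatial term's influence is tunable, and the
0/1 entropy flag passes through unscaled. When ``k`` is ``"auto"`` the
cluster count maximizing the silhouette score over a small range is chosen,
with ties broken toward fewer clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterAssignment",
    "standardize_features",
    "cluster_mutations",
    "cluster_report",
    "NUMERIC_COLUMNS",
    "COORD_COLUMNS",
]

NUMERIC_COLUMNS = ["delta_tm", "hbond", "hydrophobic"]
COORD_COLUMNS = ["ca_x", "ca_y", "ca_z"]
FLAG_COLUMN = "entropy"


@dataclass
class ClusterAssignment:
    """Result of clustering a mutation feature table."""

    labels: dict[str, int]
    k: int
    members: dict[int, list[str]]
    silhouette: float | None
    scaling: pd.DataFrame

    def partition(self) -> frozenset:
        """Label-free view of the clustering, for partition comparison."""
        return frozenset(frozenset(m) for m in self.members.values())


def standardize_features(
    table: pd.DataFrame, coordinate_weight: float = 1.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Z-score the numeric feature columns of a feature table.

    Zero-spread columns map to all zeros; the coordinate columns are scaled
    jointly then multiplied by ``coordinate_weight``; the entropy flag is
    passed through unscaled. Returns the matrix and the scaling record
    (per-column mean and spread) needed to reproduce the transform.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    columns = NUMERIC_COLUMNS + [FLAG_COLUMN] + COORD_COLUMNS
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"feature table missing columns {missing}")
    matrix = np.zeros((len(table), len(columns)))
    records = []
    for j, col in enumerate(columns):
        values = table[col].to_numpy(dtype=float)
        if col == FLAG_COLUMN:
            mean, spread, weight = 0.0, 1.0, 1.0
        else:
            mean = float(values.mean())
            spread = float(values.std())
            weight = coordinate_weight if col in COORD_COLUMNS else 1.0
        scaled = np.zeros_like(values) if spread == 0 else (values - mean) / spread
        matrix[:, j] = weight * scaled
        records.append({"column": col, "mean": mean, "spread": spread,
                        "weight": weight})
    return matrix, pd.DataFrame(records)


def cluster_mutations(
    table: pd.DataFrame,
    k: int | str = "auto",
    k_range: tuple[int, int] | None = None,
    coordinate_weight: float = 1.0,
    seed: int = 0,
    n_init: int = 20,
) -> ClusterAssignment:
    """K-means clustering of a mutation feature table.

    With ``k="auto"`` every k in ``k_range`` (default 2..min(8, n−1)) is
    fitted and the silhouette-maximizing k wins, smallest k on ties. The
    silhouette is reported as ``None`` in the degenerate cases k = 1 and
    k = n where it is undefined. Deterministic for a fixed seed.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 mutations to cluster")
    matrix, scaling = standardize_features(table, coordinate_weight)
    names = table["mutation"].astype(str).tolist()

    def fit(k_fit: int) -> tuple[np.ndarray, float | None]:
        if k_fit == n:
            labels = np.arange(n)
        else:
            km = KMeans(n_clusters=k_fit, n_init=n_init, random_state=seed)
            labels = km.fit_predict(matrix)
        sil = None
        if 2 <= k_fit <= n - 1 and len(np.unique(labels)) == k_fit:
            sil = float(silhouette_score(matrix, labels))
        return labels, sil

    if k == "auto" and n == 2:
        # silhouette undefined for n = 2; the only non-trivial split is k = 2
        k = 2
    if k == "auto":
        lo, hi = k_range if k_range is not None else (2, min(8, n - 1))
        hi = min(hi, n - 1)
        if lo > hi:
            raise ValueError(f"empty auto-k range ({lo}, {hi}) for n = {n}")
        best = None
        for k_try in range(lo, hi + 1):
            labels, sil = fit(k_try)
            if sil is not None and (best is None or sil > best[2]):
                best = (k_try, labels, sil)
        if best is None:
            raise ValueError("no k in range produced a valid silhouette")
        k_final, labels, sil = best
    else:
        k_final = int(k)
        if not 1 <= k_final <= n:
            raise ValueError(f"k = {k_final} outside 1..{n}")
        labels, sil = fit(k_final)

    # relabel to consecutive 0..k-1 in order of first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        remap.setdefault(int(lab), len(remap))
    labels = np.array([remap[int(lab)] for lab in labels])
    members: dict[int, list[str]] = {}
    for name, lab in zip(names, labels):
        members.setdefault(int(lab), []).append(name)
    return ClusterAssignment(
        labels={name: int(lab) for name, lab in zip(names, labels)},
        k=len(members),
        members={c: members[c] for c in sorted(members)},
        silhouette=sil,
        scaling=scaling,
    )


def cluster_report(
    assignment: ClusterAssignment, table: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster summary: size, mean ΔTm, centroid Cα position, and the
    member list sorted by ΔTm descending (the order greedy accumulation
    consumes)."""
    indexed = table.set_index("mutation")
    unknown = [m for m in assignment.labels if m not in indexed.index]
    if unknown:
        raise ValueError(f"assignment references unknown mutations {unknown}")
    rows = []
    for cluster, members in assignment.members.items():
        sub = indexed.loc[members]
        order = sub["delta_tm"].sort_values(ascending=False).index.tolist()
        rows.append({
            "cluster": cluster,
            "size": len(members),
            "mean_delta_tm": float(sub["delta_tm"].mean()),
            "centroid_x": float(sub["ca_x"].mean()),
            "centroid_y": float(sub["ca_y"].mean()),
            "centroid_z": float(sub["ca_z"].mean()),
            "members": "+".join(order),
        })
    return pd.DataFrame(rows, columns=[
        "cluster", "size", "mean_delta_tm",
        "centroid_x", "centroid_y", "centroid_z", "members",
    ])
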