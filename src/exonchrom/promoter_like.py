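"""Clustering of regulated exons by differential chromatin features and
selection of the 'promoter-like' subset.

More-included and less-included exon comparisons are clustered separately
(k-means on standardized differential signals of H3K9ac, H3K4me3, H3K27ac,
CTCF and control).  A cluster is promoter-like when its mean z-scores for
the three promoter marks (H3K9ac, H3K27ac, H3K4me3) are all concordant with
the inclusion direction and all at least ``tau`` in magnitude — an explicit,
deterministic restatement of picking the strong-signal clusters by eye.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .chromatin import PROMOTER_MARKS


def standardize_features(delta_matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column (population SD).

    A zero-variance column becomes all zeros with a warning.  Idempotent on
    already-standardized input.
    """
    if len(delta_matrix) < 2:
        raise ValueError("need >= 2 rows to standardize")
    X = delta_matrix.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance feature columns set to 0: {list(X.columns[zero])}",
            stacklevel=2,
        )
    sd = sd.where(~zero, 1.0)
    Z = (X - mu) / sd
    Z.loc[:, zero] = 0.0
    return Z


def kmeans_partition(matrix: pd.DataFrame, k: int = 4, restarts: int = 100, seed: int = 0,
                     order_by: str = "H3K9ac"):
    """K-means partition of exon comparisons with stable cluster labels.

    Returns ``(assignment, cluster_means)``: a Series of cluster ids 1..k
    per row, and a DataFrame of per-cluster feature means.  Cluster ids are
    relabelled in descending order of the mean ``order_by`` column so labels
    are comparable across runs; best of ``restarts`` initialisations,
    deterministic given ``seed``.
    """
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} rows, got {len(matrix)}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw_labels = km.fit_predict(matrix.to_numpy(dtype=float))
    means = pd.DataFrame(km.cluster_centers_, columns=matrix.columns)
    key = means[order_by] if order_by in means.columns else means.iloc[:, 0]
    order = np.argsort(-key.to_numpy(), kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    assignment = pd.Series([relabel[int(l)] for l in raw_labels], index=matrix.index, name="cluster")
    cluster_means = means.iloc[order].reset_index(drop=True)
    cluster_means.index = pd.RangeIndex(1, k + 1, name="cluster")
    return assignment, cluster_means


def kmeans_inertia_scan(matrix: pd.DataFrame, ks=(2, 3, 4, 5), restarts: int = 100,
                        seed: int = 0) -> pd.Series:
    """Within-cluster sum of squares for a range of k (diagnostic only)."""
    out = {}
    for k in ks:
        if len(matrix) < k:
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        km.fit(matrix.to_numpy(dtype=float))
        out[k] = float(km.inertia_)
    return pd.Series(out, name="inertia")


def select_promoter_like_clusters(cluster_means: pd.DataFrame, direction: str,
                                  marks=PROMOTER_MARKS, tau: float = 1.0) -> list:
    """Cluster ids whose mean z for ALL promoter marks is concordant with the
    inclusion direction ('more': positive; 'less': negative) and of
    magnitude >= tau."""
    if direction not in ("more", "less"):
        raise ValueError("direction must be 'more' or 'less'")
    sign = 1.0 if direction == "more" else -1.0
    selected = []
    for cid, row in cluster_means.iterrows():
        vals = sign * row[list(marks)].to_numpy(dtype=float)
        if np.all(vals >= tau):
            selected.append(int(cid))
    return selected


def call_promoter_like(delta_by_direction: dict, k: int = 4, restarts: int = 100,
                       seed: int = 0, tau: float = 1.0, marks=PROMOTER_MARKS) -> pd.DataFrame:
    """Full promoter-like call over both direction groups.

    ``delta_by_direction`` maps 'more'/'less' to a differential-signal
    DataFrame (rows: exon comparisons, columns: features).  Each group is
    standardized and clustered separately; the promoter-like set is the
    union over groups.  Returns one row per exon comparison with
    ``direction``, ``cluster`` and ``promoter_like`` columns.
    """
    frames = []
    for direction, deltas in delta_by_direction.items():
        if deltas is None or len(deltas) == 0:
            continue
        Z = standardize_features(deltas)
        assignment, means = kmeans_partition(Z, k=k, restarts=restarts, seed=seed)
        selected = set(select_promoter_like_clusters(means, direction, marks=marks, tau=tau))
        frames.append(
            pd.DataFrame(
                {
                    "direction": direction,
                    "cluster": assignment,
                    "promoter_like": assignment.isin(selected),
                },
                index=deltas.index,
            )
        )
    if not frames:
        return pd.DataFrame(columns=["direction", "cluster", "promoter_like"])
    return pd.concat(frames)


def assign_cell_roles(psi1: float, psi2: float, cell1: str, cell2: str):
    """(C-higher, C-lower) by psi ordering; ties are dropped (None)."""
    if psi1 == psi2:
        return None
    return (cell1, cell2) if psi1 > psi2 else (cell2, cell1)


def holdout_direction_validation(delta_psi, total_chromatin_delta,
                                 min_delta_psi: float = 0.1,
                                 min_total_chromatin: float = 1.0):
    """Sign concordance between inclusion change and total promoter-mark
    change on a held-out cell pair.

    Eligible exons have |delta_psi| > min_delta_psi and |total chromatin
    difference| > min_total_chromatin (total = sum of the three promoter
    mark differentials).  Returns ``(fraction_concordant, verdicts)``;
    the fraction is ``nan`` when no exon is eligible.
    """
    dpsi = np.asarray(delta_psi, dtype=float)
    dchrom = np.asarray(total_chromatin_delta, dtype=float)
    eligible = (np.abs(dpsi) > min_delta_psi) & (np.abs(dchrom) > min_total_chromatin)
    concordant = np.sign(dchrom) == np.sign(dpsi)
    verdicts = pd.DataFrame(
        {"delta_psi": dpsi, "total_chromatin_delta": dchrom,
         "eligible": eligible, "concordant": concordant & eligible}
    )
    n = int(eligible.sum())
    frac = float(concordant[eligible].mean()) if n else float("nan")
    return frac, verdicts


def pca_projection(delta_matrix: pd.DataFrame):
    """First two principal components of the (standardized) differential
    matrix; returns ``(coords, explained_variance_ratio)``."""
    n_comp = min(2, delta_matrix.shape[1], len(delta_matrix))
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(delta_matrix.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return (
        pd.DataFrame(coords, index=delta_matrix.index, columns=cols),
        pca.explained_variance_ratio_,
    )
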