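"""Exonic average signal (EAS), differential signals, profile windows and
group-level association tests across chromatin marks.

EAS is the arithmetic mean of a per-base signal track over an exon's
genomic interval.  A differential signal compares the same interval between
the two cell lines of a comparison (cell2 - cell1, matching the inclusion
orientation), either as a raw difference or as a log2 ratio with a
pseudocount (the default, robust to sequencing-depth differences).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bonferroni, rank_sum_test, signed_rank_test

PROMOTER_MARKS = ("H3K9ac", "H3K27ac", "H3K4me3")
DEFAULT_CLUSTER_FEATURES = ("H3K9ac", "H3K4me3", "H3K27ac", "CTCF", "control")


def exonic_average_signal(track, interval) -> float:
    """Mean per-base track value over the interval (0 where uncovered)."""
    return track.mean(interval.chrom, interval.start, interval.end)


def differential_eas(track_cell1, track_cell2, interval, transform: str = "log2",
                     pseudocount: float = 1.0) -> float:
    """Differential EAS of cell2 vs cell1 over one interval.

    transform="raw": EAS2 - EAS1; transform="log2":
    log2(EAS2 + pseudocount) - log2(EAS1 + pseudocount).
    """
    e1 = exonic_average_signal(track_cell1, interval)
    e2 = exonic_average_signal(track_cell2, interval)
    if transform == "raw":
        return e2 - e1
    if transform == "log2":
        return float(np.log2(e2 + pseudocount) - np.log2(e1 + pseudocount))
    raise ValueError("transform must be 'raw' or 'log2'")


def window_profile(track_cell1, track_cell2, interval, width: int = 800, bin: int = 20,
                   transform: str = "log2", pseudocount: float = 1.0) -> np.ndarray:
    """Binned differential signal in a window centred on the interval midpoint.

    The window covers ``width`` bp around the midpoint split into
    ``width // bin`` bins; the returned vector is oriented in transcription
    direction (reversed for minus-strand intervals).  Bins off the start of
    the chromosome are truncated by the underlying track (0-valued).
    """
    n_bins = width // bin
    center = interval.midpoint
    start = center - width // 2
    end = start + width
    qstart = max(0, start)
    m1 = track_cell1.binned_means(interval.chrom, qstart, end, n_bins) if qstart == start else None
    if m1 is None:
        # off-chromosome head: compute available part, pad with zeros
        pad_bins = int(np.ceil((qstart - start) / bin))
        avail = n_bins - pad_bins
        m1 = np.concatenate([
            np.zeros(pad_bins),
            track_cell1.binned_means(interval.chrom, start + pad_bins * bin, end, avail),
        ])
        m2 = np.concatenate([
            np.zeros(pad_bins),
            track_cell2.binned_means(interval.chrom, start + pad_bins * bin, end, avail),
        ])
    else:
        m2 = track_cell2.binned_means(interval.chrom, qstart, end, n_bins)
    if transform == "raw":
        prof = m2 - m1
    elif transform == "log2":
        prof = np.log2(m2 + pseudocount) - np.log2(m1 + pseudocount)
    else:
        raise ValueError("transform must be 'raw' or 'log2'")
    if interval.strand == "-":
        prof = prof[::-1]
    return prof


def aggregate_profiles(profiles) -> pd.DataFrame:
    """Mean and standard error per bin across exon profiles."""
    mat = np.asarray(list(profiles), dtype=float)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros_like(mean)
    return pd.DataFrame({"bin": np.arange(mat.shape[1]), "mean": mean, "sem": sem})


def delta_matrix(exons, tracks_cell1: dict, tracks_cell2: dict, features=None,
                 transform: str = "log2", pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-exon differential EAS matrix (rows: exons, columns: features).

    ``tracks_cellN`` map feature name -> SignalTrack.  Missing features in
    either cell raise, since the clustering step cannot tolerate missing
    values.
    """
    features = list(features) if features is not None else sorted(tracks_cell1)
    for f in features:
        if f not in tracks_cell1 or f not in tracks_cell2:
            raise KeyError(f"feature {f!r} missing from one cell's track manifest")
    rows = {}
    for exon in exons:
        iv = exon.interval if hasattr(exon, "interval") else exon
        eid = exon.exon_id if hasattr(exon, "exon_id") else f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"
        rows[eid] = [
            differential_eas(tracks_cell1[f], tracks_cell2[f], iv, transform, pseudocount)
            for f in features
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=features)


def group_association_test(delta_more: pd.DataFrame, delta_less: pd.DataFrame,
                           n_features: int = None) -> pd.DataFrame:
    """Per-feature association of differential signal with inclusion direction.

    For every feature (column) two families of tests are reported, both
    Bonferroni-corrected across features:

    - signed-rank of each group's differential values against 0
      (``p_more_vs0``, ``p_less_vs0``),
    - rank-sum between the more- and less-included groups (``p_between``).

    ``direction`` is the sign of the median differential in each group.
    Groups need >= 5 observations.
    """
    features = list(delta_more.columns)
    if list(delta_less.columns) != features:
        raise ValueError("more/less groups must share the same feature columns")
    if len(delta_more) < 5 or len(delta_less) < 5:
        raise ValueError("each group needs >= 5 observations")
    m = n_features if n_features is not None else len(features)
    rows = []
    for f in features:
        dm = delta_more[f].to_numpy(dtype=float)
        dl = delta_less[f].to_numpy(dtype=float)
        rows.append(
            {
                "feature": f,
                "p_more_vs0": float(bonferroni(signed_rank_test(dm), m)),
                "p_less_vs0": float(bonferroni(signed_rank_test(dl), m)),
                "p_between": float(bonferroni(rank_sum_test(dm, dl), m)),
                "direction_more": int(np.sign(np.median(dm))),
                "direction_less": int(np.sign(np.median(dl))),
                "median_more": float(np.median(dm)),
                "median_less": float(np.median(dl)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
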