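"""Promoter-proximity and interaction analyses.

CAGE clusters (5'-tag clusters with tag-count scores) provide both a
promoter-based gene expression measure and an annotation-independent
definition of the 'used' TSS.  ChIA-PET links give chromatin-loop
interactions between exons and promoters; chromHMM segmentations give a
linear-proximity criterion (shared chromatin-state run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromatin import PROMOTER_MARKS, differential_eas, exonic_average_signal
from .intervals import GenomicInterval
from .stats import bh_adjust, hypergeom_enrichment, signed_rank_test


@dataclass(frozen=True)
class CageCluster:
    interval: GenomicInterval
    score: float

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("CAGE cluster score must be >= 0")


@dataclass(frozen=True)
class ChiaPetLink:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    support: int = 1

    def __post_init__(self):
        if self.anchor1 == self.anchor2:
            raise ValueError("ChIA-PET anchors must differ")
        if self.support < 1:
            raise ValueError("support must be >= 1")


def read_cage_bed(path) -> list:
    """BED with score column -> CAGE clusters (strand optional)."""
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            strand = f[5] if len(f) > 5 else "+"
            clusters.append(
                CageCluster(GenomicInterval(f[0], int(f[1]), int(f[2]), strand), float(f[4]) if len(f) > 4 else 0.0)
            )
    return clusters


def read_bedpe(path) -> list:
    """BEDPE with a support column (7th field 'name' carries support if
    integer, else 8th 'score')."""
    links = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            support = 1
            for col in (7, 6):
                if len(f) > col:
                    try:
                        support = int(float(f[col]))
                        break
                    except ValueError:
                        continue
            links.append(
                ChiaPetLink(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                    max(support, 1),
                )
            )
    return links


def read_segmentation_bed(path) -> pd.DataFrame:
    """chromHMM BED: chrom, start, end, state label (name field)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            rows.append({"chrom": f[0], "start": int(f[1]), "end": int(f[2]), "state": f[3]})
    return pd.DataFrame(rows)


def gene_expression_from_cage(cage_clusters, gene_tss_set: dict, radius: int = 100) -> dict:
    """Promoter-based gene expression from CAGE cluster scores.

    Each cluster is assigned to the closest TSS within ``radius`` nt
    (unassigned otherwise; equidistant ties go to the upstream-most, i.e.
    smallest-coordinate, TSS).  Gene expression is the sum of scores of
    clusters assigned to any of the gene's TSSs.  ``gene_tss_set`` maps
    gene_id -> [(chrom, strand, tss_position)].
    """
    tss_flat = []  # (chrom, pos, gene_id)
    for gid, tsss in gene_tss_set.items():
        for chrom, _strand, pos in tsss:
            tss_flat.append((chrom, pos, gid))
    expr = {gid: 0.0 for gid in gene_tss_set}
    for cl in cage_clusters:
        best = None
        for chrom, pos, gid in tss_flat:
            if chrom != cl.interval.chrom:
                continue
            d = cl.interval.distance_to_point(pos)
            if d > radius:
                continue
            if best is None or d < best[0] or (d == best[0] and pos < best[1]):
                best = (d, pos, gid)
        if best is not None:
            expr[best[2]] += cl.score
    return expr


def distance_to_used_tss(exon, cage_clusters, min_score: float = 1.0):
    """Genomic distance from the exon to the nearest CAGE cluster with
    score >= min_score (the nearest 'used' TSS), annotation-independently.

    A qualifying cluster overlapping the exon gives distance 0.  Returns
    ``(distance, cluster)`` with ``(None, None)`` when no cluster on the
    chromosome qualifies.
    """
    iv = exon.interval if hasattr(exon, "interval") else exon
    best = None
    for cl in cage_clusters:
        if cl.score < min_score or cl.interval.chrom != iv.chrom:
            continue
        d = iv.distance_to(cl.interval)
        if best is None or d < best[0]:
            best = (d, cl)
    if best is None:
        return None, None
    return best


def compare_tss_proximity(distances_higher, distances_lower) -> dict:
    """Tally, across promoter-like exon comparisons, whether the nearest
    used TSS is closer in the C-higher or the C-lower cell line.

    Inputs are parallel sequences of distances (None = undefined).  Exact
    equality counts as 'same'; pairs with an undefined distance are counted
    under 'undefined' and excluded from the tally.
    """
    tally = {"closer_in_Chigher": 0, "closer_in_Clower": 0, "same": 0, "undefined": 0}
    for dh, dl in zip(distances_higher, distances_lower):
        if dh is None or dl is None:
            tally["undefined"] += 1
        elif dh < dl:
            tally["closer_in_Chigher"] += 1
        elif dh > dl:
            tally["closer_in_Clower"] += 1
        else:
            tally["same"] += 1
    return tally


def count_chia_pet_interactions(exon, links, pad: int = 0):
    """Number of ChIA-PET links with >= 1 anchor overlapping the exon
    (half-open overlap, optional symmetric padding); also a boolean."""
    iv = exon.interval if hasattr(exon, "interval") else exon
    query = GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad, iv.strand)
    n = sum(
        1 for ln in links if query.overlaps(ln.anchor1) or query.overlaps(ln.anchor2)
    )
    return n, n > 0


def same_state_extension(exon, used_tss_position: int, segmentation: pd.DataFrame) -> bool:
    """True iff the exon midpoint and the used TSS lie within one contiguous
    run of identically-labelled segments (adjacent equal-label segments are
    merged; a coverage gap between them breaks the run)."""
    iv = exon.interval if hasattr(exon, "interval") else exon
    seg = segmentation[segmentation["chrom"] == iv.chrom].sort_values("start")
    if seg.empty:
        return False
    # merge adjacent same-label segments
    runs = []
    for _, row in seg.iterrows():
        if runs and runs[-1][2] == row["state"] and runs[-1][1] == row["start"]:
            runs[-1][1] = row["end"]
        else:
            runs.append([row["start"], row["end"], row["state"]])
    mid = iv.midpoint
    for s, e, _state in runs:
        if s <= mid < e:
            return s <= used_tss_position < e
    return False


def tss_vs_exon_mark_shift(calls: pd.DataFrame, exons: dict, used_tss: dict,
                           tracks: dict, marks=PROMOTER_MARKS, tss_halfwidth: int = 200,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Compare the C-higher vs C-lower mark fold-change at the exon with the
    fold-change at its closest used TSS.

    ``calls`` needs columns exon_id, c_higher, c_lower.  ``exons`` maps
    exon_id -> ExonRecord; ``used_tss`` maps exon_id -> genomic TSS
    position; ``tracks`` maps cell -> {mark -> SignalTrack}.  For each mark
    the paired signed-rank test contrasts per-exon Delta_exon with
    Delta_TSS (both log2 with pseudocount, C-higher - C-lower).
    """
    rows = []
    for mark in marks:
        d_exon, d_tss = [], []
        for _, call in calls.iterrows():
            eid = call["exon_id"]
            exon = exons[eid]
            hi, lo = call["c_higher"], call["c_lower"]
            if mark not in tracks.get(hi, {}) or mark not in tracks.get(lo, {}):
                continue
            iv = exon.interval
            tss = used_tss.get(eid)
            if tss is None:
                continue
            tss_iv = GenomicInterval(iv.chrom, max(0, tss - tss_halfwidth), tss + tss_halfwidth)
            d_exon.append(
                differential_eas(tracks[lo][mark], tracks[hi][mark], iv, "log2", pseudocount)
            )
            d_tss.append(
                differential_eas(tracks[lo][mark], tracks[hi][mark], tss_iv, "log2", pseudocount)
            )
        d_exon = np.asarray(d_exon)
        d_tss = np.asarray(d_tss)
        p = signed_rank_test(d_exon - d_tss) if d_exon.size else float("nan")
        rows.append(
            {
                "mark": mark,
                "n": int(d_exon.size),
                "median_delta_exon": float(np.median(d_exon)) if d_exon.size else float("nan"),
                "median_delta_tss": float(np.median(d_tss)) if d_tss.size else float("nan"),
                "p_paired": p,
            }
        )
    return pd.DataFrame(rows).set_index("mark")


def motif_enrichment(foreground_ids, background_ids, occurrence: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric over-representation of motif hits in the foreground.

    ``occurrence`` is a binary exon x motif hit matrix covering foreground
    and background; the population is foreground + background.  Returns
    per-motif p and BH q.  Empty foreground is an error; a motif with no
    hits anywhere gets p = 1.
    """
    fg = list(foreground_ids)
    bg = list(background_ids)
    if not fg:
        raise ValueError("empty foreground")
    pop = fg + bg
    occ = occurrence.loc[pop].astype(bool)
    M = len(pop)
    n_fg = len(fg)
    rows = []
    for motif in occ.columns:
        K = int(occ[motif].sum())
        k = int(occ.loc[fg, motif].sum())
        p = 1.0 if K == 0 else hypergeom_enrichment(k, n_fg, K, M)
        rows.append({"motif": motif, "hits_fg": k, "hits_total": K, "p": p})
    out = pd.DataFrame(rows).set_index("motif")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def cage_occupancy_in_exons(exons, cage_track, tss_intervals=None) -> pd.DataFrame:
    """CAGE tag signal (EAS) over exons, optionally contrasted with the
    occupancy distribution over annotated-TSS windows."""
    rows = [
        {"id": e.exon_id if hasattr(e, "exon_id") else str(i),
         "set": "exon",
         "eas": exonic_average_signal(cage_track, e.interval if hasattr(e, "interval") else e)}
        for i, e in enumerate(exons)
    ]
    if tss_intervals is not None:
        rows += [
            {"id": f"tss_{i}", "set": "tss", "eas": exonic_average_signal(cage_track, iv)}
            for i, iv in enumerate(tss_intervals)
        ]
    return pd.DataFrame(rows)
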