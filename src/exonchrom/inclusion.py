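"""Exon inclusion quantification and differential-inclusion calling.

Inclusion level (psi): psi = 0.5*JIR / (0.5*JIR + JER), where JIR pools the
upstream and downstream junction inclusion reads over replicates and JER is
the exclusion (skipping) junction count.  The 0.5 factor corrects for each
included molecule contributing two inclusion junctions but only one
exclusion junction.

Differential inclusion between two cell lines is a pair of one-sided Fisher
exact tests on the 2x2 inclusion/exclusion read table, BH-corrected per cell
pair separately for each tail.  Orientation convention used throughout:
delta_psi = psi(cell2) - psi(cell1), and "more included" means higher
inclusion in cell2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_one_sided

COUNT_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "cell", "replicate", "count"]


@dataclass(frozen=True)
class JunctionCounts:
    """Junction read counts for one exon in one cell/replicate."""

    exon_id: str
    cell: str
    replicate: str
    jir_up: int
    jir_down: int
    jer: int

    @property
    def jir(self) -> int:
        return self.jir_up + self.jir_down


def inclusion_level(jir, jer):
    """psi = 0.5*JIR / (0.5*JIR + JER); nan when JIR = JER = 0."""
    jir = np.asarray(jir, dtype=float)
    jer = np.asarray(jer, dtype=float)
    denom = 0.5 * jir + jer
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, 0.5 * jir / np.where(denom > 0, denom, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def read_junction_table(path) -> pd.DataFrame:
    """Read a junction-count TSV (chrom, intron_start, intron_end, strand,
    cell, replicate, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "replicate": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    return df


def count_junctions(junction_table: pd.DataFrame, exon) -> list:
    """Per cell/replicate junction counts for one exon.

    Junctions are matched by exact intron coordinates; table rows for other
    introns are ignored.  Cells/replicates with no matching rows get zero
    counts only if they appear in the table at all.
    """
    lookup = {}
    for key in ("up", "down", "skip"):
        span = {
            "up": exon.upstream_junction,
            "down": exon.downstream_junction,
            "skip": exon.skip_junction,
        }[key]
        lookup[(exon.interval.chrom, span[0], span[1])] = key
    counts: dict = {}
    groups = junction_table.groupby(["cell", "replicate"], sort=True)
    for (cell, rep), sub in groups:
        acc = {"up": 0, "down": 0, "skip": 0}
        for chrom, s, e, n in zip(sub["chrom"], sub["intron_start"], sub["intron_end"], sub["count"]):
            key = lookup.get((chrom, int(s), int(e)))
            if key is not None:
                acc[key] += int(n)
        counts[(cell, rep)] = JunctionCounts(
            exon.exon_id, str(cell), str(rep), acc["up"], acc["down"], acc["skip"]
        )
    return list(counts.values())


def junction_counts_matrix(junction_table: pd.DataFrame, exons) -> pd.DataFrame:
    """Vectorised junction counting for many exons at once.

    Returns one row per (exon_id, cell, replicate) with jir_up, jir_down,
    jer columns; exons whose junctions never occur in the table still get
    zero rows for every (cell, replicate) present.
    """
    idx = junction_table.set_index(["chrom", "intron_start", "intron_end", "cell", "replicate"])[
        "count"
    ]
    idx = idx.groupby(level=[0, 1, 2, 3, 4]).sum()
    cells_reps = junction_table[["cell", "replicate"]].drop_duplicates().itertuples(index=False)
    cells_reps = [(str(c), str(r)) for c, r in cells_reps]
    rows = []
    for exon in exons:
        chrom = exon.interval.chrom
        up, down, skip = exon.upstream_junction, exon.downstream_junction, exon.skip_junction
        for cell, rep in cells_reps:
            def get(span):
                try:
                    return int(idx.loc[(chrom, span[0], span[1], cell, rep)])
                except KeyError:
                    return 0
            rows.append(
                {
                    "exon_id": exon.exon_id,
                    "gene_id": exon.gene_id,
                    "cell": cell,
                    "replicate": rep,
                    "jir_up": get(up),
                    "jir_down": get(down),
                    "jer": get(skip),
                }
            )
    return pd.DataFrame(rows)


def replicate_concordance_filter(psi_rep1, psi_rep2, max_delta: float = 0.1) -> bool:
    """Replicate agreement filter: pass iff both psi defined and
    |psi_rep1 - psi_rep2| <= max_delta."""
    if psi_rep1 is None or psi_rep2 is None:
        return False
    if np.isnan(psi_rep1) or np.isnan(psi_rep2):
        return False
    return abs(psi_rep1 - psi_rep2) <= max_delta


def differential_inclusion_test(counts_cell1, counts_cell2):
    """Two one-sided Fisher exact p-values for one exon.

    ``counts_cellN`` are (JIR, JER) tuples pooled over replicates.  The exon
    is testable only with >= 1 inclusion read in one cell and >= 1 exclusion
    read in the other (either orientation); otherwise returns None.
    """
    jir1, jer1 = counts_cell1
    jir2, jer2 = counts_cell2
    if not ((jir1 >= 1 and jer2 >= 1) or (jir2 >= 1 and jer1 >= 1)):
        return None
    return fisher_one_sided(jir1, jer1, jir2, jer2)


def classify_exons(tested: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-correct the two tails per cell pair and label each exon.

    ``tested`` needs columns p_more, p_less, psi1, psi2.  Adds q_more,
    q_less, q (min of the two), label in {more, less, notAS}, delta_psi and
    fold (psi2/psi1).  The two one-sided tails of a single table cannot both
    be significant at alpha <= 0.5; this is asserted.
    """
    out = tested.copy()
    out["q_more"] = bh_adjust(out["p_more"].to_numpy())
    out["q_less"] = bh_adjust(out["p_less"].to_numpy())
    out["q"] = np.minimum(out["q_more"], out["q_less"])
    more = (out["q_more"] < alpha) & (out["psi2"] > out["psi1"])
    less = (out["q_less"] < alpha) & (out["psi2"] < out["psi1"])
    assert not bool((more & less).any()), "both one-sided tails significant"
    out["label"] = np.where(more, "more", np.where(less, "less", "notAS"))
    out["delta_psi"] = out["psi2"] - out["psi1"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold"] = out["psi2"] / out["psi1"]
    return out


def _ratio_fold(a, b):
    """Symmetric fold change max(a/b, b/a); inf if exactly one is 0, nan if both."""
    if a == 0 and b == 0:
        return float("nan")
    if a == 0 or b == 0:
        return float("inf")
    return max(a / b, b / a)


def apply_regulation_filters(
    classified: pd.DataFrame,
    gene_expression: dict,
    mappable_fraction: dict,
    min_abs_delta: float = 0.1,
    min_fold: float = 2.0,
    max_expr_fold: float = 10.0,
    min_mappable: float = 0.75,
) -> pd.DataFrame:
    """Keep regulated exons passing the effect-size and context filters.

    - inclusion changed by at least ``min_abs_delta`` OR ``min_fold``-fold
      (OR semantics),
    - host-gene expression fold change (from CAGE) <= ``max_expr_fold``;
      a gene with zero expression in one cell has undefined fold and its
      exons are excluded,
    - mappable fraction around the acceptor >= ``min_mappable``.

    ``gene_expression`` maps gene_id -> (expr_cell1, expr_cell2);
    ``mappable_fraction`` maps exon_id -> fraction.
    """
    reg = classified[classified["label"].isin(["more", "less"])].copy()
    if reg.empty:
        return reg

    def effect_ok(row):
        if abs(row["delta_psi"]) >= min_abs_delta:
            return True
        f = _ratio_fold(row["psi1"], row["psi2"])
        return np.isfinite(f) and f >= min_fold

    def expr_ok(row):
        e = gene_expression.get(row["gene_id"])
        if e is None:
            return False
        f = _ratio_fold(e[0], e[1])
        return np.isfinite(f) and f <= max_expr_fold

    def mapp_ok(row):
        frac = mappable_fraction.get(row["exon_id"])
        return frac is not None and frac >= min_mappable

    keep = reg.apply(lambda r: effect_ok(r) and expr_ok(r) and mapp_ok(r), axis=1)
    return reg[keep.astype(bool)]


def pick_exon_per_gene(candidates: pd.DataFrame, mode: str = "regulated") -> pd.DataFrame:
    """Select representative exons per gene.

    mode="regulated": at most one more-included and one less-included exon
    per gene, the one with the lowest one-sided p in its direction.
    mode="notAS": the exon with the minimal |delta_psi| per gene.
    Ties are broken by genomic position (leftmost), using the exon_id's
    coordinates, so selection is deterministic.
    """
    if candidates.empty:
        return candidates
    df = candidates.copy()
    df["_pos"] = df["exon_id"].map(lambda e: int(e.split(":")[1].split("-")[0]))
    if mode == "regulated":
        parts = []
        for label, pcol in (("more", "p_more"), ("less", "p_less")):
            sub = df[df["label"] == label]
            if sub.empty:
                continue
            sub = sub.sort_values([pcol, "_pos"], kind="stable")
            parts.append(sub.groupby("gene_id", sort=True).head(1))
        out = pd.concat(parts) if parts else df.iloc[0:0]
    elif mode == "notAS":
        sub = df[df["label"] == "notAS"].copy()
        sub["_absd"] = sub["delta_psi"].abs()
        sub = sub.sort_values(["_absd", "_pos"], kind="stable")
        out = sub.groupby("gene_id", sort=True).head(1).drop(columns="_absd")
    else:
        raise ValueError("mode must be 'regulated' or 'notAS'")
    return out.drop(columns="_pos").sort_index()


def inclusion_range(psi_by_cell) -> float:
    """Difference between the maximum and minimum defined psi across cells."""
    vals = np.asarray([v for v in psi_by_cell if v is not None and not np.isnan(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no defined psi values")
    return float(vals.max() - vals.min())


def call_pair(
    counts: pd.DataFrame,
    cell1: str,
    cell2: str,
    alpha: float = 0.05,
    max_replicate_delta: float = 0.1,
) -> pd.DataFrame:
    """Full differential-inclusion call for one cell pair.

    ``counts`` has one row per (exon_id, gene_id, cell, replicate) with
    jir_up, jir_down, jer.  Replicates are pooled for testing after the
    per-replicate concordance filter (``max_replicate_delta=None`` skips
    the filter and tests every exon with enough pooled reads); only
    testable exons appear in the returned frame.
    """
    sub = counts[counts["cell"].isin([cell1, cell2])]
    rows = []
    for (exon_id, gene_id), g in sub.groupby(["exon_id", "gene_id"], sort=True):
        per_cell = {}
        concordant = True
        for cell in (cell1, cell2):
            gc = g[g["cell"] == cell]
            if gc.empty:
                per_cell = None
                break
            jir_reps = (gc["jir_up"] + gc["jir_down"]).to_numpy()
            jer_reps = gc["jer"].to_numpy()
            psis = inclusion_level(jir_reps, jer_reps)
            psis = np.atleast_1d(psis)
            if (
                max_replicate_delta is not None
                and len(psis) >= 2
                and not replicate_concordance_filter(psis[0], psis[1], max_replicate_delta)
            ):
                concordant = False
            per_cell[cell] = (int(jir_reps.sum()), int(jer_reps.sum()))
        if per_cell is None or not concordant:
            continue
        jir1, jer1 = per_cell[cell1]
        jir2, jer2 = per_cell[cell2]
        if not ((jir1 >= 1 and jer2 >= 1) or (jir2 >= 1 and jer1 >= 1)):
            continue
        psi1 = inclusion_level(jir1, jer1)
        psi2 = inclusion_level(jir2, jer2)
        if np.isnan(psi1) or np.isnan(psi2):
            continue
        rows.append(
            {
                "exon_id": exon_id,
                "gene_id": gene_id,
                "cell1": cell1,
                "cell2": cell2,
                "jir1": jir1,
                "jer1": jer1,
                "jir2": jir2,
                "jer2": jer2,
                "psi1": psi1,
                "psi2": psi2,
            }
        )
    tested = pd.DataFrame(rows)
    if tested.empty:
        return tested
    p_more, p_less = fisher_one_sided(
        tested["jir1"].to_numpy(),
        tested["jer1"].to_numpy(),
        tested["jir2"].to_numpy(),
        tested["jer2"].to_numpy(),
    )
    tested["p_more"] = p_more
    tested["p_less"] = p_less
    return classify_exons(tested, alpha=alpha)
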