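"""End-to-end orchestration: catalog -> inclusion calling -> chromatin
deltas -> promoter-like clustering -> promoter context, from one config.

A run consumes a bundle directory (as written by
:func:`exonchrom.simulate.write_bundle`, or real files laid out the same
way), executes the stages in dependency order and writes stage outputs plus
a JSON manifest (parameters, parameter hash, output checksums) into a run
directory.  Runs are deterministic given the seeds in the parameter block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import chromatin, context, inclusion, promoter_like
from .chromatin import DEFAULT_CLUSTER_FEATURES
from .tracks import SignalTrack, load_track


@dataclass
class PipelineParams:
    """Every analysis threshold, as a named parameter with its default."""

    alpha: float = 0.05
    max_replicate_delta: float = 0.1
    min_abs_delta: float = 0.1
    min_fold: float = 2.0
    max_expr_fold: float = 10.0
    min_mappable: float = 0.75
    mappability_window: int = 900
    min_len: int = 50
    max_len: int = 450
    min_tss_tts_distance: int = 600
    transform: str = "log2"
    pseudocount: float = 1.0
    k: int = 4
    restarts: int = 100
    tau: float = 1.0
    kmeans_seed: int = 17
    cage_radius: int = 100
    min_cage_score: float = 1.0
    profile_width: int = 800
    profile_bin: int = 20
    holdout_min_delta_psi: float = 0.1
    holdout_min_chromatin: float = 1.0


@dataclass
class RunConfig:
    bundle_dir: str
    out_dir: str
    cell_pair: tuple  # (cell1, cell2)
    marks: tuple = DEFAULT_CLUSTER_FEATURES
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> list:
        """Return the list of missing input paths (empty = valid)."""
        b = Path(self.bundle_dir)
        missing = []
        for rel in ["annotation.gtf", "genome.fa", "junctions.tsv", "mappability.bedGraph"]:
            if not (b / rel).exists():
                missing.append(str(b / rel))
        for cell in self.cell_pair:
            for rel in [f"cage.{cell}.bed", f"links.{cell}.bedpe", f"chromhmm.{cell}.bed"]:
                if not (b / rel).exists():
                    missing.append(str(b / rel))
            for mark in self.marks:
                p = b / "tracks" / f"{cell}.{mark}.bedGraph"
                if not p.exists():
                    missing.append(str(p))
        return missing


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {"cell_pair": list(config.cell_pair), "marks": list(config.marks),
         "params": asdict(config.params)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_discovery(config: RunConfig) -> dict:
    """Run all stages; returns the results bundle (also written to disk)."""
    missing = config.validate()
    if missing:
        raise FileNotFoundError("missing input files:\n" + "\n".join(missing))
    import pyfaidx

    b = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    cell1, cell2 = config.cell_pair

    # stage 1: catalog
    model = cat.load_annotation(b / "annotation.gtf", b / "genome.fa")
    genome = pyfaidx.Fasta(str(b / "genome.fa"))
    records = cat.select_candidate_exons(
        model, genome,
        min_tss_tts_distance=p.min_tss_tts_distance,
        min_len=p.min_len, max_len=p.max_len,
    )
    exon_by_id = {r.exon_id: r for r in records}
    catalog_df = cat.catalog_to_dataframe(records)
    catalog_df.to_csv(out / "catalog.tsv", sep="\t", index=False)

    # stage 2: inclusion calling
    junctions = inclusion.read_junction_table(b / "junctions.tsv")
    counts = inclusion.junction_counts_matrix(junctions, records)
    calls = inclusion.call_pair(
        counts, cell1, cell2, alpha=p.alpha, max_replicate_delta=p.max_replicate_delta
    )
    mapp_track = SignalTrack.from_bedgraph(b / "mappability.bedGraph")
    mappable = {
        eid: cat.mappable_fraction(rec, mapp_track, window=p.mappability_window)
        for eid, rec in exon_by_id.items()
    }
    gene_tss = model.gene_tss_set()
    cage_by_cell = {
        cell: context.read_cage_bed(b / f"cage.{cell}.bed") for cell in config.cell_pair
    }
    expr = {}
    expr_per_cell = {
        cell: context.gene_expression_from_cage(cage_by_cell[cell], gene_tss, radius=p.cage_radius)
        for cell in config.cell_pair
    }
    for gid in gene_tss:
        expr[gid] = (expr_per_cell[cell1].get(gid, 0.0), expr_per_cell[cell2].get(gid, 0.0))
    if not calls.empty:
        filtered = inclusion.apply_regulation_filters(
            calls, expr, mappable,
            min_abs_delta=p.min_abs_delta, min_fold=p.min_fold,
            max_expr_fold=p.max_expr_fold, min_mappable=p.min_mappable,
        )
        regulated = inclusion.pick_exon_per_gene(filtered, mode="regulated")
    else:
        regulated = calls
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    regulated.to_csv(out / "regulated.tsv", sep="\t", index=False)
    _write_bed(out / "regulated.bed", regulated, exon_by_id, f"{cell1}:{cell2}")

    # stage 3: chromatin differential signals
    tracks = {
        cell: {mark: load_track(b / "tracks" / f"{cell}.{mark}.bedGraph") for mark in config.marks}
        for cell in config.cell_pair
    }
    reg_exons = [exon_by_id[e] for e in regulated["exon_id"]] if not regulated.empty else []
    deltas = chromatin.delta_matrix(
        reg_exons, tracks[cell1], tracks[cell2], features=config.marks,
        transform=p.transform, pseudocount=p.pseudocount,
    )
    deltas.to_csv(out / "deltas.tsv", sep="\t")

    # stage 4: promoter-like clustering (skipped for groups smaller than k)
    by_dir = {}
    if not regulated.empty:
        for direction in ("more", "less"):
            ids = regulated.loc[regulated["label"] == direction, "exon_id"]
            sub = deltas.loc[ids]
            if len(sub) >= p.k:
                by_dir[direction] = sub
    pl_calls = promoter_like.call_promoter_like(
        by_dir, k=p.k, restarts=p.restarts, seed=p.kmeans_seed, tau=p.tau
    )
    pl_calls = pl_calls.rename_axis("exon_id").reset_index()
    if not pl_calls.empty:
        psi = regulated.set_index("exon_id")
        roles = [
            promoter_like.assign_cell_roles(
                psi.loc[e, "psi1"], psi.loc[e, "psi2"], cell1, cell2
            )
            for e in pl_calls["exon_id"]
        ]
        pl_calls["c_higher"] = [r[0] if r else "" for r in roles]
        pl_calls["c_lower"] = [r[1] if r else "" for r in roles]
        pl_calls.loc[pl_calls["c_higher"] == "", "promoter_like"] = False
    pl_calls.to_csv(out / "promoter_like.tsv", sep="\t", index=False)
    pl_set = pl_calls[pl_calls["promoter_like"]] if not pl_calls.empty else pl_calls
    _write_bed(out / "promoter_like.bed", pl_set, exon_by_id, f"{cell1}:{cell2}")

    # stage 5: promoter context for the promoter-like set
    links_by_cell = {
        cell: context.read_bedpe(b / f"links.{cell}.bedpe") for cell in config.cell_pair
    }
    seg_by_cell = {
        cell: context.read_segmentation_bed(b / f"chromhmm.{cell}.bed")
        for cell in config.cell_pair
    }
    ctx: dict = {"n_promoter_like": int(len(pl_set))}
    if len(pl_set):
        dists = {cell: [] for cell in config.cell_pair}
        interactions = {cell: [] for cell in config.cell_pair}
        extension = {cell: [] for cell in config.cell_pair}
        for row in pl_set.itertuples(index=False):
            rec = exon_by_id[row.exon_id]
            for cell in config.cell_pair:
                d, cl = context.distance_to_used_tss(
                    rec, cage_by_cell[cell], min_score=p.min_cage_score
                )
                dists[cell].append(d)
                n, _has = context.count_chia_pet_interactions(rec, links_by_cell[cell])
                interactions[cell].append(n)
                if d is not None and cl is not None:
                    extension[cell].append(
                        context.same_state_extension(rec, cl.interval.midpoint, seg_by_cell[cell])
                    )
                else:
                    extension[cell].append(False)
        hi = list(pl_set["c_higher"])
        lo = list(pl_set["c_lower"])
        d_hi = [dists[c][i] for i, c in enumerate(hi)]
        d_lo = [dists[c][i] for i, c in enumerate(lo)]
        ctx["tss_proximity"] = context.compare_tss_proximity(d_hi, d_lo)
        ctx["interaction_rate_c_higher"] = float(
            np.mean([interactions[c][i] > 0 for i, c in enumerate(hi)])
        )
        ctx["interaction_rate_c_lower"] = float(
            np.mean([interactions[c][i] > 0 for i, c in enumerate(lo)])
        )
        ctx["same_state_fraction"] = float(
            np.mean(
                [extension[c][i] and extension[l][i] for i, (c, l) in enumerate(zip(hi, lo))]
            )
        )
    with open(out / "context.json", "w") as fh:
        json.dump(ctx, fh, indent=2, sort_keys=True)

    manifest = {
        "bundle_dir": str(config.bundle_dir),
        "cell_pair": [cell1, cell2],
        "marks": list(config.marks),
        "params": asdict(p),
        "params_hash": _params_hash(config),
        "outputs": {
            f.name: _sha256(f)
            for f in sorted(out.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "catalog": catalog_df,
        "calls": calls,
        "regulated": regulated,
        "deltas": deltas,
        "promoter_like": pl_calls,
        "context": ctx,
        "manifest": manifest,
    }


def _write_bed(path: Path, df: pd.DataFrame, exon_by_id: dict, name: str) -> None:
    with open(path, "w") as fh:
        if df is None or df.empty:
            return
        for eid in df["exon_id"]:
            iv = exon_by_id[eid].interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def evaluate_against_truth(results: dict, truth: pd.DataFrame) -> dict:
    """Confusion counts, sensitivity and realized FDR of regulated-exon and
    promoter-like calls against the simulation truth table.

    FDR is reported as None when no calls were made.
    """
    def _confusion(called: set, positive: set, universe: set) -> dict:
        tp = len(called & positive)
        fp = len(called - positive)
        fn = len(positive - called)
        tn = len(universe - called - positive)
        return {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": tp / len(positive) if positive else None,
            "fdr": fp / len(called) if called else None,
        }

    universe = set(truth["exon_id"])
    reg_truth = set(truth.loc[truth["regulated"], "exon_id"])
    reg_called = set(results["regulated"]["exon_id"]) if len(results["regulated"]) else set()
    unknown = reg_called - universe
    if unknown:
        raise ValueError(f"called exons absent from truth table: {sorted(unknown)[:5]}")
    report = {"regulated": _confusion(reg_called, reg_truth, universe)}

    pl = results["promoter_like"]
    pl_called = (
        set(pl.loc[pl["promoter_like"], "exon_id"]) if len(pl) else set()
    )
    pl_truth = set(truth.loc[truth["promoter_like"], "exon_id"])
    report["promoter_like"] = _confusion(pl_called, pl_truth, universe)

    # per-direction breakdown of regulated calls
    for direction in ("more", "less"):
        t = set(truth.loc[truth["direction"] == direction, "exon_id"])
        c = (
            set(results["regulated"].loc[results["regulated"]["label"] == direction, "exon_id"])
            if len(results["regulated"])
            else set()
        )
        report[f"regulated_{direction}"] = _confusion(c, t, universe)
    return report
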