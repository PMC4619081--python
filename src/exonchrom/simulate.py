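"""Synthetic multi-omics data with known ground truth.

Generates a complete, internally consistent input bundle — genome FASTA,
GTF annotation with cassette-exon transcripts, binomially sampled junction
reads, per-mark signal tracks, CAGE clusters, ChIA-PET links, chromHMM
segmentations and a mappability track — so every pipeline stage runs with
no external download.  All randomness derives from a single seed; identical
config + seed gives byte-identical files.

The statistical structure mirrors the analysis assumptions: each gene
carries one cassette exon whose true inclusion (psi) per cell line is
recorded in the truth table; a configurable fraction of cassette exons is
regulated between the two cell lines (default 3 % of exons, echoing the
fraction of regulated internal exons observed in cell-line panels) and a
fraction of those (default 4 %) is 'promoter-like', receiving concordant
exon-local enrichment of H3K9ac/H3K27ac/H3K4me3 in the higher-inclusion
cell only, with a mild anti-correlated dip in the control track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import AnnotationModel, Transcript
from .intervals import ExonRecord, GenomicInterval
from .tracks import SignalTrack

MARKS = ("H3K9ac", "H3K27ac", "H3K4me3", "CTCF", "control")
PROMOTER_MARKS = ("H3K9ac", "H3K27ac", "H3K4me3")
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    depth is the mean junction-spanning read count per junction per
    replicate (for a fully used intron); mark_effect is the planted log2
    enrichment in units of the baseline noise SD.
    """

    n_genes: int = 80
    exons_per_gene: int = 5
    cells: tuple = ("cellA", "cellB")
    replicates: int = 2
    depth: float = 50.0
    frac_regulated: float = 0.03
    delta_psi_range: tuple = (0.2, 0.5)
    frac_promoter_like: float = 0.04
    mark_effect: float = 2.0
    noise_sd: float = 1.0
    baseline_log2: float = 3.0
    tss_effect: float = 4.0
    control_effect: float = -1.0
    bin_size: int = 25
    intron_len_range: tuple = (700, 1200)
    exon_len_range: tuple = (80, 300)
    flank_exon_len: int = 150
    gene_gap: int = 2500
    alt_tss_fraction: float = 0.45
    alt_tss_offset: int = 300
    link_prob_higher: float = 0.9
    link_prob_lower: float = 0.3
    share_state_fraction: float = 0.4
    min_regulated: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.exons_per_gene < 4:
            raise ValueError("need >= 4 exons per gene for internal cassette exons")
        for frac in (self.frac_regulated, self.frac_promoter_like):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class SimBundle:
    """In-memory view of a generated bundle plus its ground truth."""

    config: SimConfig
    genome: dict  # chrom -> sequence string
    model: AnnotationModel
    exons: dict  # exon_id -> ExonRecord (cassette + constitutive internal)
    truth: pd.DataFrame
    counts: pd.DataFrame = None  # junction table (long format)
    tracks: dict = field(default_factory=dict)  # cell -> mark -> SignalTrack
    cage: dict = field(default_factory=dict)  # cell -> [CageCluster]
    links: dict = field(default_factory=dict)  # cell -> [ChiaPetLink]
    segmentation: dict = field(default_factory=dict)  # cell -> DataFrame
    mappability: SignalTrack = None
    gene_tss: dict = field(default_factory=dict)


def _random_seq(rng, n) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)].copy()


def generate_genome_annotation(config: SimConfig, rng=None):
    """Genome + annotation with one cassette exon per gene.

    Every gene has ``exons_per_gene`` exons on alternating strands, with
    GT..AG introns, internal exon lengths inside [50, 450] and first/last
    introns long enough that internal exons sit >= 600 nt from the TSS/TTS.
    Two transcripts per gene: one including and one skipping the cassette
    exon (the middle internal exon), so the cassette exon is internal in
    every transcript containing it.

    Returns ``(genome, model, exons, gene_info)``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cfg = config
    chrom = "chr1"
    seq_parts = []
    pos = cfg.gene_gap
    prefix = _random_seq(rng, pos)
    seq_parts.append(prefix)
    transcripts = {}
    exons: dict = {}
    gene_info = []
    for g in range(cfg.n_genes):
        gid = f"G{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        n_ex = cfg.exons_per_gene
        lens = [cfg.flank_exon_len]
        lens += list(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_ex - 2))
        lens.append(cfg.flank_exon_len)
        intron_lens = list(
            rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, n_ex - 1)
        )
        ivs = []
        p = pos
        for i, L in enumerate(lens):
            ivs.append(GenomicInterval(chrom, p, p + int(L), strand))
            p += int(L)
            if i < n_ex - 1:
                p += int(intron_lens[i])
        gene_seq = _random_seq(rng, p - pos)
        # canonical splice dinucleotides on the genomic strand
        for i in range(n_ex - 1):
            i_start = ivs[i].end - pos
            i_end = ivs[i + 1].start - pos
            if strand == "+":
                gene_seq[i_start : i_start + 2] = list("GT")
                gene_seq[i_end - 2 : i_end] = list("AG")
            else:
                gene_seq[i_start : i_start + 2] = list("CT")
                gene_seq[i_end - 2 : i_end] = list("AC")
        seq_parts.append(gene_seq)
        gap = _random_seq(rng, cfg.gene_gap)
        seq_parts.append(gap)

        cassette_idx = n_ex // 2
        ivs_t = tuple(ivs)
        t_full = Transcript(f"{gid}.t1", gid, chrom, strand, ivs_t)
        skip_ivs = tuple(iv for i, iv in enumerate(ivs) if i != cassette_idx)
        t_skip = Transcript(f"{gid}.t2", gid, chrom, strand, skip_ivs)
        transcripts[t_full.transcript_id] = t_full
        transcripts[t_skip.transcript_id] = t_skip

        # exon records with flanking junctions for all internal exons
        for i in range(1, n_ex - 1):
            iv = ivs[i]
            left = (ivs[i - 1].end, iv.start)
            right = (iv.end, ivs[i + 1].start)
            up, down = (left, right) if strand == "+" else (right, left)
            member = (
                frozenset([t_full.transcript_id])
                if i == cassette_idx
                else frozenset([t_full.transcript_id, t_skip.transcript_id])
            )
            rec = ExonRecord(iv, gid, member, up, down)
            exons[rec.exon_id] = rec
        cassette_iv = ivs[cassette_idx]
        gene_info.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "tss": t_full.tss,
                "tts": t_full.tts,
                "cassette_exon_id": f"{chrom}:{cassette_iv.start}-{cassette_iv.end}:{strand}",
            }
        )
        pos = p + cfg.gene_gap
    genome = {chrom: "".join("".join(part) for part in seq_parts)}
    model = AnnotationModel(transcripts)
    return genome, model, exons, pd.DataFrame(gene_info)


def _plant_truth(config: SimConfig, exons: dict, gene_info: pd.DataFrame, rng) -> pd.DataFrame:
    cfg = config
    cell1, cell2 = cfg.cells[0], cfg.cells[1]
    cassette_ids = list(gene_info["cassette_exon_id"])
    rows = []
    n_reg = max(cfg.min_regulated, int(round(cfg.frac_regulated * len(cassette_ids))))
    n_reg = min(n_reg, len(cassette_ids))
    reg_ids = set(rng.choice(cassette_ids, size=n_reg, replace=False))
    n_pl = int(round(cfg.frac_promoter_like * n_reg))
    pl_ids = set(rng.choice(sorted(reg_ids), size=n_pl, replace=False)) if n_pl else set()
    cassette_set = set(cassette_ids)
    for eid, rec in sorted(exons.items()):
        is_cassette = eid in cassette_set
        if is_cassette:
            base = float(rng.uniform(0.25, 0.75))
            psis = {c: base for c in cfg.cells}
            regulated = eid in reg_ids
            direction = ""
            if regulated:
                delta = float(rng.uniform(*cfg.delta_psi_range))
                sign = 1 if rng.random() < 0.5 else -1
                lo, hi = 0.05, 0.95
                base = float(np.clip(base, lo, hi - delta) if sign > 0 else np.clip(base, lo + delta, hi))
                psis = {c: base for c in cfg.cells}
                psis[cell2] = base + sign * delta
                direction = "more" if sign > 0 else "less"
        else:
            psis = {c: 1.0 for c in cfg.cells}
            regulated = False
            direction = ""
        promoter_like = eid in pl_ids
        c_higher = ""
        if regulated:
            c_higher = cell2 if psis[cell2] > psis[cell1] else cell1
        rows.append(
            {
                "exon_id": eid,
                "gene_id": rec.gene_id,
                "is_cassette": is_cassette,
                "regulated": regulated,
                "direction": direction,
                "promoter_like": promoter_like,
                "c_higher": c_higher,
                **{f"psi_{c}": psis[c] for c in cfg.cells},
            }
        )
    return pd.DataFrame(rows)


def simulate_inclusion_counts(psi_by_cell: pd.DataFrame, depth: float, replicates: int, rng,
                              gene_ids=None) -> pd.DataFrame:
    """Junction-level counts from true psi values (no genomic coordinates).

    ``depth`` is the mean junction-spanning read count per junction.  Each
    inclusion junction draws Poisson(psi * depth) reads and the exclusion
    junction Poisson((1 - psi) * depth), so the inclusion-level estimator is
    centred on the true psi.  By Poisson thinning this is the same law as
    drawing the locus total ~ Poisson((1 + psi) * depth), splitting
    inclusion reads ~ Binomial(total, w) with w = 2*psi / (1 + psi) (the
    weight obtained by inverting the inclusion-level formula) and dividing
    them Binomial(0.5) between the two inclusion junctions.
    ``psi_by_cell``: rows = exon ids, columns = cell names.
    """
    rows = []
    cells = list(psi_by_cell.columns)
    exon_ids = list(psi_by_cell.index)
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g_{e}" for e in exon_ids]
    for cell in cells:
        psi = psi_by_cell[cell].to_numpy(dtype=float)
        for rep in range(1, replicates + 1):
            up = rng.poisson(psi * depth)
            down = rng.poisson(psi * depth)
            excl = rng.poisson((1 - psi) * depth)
            rows.append(
                pd.DataFrame(
                    {
                        "exon_id": exon_ids,
                        "gene_id": gene_ids,
                        "cell": cell,
                        "replicate": str(rep),
                        "jir_up": up,
                        "jir_down": down,
                        "jer": excl,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_junction_counts(truth: pd.DataFrame, model: AnnotationModel,
                             gene_info: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    """Long-format junction table (chrom, intron_start, intron_end, strand,
    cell, replicate, count), coherent at the transcript level.

    Each gene's inclusion isoform has abundance psi * depth and its skipping
    isoform (1 - psi) * depth; every intron of an isoform receives a
    Poisson-distributed read count at that abundance.  Introns shared by
    both isoforms then carry Poisson(depth) reads, the cassette-flanking
    introns Poisson(psi * depth) and the skip junction
    Poisson((1 - psi) * depth), so the inclusion-level estimator is centred
    on the true psi without double counting between neighbouring exons.
    """
    cfg = config
    psi_by_gene = {
        r.gene_id: {c: getattr(r, f"psi_{c}") for c in cfg.cells}
        for r in truth[truth["is_cassette"]].itertuples(index=False)
    }
    acc: dict = {}
    for g in gene_info.itertuples(index=False):
        t_full = model.transcripts[f"{g.gene_id}.t1"]
        t_skip = model.transcripts[f"{g.gene_id}.t2"]
        for cell in cfg.cells:
            psi = psi_by_gene[g.gene_id][cell]
            for t, abundance in ((t_full, psi * cfg.depth), (t_skip, (1 - psi) * cfg.depth)):
                for a, b in zip(t.exons[:-1], t.exons[1:]):
                    span = (a.end, b.start)
                    for rep in range(1, cfg.replicates + 1):
                        key = (g.chrom, span[0], span[1], g.strand, cell, str(rep))
                        n = int(rng.poisson(abundance)) if abundance > 0 else 0
                        acc[key] = acc.get(key, 0) + n
    rows = [(*k, v) for k, v in sorted(acc.items())]
    return pd.DataFrame(
        rows,
        columns=["chrom", "intron_start", "intron_end", "strand", "cell", "replicate", "count"],
    )


def simulate_signal_tracks(truth: pd.DataFrame, exons: dict, gene_info: pd.DataFrame,
                           config: SimConfig, rng, chrom_len: int) -> dict:
    """Per-mark, per-cell piecewise-constant tracks.

    Baseline: per-bin log2 values ~ N(baseline_log2, noise_sd), independent
    across bins, marks and cells.  Promoter-like exons get exon-local
    additive log2 enrichment (+mark_effect * noise_sd) on the three promoter
    marks in the C-higher cell only, and a mild anti-correlated dip on the
    control track; annotated TSSs get a large enrichment in all cells.
    Enrichment is confined to bins overlapping the exon, never its flanks.
    """
    cfg = config
    chrom = "chr1"
    n_bins = int(np.ceil(chrom_len / cfg.bin_size))
    edges = np.arange(n_bins + 1) * cfg.bin_size
    edges[-1] = max(edges[-1], chrom_len)
    starts, ends = edges[:-1], edges[1:]
    tss_mask = np.zeros(n_bins, dtype=bool)
    for tss in gene_info["tss"]:
        lo = max(0, (tss - 200) // cfg.bin_size)
        hi = min(n_bins, (tss + 200) // cfg.bin_size + 1)
        tss_mask[lo:hi] = True
    pl = truth[truth["promoter_like"]]
    exon_masks = {}
    for r in pl.itertuples(index=False):
        iv = exons[r.exon_id].interval
        lo = iv.start // cfg.bin_size
        hi = min(n_bins, int(np.ceil(iv.end / cfg.bin_size)))
        exon_masks[r.exon_id] = (slice(lo, hi), r.c_higher)
    tracks: dict = {}
    for cell in cfg.cells:
        tracks[cell] = {}
        for mark in MARKS:
            log2v = rng.normal(cfg.baseline_log2, cfg.noise_sd, size=n_bins)
            if mark in PROMOTER_MARKS:
                log2v[tss_mask] += cfg.tss_effect
            for _eid, (sl, c_higher) in exon_masks.items():
                if cell != c_higher:
                    continue
                if mark in PROMOTER_MARKS:
                    log2v[sl] += cfg.mark_effect * cfg.noise_sd
                elif mark == "control":
                    log2v[sl] += cfg.control_effect
            tracks[cell][mark] = SignalTrack({chrom: (starts, ends, np.power(2.0, log2v))})
    return tracks


def simulate_cage_and_links(truth: pd.DataFrame, exons: dict, gene_info: pd.DataFrame,
                            config: SimConfig, rng):
    """CAGE clusters, ChIA-PET links and chromHMM segmentations per cell.

    CAGE clusters with score >= 1 appear at used TSSs only; for a fraction
    of promoter-like exons the C-higher cell uses an alternative TSS closer
    to the exon.  Promoter-like exons get Pol-II loops (links) to their used
    TSS with higher probability in C-higher than C-lower, and a fraction of
    them share a chromatin-state run with their TSS.  Returns
    ``(cage, links, segmentation, used_tss, truth)`` with per-cell dicts;
    ``used_tss`` maps cell -> {exon_id -> tss position} and truth gains
    alt-TSS bookkeeping columns.
    """
    from .context import CageCluster, ChiaPetLink

    cfg = config
    chrom = "chr1"
    truth = truth.copy()
    gene_tss = dict(zip(gene_info["gene_id"], gene_info["tss"]))
    pl = truth[truth["promoter_like"]]
    alt = {}
    for r in pl.itertuples(index=False):
        alt[r.exon_id] = bool(rng.random() < cfg.alt_tss_fraction)
    truth["alt_tss"] = truth["exon_id"].map(lambda e: alt.get(e, False))

    base_score = {g: float(10 ** rng.uniform(0.5, 2.0)) for g in gene_info["gene_id"]}
    cage: dict = {}
    used_tss: dict = {}
    links: dict = {}
    seg: dict = {}
    share = {r.exon_id: bool(rng.random() < cfg.share_state_fraction) for r in pl.itertuples(index=False)}
    link_draws = {
        (r.exon_id, cell): bool(
            rng.random() < (cfg.link_prob_higher if cell == r.c_higher else cfg.link_prob_lower)
        )
        for r in pl.itertuples(index=False)
        for cell in cfg.cells
    }
    for cell in cfg.cells:
        clusters = []
        for g in gene_info.itertuples(index=False):
            score = base_score[g.gene_id] * float(2 ** rng.normal(0, 0.3))
            tss = g.tss
            clusters.append(CageCluster(GenomicInterval(chrom, max(0, tss - 5), tss + 6), score))
        cell_used = {}
        cell_links = []
        for r in pl.itertuples(index=False):
            iv = exons[r.exon_id].interval
            gene_tss_pos = gene_tss[r.gene_id]
            tss_pos = gene_tss_pos
            if alt[r.exon_id] and cell == r.c_higher:
                off = cfg.alt_tss_offset
                tss_pos = iv.start - off if iv.strand == "+" else iv.end + off
                tss_pos = max(10, tss_pos)
                clusters.append(
                    CageCluster(GenomicInterval(chrom, tss_pos - 5, tss_pos + 6), 5.0)
                )
            cell_used[r.exon_id] = tss_pos
            if link_draws[(r.exon_id, cell)]:
                cell_links.append(
                    ChiaPetLink(
                        GenomicInterval(chrom, iv.start, iv.end),
                        GenomicInterval(chrom, max(0, tss_pos - 100), tss_pos + 100),
                        int(rng.integers(1, 6)),
                    )
                )
        cage[cell] = clusters
        used_tss[cell] = cell_used
        links[cell] = cell_links
        # segmentation: promoter state around each TSS, quiescent elsewhere;
        # for sharing exons the promoter state extends TSS <-> exon
        bounds = []
        for g in gene_info.itertuples(index=False):
            bounds.append((max(0, g.tss - 500), g.tss + 500))
        for r in pl.itertuples(index=False):
            if share[r.exon_id]:
                iv = exons[r.exon_id].interval
                t = cell_used[r.exon_id]
                bounds.append((max(0, min(iv.start, t) - 50), max(iv.end, t) + 50))
        bounds.sort()
        merged = []
        for s, e in bounds:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        rows = []
        pos = 0
        for s, e in merged:
            if pos < s:
                rows.append({"chrom": chrom, "start": pos, "end": s, "state": "Quies"})
            rows.append({"chrom": chrom, "start": s, "end": e, "state": "Tss"})
            pos = e
        rows.append({"chrom": chrom, "start": pos, "end": pos + 10_000_000, "state": "Quies"})
        seg[cell] = pd.DataFrame(rows)
    expr_rows = {
        cell: {
            g.gene_id: sum(c.score for c in cage[cell] if c.interval.distance_to_point(g.tss) <= 100)
            for g in gene_info.itertuples(index=False)
        }
        for cell in cfg.cells
    }
    truth["used_tss"] = truth["exon_id"].map(
        lambda e: ";".join(f"{c}={used_tss[c][e]}" for c in cfg.cells) if e in alt else ""
    )
    return cage, links, seg, used_tss, expr_rows, truth


def simulate_delta_matrix(n_per_direction: int, n_planted: int, effect: float, seed: int,
                          features=MARKS, control_effect: float = -0.5):
    """Differential-signal matrices with a planted promoter-like subset.

    For each direction group, rows ~ N(0, 1) per feature; the first
    ``n_planted`` rows get a concordant shift of ``effect`` SD on the three
    promoter marks (positive for more-included, negative for less-included)
    and ``control_effect * effect`` on the control column.  Returns
    ``(delta_by_direction, planted_ids)``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    planted: dict = {}
    for direction, sign in (("more", 1.0), ("less", -1.0)):
        X = rng.normal(0, 1, size=(n_per_direction, len(features)))
        df = pd.DataFrame(
            X, columns=list(features),
            index=[f"{direction}_{i}" for i in range(n_per_direction)],
        )
        ids = list(df.index[:n_planted])
        for m in PROMOTER_MARKS:
            if m in df.columns:
                df.loc[ids, m] += sign * effect
        if "control" in df.columns:
            df.loc[ids, "control"] += sign * control_effect * effect
        out[direction] = df
        planted[direction] = set(ids)
    return out, planted


def simulate_holdout(n: int, concordance: float, seed: int,
                     delta_psi_range=(0.15, 0.5), chromatin_range=(1.2, 3.0)):
    """Held-out cell-pair data with planted sign concordance.

    Every exon is eligible (|delta_psi| and |total chromatin| above the
    validation cutoffs); each exon's total chromatin difference agrees in
    sign with its inclusion change with probability ``concordance``.
    """
    rng = np.random.default_rng(seed)
    dpsi = rng.uniform(*delta_psi_range, size=n) * rng.choice([-1, 1], size=n)
    agree = rng.random(n) < concordance
    mag = rng.uniform(*chromatin_range, size=n)
    dchrom = np.where(agree, np.sign(dpsi), -np.sign(dpsi)) * mag
    return dpsi, dchrom


def simulate_bundle(config: SimConfig = None, out_dir=None) -> SimBundle:
    """Generate the full synthetic bundle; optionally write it to disk.

    Files written (all plain text): genome.fa, annotation.gtf,
    junctions.tsv, mappability.bedGraph, truth.tsv, per-cell
    tracks/<cell>.<mark>.bedGraph, cage.<cell>.bed, links.<cell>.bedpe,
    chromhmm.<cell>.bed.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome, model, exons, gene_info = generate_genome_annotation(cfg, rng)
    truth = _plant_truth(cfg, exons, gene_info, rng)
    counts = simulate_junction_counts(truth, model, gene_info, cfg, rng)
    chrom_len = len(genome["chr1"])
    tracks = simulate_signal_tracks(truth, exons, gene_info, cfg, rng, chrom_len)
    cage, links, seg, used_tss, expr, truth = simulate_cage_and_links(
        truth, exons, gene_info, cfg, rng
    )
    mappability = SignalTrack.constant({"chr1": chrom_len}, 1.0)
    gene_tss = {
        g.gene_id: [(g.chrom, g.strand, g.tss)] for g in gene_info.itertuples(index=False)
    }
    bundle = SimBundle(
        config=cfg, genome=genome, model=model, exons=exons, truth=truth,
        counts=counts, tracks=tracks, cage=cage, links=links, segmentation=seg,
        mappability=mappability, gene_tss=gene_tss,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SimBundle, out_dir) -> None:
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in bundle.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(out / "annotation.gtf", "w") as fh:
        for tid in sorted(bundle.model.transcripts):
            t = bundle.model.transcripts[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\tsim\ttranscript\t{t.exons[0].start + 1}\t{t.exons[-1].end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for iv in t.exons:
                fh.write(
                    f"{t.chrom}\tsim\texon\t{iv.start + 1}\t{iv.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
    bundle.counts.to_csv(out / "junctions.tsv", sep="\t", index=False)
    bundle.mappability.to_bedgraph(out / "mappability.bedGraph")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for cell, marks in bundle.tracks.items():
        for mark, track in marks.items():
            track.to_bedgraph(out / "tracks" / f"{cell}.{mark}.bedGraph")
    for cell, clusters in bundle.cage.items():
        with open(out / f"cage.{cell}.bed", "w") as fh:
            for i, c in enumerate(clusters):
                fh.write(
                    f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\tcage{i}\t{c.score:.6g}\t{c.interval.strand}\n"
                )
    for cell, lks in bundle.links.items():
        with open(out / f"links.{cell}.bedpe", "w") as fh:
            for i, ln in enumerate(lks):
                fh.write(
                    f"{ln.anchor1.chrom}\t{ln.anchor1.start}\t{ln.anchor1.end}\t"
                    f"{ln.anchor2.chrom}\t{ln.anchor2.start}\t{ln.anchor2.end}\tlink{i}\t{ln.support}\n"
                )
    for cell, seg in bundle.segmentation.items():
        seg.to_csv(out / f"chromhmm.{cell}.bed", sep="\t", index=False, header=False)
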