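"""Candidate cassette-exon catalog from a GTF annotation and genome FASTA.

The catalog holds internal exons that could act as cassette (skipped) exons:
internal in every transcript they appear in, not overlapped by any
non-identical annotated exon, 50-450 bp long, at least 600 nt from every
annotated TSS/TTS of their gene, flanked by canonical GT..AG introns, and on
chromosomes 1-22 or X.  Context utilities (exon triplets, TSS distance,
mappability fraction, splice-site strength) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import ExonRecord, GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_CHROMS = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X"]) + tuple(
    str(i) for i in list(range(1, 23)) + ["X"]
)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_seq(genome, chrom, start, end) -> str:
    """Uppercase genomic sequence [start, end); genome is a pyfaidx.Fasta
    or a plain mapping of chromosome name to sequence string."""
    seq = genome[chrom][start:end]
    if not isinstance(seq, str):
        seq = str(seq)
    return seq.upper()


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # GenomicInterval, sorted by genomic start

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    @property
    def tts(self) -> int:
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start

    def exons_in_transcription_order(self) -> tuple:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass
class AnnotationModel:
    """Per-transcript exon structures plus gene membership."""

    transcripts: dict  # transcript_id -> Transcript
    genes: dict = field(default_factory=dict)  # gene_id -> [transcript_id]

    def __post_init__(self):
        if not self.genes:
            for t in self.transcripts.values():
                self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self):
        return len(self.transcripts)

    def distinct_exons(self):
        """All distinct (chrom, start, end, strand) exon intervals."""
        seen = {}
        for t in self.transcripts.values():
            for iv in t.exons:
                seen[(iv.chrom, iv.start, iv.end, iv.strand)] = iv
        return list(seen.values())

    def gene_tss_set(self):
        """gene_id -> list of (chrom, strand, tss_position)."""
        out = {}
        for gid, tids in self.genes.items():
            out[gid] = [
                (self.transcripts[t].chrom, self.transcripts[t].strand, self.transcripts[t].tss)
                for t in tids
            ]
        return out


def _validate_gtf_lines(gtf_path):
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from None
            if start > end:
                raise AnnotationError(f"malformed GTF line {lineno}: start > end")


def load_annotation(gtf_path, fasta_path=None) -> AnnotationModel:
    """Parse a GENCODE-style GTF into per-transcript exon structures.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    If ``fasta_path`` is given, every referenced chromosome must be present
    in the FASTA; a missing chromosome is a hard error.
    """
    import gffutils

    _validate_gtf_lines(gtf_path)
    with open(gtf_path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        return AnnotationModel({})
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes["gene_id"][0]
        iv = GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
        by_transcript.setdefault(tid, (gid, []))[1].append(iv)

    transcripts = {}
    for tid, (gid, exons) in by_transcript.items():
        exons = tuple(sorted(set(exons), key=lambda iv: (iv.start, iv.end)))
        transcripts[tid] = Transcript(tid, gid, exons[0].chrom, exons[0].strand, exons)

    model = AnnotationModel(transcripts)
    if fasta_path is not None:
        import pyfaidx

        genome = pyfaidx.Fasta(str(fasta_path))
        for t in transcripts.values():
            if t.chrom not in genome:
                raise AnnotationError(
                    f"chromosome {t.chrom!r} referenced by transcript "
                    f"{t.transcript_id} is absent from the FASTA"
                )
    return model


def _intron_is_canonical(genome, chrom, intron_start, intron_end, strand) -> bool:
    """GT at the donor, AG at the acceptor, strand-aware."""
    if intron_end - intron_start < 4:
        return False
    left = fetch_seq(genome, chrom, intron_start, intron_start + 2)
    right = fetch_seq(genome, chrom, intron_end - 2, intron_end)
    if strand == "+":
        return left == "GT" and right == "AG"
    return right == "AC" and left == "CT"  # revcomp of GT..AG


def _member_context(model: AnnotationModel):
    """Map exon key -> list of (transcript, index) memberships."""
    members: dict = {}
    for t in model.transcripts.values():
        for i, iv in enumerate(t.exons):
            members.setdefault((iv.chrom, iv.start, iv.end, iv.strand), []).append((t, i))
    return members


def select_candidate_exons(
    model: AnnotationModel,
    genome,
    min_tss_tts_distance: int = 600,
    min_len: int = 50,
    max_len: int = 450,
    chroms=DEFAULT_CHROMS,
    tss_scope: str = "gene",
) -> list:
    """Return :class:`ExonRecord` for every exon passing all catalog criteria.

    ``tss_scope`` controls the 600-nt TSS/TTS rule: ``"gene"`` (default,
    strictest) checks every transcript of the host gene; ``"member"`` only
    the transcripts containing the exon.
    """
    if tss_scope not in ("gene", "member"):
        raise ValueError("tss_scope must be 'gene' or 'member'")
    allowed = set(chroms)
    members = _member_context(model)

    # per-chromosome exon coordinate arrays for the overlap check
    by_chrom: dict = {}
    for iv in model.distinct_exons():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in by_chrom:
        coords = sorted(set(by_chrom[chrom]))
        arr = np.array(coords, dtype=np.int64).reshape(-1, 2)
        by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    records = []
    for key, ctx in sorted(members.items()):
        chrom, start, end, strand = key
        iv = GenomicInterval(chrom, start, end, strand)
        if chrom not in allowed:
            continue
        if not (min_len <= iv.length <= max_len):
            continue
        # internal in every member transcript
        if any(i == 0 or i == len(t.exons) - 1 for t, i in ctx):
            continue
        # not overlapped by any non-identical annotated exon (strand-blind)
        starts_arr, ends_arr = by_chrom[chrom]
        hits = (starts_arr < end) & (ends_arr > start)
        hits &= ~((starts_arr == start) & (ends_arr == end))
        if bool(hits.any()):
            continue
        # TSS/TTS distance
        if tss_scope == "gene":
            gene_ids = {t.gene_id for t, _ in ctx}
            check_transcripts = [
                model.transcripts[tid] for gid in gene_ids for tid in model.genes[gid]
            ]
        else:
            check_transcripts = [t for t, _ in ctx]
        too_close = any(
            iv.distance_to_point(p) < min_tss_tts_distance
            for t in check_transcripts
            for p in (t.tss, t.tts)
        )
        if too_close:
            continue
        # canonical AG-GT flanking introns in every member transcript
        ok = True
        for t, i in ctx:
            left_intron = (t.exons[i - 1].end, start)
            right_intron = (end, t.exons[i + 1].start)
            if not (
                _intron_is_canonical(genome, chrom, *left_intron, strand)
                and _intron_is_canonical(genome, chrom, *right_intron, strand)
            ):
                ok = False
                break
        if not ok:
            continue

        ref_t, ref_i = min(ctx, key=lambda ti: ti[0].transcript_id)
        left = (ref_t.exons[ref_i - 1].end, start)
        right = (end, ref_t.exons[ref_i + 1].start)
        up, down = (left, right) if strand == "+" else (right, left)
        records.append(
            ExonRecord(
                interval=iv,
                gene_id=ref_t.gene_id,
                transcript_ids=frozenset(t.transcript_id for t, _ in ctx),
                upstream_junction=up,
                downstream_junction=down,
            )
        )
    return records


def mappable_fraction(exon: ExonRecord, mappability_track, window: int = 900, threshold: float = 1.0):
    """Fraction of uniquely mappable positions in a window centred on the
    exon's acceptor site.

    The acceptor is the exon's 5' end in transcription direction.  Track
    positions with value < ``threshold`` count as unmappable.  If the window
    extends past the recorded chromosome extent it is truncated and the
    fraction computed over the available positions.
    """
    iv = exon.interval
    acceptor = iv.five_prime
    half = window // 2
    start = max(0, acceptor - half)
    end = acceptor + window - half
    chrom_len = mappability_track.chrom_length(iv.chrom)
    if chrom_len:
        end = min(end, chrom_len)
    if end <= start:
        return float("nan")
    vals = mappability_track.values(iv.chrom, start, end)
    return float(np.mean(vals >= threshold))


@dataclass(frozen=True)
class ExonTriplet:
    """A regulated exon with its nearest non-regulated flanking exons."""

    regulated: ExonRecord
    upstream: GenomicInterval = None  # transcription direction
    downstream: GenomicInterval = None
    cell_pair: tuple = None

    @property
    def complete(self) -> bool:
        return self.upstream is not None and self.downstream is not None


def build_exon_triplets(regulated_exon: ExonRecord, inclusion_results, model: AnnotationModel,
                        alpha: float = 0.05, cell_pair=None) -> ExonTriplet:
    """Nearest up-/downstream exons that share a transcript with the
    regulated exon and are not significantly regulated themselves.

    ``inclusion_results`` maps exon id (``chrom:start-end:strand``) to the
    minimum BH q over the two test tails; exons absent from the mapping
    (untestable) qualify as flanks.  A side with no qualifying flank is left
    ``None`` and the triplet is incomplete.
    """
    iv = regulated_exon.interval

    def qualifies(flank_iv: GenomicInterval) -> bool:
        q = inclusion_results.get(f"{flank_iv.chrom}:{flank_iv.start}-{flank_iv.end}:{flank_iv.strand}")
        return q is None or q >= alpha

    best_left = best_right = None
    for tid in regulated_exon.transcript_ids:
        t = model.transcripts[tid]
        try:
            i = t.exons.index(iv)
        except ValueError:
            continue
        for j in range(i - 1, -1, -1):
            if qualifies(t.exons[j]):
                if best_left is None or t.exons[j].end > best_left.end:
                    best_left = t.exons[j]
                break
        for j in range(i + 1, len(t.exons)):
            if qualifies(t.exons[j]):
                if best_right is None or t.exons[j].start < best_right.start:
                    best_right = t.exons[j]
                break
    if iv.strand == "+":
        up, down = best_left, best_right
    else:
        up, down = best_right, best_left
    return ExonTriplet(regulated_exon, up, down, cell_pair)


def distance_to_annotated_tss(exon: ExonRecord, model: AnnotationModel) -> int:
    """Minimum genomic distance from the exon's first nucleotide (5' end in
    transcription direction) to the TSS over all member transcripts."""
    first_nt = exon.interval.five_prime
    dists = [
        abs(first_nt - model.transcripts[tid].tss)
        for tid in exon.transcript_ids
        if tid in model.transcripts
    ]
    if not dists:
        raise ValueError(f"exon {exon.exon_id} has no member transcript in the model")
    return min(dists)


class PwmScorer:
    """Log-odds position-weight-matrix splice-site scorer.

    Window conventions follow maxEnt: donor 9 nt (3 exonic + 6 intronic),
    acceptor 23 nt (20 intronic + 3 exonic), both read in transcription
    direction.  Matrices are (length x 4) probability arrays over A,C,G,T;
    scores are summed log2(p / background).  A window containing N scores
    as ``nan`` (undefined).
    """

    DONOR_EXONIC = 3
    DONOR_LEN = 9
    ACCEPTOR_INTRONIC = 20
    ACCEPTOR_LEN = 23
    _IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(self, donor_pwm=None, acceptor_pwm=None, background=0.25):
        self.donor_pwm = (
            np.full((self.DONOR_LEN, 4), 0.25) if donor_pwm is None else np.asarray(donor_pwm, float)
        )
        self.acceptor_pwm = (
            np.full((self.ACCEPTOR_LEN, 4), 0.25)
            if acceptor_pwm is None
            else np.asarray(acceptor_pwm, float)
        )
        self.background = background

    def _score(self, seq: str, pwm: np.ndarray):
        if len(seq) != pwm.shape[0] or any(b not in self._IDX for b in seq):
            return float("nan")
        idx = [self._IDX[b] for b in seq]
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log2(pwm[np.arange(len(seq)), idx] / self.background)))

    def donor_score(self, seq: str):
        return self._score(seq, self.donor_pwm)

    def acceptor_score(self, seq: str):
        return self._score(seq, self.acceptor_pwm)


def splice_site_strength(exon: ExonRecord, genome, scorer: PwmScorer):
    """Exon strength = donor score + acceptor score.

    Returns ``nan`` when either window contains an undetermined base; such
    exons are excluded from strength comparisons.
    """
    iv = exon.interval
    de, dl = scorer.DONOR_EXONIC, scorer.DONOR_LEN
    ai, al = scorer.ACCEPTOR_INTRONIC, scorer.ACCEPTOR_LEN
    if iv.strand == "+":
        donor_seq = fetch_seq(genome, iv.chrom, iv.end - de, iv.end - de + dl)
        acceptor_seq = fetch_seq(genome, iv.chrom, iv.start - ai, iv.start - ai + al)
    else:
        donor_seq = revcomp(fetch_seq(genome, iv.chrom, iv.start + de - dl, iv.start + de))
        acceptor_seq = revcomp(fetch_seq(genome, iv.chrom, iv.end + ai - al, iv.end + ai))
    return scorer.donor_score(donor_seq) + scorer.acceptor_score(acceptor_seq)


def catalog_to_dataframe(records):
    """Tabular view of the exon catalog (one row per exon)."""
    import pandas as pd

    rows = []
    for r in records:
        iv = r.interval
        rows.append(
            {
                "exon_id": r.exon_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "gene_id": r.gene_id,
                "transcript_ids": ",".join(sorted(r.transcript_ids)),
                "up_intron_start": r.upstream_junction[0],
                "up_intron_end": r.upstream_junction[1],
                "down_intron_start": r.downstream_junction[0],
                "down_intron_end": r.downstream_junction[1],
            }
        )
    return pd.DataFrame(rows)
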