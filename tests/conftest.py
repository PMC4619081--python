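"""Shared fixtures: handcrafted annotation builders and random-model helpers.

All fixture data is generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from exonchrom.catalog import AnnotationModel, Transcript
from exonchrom.intervals import GenomicInterval


def write_annotation(tmp_path, genes, chrom_len=20000, chrom="chr1", planted=(),
                     fasta_name="genome.fa", gtf_name="toy.gtf"):
    """Write a handcrafted GTF + FASTA pair.

    ``genes``: list of dicts with gene_id, strand, exons=[(start, end), ...]
    (0-based half-open, genomic order) and transcripts=[[exon indices], ...].
    Canonical splice dinucleotides are planted for every implied intron;
    ``planted`` entries (pos, "XX") override sequence afterwards (e.g. to
    break a splice site).
    """
    seq = np.array(list("A" * chrom_len))
    lines = []
    for g in genes:
        for ti, idxs in enumerate(g["transcripts"], start=1):
            tid = f"{g['gene_id']}.t{ti}"
            exons = [g["exons"][i] for i in idxs]
            attrs = f'gene_id "{g["gene_id"]}"; transcript_id "{tid}";'
            for s, e in exons:
                lines.append(
                    f"{chrom}\ttest\texon\t{s + 1}\t{e}\t.\t{g['strand']}\t.\t{attrs}"
                )
            for (_, e1), (s2, _) in zip(exons[:-1], exons[1:]):
                if g["strand"] == "+":
                    seq[e1 : e1 + 2] = list("GT")
                    seq[s2 - 2 : s2] = list("AG")
                else:
                    seq[e1 : e1 + 2] = list("CT")
                    seq[s2 - 2 : s2] = list("AC")
    for pos, dinuc in planted:
        seq[pos : pos + len(dinuc)] = list(dinuc)
    gtf = tmp_path / gtf_name
    gtf.write_text("\n".join(lines) + ("\n" if lines else ""))
    fasta = tmp_path / fasta_name
    s = "".join(seq)
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")
    return gtf, fasta


@pytest.fixture
def criteria_fixture(tmp_path):
    """Hand-enumerable catalog fixture: exactly two exons pass all criteria.

    GA (+): A1 (1000-1100) and A2 (1800-1900) pass; A3 is 700 bp (too
    long), A4 is 40 bp (too short), A5 has its donor broken to GC.
    GB (+): B1 is 300 nt from the TSS (< 600).
    GC (+): C1 is internal in t1 but first in t2 (not internal in all).
    GD (+): D1 and D1b overlap non-identically (both excluded); D2 sits
    400 nt from the TTS (< 600).
    """
    genes = [
        {
            "gene_id": "GA",
            "strand": "+",
            "exons": [
                (100, 200), (1000, 1100), (1800, 1900), (2600, 3300),
                (4100, 4140), (4800, 4900), (5600, 5700),
            ],
            "transcripts": [[0, 1, 2, 3, 4, 5, 6]],
        },
        {
            "gene_id": "GB",
            "strand": "+",
            "exons": [(7000, 7100), (7300, 7400), (8600, 8700)],
            "transcripts": [[0, 1, 2]],
        },
        {
            "gene_id": "GC",
            "strand": "+",
            "exons": [(12000, 12100), (12800, 12900), (13600, 13700)],
            "transcripts": [[0, 1, 2], [1, 2]],
        },
        {
            "gene_id": "GD",
            "strand": "+",
            "exons": [
                (15000, 15100), (15800, 15900), (15790, 15910),
                (16600, 16700), (17000, 17100),
            ],
            "transcripts": [[0, 1, 3, 4], [0, 2, 3, 4]],
        },
    ]
    planted = [(4900, "GC")]  # break A5 donor
    gtf, fasta = write_annotation(tmp_path, genes, planted=planted)
    return gtf, fasta


def random_model(rng, n_transcripts=3, n_exons=5, chrom="chr1"):
    """Random single-gene annotation model (in memory) for oracle tests."""
    transcripts = {}
    strand = rng.choice(["+", "-"])
    for t in range(n_transcripts):
        pos = int(rng.integers(100, 2000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 300))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(100, 800))
        tid = f"T{t}"
        transcripts[tid] = Transcript(tid, "G0", chrom, strand, tuple(exons))
    return AnnotationModel(transcripts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
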