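"""Readers and writers for the package's plain-text interchange formats.

Genomes are FASTA (read via pyfaidx for random access, or fully in memory);
transcripts are TSV with columns gene_symbol, chrom, start, end, strand;
conservation identity blocks and predictions travel as BED6; expression is a
gene x tissue TSV. All coordinates on disk follow the BED convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval, TranscriptRecord
from .motifs import ALPHABET, PWM

__all__ = [
    "read_genome",
    "write_fasta",
    "read_transcripts",
    "write_transcripts",
    "read_identity_bed",
    "write_identity_bed",
    "read_expression",
    "write_bed",
    "read_bed",
    "write_meme",
    "write_bundle",
]

TRANSCRIPT_COLUMNS = ["gene_symbol", "chrom", "start", "end", "strand"]


def read_genome(path) -> Mapping[str, str]:
    """Load a FASTA file as an in-memory chrom -> sequence mapping."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_transcripts(path) -> list[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    return [
        TranscriptRecord(
            str(r.gene_symbol),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
        )
        for r in df.itertuples()
    ]


def write_transcripts(transcripts, path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_symbol": t.gene_symbol,
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.interval.strand,
            }
            for t in transcripts
        ],
        columns=TRANSCRIPT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_identity_bed(path) -> list[tuple[GenomicInterval, float]]:
    """BED with the identity fraction scaled x1000 in the score column."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = float(parts[4]) / 1000.0 if len(parts) > 4 else 1.0
            out.append((GenomicInterval(chrom, start, end), score))
    return out


def write_identity_bed(blocks, path) -> None:
    with open(path, "w") as fh:
        for iv, ident in blocks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcne\t{round(ident * 1000)}\t.\n"
            )


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("expression table needs at least one tissue column")
    return df


def write_bed(intervals, path, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_motif_hits(hits, path) -> None:
    """Motif hits as BED6 with the score column = -log10 p-value."""
    import math

    with open(path, "w") as fh:
        for h in hits:
            neglog = 999.0 if h.pvalue <= 0 else -math.log10(h.pvalue)
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
                f"{h.motif_id}\t{neglog:.3f}\t{h.strand}\n"
            )


def write_meme(library: list[PWM], path, background=None) -> None:
    """Write a motif library in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if background is not None:
            freqs = " ".join(
                f"{c} {f:.5f}" for c, f in zip(ALPHABET, background.freqs)
            )
            fh.write(f"Background letter frequencies\n{freqs}\n\n")
        for pwm in library:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_bundle(bundle, outdir) -> dict[str, str]:
    """Write a synthetic bundle as FASTA/TSV/BED/MEME plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "transcripts": str(outdir / "transcripts.tsv"),
        "conservation": str(outdir / "conservation.bed"),
        "expression": str(outdir / "expression.tsv"),
        "truth_enhancers": str(outdir / "truth_enhancers.bed"),
        "motifs": str(outdir / "library.meme"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_fasta(bundle.genome, paths["genome"])
    write_transcripts(bundle.transcripts, paths["transcripts"])
    write_identity_bed(bundle.identity_blocks, paths["conservation"])
    bundle.expression.to_csv(paths["expression"], sep="\t")
    write_bed(bundle.truth_enhancers, paths["truth_enhancers"])
    write_meme(bundle.library, paths["motifs"], bundle.spec.background)
    from dataclasses import asdict

    spec_dict = asdict(bundle.spec)
    spec_dict["background"] = list(bundle.spec.background.freqs)
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "spec": spec_dict,
                "planted_motif_ids": bundle.planted_motif_ids,
                "high_genes": bundle.high_genes,
                "low_genes": bundle.low_genes,
            },
            fh,
            indent=2,
        )
    return paths
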