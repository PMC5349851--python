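"""Readers and writers for the formats the pipeline touches.

Reads come in as FASTQ (qualities ignored) or one-read-per-line text,
profiles as TSV (`kmer count expected enrichment csi`, gzip supported),
peaks as BED3+, genomes as FASTA (via pyfaidx), and SNPs as TSV or a
minimal VCF subset (via cyvcf2).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genomescape import GenomicInterval
from .selex import BindingProfile, rank_order, top_sequences
from .seqcode import index_to_kmer, kmer_to_index
from .snp import SNPRecord

FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTQ (quality ignored) or plain one-per-line text."""
    path = Path(path)
    name = path.name.lower()
    if any(name.endswith(s) for s in FASTQ_SUFFIXES):
        with _open_text(path) as fh:
            return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]
    with _open_text(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """TSV barcode<TAB>sample_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "sample_id"], dtype=str)
    return dict(zip(df["barcode"], df["sample_id"]))


def write_profile(profile: BindingProfile, path: str | Path) -> None:
    """Profile TSV sorted by CSI descending (lexicographic tie-break)."""
    order = rank_order(profile.csi)
    df = pd.DataFrame(
        {
            "kmer": [index_to_kmer(int(i), profile.k) for i in order],
            "count": profile.counts[order].astype(np.int64),
            "expected": profile.expected[order],
            "enrichment": profile.enrichment[order],
            "csi": profile.csi[order],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_profile(
    path: str | Path, dimer_id: str | None = None, strand_mode: str = "collapsed"
) -> BindingProfile:
    """Load a profile TSV; the table must cover all 4**k k-mers."""
    df = pd.read_csv(path, sep="\t")
    k = len(df["kmer"].iloc[0])
    n = 4**k
    if len(df) != n:
        raise ValueError(f"profile must cover all {n} {k}-mers, found {len(df)}")
    idx = np.fromiter((kmer_to_index(w) for w in df["kmer"]), dtype=np.int64, count=n)
    arrays = {}
    for col in ("count", "expected", "enrichment", "csi"):
        v = np.empty(n, dtype=float)
        v[idx] = df[col].to_numpy()
        arrays[col] = v
    return BindingProfile(
        dimer_id=dimer_id or Path(path).stem,
        k=k,
        strand_mode=strand_mode,
        counts=arrays["count"],
        expected=arrays["expected"],
        enrichment=arrays["enrichment"],
        csi=arrays["csi"],
    )


def write_top_fasta(profile: BindingProfile, n: int, path: str | Path) -> None:
    """Top-n k-mers as FASTA for external motif tools."""
    with _open_text(path, "wt") as fh:
        for rank, kmer in enumerate(top_sequences(profile, n), start=1):
            fh.write(f">rank{rank}_{profile.dimer_id}\n{kmer}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def read_fasta(path: str | Path):
    """Indexed FASTA access (pyfaidx); behaves like a chrom -> sequence mapping."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads(reads: Sequence[str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(r + "\n")


def read_snp_tsv(path: str | Path) -> list[SNPRecord]:
    """SNP TSV with columns id chrom pos ref alt [trait]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SNPRecord(
                id=str(row.id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                trait=str(getattr(row, "trait", "")),
            )
        )
    return records


def write_snp_tsv(snps: Sequence[SNPRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "ref": [s.ref for s in snps],
            "alt": [s.alt for s in snps],
            "trait": [s.trait for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path) -> list[SNPRecord]:
    """Minimal VCF subset: CHROM, POS, ID, REF, ALT; other fields ignored.

    Multi-allelic records are expanded; indels are rejected by SNPRecord.
    """
    from cyvcf2 import VCF

    records = []
    for var in VCF(str(path)):
        for alt in var.ALT:
            records.append(
                SNPRecord(
                    id=var.ID or f"{var.CHROM}:{var.POS}",
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                )
            )
    return records
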