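"""Input/output: genome access, exon/variant readers, FASTQ helpers.

TSV with a header line is the universal tabular interchange format. FASTQ
may be plain or gzip-compressed; compression is detected from the file
magic, not the extension, on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, NamedTuple

import pandas as pd

from .design_pool import GenomicExon, VariantSpec
from .errors import MissingSequenceError, VexSeqError


class GenomeSource:
    """Uniform 1-based-inclusive access to a genome from FASTA or a dict."""

    def __init__(self, fetch, lengths):
        self._fetch = fetch
        self._lengths = lengths

    @classmethod
    def from_dict(cls, seqs: dict) -> "GenomeSource":
        seqs = {c: str(s).upper() for c, s in seqs.items()}

        def fetch(chrom, start, end):
            return seqs[chrom][start - 1 : end]

        return cls(fetch, {c: len(s) for c, s in seqs.items()})

    @classmethod
    def from_fasta(cls, path) -> "GenomeSource":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

        def fetch(chrom, start, end):
            return str(fa[chrom][start - 1 : end])

        return cls(fetch, {name: len(fa[name]) for name in fa.keys()})

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive."""
        if chrom not in self._lengths:
            raise MissingSequenceError(f"chromosome {chrom!r} not in genome")
        if start < 1 or end > self._lengths[chrom]:
            raise MissingSequenceError(
                f"{chrom}:{start}-{end} outside sequence of length "
                f"{self._lengths[chrom]}"
            )
        seq = self._fetch(chrom, start, end)
        if len(seq) != end - start + 1:
            raise MissingSequenceError(f"gap in genome at {chrom}:{start}-{end}")
        return seq


def load_genome(source) -> GenomeSource:
    if isinstance(source, GenomeSource):
        return source
    if isinstance(source, dict):
        return GenomeSource.from_dict(source)
    return GenomeSource.from_fasta(source)


# ---------------------------------------------------------------------------
# exon annotations


def read_exons_bed(path) -> list[GenomicExon]:
    """BED6 exons; 0-based half-open converted to 1-based inclusive."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GenomicExon(
            id=r.name if isinstance(r.name, str) else f"exon_{i}",
            chrom=r.chrom,
            start=int(r.start) + 1,
            end=int(r.end),
            strand=r.strand,
        )
        for i, r in enumerate(df.itertuples(index=False))
    ]


def read_exons_gtf(path) -> list[GenomicExon]:
    """Exon features from a GTF (1-based inclusive already)."""
    import re

    exons = []
    opener = gzip.open if _is_gzip(path) else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = fields[8]
            m = re.search(r'exon_id "([^"]+)"', attrs) or re.search(
                r'gene_id "([^"]+)"', attrs
            )
            exons.append(
                GenomicExon(
                    id=m.group(1) if m else f"exon_{i}",
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return exons


def read_exons(path) -> list[GenomicExon]:
    suffixes = {s.lower() for s in Path(path).suffixes}
    if ".gtf" in suffixes or ".gff" in suffixes:
        return read_exons_gtf(path)
    return read_exons_bed(path)


def read_variants_vcf(path) -> list[VariantSpec]:
    """CHROM/POS/REF/ALT/ID from a VCF; one VariantSpec per ALT allele."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for j, alt in enumerate(rec.ALT):
            ref, a = rec.REF, alt
            if len(ref) == len(a) == 1:
                klass = "SNV"
            elif len(ref) < len(a):
                klass = "insertion"
            elif len(ref) > len(a):
                klass = "deletion"
            else:
                klass = "MNV"
            vid = rec.ID or f"{rec.CHROM}_{rec.POS}_{ref}_{a}"
            if len(rec.ALT) > 1:
                vid = f"{vid}_{j}"
            out.append(
                VariantSpec(
                    id=vid, chrom=rec.CHROM, pos=rec.POS, ref_allele=ref,
                    alt_allele=a, klass=klass,
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTQ


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def read_fastq(path) -> Iterator[FastqRead]:
    """Iterate a FASTQ file (plain or gzipped, detected by magic bytes)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRead(entry.name, entry.sequence, entry.quality or "")


def write_fastq(path, reads) -> None:
    """Write 4-line FASTQ records; gzip if the path ends in .gz."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq, qual in reads:
            if len(qual) != len(seq):
                raise VexSeqError(f"read {name}: quality length != sequence length")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[FastqRead, FastqRead]]:
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise VexSeqError("read-2 file has fewer records than read-1 file")
        yield r1, r2
    if next(it2, None) is not None:
        raise VexSeqError("read-2 file has more records than read-1 file")
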