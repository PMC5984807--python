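"""Design of the barcoded test-exon reporter library.

A *test region* is the candidate alternative exon together with its designed
intronic flanks (>=50 nt upstream, >=20 nt downstream, in splicing sense).
Variants from a VCF are written into the region, per-exon splice-site
controls are derived from the reference region, and each variant sequence is
assembled into a synthesizable oligo: common primers, cloning restriction
sites, the test region, and an 8-nt barcode that identifies the variant even
when the test exon is skipped.

Coordinates: genomic inputs are 1-based inclusive; all internal offsets are
0-based half-open. Minus-strand exons are reverse-complemented at extraction
so every downstream step is strand-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .config import DesignConfig
from .errors import (
    DesignConstraintError,
    FlankTooShortError,
    InfeasibleBarcodeError,
    NonCanonicalBoundaryError,
    OligoLengthError,
    RefMismatchError,
    StrayMotifError,
    VexSeqError,
)
from .util import revcomp, random_dna_matrix

VARIANT_CLASSES = (
    "SNV",
    "insertion",
    "deletion",
    "MNV",
    "control_consensus",
    "control_mutated",
    "reference",
)


@dataclass(frozen=True)
class GenomicExon:
    """An exon in genomic coordinates (1-based inclusive)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end < self.start:
            raise VexSeqError(f"exon {self.id}: end < start")
        if self.strand not in "+-":
            raise VexSeqError(f"exon {self.id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Edit(NamedTuple):
    """One applied sequence change, in reference-region coordinates."""

    offset: int
    ref: str
    alt: str

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)

    def serialize(self) -> str:
        return f"{self.offset}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "Edit":
        off, alleles = text.split(":")
        ref, alt = alleles.split(">")
        return cls(int(off), ref, alt)


def serialize_edits(edits: Sequence[Edit]) -> str:
    return ";".join(e.serialize() for e in edits)


def parse_edits(text: str) -> tuple[Edit, ...]:
    if not text or text != text:  # empty or NaN
        return ()
    return tuple(Edit.parse(t) for t in str(text).split(";"))


@dataclass(frozen=True)
class VariantSpec:
    """A variant in VCF-style coordinates, or a control marker.

    For controls and the reference entry, ``ref_allele``/``alt_allele`` are
    empty and ``klass`` encodes the transformation.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    klass: str

    def __post_init__(self):
        if self.klass not in VARIANT_CLASSES:
            raise VexSeqError(f"unknown variant class {self.klass!r}")


@dataclass(frozen=True)
class BarcodeAssignment:
    barcode: str
    variant_id: str


@dataclass(frozen=True)
class TestRegion:
    """Test exon plus flanks, always stored in splicing sense.

    ``coord_map`` maps genomic position (1-based) to the current 0-based
    offset within the region; it stays valid through edits (deleted
    positions are dropped, inserted bases have no genomic position).
    ``edits`` are recorded in reference-region coordinates. ``up_context`` /
    ``down_context`` hold extra genomic sequence used to restore flank
    minima after deletions; context bases promoted into a flank are counted
    by ``pad_up`` / ``pad_down`` and are not genomically addressable.
    """

    up: str
    exon: str
    down: str
    origin: GenomicExon
    coord_map: Mapping[int, int] = field(default_factory=dict, repr=False)
    edits: tuple = ()
    up_context: str = ""
    down_context: str = ""
    pad_up: int = 0
    pad_down: int = 0

    @property
    def sequence(self) -> str:
        return self.up + self.exon + self.down

    @property
    def exon_start(self) -> int:
        return len(self.up)

    @property
    def exon_end(self) -> int:
        return len(self.up) + len(self.exon)

    @property
    def is_reference(self) -> bool:
        return not self.edits


def _genome_slice(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a genome source (dict or GenomeSource)."""
    from .io import GenomeSource

    if isinstance(genome, GenomeSource):
        return genome.slice(chrom, start, end)
    return GenomeSource.from_dict(dict(genome)).slice(chrom, start, end)


def extract_test_region(
    exon: GenomicExon, genome, cfg: DesignConfig = DesignConfig()
) -> TestRegion:
    """Slice the test region (exon + minimal flanks) from the genome.

    Minus-strand exons are reverse-complemented so the returned region reads
    in splicing sense: ``up`` ends at the 3' splice site, ``down`` starts at
    the 5' splice site.
    """
    if not (cfg.min_exon_len <= exon.length <= cfg.max_exon_len):
        raise DesignConstraintError(
            f"exon {exon.id} length {exon.length} outside "
            f"[{cfg.min_exon_len}, {cfg.max_exon_len}]"
        )
    ctx = cfg.flank_context
    if exon.strand == "+":
        up_len, down_len = cfg.min_up_flank, cfg.min_down_flank
    else:
        # genomic left of a minus-strand exon is its downstream flank
        up_len, down_len = cfg.min_down_flank, cfg.min_up_flank
    g_start = exon.start - up_len - ctx
    g_end = exon.end + down_len + ctx
    plus = _genome_slice(genome, exon.chrom, g_start, g_end)

    positions = list(range(g_start, g_end + 1))
    if exon.strand == "-":
        plus = revcomp(plus)
        positions = positions[::-1]

    sense_up = cfg.min_up_flank
    sense_down = cfg.min_down_flank
    up = plus[ctx : ctx + sense_up]
    ex = plus[ctx + sense_up : ctx + sense_up + exon.length]
    down = plus[ctx + sense_up + exon.length : ctx + sense_up + exon.length + sense_down]
    coord_map = {
        positions[ctx + i]: i for i in range(sense_up + exon.length + sense_down)
    }
    return TestRegion(
        up=up,
        exon=ex,
        down=down,
        origin=exon,
        coord_map=coord_map,
        up_context=plus[:ctx],
        down_context=plus[ctx + sense_up + exon.length + sense_down :],
    )


def _ref_offset(region: TestRegion, cur_off: int) -> int:
    """Convert a current-region offset back to reference-region coordinates."""
    off = cur_off - region.pad_up
    for e in region.edits:
        if off > e.offset:
            off -= e.delta
    return off


def apply_variant(region: TestRegion, v: VariantSpec) -> TestRegion:
    """Write a VCF-style variant into the region.

    The variant is given on the genomic plus strand; for minus-strand exons
    the alleles are reverse-complemented at application. Deletions that
    shorten a flank below its minimum are padded back from the retained
    genomic context.
    """
    strand = region.origin.strand
    g_positions = range(v.pos, v.pos + len(v.ref_allele))
    try:
        offs = sorted(region.coord_map[g] for g in g_positions)
    except KeyError as exc:
        raise VexSeqError(
            f"variant {v.id}: position {exc.args[0]} outside the test region"
        ) from None
    if offs != list(range(offs[0], offs[0] + len(v.ref_allele))):
        raise VexSeqError(f"variant {v.id}: REF positions not contiguous in region")

    a = offs[0]
    ref_here = v.ref_allele if strand == "+" else revcomp(v.ref_allele)
    alt_here = v.alt_allele if strand == "+" else revcomp(v.alt_allele)
    seq = region.sequence
    if seq[a : a + len(ref_here)] != ref_here:
        raise RefMismatchError(
            f"variant {v.id}: expected {ref_here} at region offset {a}, "
            f"found {seq[a : a + len(ref_here)]}"
        )

    edit = Edit(_ref_offset(region, a), ref_here, alt_here)
    return _apply_edit(region, a, ref_here, alt_here, edit)


def _apply_edit(
    region: TestRegion, a: int, ref_seg: str, alt_seg: str, edit: Edit
) -> TestRegion:
    """Replace region[a : a+len(ref_seg)] with alt_seg and rebook everything."""
    b = a + len(ref_seg)
    delta = len(alt_seg) - len(ref_seg)
    seq = region.sequence[:a] + alt_seg + region.sequence[b:]

    # part boundaries shift only where the edit lands before them
    up_len, ex_len = len(region.up), len(region.exon)
    ex_start, ex_end = up_len, up_len + ex_len
    if b <= ex_start:
        ex_start += delta
        ex_end += delta
    elif a >= ex_end:
        pass
    elif a >= ex_start and b <= ex_end:
        ex_end += delta
    else:
        raise VexSeqError("edit straddles an exon/intron boundary")

    coord_map = {}
    for g, o in region.coord_map.items():
        if o < a:
            coord_map[g] = o
        elif o >= b:
            coord_map[g] = o + delta
    new = TestRegion(
        up=seq[:ex_start],
        exon=seq[ex_start:ex_end],
        down=seq[ex_end:],
        origin=region.origin,
        coord_map=coord_map,
        edits=region.edits + (edit,),
        up_context=region.up_context,
        down_context=region.down_context,
        pad_up=region.pad_up,
        pad_down=region.pad_down,
    )
    return _pad_flanks(new)


def _pad_flanks(region: TestRegion, cfg: DesignConfig = DesignConfig()) -> TestRegion:
    """Restore flank minima from stored context after a deletion."""
    up, down = region.up, region.down
    ctx_up, ctx_down = region.up_context, region.down_context
    pad_up, pad_down = region.pad_up, region.pad_down
    need = cfg.min_up_flank - len(up)
    if need > 0:
        if len(ctx_up) < need:
            raise FlankTooShortError("not enough genomic context to pad upstream flank")
        up = ctx_up[-need:] + up
        ctx_up = ctx_up[:-need]
        pad_up += need
    need_d = cfg.min_down_flank - len(down)
    if need_d > 0:
        if len(ctx_down) < need_d:
            raise FlankTooShortError("not enough genomic context to pad downstream flank")
        down = down + ctx_down[:need_d]
        ctx_down = ctx_down[need_d:]
        pad_down += need_d
    if need <= 0 and need_d <= 0:
        return region
    coord_map = (
        {g: o + max(need, 0) for g, o in region.coord_map.items()}
        if need > 0
        else dict(region.coord_map)
    )
    return replace(
        region,
        up=up,
        down=down,
        up_context=ctx_up,
        down_context=ctx_down,
        pad_up=pad_up,
        pad_down=pad_down,
        coord_map=coord_map,
    )


def make_mutated_control(region: TestRegion) -> TestRegion:
    """Splice-site knockout control: 3'ss AG -> TC and 5'ss GT -> CA.

    Only the four splice-site bases change; the exon is untouched. Applying
    it to a region whose boundaries are no longer canonical is an error.
    """
    if region.up[-2:] != "AG" or region.down[:2] != "GT":
        raise NonCanonicalBoundaryError(
            f"expected AG|exon|GT boundaries, found "
            f"{region.up[-2:]}|exon|{region.down[:2]}"
        )
    a3 = len(region.up) - 2
    r = _apply_edit(region, a3, "AG", "TC", Edit(_ref_offset(region, a3), "AG", "TC"))
    a5 = len(r.up) + len(r.exon)
    return _apply_edit(r, a5, "GT", "CA", Edit(_ref_offset(r, a5), "GT", "CA"))


def make_consensus_control(
    region: TestRegion, cfg: DesignConfig = DesignConfig()
) -> TestRegion:
    """Splice-site strengthening control.

    The 22 nt of upstream intron ending at the exon become a 20-nt pyrimidine
    tract followed by AG, and the first 6 nt of downstream intron become the
    consensus 5' splice site GTAAGT.
    """
    if len(region.up) < 22:
        raise FlankTooShortError("upstream intron shorter than 22 nt")
    if len(region.down) < 6:
        raise FlankTooShortError("downstream intron shorter than 6 nt")
    a3 = len(region.up) - 22
    old = region.up[-22:]
    new3 = cfg.pyrimidine_tract + "AG"
    r = _apply_edit(region, a3, old, new3, Edit(_ref_offset(region, a3), old, new3))
    a5 = len(r.up) + len(r.exon)
    old5 = r.down[:6]
    return _apply_edit(r, a5, old5, "GTAAGT", Edit(_ref_offset(r, a5), old5, "GTAAGT"))


# ---------------------------------------------------------------------------
# barcodes


def generate_barcodes(
    n: int, cfg: DesignConfig = DesignConfig(), seed: int = 0
) -> list[str]:
    """Draw n distinct barcodes satisfying the pool constraints.

    Constraints: fixed length (8), no restriction motif or its reverse
    complement as a substring, pairwise Hamming distance >= 2. Deterministic
    for a fixed seed. A Singleton-bound argument caps any distance-2 code of
    length 8 over 4 letters at 4**7 words, so larger requests fail fast.
    """
    L = cfg.barcode_len
    if n > 4 ** (L - cfg.min_barcode_hamming + 1):
        raise InfeasibleBarcodeError(
            f"{n} barcodes of length {L} with Hamming >= "
            f"{cfg.min_barcode_hamming} is infeasible"
        )
    motifs = set(cfg.restriction_motifs.values())
    motifs |= {revcomp(m) for m in motifs}
    if cfg.min_barcode_hamming > 2:
        raise InfeasibleBarcodeError("min_barcode_hamming > 2 is not supported")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    # exact O(1) distance check: 'covered' holds every word within Hamming
    # distance (min_barcode_hamming - 1) of an accepted barcode
    covered: set[str] = set()
    attempts, cap = 0, 200 * n + 100_000
    while len(accepted) < n:
        batch = random_dna_matrix(rng, 1024, L)
        for row in batch:
            attempts += 1
            if attempts > cap:
                raise InfeasibleBarcodeError(
                    f"could not find {n} admissible barcodes "
                    f"(found {len(accepted)} after {attempts} draws)"
                )
            bc = row.tobytes().decode()
            if bc in covered or any(m in bc for m in motifs):
                continue
            accepted.append(bc)
            covered.add(bc)
            if cfg.min_barcode_hamming == 2:
                for i in range(L):
                    for base in "ACGT":
                        if base != bc[i]:
                            covered.add(bc[:i] + base + bc[i + 1 :])
            if len(accepted) == n:
                break
    return accepted


# ---------------------------------------------------------------------------
# oligo assembly


@dataclass(frozen=True)
class OligoRecord:
    """One synthesizable oligo with its component map.

    ``parts`` maps part name -> (start, end) half-open offsets into
    ``sequence``; ``edits`` are in reference-region coordinates (see
    TestRegion); ``pad_up`` counts context bases prepended to the upstream
    flank by deletion padding.
    """

    oligo_id: str
    sequence: str
    parts: dict
    variant_id: str
    exon_id: str
    barcode: str
    variant_class: str
    edits: tuple = ()
    pad_up: int = 0

    def part_seq(self, name: str) -> str:
        a, b = self.parts[name]
        return self.sequence[a:b]

    @property
    def region_start(self) -> int:
        return self.parts["upstream_intron"][0]

    def region_offset_to_oligo(self, ref_off: int) -> int:
        """Map a reference-region offset to this oligo's coordinates."""
        off = ref_off
        for e in self.edits:
            if ref_off >= e.offset + len(e.ref):
                off += e.delta
            elif ref_off > e.offset:
                off = e.offset + sum(
                    x.delta for x in self.edits if x.offset + len(x.ref) <= e.offset
                )
                break
        return self.region_start + self.pad_up + off


def assemble_oligo(
    region: TestRegion,
    ba: BarcodeAssignment,
    cfg: DesignConfig = DesignConfig(),
    oligo_id: str | None = None,
    exon_id: str | None = None,
    variant_class: str = "SNV",
) -> OligoRecord:
    """Assemble the full oligo and validate it.

    Default layout: fwd_primer . PstI . upstream_intron . exon .
    downstream_intron . MfeI . SpeI . barcode . XbaI . revcomp(rev_primer).
    Any restriction motif occurring outside its designated site aborts the
    design with the motif name and offset.
    """
    if len(ba.barcode) != cfg.barcode_len:
        raise VexSeqError(f"barcode {ba.barcode} is not {cfg.barcode_len} nt")
    pieces = [
        ("fwd_primer", cfg.fwd_primer),
        ("site_5", cfg.motif(cfg.site_5)),
        ("upstream_intron", region.up),
        ("exon", region.exon),
        ("downstream_intron", region.down),
        ("site_mid1", cfg.motif(cfg.site_mid[0])),
        ("site_mid2", cfg.motif(cfg.site_mid[1])),
        ("barcode", ba.barcode),
        ("site_3", cfg.motif(cfg.site_3)),
        ("rev_primer_rc", revcomp(cfg.rev_primer)),
    ]
    parts, seq, pos = {}, [], 0
    for name, s in pieces:
        parts[name] = (pos, pos + len(s))
        seq.append(s)
        pos += len(s)
    sequence = "".join(seq)
    if len(sequence) > cfg.max_oligo_len:
        raise OligoLengthError(
            f"oligo length {len(sequence)} exceeds max {cfg.max_oligo_len}"
        )
    site_parts = {"site_5", "site_mid1", "site_mid2", "site_3"}
    designated = {parts[p][0] for p in site_parts}
    for name, motif in cfg.restriction_motifs.items():
        start = sequence.find(motif)
        while start != -1:
            if start not in designated:
                raise StrayMotifError(name, motif, start)
            start = sequence.find(motif, start + 1)
    return OligoRecord(
        oligo_id=oligo_id or f"{ba.variant_id}_{ba.barcode}",
        sequence=sequence,
        parts=parts,
        variant_id=ba.variant_id,
        exon_id=exon_id or region.origin.id,
        barcode=ba.barcode,
        variant_class=variant_class,
        edits=tuple(region.edits),
        pad_up=region.pad_up,
    )


# ---------------------------------------------------------------------------
# pool table I/O and summary

POOL_COLUMNS = [
    "oligo_id",
    "variant_id",
    "exon_id",
    "barcode",
    "variant_class",
    "oligo_sequence",
    "parts",
    "edits",
    "pad_up",
]


def pool_to_frame(pool: Iterable[OligoRecord]) -> pd.DataFrame:
    rows = [
        {
            "oligo_id": o.oligo_id,
            "variant_id": o.variant_id,
            "exon_id": o.exon_id,
            "barcode": o.barcode,
            "variant_class": o.variant_class,
            "oligo_sequence": o.sequence,
            "parts": json.dumps({k: list(v) for k, v in o.parts.items()}),
            "edits": serialize_edits(o.edits),
            "pad_up": o.pad_up,
        }
        for o in pool
    ]
    return pd.DataFrame(rows, columns=POOL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[OligoRecord]:
    out = []
    for row in df.itertuples(index=False):
        parts = {k: tuple(v) for k, v in json.loads(row.parts).items()}
        out.append(
            OligoRecord(
                oligo_id=row.oligo_id,
                sequence=row.oligo_sequence,
                parts=parts,
                variant_id=row.variant_id,
                exon_id=row.exon_id,
                barcode=row.barcode,
                variant_class=row.variant_class,
                edits=parse_edits(row.edits),
                pad_up=int(row.pad_up),
            )
        )
    return out


def write_pool(pool: Iterable[OligoRecord] | pd.DataFrame, path) -> None:
    df = pool if isinstance(pool, pd.DataFrame) else pool_to_frame(pool)
    df.to_csv(path, sep="\t", index=False)


def read_pool(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"edits": str}, keep_default_na=False)
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise VexSeqError(f"pool table missing columns: {sorted(missing)}")
    return df


def write_pool_fasta(pool: Iterable[OligoRecord], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(o.sequence), id=o.oligo_id, description="") for o in pool
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class PoolSummary:
    """Design-rule summary of a pool table."""

    n_variants_total: int
    n_variants_test: int  # excluding reference and control entries
    n_exons: int
    min_barcodes_per_variant: int
    max_barcodes_per_variant: int
    min_exon_len: int
    max_exon_len: int
    min_up_flank: int
    min_down_flank: int
    n_oligos: int
    violations: tuple = ()


def summarize_pool(
    pool: Iterable[OligoRecord] | pd.DataFrame, cfg: DesignConfig = DesignConfig()
) -> PoolSummary:
    """Count variants/exons/barcodes and check design rules on a pool.

    Reports both the total distinct variant count (including per-exon
    reference and control entries) and the count excluding them, since a
    pool table may or may not fold controls into its headline number.
    """
    records = frame_to_records(pool) if isinstance(pool, pd.DataFrame) else list(pool)
    if not records:
        raise VexSeqError("empty pool")
    bc_per_variant: dict[str, int] = {}
    klass: dict[str, str] = {}
    exons = set()
    exon_lens, up_lens, down_lens = [], [], []
    for o in records:
        bc_per_variant[o.variant_id] = bc_per_variant.get(o.variant_id, 0) + 1
        klass[o.variant_id] = o.variant_class
        exons.add(o.exon_id)
        a, b = o.parts["exon"]
        exon_lens.append(b - a)
        a, b = o.parts["upstream_intron"]
        up_lens.append(b - a)
        a, b = o.parts["downstream_intron"]
        down_lens.append(b - a)
    non_test = {"reference", "control_consensus", "control_mutated"}
    violations = []
    min_bc = min(bc_per_variant.values())
    if min_bc < cfg.min_barcodes:
        short = [v for v, c in bc_per_variant.items() if c < cfg.min_barcodes]
        violations.append(f"{len(short)} variants below min_barcodes={cfg.min_barcodes}")
    ref_lens = [
        (o.parts["exon"][1] - o.parts["exon"][0])
        for o in records
        if not o.edits
    ]
    if ref_lens and not all(
        cfg.min_exon_len <= L <= cfg.max_exon_len for L in ref_lens
    ):
        violations.append("reference exon length outside design window")
    if min(up_lens) < cfg.min_up_flank or min(down_lens) < cfg.min_down_flank:
        violations.append("flank below design minimum")
    return PoolSummary(
        n_variants_total=len(bc_per_variant),
        n_variants_test=sum(1 for v, k in klass.items() if k not in non_test),
        n_exons=len(exons),
        min_barcodes_per_variant=min_bc,
        max_barcodes_per_variant=max(bc_per_variant.values()),
        min_exon_len=min(exon_lens),
        max_exon_len=max(exon_lens),
        min_up_flank=min(up_lens),
        min_down_flank=min(down_lens),
        n_oligos=len(records),
        violations=tuple(violations),
    )
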