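"""Plasmid-pool quality control.

Paired amplicon reads covering the whole insert are merged, binned by
barcode, and each merged read is compared against the designed oligo for
that barcode. Per-barcode fidelity (fraction of reads carrying the expected
variant) drives the exclusion rule: barcodes with >= 15% incorrect reads are
dropped. Pool-level diagnostics are the misassignment rate (barcode attached
to a different designed variant) and the depth skew ratio
(90th / 10th percentile of per-barcode read depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .design_pool import OligoRecord, frame_to_records
from .errors import InsufficientDataError, UndefinedRateError
from .util import revcomp

CALL_CATEGORIES = ("expected", "other_designed", "unrecognized", "indel_only")


class MergedRead(NamedTuple):
    sequence: str
    quality: str
    overlap_len: int


class VariantCall(NamedTuple):
    barcode: str
    call: str


@dataclass(frozen=True)
class BarcodeFidelity:
    barcode: str
    variant_id: str
    n_reads: int
    n_expected: int

    @property
    def frac_incorrect(self) -> float:
        return 1.0 - self.n_expected / self.n_reads


@dataclass
class QcReport:
    kept: list
    dropped: list
    misassignment_rate: float
    misassignment_rate_kept: float
    skew_ratio: float
    depths: pd.Series
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# read merging


def merge_pair(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | None:
    """Merge a read pair by their 3' overlap.

    Read 2 is supplied as sequenced (reverse strand) and is reverse
    complemented here. Among admissible overlaps (length >= min_overlap,
    mismatch fraction <= max_mismatch_frac) the one maximizing the number of
    matched bases wins. Disagreeing overlap bases take the higher-quality
    call; quality ties take read 1's base. Returns None when no admissible
    overlap exists.
    """
    s2 = revcomp(r2_seq)
    q2 = r2_qual[::-1]
    n1, n2 = len(r1_seq), len(s2)
    # fast path: an exact 16-mer seed from the start of s2 pins the shift
    o = None
    seed = s2[:16]
    if len(seed) == 16:
        j = r1_seq.find(seed)
        if j != -1 and r1_seq.find(seed, j + 1) == -1:
            cand = n1 - j
            if min_overlap <= cand <= n2:
                a, b = r1_seq[n1 - cand :], s2[:cand]
                mm = sum(x != y for x, y in zip(a, b))
                if mm / cand <= max_mismatch_frac:
                    o = cand
    if o is None:
        best = None  # (matched, overlap)
        for cand in range(min_overlap, min(n1, n2) + 1):
            a, b = r1_seq[n1 - cand :], s2[:cand]
            mm = sum(x != y for x, y in zip(a, b))
            if mm / cand > max_mismatch_frac:
                continue
            if best is None or cand - mm > best[0]:
                best = (cand - mm, cand)
        if best is None:
            return None
        o = best[1]
    head, tail = r1_seq[: n1 - o], s2[o:]
    head_q, tail_q = r1_qual[: n1 - o], q2[o:]
    mid, mid_q = [], []
    for i in range(o):
        b1, b2 = r1_seq[n1 - o + i], s2[i]
        c1, c2 = r1_qual[n1 - o + i], q2[i]
        if b1 == b2 or c1 >= c2:
            mid.append(b1)
            mid_q.append(max(c1, c2) if b1 == b2 else c1)
        else:
            mid.append(b2)
            mid_q.append(c2)
    return MergedRead(head + "".join(mid) + tail, head_q + "".join(mid_q) + tail_q, o)


# ---------------------------------------------------------------------------
# barcode assignment and variant calling


def assign_barcode(
    sequence: str,
    barcodes: set[str],
    anchor: str = "ACTAGT",
    barcode_len: int = 8,
) -> tuple[str | None, str]:
    """Locate the barcode immediately after the anchor restriction site.

    Returns (barcode, "assigned"), (None, "no_anchor"), or
    (None, "unknown_barcode"). Matching is exact on both the anchor and the
    8-mer; near-miss barcodes are not rescued.
    """
    idx = sequence.find(anchor)
    if idx == -1:
        return None, "no_anchor"
    bc = sequence[idx + len(anchor) : idx + len(anchor) + barcode_len]
    if bc in barcodes:
        return bc, "assigned"
    return None, "unknown_barcode"


def _identity(a: str, b: str) -> float:
    """Fraction of matched bases; Hamming when lengths agree, else a global
    alignment (match +1, mismatch -1, gap open -2, extend -1)."""
    if len(a) == len(b):
        mm = sum(x != y for x, y in zip(a, b))
        return 1.0 - mm / len(a)
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for sa, sb in zip(str(aln[0]), str(aln[1]))
        if sa == sb and sa != "-"
    )
    return matches / max(len(a), len(b))


def _locus_intervals(candidate: OligoRecord, exon_oligos: Sequence[OligoRecord]):
    """Oligo-coordinate intervals of every designed variant locus, in the
    candidate's frame. Intervals from other variants that overlap the
    candidate's own edits (in reference-region coordinates) are dropped."""
    own = [(e.offset, e.offset + len(e.ref)) for e in candidate.edits]
    intervals = []
    seen_variants = set()
    for o in exon_oligos:
        if o.variant_id in seen_variants:
            continue
        seen_variants.add(o.variant_id)
        for e in o.edits:
            a, b = e.offset, e.offset + len(e.ref)
            if o.variant_id != candidate.variant_id and any(
                a < ob and oa < b for oa, ob in own
            ):
                continue
            start = candidate.region_offset_to_oligo(e.offset)
            length = len(e.alt) if o.variant_id == candidate.variant_id else len(e.ref)
            intervals.append((start, start + length))
    return intervals


def call_read_variant(
    merged_seq: str,
    expected: OligoRecord,
    exon_oligos: Sequence[OligoRecord],
    identity_min: float = 0.9,
) -> str:
    """Classify one barcode-assigned read against the designed pool.

    expected: the read matches the expected oligo at every designed variant
    locus of the exon. other_designed: it matches a different designed oligo
    of the same exon at those loci. Reads below the identity floor are
    unrecognized; length-changing differences elsewhere are indel_only.
    """
    ident = _identity(merged_seq, expected.sequence)
    if ident < identity_min:
        return "unrecognized"
    ordered = [expected] + [o for o in exon_oligos if o.oligo_id != expected.oligo_id]
    for cand in ordered:
        if len(merged_seq) != len(cand.sequence):
            continue
        ok = all(
            merged_seq[a:b] == cand.sequence[a:b]
            for a, b in _locus_intervals(cand, exon_oligos)
        )
        if ok:
            return "expected" if cand.variant_id == expected.variant_id else "other_designed"
    if len(merged_seq) != len(expected.sequence):
        return "indel_only"
    return "unrecognized"


# ---------------------------------------------------------------------------
# pool-level statistics


def filter_barcodes(
    fidelities: Iterable[BarcodeFidelity], incorrect_threshold: float = 0.15
) -> tuple[list[BarcodeFidelity], list[BarcodeFidelity]]:
    """Drop barcodes with >= incorrect_threshold incorrect reads (boundary
    inclusive: exactly 15% incorrect is dropped)."""
    kept, dropped = [], []
    for f in fidelities:
        (dropped if f.frac_incorrect >= incorrect_threshold else kept).append(f)
    return kept, dropped


def misassignment_rate(calls: Iterable[VariantCall]) -> float:
    """Fraction of barcode-assigned reads carrying a different designed
    variant: #other_designed / #all assigned reads."""
    n = {c: 0 for c in CALL_CATEGORIES}
    for call in calls:
        n[call.call] += 1
    total = sum(n.values())
    if total == 0:
        raise UndefinedRateError("no assigned reads")
    return n["other_designed"] / total


def skew_ratio(depths) -> float:
    """P90 / P10 of per-barcode read depth (linear interpolation between
    closest ranks). Returns inf when P10 is zero."""
    depths = np.asarray(list(depths), dtype=float)
    if (depths > 0).sum() < 2:
        raise InsufficientDataError("need >= 2 barcodes with depth > 0")
    p10, p90 = np.percentile(depths, [10, 90])
    if p10 == 0:
        return math.inf
    return p90 / p10


# ---------------------------------------------------------------------------
# full pipeline


def run_plasmid_qc(
    read_pairs,
    pool: pd.DataFrame | Sequence[OligoRecord],
    incorrect_threshold: float = 0.15,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    anchor: str = "ACTAGT",
) -> tuple[QcReport, pd.DataFrame]:
    """Merge, assign, call, and filter a plasmid amplicon run.

    ``read_pairs`` yields ((seq1, qual1), (seq2, qual2)) or FastqRead pairs.
    Returns the QC report and the per-barcode fidelity table. Every input
    pair is accounted for in ``report.counts``.
    """
    records = frame_to_records(pool) if isinstance(pool, pd.DataFrame) else list(pool)
    by_barcode = {o.barcode: o for o in records}
    by_exon: dict[str, list[OligoRecord]] = {}
    for o in records:
        by_exon.setdefault(o.exon_id, []).append(o)

    counts = {
        "n_pairs": 0,
        "n_no_merge": 0,
        "n_no_anchor": 0,
        "n_unknown_barcode": 0,
        "n_assigned": 0,
    }
    counts.update({f"n_{c}": 0 for c in CALL_CATEGORIES})
    per_bc: dict[str, dict] = {}
    calls: list[VariantCall] = []
    for r1, r2 in read_pairs:
        counts["n_pairs"] += 1
        s1, q1 = (r1.sequence, r1.quality) if hasattr(r1, "sequence") else r1
        s2, q2 = (r2.sequence, r2.quality) if hasattr(r2, "sequence") else r2
        merged = merge_pair(s1, q1, s2, q2, min_overlap, max_mismatch_frac)
        if merged is None:
            counts["n_no_merge"] += 1
            continue
        bc, reason = assign_barcode(merged.sequence, by_barcode.keys(), anchor)
        if bc is None:
            counts[f"n_{reason}"] += 1
            continue
        counts["n_assigned"] += 1
        expected = by_barcode[bc]
        call = call_read_variant(merged.sequence, expected, by_exon[expected.exon_id])
        counts[f"n_{call}"] += 1
        calls.append(VariantCall(bc, call))
        acc = per_bc.setdefault(bc, {"n_reads": 0, "n_expected": 0})
        acc["n_reads"] += 1
        acc["n_expected"] += call == "expected"

    fidelities = [
        BarcodeFidelity(bc, by_barcode[bc].variant_id, d["n_reads"], d["n_expected"])
        for bc, d in sorted(per_bc.items())
    ]
    kept, dropped = filter_barcodes(fidelities, incorrect_threshold)
    kept_bcs = {f.barcode for f in kept}
    rate = misassignment_rate(calls) if calls else float("nan")
    kept_calls = [c for c in calls if c.barcode in kept_bcs]
    rate_kept = misassignment_rate(kept_calls) if kept_calls else float("nan")
    depths = pd.Series(
        {f.barcode: f.n_reads for f in fidelities}, dtype=float, name="depth"
    )
    skew = skew_ratio(depths) if (depths > 0).sum() >= 2 else float("nan")

    fid_df = pd.DataFrame(
        {
            "barcode": [f.barcode for f in fidelities],
            "variant_id": [f.variant_id for f in fidelities],
            "n_reads": [f.n_reads for f in fidelities],
            "n_expected": [f.n_expected for f in fidelities],
            "frac_incorrect": [f.frac_incorrect for f in fidelities],
            "kept": [f.barcode in kept_bcs for f in fidelities],
        }
    )
    report = QcReport(
        kept=sorted(kept_bcs),
        dropped=sorted(f.barcode for f in dropped),
        misassignment_rate=rate,
        misassignment_rate_kept=rate_kept,
        skew_ratio=skew,
        depths=depths,
        counts=counts,
    )
    return report, fid_df
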