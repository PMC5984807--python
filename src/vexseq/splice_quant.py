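"""Quantification of exon inclusion from barcoded, UMI-tagged RNA amplicons.

Read 2 carries the 10-nt UMI, the 3'-UTR anchor, and the barcode cassette:
it identifies the molecule and its variant. Read 1 starts inside constitutive
exon 1 and crosses the first splice junction: the bases immediately after the
exon-1 boundary identify the splicing outcome (test-exon inclusion vs
exon-1/exon-3 skipping) against a variant-specific mini-gene reference.
Reads spanning neither annotated junction are UNANNOTATED and excluded from
Ψ. PCR duplicates sharing a (barcode, UMI) are collapsed to one molecule by
majority vote. Ψ = 100 · inclusion / (inclusion + skipping) molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Backbone, ReadLayout
from .design_pool import OligoRecord, frame_to_records
from .errors import InsufficientDataError, VexSeqError
from .util import mismatches_within, revcomp

INCLUSION = "INCLUSION"
SKIPPING = "SKIPPING"
UNANNOTATED = "UNANNOTATED"

REJECT_REASONS = ("no_exon3", "bad_site", "unknown_barcode")


@dataclass(frozen=True)
class MiniGeneReference:
    """Variant-specific mini-gene: exon-1 suffix, test exon, exon-3 prefix."""

    variant_id: str
    exon1_suffix: str
    test_exon: str
    exon3: str

    @property
    def inclusion_seq(self) -> str:
        return self.exon1_suffix + self.test_exon + self.exon3

    @property
    def skipping_seq(self) -> str:
        return self.exon1_suffix + self.exon3

    @property
    def inclusion_junctions(self) -> tuple[int, int]:
        b = len(self.exon1_suffix)
        return (b, b + len(self.test_exon))

    @property
    def skipping_junction(self) -> int:
        return len(self.exon1_suffix)


class DemuxedMolecule(NamedTuple):
    barcode: str
    umi: str
    outcome: str
    support: int


def build_reference(oligo: OligoRecord, backbone: Backbone) -> MiniGeneReference:
    """Mini-gene reference for one designed oligo (its exon part carries any
    applied exonic variant)."""
    if not backbone.exon1_suffix or not backbone.exon3:
        raise VexSeqError("backbone must supply exon-1 suffix and exon-3 sequence")
    return MiniGeneReference(
        variant_id=oligo.variant_id,
        exon1_suffix=backbone.exon1_suffix,
        test_exon=oligo.part_seq("exon"),
        exon3=backbone.exon3,
    )


def demux_read2(
    seq: str,
    barcodes: set[str],
    layout: ReadLayout,
    exon3_check: str,
) -> tuple[tuple[str, str] | None, str]:
    """Extract (barcode, UMI) from read 2, or reject with a reason.

    ``exon3_check`` is the reverse complement of the exon-3 tail expected at
    the layout's exon-3 offset. Anchors tolerate up to
    ``layout.max_anchor_mismatch`` mismatches; the barcode must match a pool
    barcode exactly.
    """
    umi = seq[: layout.umi_len]
    w = seq[layout.exon3_offset : layout.exon3_offset + len(exon3_check)]
    if len(w) < len(exon3_check) or not mismatches_within(
        w, exon3_check, layout.max_anchor_mismatch
    ):
        return None, "no_exon3"
    site = seq[layout.site_offset : layout.site_offset + len(layout.barcode_site)]
    if not mismatches_within(site, layout.barcode_site, layout.max_anchor_mismatch):
        return None, "bad_site"
    bc = revcomp(seq[layout.barcode_offset : layout.barcode_offset + layout.barcode_len])
    if bc not in barcodes:
        return None, "unknown_barcode"
    return (bc, umi), "accepted"


def classify_outcome(
    read1: str,
    ref: MiniGeneReference,
    anchor_k: int = 10,
    max_mismatch: int = 1,
) -> str:
    """Assign a splicing outcome from the bases after the exon-1 boundary.

    The ``anchor_k`` bases following the fixed exon-1 boundary are compared
    to the starts of the test exon (inclusion) and of exon 3 (skipping);
    the unique label within ``max_mismatch`` wins, anything else (both,
    neither, or a too-short read) is UNANNOTATED.
    """
    b = len(ref.exon1_suffix)
    window = read1[b : b + anchor_k]
    if len(window) < anchor_k:
        return UNANNOTATED
    inc = mismatches_within(window, ref.test_exon[:anchor_k], max_mismatch)
    skip = mismatches_within(window, ref.exon3[:anchor_k], max_mismatch)
    if inc and not skip:
        return INCLUSION
    if skip and not inc:
        return SKIPPING
    return UNANNOTATED


def collapse_umis(
    records: Iterable[tuple[str, str, str]],
) -> tuple[list[DemuxedMolecule], int]:
    """One molecule per (barcode, UMI): majority outcome, exact ties dropped.

    Returns (molecules, n_tied_umis).
    """
    groups: dict[tuple[str, str], dict[str, int]] = {}
    for bc, umi, outcome in records:
        groups.setdefault((bc, umi), {}).setdefault(outcome, 0)
        groups[(bc, umi)][outcome] += 1
    molecules, ties = [], 0
    for (bc, umi), votes in groups.items():
        top = max(votes.values())
        winners = [o for o, c in votes.items() if c == top]
        if len(winners) > 1:
            ties += 1
            continue
        molecules.append(DemuxedMolecule(bc, umi, winners[0], sum(votes.values())))
    return molecules, ties


def compute_psi(n_inclusion: int, n_skipping: int) -> float:
    """Percent spliced in; NaN when no informative molecules exist."""
    total = n_inclusion + n_skipping
    if total == 0:
        return float("nan")
    return 100.0 * n_inclusion / total


# ---------------------------------------------------------------------------
# run-level pipeline


def quantify(
    read_pairs,
    pool: pd.DataFrame | Sequence[OligoRecord],
    backbone: Backbone,
    layout: ReadLayout = ReadLayout(),
    condition: str = "condition",
    kept_barcodes: set[str] | None = None,
    anchor_k: int = 10,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Demultiplex, classify, collapse, and compute per-barcode Ψ.

    Barcodes dropped by plasmid QC are excluded via ``kept_barcodes``.
    Returns (barcode-level Ψ table, accounting log). All input pairs are
    accounted for: accepted + rejected-by-reason = total.
    """
    records = frame_to_records(pool) if isinstance(pool, pd.DataFrame) else list(pool)
    if kept_barcodes is not None:
        records = [o for o in records if o.barcode in kept_barcodes]
    refs = {o.barcode: build_reference(o, backbone) for o in records}
    meta = {o.barcode: (o.variant_id, o.exon_id, o.variant_class) for o in records}
    barcodes = set(refs)
    exon3_check = revcomp(backbone.exon3[-layout.exon3_check_len :])

    log = {"n_pairs": 0, "n_accepted": 0}
    log.update({f"n_{r}": 0 for r in REJECT_REASONS})
    hits: list[tuple[str, str, str]] = []
    for r1, r2 in read_pairs:
        log["n_pairs"] += 1
        s1 = r1.sequence if hasattr(r1, "sequence") else r1[0]
        s2 = r2.sequence if hasattr(r2, "sequence") else r2[0]
        key, reason = demux_read2(s2, barcodes, layout, exon3_check)
        if key is None:
            log[f"n_{reason}"] += 1
            continue
        log["n_accepted"] += 1
        bc, umi = key
        hits.append((bc, umi, classify_outcome(s1, refs[bc], anchor_k, max_mismatch)))

    molecules, ties = collapse_umis(hits)
    log["n_umi_ties_discarded"] = ties
    log["n_molecules"] = len(molecules)

    per_bc: dict[str, dict[str, int]] = {
        bc: {INCLUSION: 0, SKIPPING: 0, UNANNOTATED: 0} for bc in barcodes
    }
    for m in molecules:
        per_bc[m.barcode][m.outcome] += 1
    rows = []
    for bc in sorted(barcodes):
        vid, exon_id, klass = meta[bc]
        c = per_bc[bc]
        rows.append(
            {
                "barcode": bc,
                "variant_id": vid,
                "exon_id": exon_id,
                "variant_class": klass,
                "condition": condition,
                "n_inclusion": c[INCLUSION],
                "n_skipping": c[SKIPPING],
                "n_unannotated": c[UNANNOTATED],
                "psi": compute_psi(c[INCLUSION], c[SKIPPING]),
            }
        )
    return pd.DataFrame(rows), log


def aggregate(barcode_table: pd.DataFrame) -> pd.DataFrame:
    """Variant-level Ψ per condition: unweighted mean over barcodes with a
    defined Ψ. Variants with no surviving barcode in a condition are
    excluded (their count appears as zero rows, not imputed values)."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        defined = g["psi"].dropna()
        return pd.Series(
            {
                "exon_id": g["exon_id"].iloc[0],
                "variant_class": g["variant_class"].iloc[0],
                "n_barcodes": int(defined.size),
                "n_inclusion": int(g["n_inclusion"].sum()),
                "n_skipping": int(g["n_skipping"].sum()),
                "psi": defined.mean() if defined.size else float("nan"),
            }
        )

    out = (
        barcode_table.groupby(["variant_id", "condition"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out[out["n_barcodes"] > 0].reset_index(drop=True)


def average_conditions(
    variant_table: pd.DataFrame, condition_to_group: dict[str, str]
) -> pd.DataFrame:
    """Average replicate-level variant Ψ within named groups (e.g. cell
    lines), then ``average_conditions`` again with all groups mapped to one
    name yields the cross-cell-line mean of means."""
    df = variant_table.copy()
    df["condition"] = df["condition"].map(condition_to_group)
    if df["condition"].isna().any():
        raise VexSeqError("condition_to_group does not cover all conditions")
    out = (
        df.groupby(["variant_id", "condition"], sort=True)
        .agg(
            exon_id=("exon_id", "first"),
            variant_class=("variant_class", "first"),
            n_barcodes=("n_barcodes", "min"),
            psi=("psi", "mean"),
        )
        .reset_index()
    )
    return out


def delta_psi(variant_table: pd.DataFrame) -> pd.DataFrame:
    """ΔΨ = Ψ(variant) − Ψ(matched reference exon, same condition).

    Reference rows get ΔΨ = 0 by construction; variants whose exon lacks a
    reference record in that condition are excluded.
    """
    refs = variant_table[variant_table["variant_class"] == "reference"]
    ref_psi = refs.set_index(["exon_id", "condition"])["psi"]
    rows = []
    for row in variant_table.itertuples(index=False):
        key = (row.exon_id, row.condition)
        if key not in ref_psi.index:
            continue
        rp = ref_psi.loc[key]
        rows.append(
            {
                "variant_id": row.variant_id,
                "exon_id": row.exon_id,
                "variant_class": row.variant_class,
                "condition": row.condition,
                "psi": row.psi,
                "ref_psi": rp,
                "delta_psi": 0.0
                if row.variant_class == "reference"
                else row.psi - rp,
            }
        )
    return pd.DataFrame(rows)


def counts_matrix(barcode_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant inclusion/skipping molecule counts by condition, in the
    wide layout consumed by external differential-splicing tests."""
    agg = (
        barcode_table.groupby(["variant_id", "condition"])[
            ["n_inclusion", "n_skipping"]
        ]
        .sum()
        .unstack("condition")
    )
    agg.columns = [f"{metric}_{cond}" for metric, cond in agg.columns]
    return agg.reset_index()


def correlation_report(a, b) -> tuple[float, float, int]:
    """(Pearson r, Spearman ρ, n) over paired finite values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise VexSeqError("correlation_report needs equal-length inputs")
    mask = np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 paired finite values, have {n}")
    r = stats.pearsonr(a[mask], b[mask]).statistic
    rho = stats.spearmanr(a[mask], b[mask]).statistic
    return float(r), float(rho), n
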