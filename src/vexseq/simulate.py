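"""Synthetic design pools and FASTQ read sets with known ground truth.

The generator emulates the data-generating structure of the assay: a
designed pool (reference + SNVs + splice-site controls per exon, >=3
barcodes each), plasmid amplicon pairs with log-normally skewed per-barcode
depth and barcode-variant misassignment, and RNA amplicon pairs with true
per-variant Ψ, 10-nt UMIs, geometric PCR duplication, and i.i.d.
substitution sequencing errors. Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Backbone, DEFAULT_BACKBONE, DesignConfig, ReadLayout
from .design_pool import (
    BarcodeAssignment,
    GenomicExon,
    OligoRecord,
    VariantSpec,
    apply_variant,
    assemble_oligo,
    extract_test_region,
    generate_barcodes,
    make_consensus_control,
    make_mutated_control,
    pool_to_frame,
)
from .errors import StrayMotifError, VexSeqError
from .io import GenomeSource, write_fastq
from .util import revcomp

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Depth skew (log-normal sigma 0.665 => P90/P10 ratio 5.5) and the
    misassignment rate (4.59%) default to the values measured for the real
    plasmid pool; Ψ priors implement the expected control behaviour
    (splice-site knockouts near 0, consensus sites near 100, reference
    exons intermediate).
    """

    n_exons: int = 10
    variants_per_exon: int = 4  # SNVs, excluding reference/controls
    barcodes_per_variant: int = 3
    include_controls: bool = True
    depth_mu: float = math.log(100.0)
    depth_sigma: float = 0.665
    error_rate: float = 0.001
    misassignment_rate: float = 0.0459
    duplication_p: float = 0.5  # geometric; mean reads/molecule = 1/p
    n_molecules_per_barcode: int = 200
    read_len: int = 150
    conditions: tuple = ("K562", "HepG2")
    ref_psi_beta: tuple = (2.0, 2.0)
    mutated_psi_beta: tuple = (1.0, 20.0)
    consensus_psi_beta: tuple = (20.0, 1.0)
    effect_null_prob: float = 0.5
    effect_sd: float = 15.0
    cell_noise_sd: float = 3.0
    effect_mode: str = "shared"  # or "independent"
    minus_strand_fraction: float = 0.5

    def __post_init__(self):
        if self.effect_mode not in ("shared", "independent"):
            raise VexSeqError("effect_mode must be 'shared' or 'independent'")
        if not (0 < self.duplication_p <= 1):
            raise VexSeqError("duplication_p must be in (0, 1]")
        for r in (self.error_rate, self.misassignment_rate):
            if not (0 <= r <= 1):
                raise VexSeqError("rates must lie in [0, 1]")
        if min(self.n_exons, self.variants_per_exon, self.barcodes_per_variant) < 1:
            raise VexSeqError("counts must be >= 1")


@dataclass
class SimulatedPool:
    records: list
    pool: pd.DataFrame
    truth: pd.DataFrame
    genome: dict
    exons: list
    qual_char: str = "?"  # Q30


def derive_seeds(seed: int, n: int = 4) -> list[int]:
    """Named substreams from one master seed (pool, plasmid, rna, extra)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _scrub_motifs(seq: list, motifs, protected: set, rng) -> None:
    """Destroy restriction motifs in-place, leaving protected offsets alone."""
    text = "".join(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        for m in motifs:
            i = text.find(m)
            if i != -1:
                free = [j for j in range(i, i + len(m)) if j not in protected]
                j = int(rng.choice(free))
                seq[j] = rng.choice([b for b in _BASES if b != seq[j]])
                changed = True
                break


def simulate_pool(
    cfg: SimulationConfig,
    seed: int = 0,
    design_cfg: DesignConfig = DesignConfig(),
    variant_schedule=None,
) -> SimulatedPool:
    """Generate a synthetic genome, exons, variants, barcodes, oligos, and a
    per-variant/per-condition truth-Ψ table.

    ``variant_schedule`` optionally gives the SNV count per exon (length
    ``cfg.n_exons``), overriding the uniform ``cfg.variants_per_exon``.
    """
    if variant_schedule is not None and len(variant_schedule) != cfg.n_exons:
        raise VexSeqError("variant_schedule length must equal n_exons")
    rng = np.random.default_rng(seed)
    motifs = set(design_cfg.restriction_motifs.values())
    motifs |= {revcomp(m) for m in motifs}
    ctx = design_cfg.flank_context
    up_f, down_f = design_cfg.min_up_flank, design_cfg.min_down_flank

    genome: dict[str, str] = {}
    exons: list[GenomicExon] = []
    variant_specs: list[tuple] = []  # (exon, VariantSpec)

    for i in range(cfg.n_exons):
        exon_id = f"EX{i:04d}"
        exon_len = int(rng.integers(design_cfg.min_exon_len, design_cfg.max_exon_len + 1))
        total = ctx + up_f + exon_len + down_f + ctx
        a3 = ctx + up_f
        d5 = a3 + exon_len
        tract = design_cfg.pyrimidine_tract
        for _attempt in range(100):
            sense = [str(b) for b in rng.choice(list(_BASES), size=total)]
            # canonical splice sites
            sense[a3 - 2], sense[a3 - 1] = "A", "G"
            sense[d5], sense[d5 + 1] = "G", "T"
            protected = {a3 - 2, a3 - 1, d5, d5 + 1}
            _scrub_motifs(sense, motifs, protected, rng)
            sense_str = "".join(sense)
            # the control transforms must not create motifs at their new
            # boundaries either
            up_s = sense_str[ctx:a3]
            ex_s = sense_str[a3:d5]
            down_s = sense_str[d5 : d5 + down_f]
            mut_s = up_s[:-2] + "TC" + ex_s + "CA" + down_s[2:]
            cons_s = up_s[:-22] + tract + "AG" + ex_s + "GTAAGT" + down_s[6:]
            if not any(m in mut_s or m in cons_s for m in motifs):
                break
        else:
            raise VexSeqError(f"could not build a motif-free exon {exon_id}")

        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        chrom = f"chr_{exon_id}"
        pad = 5
        plus = sense_str if strand == "+" else revcomp(sense_str)
        genome[chrom] = "A" * pad + plus + "A" * pad
        # sense offset a3 is the exon start; on the minus strand it counts
        # from the plus-strand end
        start = pad + a3 + 1 if strand == "+" else pad + (total - a3 - exon_len) + 1
        exon = GenomicExon(exon_id, chrom, start, start + exon_len - 1, strand)
        exons.append(exon)

        region = extract_test_region(exon, genome, design_cfg)
        inv = {o: g for g, o in region.coord_map.items()}
        variant_specs.append((exon, VariantSpec(f"{exon_id}_ref", chrom, 0, "", "", "reference")))
        if cfg.include_controls:
            variant_specs.append(
                (exon, VariantSpec(f"{exon_id}_mut", chrom, 0, "", "", "control_mutated"))
            )
            variant_specs.append(
                (exon, VariantSpec(f"{exon_id}_cons", chrom, 0, "", "", "control_consensus"))
            )
        region_len = len(region.sequence)
        chosen: set[int] = set()
        n_snvs = (
            int(variant_schedule[i]) if variant_schedule is not None
            else cfg.variants_per_exon
        )
        for j in range(n_snvs):
            for _ in range(200):
                off = int(rng.integers(0, region_len))
                if off in chosen:
                    continue
                sense_ref = region.sequence[off]
                alt = str(rng.choice([b for b in _BASES if b != sense_ref]))
                lo = max(0, off - 5)
                window = (
                    region.sequence[lo:off] + alt + region.sequence[off + 1 : off + 6]
                )
                if any(m in window for m in motifs):
                    continue
                chosen.add(off)
                gpos = inv[off]
                if strand == "+":
                    g_ref, g_alt = sense_ref, alt
                else:
                    g_ref, g_alt = _COMP[sense_ref], _COMP[alt]
                variant_specs.append(
                    (
                        exon,
                        VariantSpec(
                            f"{exon_id}_v{j}", chrom, gpos, g_ref, g_alt, "SNV"
                        ),
                    )
                )
                break
            else:
                raise VexSeqError(f"could not place SNV {j} in exon {exon_id}")

    # regions per variant
    regions = {}
    ref_regions = {}
    for exon, v in variant_specs:
        if v.klass == "reference":
            ref_regions[exon.id] = extract_test_region(exon, genome, design_cfg)
    for exon, v in variant_specs:
        base = ref_regions[exon.id]
        if v.klass == "reference":
            regions[v.id] = base
        elif v.klass == "control_mutated":
            regions[v.id] = make_mutated_control(base)
        elif v.klass == "control_consensus":
            regions[v.id] = make_consensus_control(base, design_cfg)
        else:
            regions[v.id] = apply_variant(base, v)

    # barcodes and oligo assembly (retry on junction-created stray motifs)
    n_slots = len(variant_specs) * cfg.barcodes_per_variant
    barcode_seed = int(rng.integers(0, 2**31))
    barcodes = generate_barcodes(
        int(n_slots * 1.15) + 32, design_cfg, seed=barcode_seed
    )
    bc_iter = iter(barcodes)
    records: list[OligoRecord] = []
    for exon, v in variant_specs:
        for k in range(cfg.barcodes_per_variant):
            for _ in range(20):
                bc = next(bc_iter)
                try:
                    rec = assemble_oligo(
                        regions[v.id],
                        BarcodeAssignment(bc, v.id),
                        design_cfg,
                        oligo_id=f"{v.id}_bc{k}",
                        exon_id=exon.id,
                        variant_class=v.klass,
                    )
                except StrayMotifError:
                    continue
                records.append(rec)
                break
            else:
                raise VexSeqError(f"no admissible barcode for {v.id}")

    truth = _draw_truth(cfg, variant_specs, rng)
    return SimulatedPool(records, pool_to_frame(records), truth, genome, exons)


def _draw_truth(cfg: SimulationConfig, variant_specs, rng) -> pd.DataFrame:
    rows = []
    ref_psi: dict[tuple, float] = {}
    for exon, v in variant_specs:
        if v.klass == "reference":
            for cond in cfg.conditions:
                ref_psi[(exon.id, cond)] = 100.0 * rng.beta(*cfg.ref_psi_beta)
    for exon, v in variant_specs:
        if v.klass == "reference":
            deltas = {cond: 0.0 for cond in cfg.conditions}
        elif v.klass == "control_mutated":
            deltas = None
            psis = {
                cond: 100.0 * rng.beta(*cfg.mutated_psi_beta)
                for cond in cfg.conditions
            }
        elif v.klass == "control_consensus":
            deltas = None
            psis = {
                cond: 100.0 * rng.beta(*cfg.consensus_psi_beta)
                for cond in cfg.conditions
            }
        else:
            if cfg.effect_mode == "shared":
                base = (
                    0.0
                    if rng.random() < cfg.effect_null_prob
                    else rng.normal(0.0, cfg.effect_sd)
                )
                deltas = {
                    cond: base + rng.normal(0.0, cfg.cell_noise_sd)
                    for cond in cfg.conditions
                }
            else:
                deltas = {
                    cond: (
                        0.0
                        if rng.random() < cfg.effect_null_prob
                        else rng.normal(0.0, cfg.effect_sd)
                    )
                    + rng.normal(0.0, cfg.cell_noise_sd)
                    for cond in cfg.conditions
                }
        for cond in cfg.conditions:
            if deltas is None:
                psi = psis[cond]
                delta = float("nan")
            else:
                delta = deltas[cond]
                psi = float(np.clip(ref_psi[(exon.id, cond)] + delta, 0.5, 99.5))
            rows.append(
                {
                    "variant_id": v.id,
                    "exon_id": exon.id,
                    "variant_class": v.klass,
                    "condition": cond,
                    "true_psi": psi,
                    "true_delta_psi": delta,
                }
            )
    return pd.DataFrame(rows)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sequencing


def _add_errors(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = str(rng.choice([b for b in _BASES if b != out[p]]))
    return "".join(out)


def simulate_plasmid_fastq(
    sim: SimulatedPool,
    cfg: SimulationConfig,
    seed: int,
    r1_path,
    r2_path,
) -> pd.DataFrame:
    """Plasmid amplicon pairs: whole-insert coverage, log-normal depth,
    planted per-read misassignment (a chimera carrying this barcode but
    another designed variant's insert). Returns the per-barcode depth table.
    """
    rng = np.random.default_rng(seed)
    records = sim.records
    by_exon: dict[str, list[OligoRecord]] = {}
    for o in records:
        by_exon.setdefault(o.exon_id, []).append(o)
    q = sim.qual_char
    rows, r1s, r2s = [], [], []
    idx = 0
    for o in records:
        depth = max(1, int(round(rng.lognormal(cfg.depth_mu, cfg.depth_sigma))))
        rows.append({"barcode": o.barcode, "variant_id": o.variant_id, "depth": depth})
        others = [
            x for x in by_exon[o.exon_id] if x.variant_id != o.variant_id
        ]
        for _ in range(depth):
            insert = o.sequence
            if others and rng.random() < cfg.misassignment_rate:
                donor = others[int(rng.integers(len(others)))]
                a, b = donor.parts["barcode"]
                insert = donor.sequence[:a] + o.barcode + donor.sequence[b:]
            s1 = _add_errors(insert[: cfg.read_len], rng, cfg.error_rate)
            s2 = _add_errors(revcomp(insert)[: cfg.read_len], rng, cfg.error_rate)
            idx += 1
            r1s.append((f"pl{idx}", s1, q * len(s1)))
            r2s.append((f"pl{idx}", s2, q * len(s2)))
    write_fastq(r1_path, r1s)
    write_fastq(r2_path, r2s)
    return pd.DataFrame(rows)


def simulate_rna_fastq(
    sim: SimulatedPool,
    cfg: SimulationConfig,
    seed: int,
    r1_path,
    r2_path,
    condition: str,
    backbone: Backbone = DEFAULT_BACKBONE,
    layout: ReadLayout = ReadLayout(),
    nmd_survival: dict | None = None,
) -> pd.DataFrame:
    """RNA amplicon pairs for one condition.

    Per barcode, ``n_molecules_per_barcode`` cDNA molecules are drawn:
    inclusion with probability Ψ/100, a distinct 10-nt UMI each, and a
    geometric number of PCR copies. ``nmd_survival`` optionally thins
    inclusion molecules per variant (a per-variant decay factor). Returns
    the per-barcode molecule truth (realized inclusion/skipping counts).
    """
    rng = np.random.default_rng(seed)
    psi = (
        sim.truth[sim.truth["condition"] == condition]
        .set_index("variant_id")["true_psi"]
        .to_dict()
    )
    q = sim.qual_char
    L = cfg.read_len
    rows, r1s, r2s = [], [], []
    idx = 0
    for o in sim.records:
        p_inc = psi[o.variant_id] / 100.0
        test_exon = o.part_seq("exon")
        bc = o.barcode
        trailer = (
            layout.inner_site + bc + layout.barcode_site + revcomp(layout.utr_anchor)
        )
        n_mol = cfg.n_molecules_per_barcode
        inc_flags = rng.random(n_mol) < p_inc
        if nmd_survival is not None:
            s = nmd_survival.get(o.variant_id, 1.0)
            keep = ~inc_flags | (rng.random(n_mol) < s)
            inc_flags = inc_flags[keep]
            n_mol = inc_flags.size
        umis = set()
        while len(umis) < n_mol:
            need = n_mol - len(umis)
            block = rng.choice(list(_BASES), size=(need, layout.umi_len))
            umis.update("".join(r) for r in block)
        umis = sorted(umis)
        copies = rng.geometric(cfg.duplication_p, size=n_mol)
        n_inc = 0
        for mi in range(n_mol):
            inc = bool(inc_flags[mi])
            n_inc += inc
            body = test_exon if inc else ""
            transcript = backbone.exon1_suffix + body + backbone.exon3 + trailer
            read1_t = (transcript + "A" * L)[:L]
            read2_t = (
                umis[mi]
                + layout.utr_anchor
                + revcomp(backbone.exon1_suffix + body + backbone.exon3
                          + layout.inner_site + bc + layout.barcode_site)
                + "A" * L
            )[:L]
            for _ in range(int(copies[mi])):
                idx += 1
                s1 = _add_errors(read1_t, rng, cfg.error_rate)
                s2 = _add_errors(read2_t, rng, cfg.error_rate)
                r1s.append((f"rna{idx}", s1, q * len(s1)))
                r2s.append((f"rna{idx}", s2, q * len(s2)))
        rows.append(
            {
                "barcode": bc,
                "variant_id": o.variant_id,
                "condition": condition,
                "n_molecules": n_mol,
                "n_inclusion_true": n_inc,
                "n_skipping_true": n_mol - n_inc,
            }
        )
    write_fastq(r1_path, r1s)
    write_fastq(r2_path, r2s)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end recovery


def end_to_end_check(
    cfg: SimulationConfig,
    seed: int = 0,
    workdir=None,
    backbone: Backbone = DEFAULT_BACKBONE,
    layout: ReadLayout = ReadLayout(),
) -> dict:
    """Run design -> simulate -> QC -> quantify -> downstream and report
    how well the planted truth is recovered."""
    from .plasmid_qc import run_plasmid_qc
    from .splice_quant import aggregate, delta_psi, quantify
    from .io import read_fastq_pairs
    from .downstream import directionality_agreement

    seeds = derive_seeds(seed)
    stage = "simulate_pool"
    try:
        sim = simulate_pool(cfg, seeds[0])
        with tempfile.TemporaryDirectory() as tmp:
            out = Path(workdir) if workdir else Path(tmp)
            out.mkdir(parents=True, exist_ok=True)
            stage = "plasmid"
            simulate_plasmid_fastq(sim, cfg, seeds[1], out / "pl_1.fastq", out / "pl_2.fastq")
            report, _fid = run_plasmid_qc(
                read_fastq_pairs(out / "pl_1.fastq", out / "pl_2.fastq"), sim.pool
            )
            kept = set(report.kept)
            stage = "rna"
            var_tables = []
            for ci, cond in enumerate(cfg.conditions):
                r1 = out / f"rna_{cond}_1.fastq"
                r2 = out / f"rna_{cond}_2.fastq"
                simulate_rna_fastq(sim, cfg, seeds[2] + ci, r1, r2, cond, backbone, layout)
                bc_table, _log = quantify(
                    read_fastq_pairs(r1, r2),
                    sim.pool,
                    backbone,
                    layout,
                    condition=cond,
                    kept_barcodes=kept,
                )
                var_tables.append(aggregate(bc_table))
            stage = "downstream"
            var_all = pd.concat(var_tables, ignore_index=True)
            dpsi = delta_psi(var_all)
            merged = var_all.merge(
                sim.truth, on=["variant_id", "exon_id", "variant_class", "condition"]
            )
            m = merged["n_inclusion"] + merged["n_skipping"]
            se = np.sqrt(
                merged["true_psi"] * (100 - merged["true_psi"]) / m.clip(lower=1)
            )
            err = (merged["psi"] - merged["true_psi"]).abs()
            within = err <= 3 * np.maximum(se, 1e-9)
            by_class = merged.groupby("variant_class")["psi"].mean()
            order_ok = None
            if cfg.include_controls and {
                "control_mutated",
                "reference",
                "control_consensus",
            } <= set(by_class.index):
                order_ok = bool(
                    by_class["control_mutated"]
                    < by_class["reference"]
                    < by_class["control_consensus"]
                )
            agreement = None
            if len(cfg.conditions) >= 2:
                a, b = cfg.conditions[:2]
                snv = dpsi[dpsi["variant_class"] == "SNV"]
                pa = snv[snv["condition"] == a].set_index("variant_id")["delta_psi"]
                pb = snv[snv["condition"] == b].set_index("variant_id")["delta_psi"]
                common = pa.index.intersection(pb.index)
                agreement = [
                    (r.threshold, r.n_eligible, r.fraction)
                    for r in directionality_agreement(pb[common], pa[common])
                ]
            return {
                "n_variants": int(merged["variant_id"].nunique()),
                "n_kept_barcodes": len(kept),
                "misassignment_rate": report.misassignment_rate,
                "skew_ratio": report.skew_ratio,
                "max_abs_psi_error": float(err.max()),
                "frac_within_3se": float(within.mean()),
                "mean_psi_by_class": by_class.to_dict(),
                "control_ordering_ok": order_ok,
                "agreement": agreement,
            }
    except Exception as exc:  # annotate which stage failed
        raise VexSeqError(f"end-to-end check failed at stage {stage!r}: {exc}") from exc
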