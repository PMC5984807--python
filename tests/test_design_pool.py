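"""Library design: region extraction, variants, controls, barcodes, oligos."""

import re

import numpy as np
import pytest

from vexseq.config import DesignConfig
from vexseq.design_pool import (
    BarcodeAssignment,
    GenomicExon,
    TestRegion,
    VariantSpec,
    apply_variant,
    assemble_oligo,
    extract_test_region,
    frame_to_records,
    generate_barcodes,
    make_consensus_control,
    make_mutated_control,
    pool_to_frame,
    read_pool,
    summarize_pool,
    write_pool,
)
from vexseq.errors import (
    DesignConstraintError,
    FlankTooShortError,
    InfeasibleBarcodeError,
    NonCanonicalBoundaryError,
    RefMismatchError,
    StrayMotifError,
)
from vexseq.util import revcomp

from conftest import MOTIFS, make_toy_locus


class TestExtractTestRegion:
    def test_plus_strand_slices_genome_directly(self, toy_plus):
        genome, exon, region = toy_plus
        assert len(region.up) == 50 and len(region.down) == 20
        assert len(region.sequence) == 50 + exon.length + 20
        chrom = genome[exon.chrom]
        assert region.exon == chrom[exon.start - 1 : exon.end]
        assert region.up[-2:] == "AG" and region.down[:2] == "GT"

    def test_minus_strand_is_reverse_complement_with_swapped_flanks(self, toy_minus):
        genome, exon, region = toy_minus
        chrom = genome[exon.chrom]
        plus_slice = chrom[exon.start - 1 - 20 : exon.end + 50]
        assert region.sequence == revcomp(plus_slice)
        assert region.up[-2:] == "AG" and region.down[:2] == "GT"

    def test_coord_map_is_invertible(self, toy_plus):
        _, _, region = toy_plus
        offsets = list(region.coord_map.values())
        assert sorted(offsets) == list(range(len(region.sequence)))

    @pytest.mark.parametrize("exon_len", [67, 98])
    def test_exon_length_outside_window_rejected(self, exon_len):
        genome, exon = make_toy_locus(seed=1, exon_len=exon_len)
        with pytest.raises(DesignConstraintError):
            extract_test_region(exon, genome)


class TestApplyVariant:
    def test_snv_changes_exactly_one_base(self, toy_plus):
        genome, exon, region = toy_plus
        pos = exon.start + 3
        ref = genome[exon.chrom][pos - 1]
        alt = "A" if ref != "A" else "C"
        v = VariantSpec("v1", exon.chrom, pos, ref, alt, "SNV")
        out = apply_variant(region, v)
        diff = [i for i, (a, b) in enumerate(zip(region.sequence, out.sequence)) if a != b]
        assert diff == [region.coord_map[pos]]
        assert out.sequence[diff[0]] == alt

    def test_minus_strand_allele_is_complemented(self, toy_minus):
        genome, exon, region = toy_minus
        pos = exon.start + 5
        ref = genome[exon.chrom][pos - 1]
        alt = "G" if ref != "G" else "T"
        v = VariantSpec("v2", exon.chrom, pos, ref, alt, "SNV")
        out = apply_variant(region, v)
        off = region.coord_map[pos]
        assert out.sequence[off] == revcomp(alt)

    def test_intronic_deletion_shifts_offsets_and_restores_flank(self, toy_plus):
        genome, exon, region = toy_plus
        # delete 2 bases in the upstream intron (sense offsets 10, 11)
        inv = {o: g for g, o in region.coord_map.items()}
        pos = inv[9]  # VCF-style: anchor base + 2 deleted
        ref3 = genome[exon.chrom][pos - 1 : pos + 2]
        v = VariantSpec("del1", exon.chrom, pos, ref3, ref3[0], "deletion")
        out = apply_variant(region, v)
        assert len(out.up) == 50  # padded back to the minimum
        assert out.pad_up == 2
        # the deleted genomic positions are gone from the coordinate map
        assert pos + 1 not in out.coord_map and pos + 2 not in out.coord_map
        # downstream positions shift by -2 then +2 from padding: net stable
        assert out.coord_map[inv[30]] == 30

    def test_ref_mismatch_is_rejected(self, toy_plus):
        genome, exon, region = toy_plus
        pos = exon.start + 3
        ref = genome[exon.chrom][pos - 1]
        wrong = "A" if ref != "A" else "C"
        v = VariantSpec("bad", exon.chrom, pos, wrong, "G" if wrong != "G" else "T", "SNV")
        with pytest.raises(RefMismatchError):
            apply_variant(region, v)

    def test_position_outside_region_is_rejected(self, toy_plus):
        genome, exon, region = toy_plus
        v = VariantSpec("far", exon.chrom, 2, "A", "C", "SNV")
        with pytest.raises(Exception, match="outside"):
            apply_variant(region, v)


class TestControls:
    def test_mutated_control_changes_only_the_splice_sites(self, toy_plus):
        _, _, region = toy_plus
        out = make_mutated_control(region)
        assert out.up[-2:] == "TC" and out.down[:2] == "CA"
        assert out.exon == region.exon
        dist = sum(a != b for a, b in zip(region.sequence, out.sequence))
        assert dist == 4

    def test_mutated_control_is_not_reapplicable(self, toy_plus):
        _, _, region = toy_plus
        with pytest.raises(NonCanonicalBoundaryError):
            make_mutated_control(make_mutated_control(region))

    def test_consensus_control_installs_tract_and_donor(self, toy_plus):
        _, _, region = toy_plus
        out = make_consensus_control(region)
        assert re.fullmatch(r"[CT]{20}AG", out.up[-22:])
        assert out.down[:6] == "GTAAGT"
        assert out.exon == region.exon

    def test_consensus_control_needs_long_enough_flanks(self, toy_plus):
        _, _, region = toy_plus
        short = TestRegion(
            up=region.up[-21:], exon=region.exon, down=region.down,
            origin=region.origin,
        )
        with pytest.raises(FlankTooShortError):
            make_consensus_control(short)


class TestGenerateBarcodes:
    def test_deterministic_for_fixed_seed(self):
        assert generate_barcodes(25, seed=3) == generate_barcodes(25, seed=3)

    def test_motif_and_distance_constraints_brute_force(self):
        bcs = generate_barcodes(60, seed=5)
        assert len(set(bcs)) == 60 and all(len(b) == 8 for b in bcs)
        for bc in bcs:  # brute-force substring scan
            assert not any(m in bc for m in MOTIFS)
        for i, a in enumerate(bcs):
            for b in bcs[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 2

    def test_infeasible_request_raises(self):
        with pytest.raises(InfeasibleBarcodeError):
            generate_barcodes(4 ** 8)


class TestAssembleOligo:
    def test_parts_concatenate_to_sequence(self, toy_plus, design_cfg):
        _, _, region = toy_plus
        bc = generate_barcodes(1, seed=9)[0]
        rec = assemble_oligo(region, BarcodeAssignment(bc, "v"), design_cfg)
        rebuilt = "".join(rec.part_seq(p) for p in rec.parts)
        assert rebuilt == rec.sequence
        assert rec.sequence.startswith(design_cfg.fwd_primer)
        assert rec.sequence.endswith(revcomp(design_cfg.rev_primer))
        assert rec.sequence.count(bc) == 1

    def test_internal_restriction_motif_is_flagged_with_name(self, toy_plus, design_cfg):
        _, _, region = toy_plus
        poisoned = TestRegion(
            up=region.up[:-8] + "CTGCAG" + region.up[-2:],
            exon=region.exon, down=region.down, origin=region.origin,
        )
        bc = generate_barcodes(1, seed=9)[0]
        with pytest.raises(StrayMotifError, match="PstI"):
            assemble_oligo(poisoned, BarcodeAssignment(bc, "v"), design_cfg)


class TestPoolTable:
    def test_roundtrip_through_tsv(self, small_sim, tmp_path):
        _, sim = small_sim
        path = tmp_path / "pool.tsv"
        write_pool(sim.records, path)
        back = frame_to_records(read_pool(path))
        assert back == sim.records

    def test_variant_oligos_differ_from_reference_by_designed_edit_only(self, small_sim):
        """Brute-force diff oracle: region part of a SNV oligo vs its
        reference oligo differs at exactly the designed position."""
        _, sim = small_sim
        by_variant = {}
        for o in sim.records:
            by_variant.setdefault(o.variant_id, o)
        for o in by_variant.values():
            if o.variant_class != "SNV":
                continue
            ref = by_variant[f"{o.exon_id}_ref"]

            def region_part(rec):
                a = rec.parts["upstream_intron"][0]
                b = rec.parts["downstream_intron"][1]
                return rec.sequence[a:b]

            diffs = [
                i for i, (a, b) in enumerate(zip(region_part(ref), region_part(o)))
                if a != b
            ]
            (edit,) = o.edits
            assert diffs == [edit.offset]

    def test_summarize_counts_and_violations(self, small_sim, design_cfg):
        _, sim = small_sim
        s = summarize_pool(sim.pool)
        assert s.n_exons == 4
        assert s.n_variants_total == 4 * (3 + 3)  # ref + 2 controls + 3 SNVs
        assert s.n_variants_test == 4 * 3
        assert s.min_barcodes_per_variant == 3
        assert design_cfg.min_exon_len <= s.min_exon_len
        assert s.max_exon_len <= design_cfg.max_exon_len
        assert s.min_up_flank >= 50 and s.min_down_flank >= 20
        assert s.violations == ()
        # removing two barcodes of one variant trips the min-barcodes rule
        vid = sim.records[0].variant_id
        trimmed = [o for o in sim.records if o.variant_id != vid]
        trimmed += [o for o in sim.records if o.variant_id == vid][:1]
        flagged = summarize_pool(trimmed)
        assert any("min_barcodes" in v for v in flagged.violations)
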