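"""Downstream analyses: hexamer deltas, agreement, PTC/NMD, conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from vexseq.downstream import (
    conservation_contrast,
    directionality_agreement,
    eseseq_delta,
    external_score_join,
    fit_nmd_model,
    hexamer_association,
    hexamer_gain_loss,
    predict_endogenous_nmd_effect,
    predict_ptc,
)
from vexseq.errors import InsufficientDataError, InvalidOrfError, VexSeqError

TOY_TABLE = {"AAAAAA": 1.0, "AAATAA": -0.5, "AATAAA": -0.3}


class TestEseseqDelta:
    def test_identical_sequences_score_zero(self):
        exon = "ACGTACGTACGT"
        assert eseseq_delta(exon, exon, (3, 4), (3, 4), TOY_TABLE) == 0.0

    def test_toy_snv_hand_enumeration(self):
        # ref AAAAAAA (windows at 0,1 both AAAAAA = 2.0); SNV at offset 3
        # gives AAATAAA (windows AAATAA=-0.5, AATAAA=-0.3 = -0.8)
        delta = eseseq_delta("AAAAAAA", "AAATAAA", (3, 4), (3, 4), TOY_TABLE)
        assert delta == pytest.approx(-2.8)

    def test_only_hexamers_fully_inside_the_exon_count(self):
        # variant at exon offset 0: the single admissible window starts at 0
        ref, var = "AAAAAAAA", "TAAAAAAA"
        table = {"AAAAAA": 1.0, "TAAAAA": 4.0}
        assert eseseq_delta(ref, var, (0, 1), (0, 1), table) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        exon = "".join(rng.choice(list("ACGT"), size=30))
        pos = int(rng.integers(0, 30))
        var = exon[:pos] + ("A" if exon[pos] != "A" else "C") + exon[pos + 1 :]
        table = {
            "".join(rng.choice(list("ACGT"), size=6)): float(rng.normal())
            for _ in range(50)
        }
        locus = (pos, pos + 1)
        fwd = eseseq_delta(exon, var, locus, locus, table)
        rev = eseseq_delta(var, exon, locus, locus, table)
        assert fwd == pytest.approx(-rev)


class TestHexamerAssociation:
    def test_sign_convention_and_averaging(self):
        events = [({"AAAAAA"}, set(), 10.0)]
        df = hexamer_association(events)
        assert df.iloc[0]["mean_signed_dpsi"] == pytest.approx(10.0)

        events = [(set(), {"AAAAAA"}, 10.0)]
        assert hexamer_association(events).iloc[0]["mean_signed_dpsi"] == pytest.approx(-10.0)

        events = [({"AAAAAA"}, set(), 10.0), (set(), {"AAAAAA"}, 4.0)]
        df = hexamer_association(events)
        assert df.iloc[0]["mean_signed_dpsi"] == pytest.approx(3.0)
        assert df.iloc[0]["n_events"] == 2

    def test_gain_loss_sets_from_windows(self):
        gained, lost = hexamer_gain_loss("AAAAAAA", "AAATAAA", (3, 4), (3, 4))
        assert gained == {"AAATAA", "AATAAA"} and lost == {"AAAAAA"}


class TestDirectionalityAgreement:
    def test_worked_examples(self):
        reports = directionality_agreement(
            [+5, -2, +4], [+3, -1, -4], thresholds=[0]
        )
        assert reports[0].n_eligible == 3
        assert reports[0].fraction == pytest.approx(2 / 3)

        reports = directionality_agreement(
            [+6, -7, +1], [+1, -2, +1], thresholds=[5]
        )
        assert (reports[0].n_eligible, reports[0].fraction) == (2, 1.0)

    def test_zero_values_are_ineligible(self):
        reports = directionality_agreement([0.0, 3.0], [2.0, 0.0], thresholds=[0])
        assert reports[0].n_eligible == 0
        assert math.isnan(reports[0].fraction)

    def test_invariant_to_positive_rescaling(self):
        # signs are scale-free; the |ΔΨ| cut must scale with the data
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=100) * 10, rng.normal(size=100) * 10
        base = directionality_agreement(a, b, thresholds=[0, 5, 10])
        scaled = directionality_agreement(
            2.5 * a, 7.0 * b, thresholds=[0, 2.5 * 5, 2.5 * 10]
        )
        assert [(r.n_eligible, r.n_agree) for r in base] == [
            (r.n_eligible, r.n_agree) for r in scaled
        ]


def _random_transcript(rng, n_codons=60):
    mrna = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * n_codons))
    junctions = sorted(rng.choice(np.arange(10, len(mrna) - 1), size=2, replace=False))
    return mrna, [int(j) for j in junctions]


class TestPredictPtc:
    def test_distance_rule_boundaries(self):
        # ATG, one codon, then TAA ending at offset 8
        mrna = "ATG" + "AAA" + "TAA" + "C" * 80
        assert predict_ptc(mrna, 0, [8 + 60]).is_ptc is True
        assert predict_ptc(mrna, 0, [8 + 50]).is_ptc is True  # inclusive boundary
        assert predict_ptc(mrna, 0, [8 + 49]).is_ptc is False

    def test_no_stop_is_flagged(self):
        mrna = "ATG" + "AAA" * 30
        call = predict_ptc(mrna, 0, [50])
        assert call.is_ptc is False and call.no_stop is True

    def test_invalid_orf_start(self):
        with pytest.raises(InvalidOrfError):
            predict_ptc("CCCATGTAA", 0, [5])

    def test_agrees_with_translation_oracle(self):
        """Independent oracle: find the first stop via Biopython translation,
        then apply the distance rule directly."""
        from Bio.Seq import Seq

        rng = np.random.default_rng(2)
        for _ in range(300):
            mrna, junctions = _random_transcript(rng)
            call = predict_ptc(mrna, 0, junctions)
            prot = str(Seq(mrna).translate())
            if "*" in prot:
                stop_end = 3 * prot.index("*") + 2
                expected = junctions[-1] - stop_end >= 50
                assert call.stop_offset == 3 * prot.index("*")
            else:
                expected = False
                assert call.no_stop
            assert call.is_ptc is expected


class TestNmdModel:
    @staticmethod
    def _dataset(rng, n=600, sigma=0.0, effect=-20.0):
        x = rng.uniform(0, 100, size=n)
        ptc = rng.random(n) < 0.5
        y = 5.0 + 0.9 * x + effect * ptc + rng.normal(0, sigma, size=n)
        return y, x, ptc

    def test_noiseless_coefficients_recovered_exactly(self):
        rng = np.random.default_rng(3)
        y, x, ptc = self._dataset(rng, sigma=0.0)
        fit = fit_nmd_model(y, x, ptc, seed=0)
        assert fit.intercept == pytest.approx(5.0, abs=1e-8)
        assert fit.beta_psi == pytest.approx(0.9, abs=1e-10)
        assert fit.beta_ptc == pytest.approx(-20.0, abs=1e-8)
        assert fit.mse_test == pytest.approx(0.0, abs=1e-12)
        assert len(fit.test_idx) == pytest.approx(200, abs=2)

    def test_ptc_term_improves_heldout_mse_across_seeds(self):
        wins, betas = 0, []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y, x, ptc = self._dataset(rng, sigma=5.0)
            fit = fit_nmd_model(y, x, ptc, seed=seed)
            wins += fit.mse_test < fit.mse_test_noptc
            betas.append(fit.beta_ptc)
        assert wins == 5
        assert np.mean(betas) == pytest.approx(-20.0, abs=1.5)

    def test_all_false_flags_degenerates_to_simple_regression(self):
        rng = np.random.default_rng(4)
        y, x, _ = self._dataset(rng, sigma=1.0)
        fit = fit_nmd_model(y, x, np.zeros_like(y), seed=0)
        assert math.isnan(fit.beta_ptc)
        assert fit.mse_test == fit.mse_test_noptc

    def test_endogenous_prediction_applies_ptc_effect_and_clamps(self):
        rng = np.random.default_rng(5)
        y, x, ptc = self._dataset(rng, sigma=0.0)
        fit = fit_nmd_model(y, x, ptc, seed=0)
        table = pd.DataFrame(
            {
                "variant_id": ["a", "b", "c"],
                "psi": [50.0, 50.0, 2.0],
                "ref_psi": [60.0, 60.0, 60.0],
                "delta_psi": [-10.0, -10.0, -58.0],
                "first_annotation": ["stop_gained", "missense_variant", "frameshift_variant"],
            }
        )
        out = predict_endogenous_nmd_effect(table, fit)
        a = out[out["variant_id"] == "a"].iloc[0]
        assert a["predicted_endogenous_psi"] == pytest.approx(5 + 0.9 * 50 - 20)
        b = out[out["variant_id"] == "b"].iloc[0]
        assert b["predicted_endogenous_psi"] == 50.0 and not b["nmd_adjusted"]
        c = out[out["variant_id"] == "c"].iloc[0]
        assert c["predicted_endogenous_psi"] == 0.0 and c["psi_clamped"]


class TestConservationContrast:
    @staticmethod
    def _table(rng, shift, n=100):
        dpsi = np.concatenate([rng.uniform(5, 40, n), rng.uniform(0, 4.99, n)])
        cons = np.concatenate(
            [rng.normal(shift, 1, n), rng.normal(0, 1, n)]
        )
        return pd.DataFrame(
            {"delta_psi": dpsi, "conservation": cons,
             "first_annotation": "synonymous_variant"}
        )

    def test_null_distributions_not_significant(self):
        rng = np.random.default_rng(6)
        c = conservation_contrast(self._table(rng, shift=0.0))
        assert c.p_value > 0.05

    def test_shifted_high_impact_group_detected(self):
        rng = np.random.default_rng(7)
        c = conservation_contrast(self._table(rng, shift=1.0))
        assert c.p_value < 0.01 and c.median_high > c.median_low

    def test_threshold_boundary_is_inclusive(self):
        table = pd.DataFrame(
            {
                "delta_psi": [5.0, -5.0, 4.9, 0.0],
                "conservation": [1.0, 2.0, 3.0, 4.0],
                "first_annotation": "intron_variant",
            }
        )
        c = conservation_contrast(table, threshold=5.0)
        assert (c.n_high, c.n_low) == (2, 2)

    def test_empty_group_raises(self):
        table = pd.DataFrame(
            {"delta_psi": [1.0, 2.0], "conservation": [0.1, 0.2],
             "first_annotation": "intron_variant"}
        )
        with pytest.raises(InsufficientDataError):
            conservation_contrast(table, threshold=5.0)


class TestExternalScoreJoin:
    def test_identical_scores_give_rho_one(self):
        dpsi = pd.DataFrame({"variant_id": list("abcde"), "delta_psi": [1, 3, 2, 5, 4]})
        scores = pd.DataFrame({"variant_id": list("abcde"), "score": [1, 3, 2, 5, 4]})
        _, rho, _ = external_score_join(dpsi, scores)
        assert rho == pytest.approx(1.0)

    def test_permuted_scores_not_significant(self):
        rng = np.random.default_rng(8)
        ids = [f"v{i}" for i in range(60)]
        x = rng.normal(size=60)
        dpsi = pd.DataFrame({"variant_id": ids, "delta_psi": x})
        scores = pd.DataFrame({"variant_id": ids, "score": rng.permutation(x)})
        _, rho, p = external_score_join(dpsi, scores)
        assert abs(rho) < 0.3 and p > 0.05

    def test_duplicate_id_is_named_in_error(self):
        dpsi = pd.DataFrame({"variant_id": ["a"], "delta_psi": [1.0]})
        scores = pd.DataFrame({"variant_id": ["a", "a"], "score": [1.0, 2.0]})
        with pytest.raises(VexSeqError, match="a"):
            external_score_join(dpsi, scores)
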