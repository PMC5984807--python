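"""Interpretive analyses over Ψ/ΔΨ tables.

Covers: exonic splicing enhancer (ESE) hexamer score deltas and per-hexamer
associations with ΔΨ, cross-condition directionality agreement, the 50-nt
premature-termination-codon (PTC) rule with a linear NMD model, conservation
contrasts between high- and low-impact variants, and joins against
externally computed per-variant scores (splice-site strength, conservation,
effect annotations — these are ingested as TSV, never recomputed here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, InvalidOrfError, VexSeqError

STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# hexamer (ESEseq) analyses


def read_hexamer_table(path) -> dict[str, float]:
    """TSV with columns hexamer, score -> mapping; absent keys score 0."""
    df = pd.read_csv(path, sep="\t")
    table = dict(zip(df.iloc[:, 0].str.upper(), df.iloc[:, 1].astype(float)))
    bad = [h for h in table if len(h) != 6 or set(h) - set("ACGT")]
    if bad:
        raise VexSeqError(f"invalid hexamer keys: {bad[:5]}")
    return table


def _window_sum(
    exon: str, locus_start: int, locus_end: int, table: Mapping[str, float]
) -> float:
    """Sum of scores of hexamers fully inside the exon overlapping
    [locus_start, locus_end)."""
    lo = max(0, locus_start - 5)
    hi = min(locus_end - 1, len(exon) - 6)
    return sum(table.get(exon[s : s + 6], 0.0) for s in range(lo, hi + 1))


def eseseq_delta(
    ref_exon: str,
    var_exon: str,
    ref_locus: tuple[int, int],
    var_locus: tuple[int, int],
    table: Mapping[str, float],
) -> float:
    """ΔESE: hexamer-score sum over the variant's window in the variant exon
    minus the same sum in the reference exon.

    The window is every hexamer fully contained in the exon that overlaps
    the variant locus (half-open offsets within the exon); for indels the
    two loci differ in length, giving the union of affected windows on each
    side. Hexamers absent from the table contribute 0. Swapping the two
    sequences negates the result.
    """
    return _window_sum(var_exon, *var_locus, table) - _window_sum(
        ref_exon, *ref_locus, table
    )


def hexamer_gain_loss(
    ref_exon: str,
    var_exon: str,
    ref_locus: tuple[int, int],
    var_locus: tuple[int, int],
) -> tuple[set, set]:
    """Hexamers gained/lost within the variant window (multiset difference
    collapsed to sets)."""
    def _window(exon, a, b):
        lo = max(0, a - 5)
        hi = min(b - 1, len(exon) - 6)
        return [exon[s : s + 6] for s in range(lo, hi + 1)]

    ref_h = _window(ref_exon, *ref_locus)
    var_h = _window(var_exon, *var_locus)
    return set(var_h) - set(ref_h), set(ref_h) - set(var_h)


def hexamer_association(
    events: Sequence[tuple[set, set, float]],
    table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-hexamer mean signed ΔΨ over gain/loss events.

    ``events`` are (gained hexamers, lost hexamers, ΔΨ); a gain contributes
    +ΔΨ and a loss −ΔΨ to each affected hexamer. When a score table is
    given, a ``score`` column is attached (use ``correlation_report`` or
    ``scipy.stats.spearmanr`` for the association with ESE scores).
    """
    acc: dict[str, list[float]] = {}
    for gained, lost, dpsi in events:
        for h in gained:
            acc.setdefault(h, []).append(+dpsi)
        for h in lost:
            acc.setdefault(h, []).append(-dpsi)
    rows = [
        {"hexamer": h, "mean_signed_dpsi": float(np.mean(v)), "n_events": len(v)}
        for h, v in sorted(acc.items())
    ]
    df = pd.DataFrame(rows, columns=["hexamer", "mean_signed_dpsi", "n_events"])
    if table is not None and not df.empty:
        df["score"] = df["hexamer"].map(lambda h: table.get(h, np.nan))
    return df


# ---------------------------------------------------------------------------
# cross-condition directionality


@dataclass(frozen=True)
class AgreementReport:
    threshold: float
    n_eligible: int
    n_agree: int

    @property
    def fraction(self) -> float:
        return self.n_agree / self.n_eligible if self.n_eligible else float("nan")


def directionality_agreement(
    dpsi_a, dpsi_b, thresholds: Sequence[float] = (0, 5, 10)
) -> list[AgreementReport]:
    """Sign agreement of ΔΨ between two conditions.

    Condition A is the conditioning one: at each threshold τ a variant is
    eligible when |ΔΨ_A| > τ and both values are nonzero; agreement means
    equal signs. Fractions are invariant to positive rescaling of either
    column.
    """
    a = np.asarray(dpsi_a, dtype=float)
    b = np.asarray(dpsi_b, dtype=float)
    if a.shape != b.shape:
        raise VexSeqError("paired ΔΨ vectors must have equal length")
    finite = np.isfinite(a) & np.isfinite(b) & (a != 0) & (b != 0)
    out = []
    for tau in thresholds:
        elig = finite & (np.abs(a) > tau)
        agree = elig & (np.sign(a) == np.sign(b))
        out.append(AgreementReport(float(tau), int(elig.sum()), int(agree.sum())))
    return out


# ---------------------------------------------------------------------------
# PTC / NMD


@dataclass(frozen=True)
class PtcCall:
    variant_id: str
    isoform: str
    stop_offset: int | None  # 0-based offset of the stop codon's first base
    last_junction_offset: int
    is_ptc: bool
    no_stop: bool = False


def predict_ptc(
    mrna: str,
    orf_start: int,
    junction_offsets: Sequence[int],
    variant_id: str = "",
    isoform: str = "inclusion",
    min_distance: int = 50,
) -> PtcCall:
    """Apply the 50-nt PTC rule to one isoform.

    Translation starts at ``orf_start`` (must be ATG); the first in-frame
    stop is a PTC when the last exon-exon junction lies >= ``min_distance``
    nt downstream of the stop codon's last base (boundary inclusive). No
    in-frame stop before the transcript end -> not a PTC, flagged no_stop.
    """
    if mrna[orf_start : orf_start + 3] != "ATG":
        raise InvalidOrfError(f"no ATG at ORF start offset {orf_start}")
    if list(junction_offsets) != sorted(set(junction_offsets)):
        raise VexSeqError("junction offsets must be strictly increasing")
    last_junction = junction_offsets[-1]
    for i in range(orf_start, len(mrna) - 2, 3):
        if mrna[i : i + 3] in STOP_CODONS:
            stop_end = i + 2
            return PtcCall(
                variant_id,
                isoform,
                i,
                last_junction,
                last_junction - stop_end >= min_distance,
            )
    return PtcCall(variant_id, isoform, None, last_junction, False, no_stop=True)


@dataclass(frozen=True)
class NmdModelFit:
    """OLS fit of control-condition Ψ on knockdown Ψ and a PTC flag."""

    intercept: float
    beta_psi: float
    beta_ptc: float
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    mse_test: float
    mse_test_noptc: float

    def predict(self, psi_kd, ptc) -> np.ndarray:
        psi_kd = np.asarray(psi_kd, dtype=float)
        ptc = np.asarray(ptc, dtype=float)
        b_ptc = 0.0 if np.isnan(self.beta_ptc) else self.beta_ptc
        return self.intercept + self.beta_psi * psi_kd + b_ptc * ptc


def fit_nmd_model(
    psi_control, psi_knockdown, ptc_flags, seed: int = 0, min_records: int = 30
) -> NmdModelFit:
    """Predict the NMD-competent (control) Ψ from the knockdown Ψ and the
    PTC flag: psi_control ~ 1 + psi_knockdown + ptc, ordinary least squares.

    A seeded 2/3 train / 1/3 test split, stratified by the PTC flag, gives a
    held-out MSE; the nested model without the PTC term is refit on the same
    split (mse_test_noptc). With no PTC-positive records the PTC coefficient
    is reported NA and both MSEs coincide.
    """
    y = np.asarray(psi_control, dtype=float)
    x = np.asarray(psi_knockdown, dtype=float)
    p = np.asarray(ptc_flags, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(p)
    y, x, p = y[ok], x[ok], p[ok]
    n = y.size
    if n < min_records:
        raise InsufficientDataError(f"need >= {min_records} complete records, have {n}")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(n, dtype=bool)
    for stratum in np.unique(p):
        idx = np.flatnonzero(p == stratum)
        k = int(round(len(idx) / 3))
        test_mask[rng.choice(idx, size=k, replace=False)] = True
    train_idx = np.flatnonzero(~test_mask)
    test_idx = np.flatnonzero(test_mask)

    degenerate = len(np.unique(p)) == 1
    X_tr = sm.add_constant(
        np.column_stack([x[train_idx]] if degenerate else [x[train_idx], p[train_idx]])
    )
    fit = sm.OLS(y[train_idx], X_tr).fit()
    if np.linalg.matrix_rank(X_tr) < X_tr.shape[1]:
        raise VexSeqError("rank-deficient design matrix")
    if degenerate:
        intercept, beta_psi = fit.params
        beta_ptc = float("nan")
        pred = intercept + beta_psi * x[test_idx]
    else:
        intercept, beta_psi, beta_ptc = fit.params
        pred = intercept + beta_psi * x[test_idx] + beta_ptc * p[test_idx]
    mse = float(np.mean((y[test_idx] - pred) ** 2))

    X0 = sm.add_constant(x[train_idx])
    fit0 = sm.OLS(y[train_idx], X0).fit()
    pred0 = fit0.params[0] + fit0.params[1] * x[test_idx]
    mse0 = float(np.mean((y[test_idx] - pred0) ** 2))
    return NmdModelFit(
        float(intercept),
        float(beta_psi),
        float(beta_ptc),
        seed,
        train_idx,
        test_idx,
        mse_test=mse,
        mse_test_noptc=mse0 if not degenerate else mse,
    )


def predict_endogenous_nmd_effect(
    variant_table: pd.DataFrame,
    fit: NmdModelFit,
    nmd_classes: Sequence[str] = ("stop_gained", "frameshift_variant"),
) -> pd.DataFrame:
    """Predicted endogenous ΔΨ for variants that create a PTC endogenously.

    For variants whose first annotation is in ``nmd_classes``, the fitted
    model is applied with ptc=1 to the measured (knockdown-context) Ψ; the
    adjusted ΔΨ is recomputed against the unadjusted reference Ψ. Predicted
    Ψ is clamped to [0, 100] and clamping is flagged. Requires columns
    variant_id, psi, ref_psi, delta_psi, first_annotation.
    """
    if fit is None:
        raise VexSeqError("an NMD model fit is required")
    df = variant_table.copy()
    flagged = df["first_annotation"].isin(nmd_classes)
    pred = fit.predict(df["psi"], np.ones(len(df)))
    clamped = (pred < 0) | (pred > 100)
    pred = np.clip(pred, 0.0, 100.0)
    df["predicted_endogenous_psi"] = np.where(flagged, pred, df["psi"])
    df["psi_clamped"] = flagged & clamped
    df["predicted_endogenous_delta_psi"] = np.where(
        flagged, df["predicted_endogenous_psi"] - df["ref_psi"], df["delta_psi"]
    )
    df["nmd_adjusted"] = flagged
    return df


# ---------------------------------------------------------------------------
# conservation


@dataclass(frozen=True)
class ConservationContrast:
    threshold: float
    subgroup: str
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    u_statistic: float
    p_value: float


NON_PROTEIN_CHANGING = (
    "intron_variant",
    "synonymous_variant",
    "splice_region_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
)

SUBGROUP_FILTERS = {
    "all": None,
    "non_protein_changing": NON_PROTEIN_CHANGING,
    "synonymous": ("synonymous_variant",),
    "intron": ("intron_variant",),
}


def conservation_contrast(
    table: pd.DataFrame,
    threshold: float = 5.0,
    subgroup: str = "all",
) -> ConservationContrast:
    """Two-sided Mann-Whitney U of conservation scores between high-impact
    (|ΔΨ| >= threshold, boundary inclusive) and low-impact variants.

    Requires columns delta_psi, conservation, and first_annotation when a
    subgroup filter is used.
    """
    if subgroup not in SUBGROUP_FILTERS:
        raise VexSeqError(f"unknown subgroup {subgroup!r}")
    df = table.dropna(subset=["delta_psi", "conservation"])
    classes = SUBGROUP_FILTERS[subgroup]
    if classes is not None:
        df = df[df["first_annotation"].isin(classes)]
    high = df[df["delta_psi"].abs() >= threshold]["conservation"]
    low = df[df["delta_psi"].abs() < threshold]["conservation"]
    if len(high) < 1 or len(low) < 1:
        raise InsufficientDataError(
            f"empty group for subgroup={subgroup}: high={len(high)}, low={len(low)}"
        )
    res = stats.mannwhitneyu(high, low, alternative="two-sided")
    return ConservationContrast(
        threshold,
        subgroup,
        len(high),
        len(low),
        float(high.median()),
        float(low.median()),
        float(res.statistic),
        float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# external score joins


def external_score_join(
    dpsi_table: pd.DataFrame,
    score_table: pd.DataFrame,
    score_column: str | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Inner join of a ΔΨ table with an external per-variant score table
    (both keyed by variant_id); returns (joined, Spearman ρ, p).

    Duplicate variant ids in the score table are an error; an empty
    intersection is an error.
    """
    if score_column is None:
        score_column = [c for c in score_table.columns if c != "variant_id"][0]
    dup = score_table["variant_id"][score_table["variant_id"].duplicated()]
    if len(dup):
        raise VexSeqError(f"duplicate variant id in score table: {dup.iloc[0]}")
    joined = dpsi_table.merge(
        score_table[["variant_id", score_column]], on="variant_id", how="inner"
    ).dropna(subset=["delta_psi", score_column])
    if joined.empty:
        raise VexSeqError("no shared variant ids between tables")
    rho, p = stats.spearmanr(joined["delta_psi"], joined[score_column])
    return joined, float(rho), float(p)


def read_annotation_table(path) -> pd.DataFrame:
    """Per-variant effect annotations (variant_id, first_annotation); when a
    variant has several rows, the first reported annotation wins."""
    df = pd.read_csv(path, sep="\t")
    return df.drop_duplicates(subset="variant_id", keep="first").reset_index(drop=True)
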