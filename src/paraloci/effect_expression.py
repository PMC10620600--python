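"""Variant-effect classification and relative expression quantification.

Effect classification consumes externally computed predictor scores (SIFT in
[0,1], PROVEAN unbounded) and applies fixed thresholds: SIFT ≤ 0.05 is
deleterious, PROVEAN < −2.5 is deleterious.  The SIFT boundary is inclusive:
the published score table flags substitutions scoring exactly 0.05 as
deleterious even though the methods prose says "below 0.05"; the inclusive
rule reproduces the table.  A variant is "clearly deleterious" only when
both tools agree.

Expression uses the relative standard curve method: a dilution series per
assay gives Ct = intercept + slope·log10(quantity); unknown Cts are
interpolated to quantities, normalized to a reference gene (actin), and
compared between targets as a ratio of group means, with an unpaired
Welch t-test for significance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .locus_model import InputError
from .synthetic_data import QpcrPlate

__all__ = [
    "SIFT_CUTOFF",
    "PROVEAN_CUTOFF",
    "classify_deleterious",
    "count_novel_deleterious",
    "load_effect_scores",
    "StandardCurve",
    "fit_standard_curve",
    "relative_quantity",
    "normalized_expression",
    "fold_change",
    "welch_t_test",
    "quantify_expression",
    "ExpressionResult",
]

SIFT_CUTOFF = 0.05     # inclusive
PROVEAN_CUTOFF = -2.5  # strict

DELETERIOUS_BOTH = "deleterious_both"
PROVEAN_ONLY = "provean_only"
SIFT_ONLY = "sift_only"
TOLERATED = "tolerated"


def load_effect_scores() -> pd.DataFrame:
    """The bundled predictor-score table for the worked variant set.

    Columns: gene, location, snp, aa_change, frequency_pct, rs_id (empty =
    novel), provean, sift, provean_flagged, sift_flagged (the published
    deleterious flags), variant_type (snv/mnv/del).
    """
    with resources.files("paraloci.data").joinpath("effect_scores.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype={"rs_id": "string"})
    frame["rs_id"] = frame["rs_id"].fillna("")
    for col in ("provean_flagged", "sift_flagged"):
        frame[col] = frame[col].astype("Int64")
    return frame


def classify_deleterious(
    rows: pd.DataFrame,
    sift_cutoff: float = SIFT_CUTOFF,
    provean_cutoff: float = PROVEAN_CUTOFF,
) -> pd.DataFrame:
    """Append a ``category`` column from the two threshold rules.

    Rows with a missing score are dropped with a warning (the frameshift row
    of the worked table has no scores).
    """
    out = rows.copy()
    missing = out["provean"].isna() | out["sift"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} row(s) without scores skipped")
        out = out[~missing].copy()
    sift_del = out["sift"] <= sift_cutoff
    prov_del = out["provean"] < provean_cutoff
    out["category"] = np.select(
        [sift_del & prov_del, prov_del, sift_del],
        [DELETERIOUS_BOTH, PROVEAN_ONLY, SIFT_ONLY],
        default=TOLERATED,
    )
    return out


def count_novel_deleterious(classified: pd.DataFrame, gene: str | None = None) -> int:
    """Novel single-nucleotide missense variants deleterious under BOTH tools.

    Novel = no rs identifier; multi-nucleotide and indel rows are excluded
    (the published counts enumerate novel amino-acid-changing SNPs only).
    """
    frame = classified
    if gene is not None:
        frame = frame[frame["gene"] == gene]
    novel = frame["rs_id"].astype(str).str.strip().isin(("", "novel"))
    snv = frame.get("variant_type", pd.Series("snv", index=frame.index)) == "snv"
    return int((novel & snv & (frame["category"] == DELETERIOUS_BOTH)).sum())


# ---------------------------------------------------------------------------
# Relative standard curve quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    ct_range: tuple[float, float]

    def quantity(self, ct: float) -> float:
        return relative_quantity(ct, self)


def fit_standard_curve(quantities, cts) -> StandardCurve:
    """Least-squares Ct = intercept + slope·log10(quantity).

    Efficiency = 10^(−1/slope) − 1 (1.0 = perfect doubling per cycle,
    slope −3.3219).
    """
    q = np.asarray(quantities, float)
    ct = np.asarray(cts, float)
    if np.any(q <= 0):
        raise InputError("standard-curve quantities must be positive")
    if np.unique(q).size < 2:
        raise InputError("degenerate standard curve: all quantities equal")
    fit = stats.linregress(np.log10(q), ct)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
        ct_range=(float(ct.min()), float(ct.max())),
    )


def relative_quantity(ct: float, curve: StandardCurve) -> float:
    if curve.slope == 0:
        raise InputError("zero-slope standard curve")
    lo, hi = curve.ct_range
    margin = 0.05 * (hi - lo)
    if not (lo - margin <= ct <= hi + margin):
        warnings.warn(f"Ct {ct:.2f} outside standard-curve range [{lo:.2f}, {hi:.2f}]")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalized_expression(target_quantity: float, reference_quantity: float) -> float:
    if reference_quantity <= 0:
        raise InputError("non-positive reference quantity")
    return target_quantity / reference_quantity


def fold_change(group_a, group_b) -> float:
    """Ratio of group means of normalized expressions."""
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size == 0 or b.size == 0 or b.mean() == 0:
        raise InputError("fold change undefined for empty or zero-mean groups")
    return float(a.mean() / b.mean())


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unpaired t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size < 2 or b.size < 2:
        raise InputError("Welch test needs at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return (0.0, float(na + nb - 2), 1.0) if a.mean() == b.mean() else (math.inf, float(na + nb - 2), 0.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


@dataclass
class ExpressionResult:
    curves: dict[str, StandardCurve]
    normalized: pd.DataFrame  # sample, assay, quantity, normalized
    fold_change: float
    t_statistic: float
    df: float
    p_value: float
    target_a: str
    target_b: str


def quantify_expression(
    plate: QpcrPlate,
    target_a: str | None = None,
    target_b: str | None = None,
    reference: str | None = None,
) -> ExpressionResult:
    """Full relative-standard-curve workflow on one plate.

    Fits one curve per assay, interpolates sample Cts to quantities,
    normalizes both targets by the reference assay per sample, and compares
    the two targets (ratio of means + Welch test).
    """
    spec = plate.spec
    target_a = target_a or spec.target_a
    target_b = target_b or spec.target_b
    reference = reference or spec.reference

    curves = {}
    for assay, group in plate.standards.groupby("assay"):
        curves[assay] = fit_standard_curve(group["quantity"], group["ct"])
    for assay in (target_a, target_b, reference):
        if assay not in curves:
            raise InputError(f"no standard curve for assay {assay!r}")

    rows = []
    norm: dict[str, dict[str, float]] = {}
    for (sample, assay), group in plate.samples.groupby(["sample", "assay"]):
        q = float(np.mean([relative_quantity(ct, curves[assay]) for ct in group["ct"]]))
        norm.setdefault(sample, {})[assay] = q
    for sample, quantities in sorted(norm.items()):
        ref_q = quantities[reference]
        for assay in (target_a, target_b):
            rows.append({
                "sample": sample, "assay": assay,
                "quantity": quantities[assay],
                "normalized": normalized_expression(quantities[assay], ref_q),
            })
    frame = pd.DataFrame(rows)
    group_a = frame.loc[frame["assay"] == target_a, "normalized"]
    group_b = frame.loc[frame["assay"] == target_b, "normalized"]
    ratio = fold_change(group_a, group_b)
    t, df, p = welch_t_test(group_a, group_b)
    return ExpressionResult(curves, frame, ratio, t, df, p, target_a, target_b)
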