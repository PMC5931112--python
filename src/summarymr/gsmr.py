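"""Multi-SNP causal-effect estimation from harmonised instruments.

Per-SNP Wald ratios b_xy,i = b_zy,i / b_zx,i are pooled by generalised least
squares under the first-order covariance C_ij = r_ij * se_xy,i * se_xy,j,
where r_ij is the LD correlation between instruments i and j:

    b_xy_hat = (1' C^-1 b) / (1' C^-1 1),    se = (1' C^-1 1)^(-1/2)

With uncorrelated instruments (identity LD) this reduces to the classical
inverse-variance-weighted estimator. Horizontally pleiotropic instruments are
detected and removed beforehand by a HEIDI-outlier test: each SNP's ratio is
compared with the ratio at a reference SNP (the top exposure association) and
SNPs whose deviation is improbably large under the null of a single shared
causal effect are excluded.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg, stats

from .types import (
    HarmonisedInstrument,
    HeidiReport,
    HeidiSnp,
    LDMatrix,
    MRResult,
    ValidationError,
)

__all__ = [
    "HEIDI_P_THRESHOLD",
    "EVIDENCE_P_GLOBAL",
    "EVIDENCE_P_BONFERRONI",
    "SingularLDError",
    "wald_ratio",
    "gsmr_estimate",
    "heidi_outlier",
    "classify_evidence",
    "estimate_with_heidi",
]

#: HEIDI-outlier removal threshold.
HEIDI_P_THRESHOLD = 0.01
#: Global significance level.
EVIDENCE_P_GLOBAL = 0.05
#: Bonferroni-corrected level for 10 traits x 3 outcomes.
EVIDENCE_P_BONFERRONI = 0.0017

_COND_MAX = 1e12


class SingularLDError(np.linalg.LinAlgError):
    """The ratio covariance matrix is numerically singular."""


def wald_ratio(b_zx: float, se_zx: float, b_zy: float, se_zy: float) -> tuple[float, float]:
    """Per-SNP causal estimate b_zy / b_zx with its first-order delta-method SE.

    se^2 = se_zy^2 / b_zx^2 + b_zy^2 * se_zx^2 / b_zx^4.
    """
    if b_zx == 0:
        raise ValidationError("b_zx = 0: SNP carries no exposure signal, ratio undefined")
    b_xy = b_zy / b_zx
    var = se_zy**2 / b_zx**2 + b_zy**2 * se_zx**2 / b_zx**4
    return b_xy, math.sqrt(var)


def _ratio_covariance(instruments: list[HarmonisedInstrument], ld: LDMatrix) -> np.ndarray:
    se = np.array([ins.se_xy for ins in instruments])
    r = ld.submatrix([ins.snp_id for ins in instruments]).r_matrix
    return r * np.outer(se, se)


def gsmr_estimate(
    instruments: list[HarmonisedInstrument],
    ld: LDMatrix,
    trait_name: str = "exposure",
    outcome_name: str = "outcome",
    outliers_removed: list[str] | None = None,
    bonferroni_p: float = EVIDENCE_P_BONFERRONI,
) -> MRResult:
    """GLS pooling of per-SNP Wald ratios under LD-aware covariance."""
    if not instruments:
        raise ValidationError("no instruments to pool")
    missing = [ins.snp_id for ins in instruments if ins.snp_id not in ld]
    if missing:
        raise ValidationError(f"instrument(s) absent from LD matrix: {', '.join(missing)}")
    b = np.array([ins.b_xy for ins in instruments])
    C = _ratio_covariance(instruments, ld)
    if np.linalg.cond(C) > _COND_MAX:
        raise SingularLDError(
            "ratio covariance is numerically singular; instruments are too strongly "
            "correlated — prune at a stricter r2 threshold"
        )
    cho = linalg.cho_factor(C, lower=True)
    ones = np.ones_like(b)
    cinv_b = linalg.cho_solve(cho, b)
    cinv_1 = linalg.cho_solve(cho, ones)
    denom = float(ones @ cinv_1)
    b_hat = float(ones @ cinv_b) / denom
    se = denom ** -0.5
    z = b_hat / se
    pvalue = float(2.0 * stats.norm.sf(abs(z)))
    pvalue = max(pvalue, np.nextafter(0, 1))
    return MRResult(
        trait_name=trait_name,
        outcome_name=outcome_name,
        b_xy_hat=b_hat,
        se_xy=se,
        pvalue=pvalue,
        n_snps_used=len(instruments),
        outliers_removed=list(outliers_removed or []),
        evidence_tier=classify_evidence(pvalue, bonferroni_p=bonferroni_p),
    )


def heidi_outlier(
    instruments: list[HarmonisedInstrument],
    ld: LDMatrix,
    p_threshold: float = HEIDI_P_THRESHOLD,
) -> tuple[HeidiReport, list[HarmonisedInstrument]]:
    """HEIDI-outlier test for horizontally pleiotropic instruments.

    The reference SNP is the instrument with the smallest exposure P value.
    For every other SNP i the deviation d_i = b_xy,i - b_xy,ref has variance
    se_xy,i^2 + se_xy,ref^2 - 2 * r_(i,ref) * se_xy,i * se_xy,ref, and
    d_i^2 / var(d_i) is referred to chi-square(1). SNPs with P below
    ``p_threshold`` are flagged and removed in a single pass; re-estimation on
    the survivors is the caller's concern (see :func:`estimate_with_heidi`).
    """
    if not instruments:
        raise ValidationError("HEIDI requires at least one instrument")
    ref = min(instruments, key=lambda ins: (ins.p_zx, -abs(ins.b_zx), ins.snp_id))
    rows: list[HeidiSnp] = []
    retained: list[HarmonisedInstrument] = []
    for ins in instruments:
        if ins.snp_id == ref.snp_id:
            retained.append(ins)
            continue
        d = ins.b_xy - ref.b_xy
        var_d = (
            ins.se_xy**2
            + ref.se_xy**2
            - 2.0 * ld.r(ins.snp_id, ref.snp_id) * ins.se_xy * ref.se_xy
        )
        if var_d <= 0:
            # fully collinear with the reference: no independent information
            var_d = np.finfo(float).tiny
        p = float(stats.chi2.sf(d * d / var_d, df=1))
        flagged = p < p_threshold
        rows.append(HeidiSnp(ins.snp_id, d, math.sqrt(var_d), p, flagged))
        if not flagged:
            retained.append(ins)
    report = HeidiReport(reference_snp=ref.snp_id, rows=rows, p_threshold=p_threshold)
    return report, retained


def classify_evidence(
    pvalue: float,
    global_p: float = EVIDENCE_P_GLOBAL,
    bonferroni_p: float = EVIDENCE_P_BONFERRONI,
) -> str:
    """Tier a causal P value: none (> 0.05), potential (<= 0.05), significant (<= Bonferroni)."""
    if not 0 < pvalue <= 1:
        raise ValidationError(f"pvalue must be in (0, 1], got {pvalue}")
    if pvalue <= bonferroni_p:
        return "significant"
    if pvalue <= global_p:
        return "potential"
    return "none"


def estimate_with_heidi(
    instruments: list[HarmonisedInstrument],
    ld: LDMatrix,
    trait_name: str = "exposure",
    outcome_name: str = "outcome",
    heidi_p: float = HEIDI_P_THRESHOLD,
    bonferroni_p: float = EVIDENCE_P_BONFERRONI,
    iterate: bool = False,
) -> tuple[MRResult, HeidiReport | None]:
    """HEIDI-filter then GSMR-estimate.

    A single filtering pass by default; ``iterate=True`` repeats removal until
    no instrument is flagged.
    """
    report: HeidiReport | None = None
    retained = instruments
    removed: list[str] = []
    if len(retained) >= 2:
        while True:
            report_i, survivors = heidi_outlier(retained, ld, heidi_p)
            if report is None:
                report = report_i
            removed.extend(report_i.flagged_snps)
            retained = survivors
            if not iterate or not report_i.flagged_snps or len(retained) < 2:
                break
    result = gsmr_estimate(
        retained,
        ld,
        trait_name=trait_name,
        outcome_name=outcome_name,
        outliers_removed=removed,
        bonferroni_p=bonferroni_p,
    )
    return result, report
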