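"""Published summary estimates from the glioma MR study of obesity-related traits.

These are the printed inputs the package's evidence analyses consume: the
GSMR odds ratios of glioma (12,488 cases, 18,169 controls) per SD of each of
ten obesity-related exposures with their 95% CIs, the observational
"maximum likely OR" used to calibrate the Wakefield prior (2.0 where no
observational estimate exists), the instrument counts before quality
control, and the recorded per-SNP exclusions (instruments missing from the
outcome GWAS, and instruments removed by the HEIDI-outlier test).

They are study inputs, not package outputs: everything computed from them
(Bayes factors, minimum priors, post-QC counts) is recomputed at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TraitRecord",
    "OBESITY_TRAITS",
    "glioma_all_estimates",
    "instrument_bookkeeping",
]


@dataclass(frozen=True)
class TraitRecord:
    """Printed inputs for one obesity-related exposure."""

    trait: str
    #: all-glioma GSMR estimate: OR per exposure SD (per log-OR unit for
    #: the binary type-2 diabetes exposure) with 95% CI
    or_: float
    ci_low: float
    ci_high: float
    #: largest OR reported in observational studies (2.0 when none exists)
    or_max: float
    #: instrument count at genome-wide significance after LD pruning,
    #: before outcome-availability and pleiotropy exclusions
    n_snps_pre_qc: int
    #: instruments absent from the outcome GWAS
    missing_in_outcome: tuple[str, ...] = ()
    #: instruments removed by the HEIDI-outlier test
    heidi_outliers: tuple[str, ...] = ()
    #: whether recomputing the minimum prior from the printed (rounded) CI
    #: reproduces the printed value to 2 dp; False for the two rows whose
    #: published priors evidently used unrounded estimates
    rounding_stable: bool = True
    binary_exposure: bool = False
    #: proportion of exposure variance explained by the panel, percent
    pve_pct: float | None = None


OBESITY_TRAITS: tuple[TraitRecord, ...] = (
    TraitRecord("two_hour_glucose", 1.25, 0.93, 1.67, 2.00, 7, pve_pct=1.7),
    TraitRecord("bmi", 0.91, 0.77, 1.07, 1.27, 75, pve_pct=2.4),
    TraitRecord("fasting_glucose", 1.00, 0.78, 1.30, 1.57, 33, pve_pct=4.8),
    TraitRecord(
        "fasting_insulin", 1.32, 0.71, 2.46, 2.00, 13,
        missing_in_outcome=("rs1530559",), pve_pct=1.2,
    ),
    TraitRecord("hdl_cholesterol", 1.01, 0.98, 1.05, 2.00, 54, rounding_stable=False, pve_pct=13.7),
    TraitRecord("ldl_cholesterol", 1.00, 0.95, 1.05, 2.00, 26, pve_pct=14.6),
    TraitRecord(
        "type2_diabetes", 1.04, 0.97, 1.11, 0.60, 38,
        missing_in_outcome=("rs2972156", "rs34706136", "rs11257658", "rs144613775"),
        binary_exposure=True, pve_pct=1.6,
    ),
    TraitRecord(
        "total_cholesterol", 0.98, 0.88, 1.09, 2.00, 39,
        missing_in_outcome=("rs7570971",),
        heidi_outliers=("rs11603023",), pve_pct=15.0,
    ),
    TraitRecord(
        "triglycerides", 1.01, 0.97, 1.06, 2.00, 25,
        heidi_outliers=("rs5756931",),
        rounding_stable=False, pve_pct=11.7,
    ),
    TraitRecord("whr", 1.11, 0.84, 1.46, 2.00, 33, pve_pct=0.7),
)

#: instrument counts actually used per trait, after all exclusions
SNPS_AFTER_QC: dict[str, int] = {
    "two_hour_glucose": 7,
    "bmi": 75,
    "fasting_glucose": 33,
    "fasting_insulin": 12,
    "hdl_cholesterol": 54,
    "ldl_cholesterol": 26,
    "type2_diabetes": 34,
    "total_cholesterol": 37,
    "triglycerides": 24,
    "whr": 33,
}

#: outcome GWAS dimensions
GLIOMA_N_CASES = 12_488
GLIOMA_N_CONTROLS = 18_169


def glioma_all_estimates() -> pd.DataFrame:
    """All-glioma estimates and prior calibration as a DataFrame."""
    return pd.DataFrame(
        [
            (t.trait, t.or_, t.ci_low, t.ci_high, t.or_max, t.rounding_stable)
            for t in OBESITY_TRAITS
        ],
        columns=["trait", "or", "ci_low", "ci_high", "or_max", "rounding_stable"],
    )


def instrument_bookkeeping() -> pd.DataFrame:
    """Per-trait instrument counts before QC with the recorded exclusions."""
    return pd.DataFrame(
        [
            (
                t.trait,
                t.n_snps_pre_qc,
                len(t.missing_in_outcome),
                len(t.heidi_outliers),
                SNPS_AFTER_QC[t.trait],
            )
            for t in OBESITY_TRAITS
        ],
        columns=["trait", "n_pre_qc", "n_missing_in_outcome", "n_heidi_outliers", "n_after_qc"],
    )
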