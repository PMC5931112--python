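"""Domain containers shared across the pipeline.

All containers are plain dataclasses over numpy/pandas primitives; validation
happens in ``__post_init__`` so an instance that exists is an instance that
satisfies its invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_ALLELES = frozenset("ACGT")

#: Complementary base map used for strand-flip resolution.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ValidationError(ValueError):
    """An input record or matrix violates a domain invariant."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS.

    ``beta`` is the per-effect-allele estimate in trait SD units for
    quantitative traits, or the log odds ratio for binary traits; ``se`` is
    its standard error.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}: pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G SNPs look identical on both strands."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonisedInstrument:
    """Exposure and outcome effects for one SNP on a shared effect allele.

    ``b_xy`` is the Wald ratio b_zy / b_zx with its delta-method SE.
    """

    snp_id: str
    effect_allele: str
    b_zx: float
    se_zx: float
    p_zx: float
    b_zy: float
    se_zy: float
    p_zy: float
    b_xy: float
    se_xy: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not self.se_zx > 0:
            raise ValidationError(f"{self.snp_id}: se_zx must be > 0")
        if not self.se_zy > 0:
            raise ValidationError(f"{self.snp_id}: se_zy must be > 0")
        if self.b_zx != 0 and not np.isclose(self.b_xy, self.b_zy / self.b_zx, rtol=1e-9, atol=0):
            raise ValidationError(f"{self.snp_id}: b_xy inconsistent with b_zy / b_zx")


class LDMatrix:
    """Symmetric SNP x SNP allelic correlation (r) matrix.

    Values are correlations in [-1, 1]; ``r2`` accessors square them.
    Asymmetry beyond 1e-8 or |r| > 1 + 1e-12 is rejected; tiny numerical
    overshoot of +/-1 is clipped.
    """

    _ASYM_TOL = 1e-8
    _CLIP_TOL = 1e-12
    _PSD_TOL = -1e-8

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        snp_ids = list(snp_ids)
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError(f"LD matrix must be square, got shape {r.shape}")
        if len(snp_ids) != r.shape[0]:
            raise ValidationError(
                f"{len(snp_ids)} SNP ids for a {r.shape[0]}x{r.shape[1]} matrix"
            )
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("duplicate SNP ids in LD matrix")
        asym = np.max(np.abs(r - r.T)) if r.size else 0.0
        if asym > self._ASYM_TOL:
            raise ValidationError(f"LD matrix asymmetric (max |r - r.T| = {asym:.3g})")
        r = (r + r.T) / 2.0
        overshoot = np.max(np.abs(r)) - 1.0 if r.size else 0.0
        if overshoot > self._CLIP_TOL:
            raise ValidationError(f"|r| exceeds 1 by {overshoot:.3g}")
        r = np.clip(r, -1.0, 1.0)
        if r.size and not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        np.fill_diagonal(r, 1.0)
        if r.size:
            min_eig = float(np.linalg.eigvalsh(r).min())
            if min_eig < self._PSD_TOL:
                raise ValidationError(
                    f"LD matrix not positive semi-definite (min eigenvalue {min_eig:.3g})"
                )
        self.snp_ids: list[str] = snp_ids
        self.r_matrix: np.ndarray = r
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r(self, a: str, b: str) -> float:
        return float(self.r_matrix[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r_matrix[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(snp_ids, np.eye(len(snp_ids)))


@dataclass
class MRResult:
    """Pooled causal estimate for one exposure-outcome pair.

    ``b_xy_hat`` is the log OR of the outcome per SD of the exposure (per
    log-OR unit for binary exposures); the OR-scale CI uses the 1.96 normal
    multiplier.
    """

    trait_name: str
    outcome_name: str
    b_xy_hat: float
    se_xy: float
    pvalue: float
    n_snps_used: int
    outliers_removed: list[str] = field(default_factory=list)
    evidence_tier: str = "none"

    def __post_init__(self) -> None:
        if self.n_snps_used < 1:
            raise ValidationError("MRResult requires at least one instrument")

    @property
    def or_(self) -> float:
        return float(np.exp(self.b_xy_hat))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.b_xy_hat - 1.96 * self.se_xy))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.b_xy_hat + 1.96 * self.se_xy))


@dataclass(frozen=True)
class HeidiSnp:
    """Per-SNP row of a HEIDI-outlier report."""

    snp_id: str
    d_i: float
    se_d_i: float
    p_heidi: float
    flagged: bool


@dataclass
class HeidiReport:
    """HEIDI-outlier test over an instrument set relative to a reference SNP."""

    reference_snp: str
    rows: list[HeidiSnp]
    p_threshold: float

    @property
    def flagged_snps(self) -> list[str]:
        return [row.snp_id for row in self.rows if row.flagged]


@dataclass(frozen=True)
class BFNPResult:
    """Wakefield approximate Bayes factor and the minimum prior for BFNP > tau."""

    theta_hat: float
    v: float
    w: float
    z: float
    bf: float
    tau: float
    min_prior: float
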