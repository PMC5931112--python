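"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the ingredients of a summary-data MR study: an
exposure GWAS of a standardised quantitative trait (per-allele effects in SD
units) and a case-control outcome GWAS, sharing a set of instrument SNPs
with block LD structure, a configurable true causal effect, and optionally a
subset of horizontally pleiotropic SNPs with a direct outcome effect.

Sampling model, per SNP i with effect-allele frequency p_i:

* true exposure effects b_zx,i are drawn with magnitudes uniform on
  [0.5, 1.5] x scale and random signs, the scale chosen so that
  sum 2 p_i (1 - p_i) b_zx,i^2 equals the target PVE;
* the observed effect is b_zx,i plus noise with SD 1 / sqrt(2 p_i (1-p_i) n),
  the standard error of a per-allele regression estimate on a standardised
  trait; noise is correlated across SNPs according to the block LD used for
  pruning (the same structure HEIDI's covariance term assumes);
* true outcome effects are b_xy * b_zx,i, plus the pleiotropy offset for
  planted SNPs, observed with SD 1 / sqrt(2 p (1-p) N phi (1-phi)) — the
  binary-trait approximation with case fraction phi, consistent with the
  power formula;
* Wald P values from the observed Z scores.

Defaults mirror the glioma study design: 12,488 cases and 18,169 controls in
the outcome study and a consortium-scale exposure study of 200,000.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from . import gwas_io
from .types import LDMatrix, ValidationError, VariantAssociation

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticStudy",
    "simulate_two_sample",
    "simulate_multi_outcome",
    "write_run",
    "make_fixture_tables",
    "block_ld_matrix",
]

# Non-palindromic allele pairs, so harmonisation is frequency-independent.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated two-sample study."""

    n_snps: int = 30
    true_b_xy: float = 0.0
    n_exposure: int = 200_000
    n_cases: int = 12_488
    n_controls: int = 18_169
    eaf_range: tuple[float, float] = (0.1, 0.9)
    pve_target: float = 0.05
    #: list of (block size, within-block r); None means all SNPs independent.
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    n_pleiotropic: int = 0
    pleiotropy_effect: float = 0.0
    #: "positive" plants a one-sided offset; "balanced" alternates the sign.
    pleiotropy_signs: str = "positive"
    #: draw summary-statistic noise with the block-LD correlation (True) or
    #: independently (False, for IVW-oracle checks).
    correlated_noise: bool = True
    seed: int = 0
    snp_prefix: str = "snp"

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if not 0 < self.pve_target < 1:
            raise ValidationError(f"pve_target must be in (0, 1), got {self.pve_target}")
        if not (0 < self.eaf_range[0] < self.eaf_range[1] < 1):
            raise ValidationError(f"eaf_range must be within (0, 1), got {self.eaf_range}")
        if self.n_pleiotropic > self.n_snps:
            raise ValidationError("n_pleiotropic cannot exceed n_snps")
        if self.ld_blocks is not None:
            sizes = sum(size for size, _ in self.ld_blocks)
            if sizes != self.n_snps:
                raise ValidationError(
                    f"ld_blocks sizes sum to {sizes}, expected n_snps = {self.n_snps}"
                )
            for _, r in self.ld_blocks:
                if not -1 < r < 1:
                    raise ValidationError(f"within-block r must be in (-1, 1), got {r}")
        if self.pleiotropy_signs not in ("positive", "balanced"):
            raise ValidationError("pleiotropy_signs must be 'positive' or 'balanced'")


@dataclass(frozen=True)
class SimulationTruth:
    true_b_xy: float
    pleiotropic_snp_ids: tuple[str, ...]
    b_zx_true: dict[str, float]
    b_zy_true: dict[str, float]


@dataclass
class SyntheticStudy:
    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    ld: LDMatrix
    truth: SimulationTruth
    config: SimulationConfig


def block_ld_matrix(
    snp_ids: list[str], ld_blocks: tuple[tuple[int, float], ...] | None
) -> LDMatrix:
    """Block-diagonal LD with constant correlation r within each block."""
    n = len(snp_ids)
    r = np.eye(n)
    if ld_blocks is not None:
        start = 0
        for size, rho in ld_blocks:
            block = np.full((size, size), rho)
            np.fill_diagonal(block, 1.0)
            r[start : start + size, start : start + size] = block
            start += size
    return LDMatrix(snp_ids, r)


@dataclass
class _ExposureDraw:
    snp_ids: list[str]
    alleles: list[tuple[str, str]]
    eaf: np.ndarray
    b_zx_true: np.ndarray
    b_zx_hat: np.ndarray
    se_zx: np.ndarray
    ld: LDMatrix
    chol: np.ndarray
    pleio_idx: np.ndarray
    pleio_offsets: np.ndarray


def _correlated_noise(rng: np.random.Generator, chol: np.ndarray, sd: np.ndarray, correlated: bool) -> np.ndarray:
    z = rng.standard_normal(len(sd))
    if correlated:
        z = chol @ z
    return z * sd


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, _P_FLOOR)


def _draw_exposure(config: SimulationConfig, rng: np.random.Generator) -> _ExposureDraw:
    n = config.n_snps
    snp_ids = [f"{config.snp_prefix}{i:04d}" for i in range(n)]
    alleles = [_ALLELE_PAIRS[j] for j in rng.integers(0, len(_ALLELE_PAIRS), size=n)]
    eaf = rng.uniform(*config.eaf_range, size=n)
    het = 2.0 * eaf * (1.0 - eaf)

    magnitudes = rng.uniform(0.5, 1.5, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    scale = np.sqrt(config.pve_target / np.sum(het * magnitudes**2))
    b_zx_true = signs * magnitudes * scale
    if np.sum(het * b_zx_true**2) > 1.0:
        raise ValidationError("pve_target infeasible: scaled effects exceed unit trait variance")

    ld = block_ld_matrix(snp_ids, config.ld_blocks)
    # small jitter keeps Cholesky valid for blocks with r close to +/-1
    chol = np.linalg.cholesky(ld.r_matrix + 1e-12 * np.eye(n))

    se_zx = 1.0 / np.sqrt(het * config.n_exposure)
    b_zx_hat = b_zx_true + _correlated_noise(rng, chol, se_zx, config.correlated_noise)

    pleio_idx = np.sort(rng.choice(n, size=config.n_pleiotropic, replace=False))
    offsets = np.full(config.n_pleiotropic, config.pleiotropy_effect, dtype=float)
    if config.pleiotropy_signs == "balanced":
        offsets[1::2] *= -1.0
    return _ExposureDraw(
        snp_ids, alleles, eaf, b_zx_true, b_zx_hat, se_zx, ld, chol, pleio_idx, offsets
    )


def _draw_outcome(
    config: SimulationConfig, rng: np.random.Generator, exp: _ExposureDraw
) -> tuple[list[VariantAssociation], np.ndarray]:
    n_total = config.n_cases + config.n_controls
    phi = config.n_cases / n_total
    het = 2.0 * exp.eaf * (1.0 - exp.eaf)
    se_zy = 1.0 / np.sqrt(het * n_total * phi * (1 - phi))

    b_zy_true = config.true_b_xy * exp.b_zx_true
    b_zy_true = b_zy_true.copy()
    b_zy_true[exp.pleio_idx] += exp.pleio_offsets
    b_zy_hat = b_zy_true + _correlated_noise(rng, exp.chol, se_zy, config.correlated_noise)
    p_zy = _wald_p(b_zy_hat, se_zy)

    # half the outcome records are reported on the opposite effect allele, so
    # harmonisation genuinely has sign flips to resolve
    swap = rng.random(config.n_snps) < 0.5
    records = []
    for i, snp_id in enumerate(exp.snp_ids):
        a1, a2 = exp.alleles[i]
        beta, eaf_i = b_zy_hat[i], exp.eaf[i]
        if swap[i]:
            a1, a2 = a2, a1
            beta, eaf_i = -beta, 1.0 - eaf_i
        records.append(
            VariantAssociation(
                snp_id=snp_id,
                effect_allele=a1,
                other_allele=a2,
                eaf=float(eaf_i),
                beta=float(beta),
                se=float(se_zy[i]),
                pvalue=float(p_zy[i]),
                n=float(n_total),
            )
        )
    return records, b_zy_true


def _exposure_records(config: SimulationConfig, exp: _ExposureDraw) -> list[VariantAssociation]:
    p_zx = _wald_p(exp.b_zx_hat, exp.se_zx)
    return [
        VariantAssociation(
            snp_id=snp_id,
            effect_allele=exp.alleles[i][0],
            other_allele=exp.alleles[i][1],
            eaf=float(exp.eaf[i]),
            beta=float(exp.b_zx_hat[i]),
            se=float(exp.se_zx[i]),
            pvalue=float(p_zx[i]),
            n=float(config.n_exposure),
        )
        for i, snp_id in enumerate(exp.snp_ids)
    ]


def simulate_two_sample(config: SimulationConfig) -> SyntheticStudy:
    """Draw one synthetic exposure/outcome study pair; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    exp = _draw_exposure(config, rng)
    outcome, b_zy_true = _draw_outcome(config, rng, exp)
    truth = SimulationTruth(
        true_b_xy=config.true_b_xy,
        pleiotropic_snp_ids=tuple(exp.snp_ids[i] for i in exp.pleio_idx),
        b_zx_true={s: float(b) for s, b in zip(exp.snp_ids, exp.b_zx_true)},
        b_zy_true={s: float(b) for s, b in zip(exp.snp_ids, b_zy_true)},
    )
    return SyntheticStudy(
        exposure=_exposure_records(config, exp),
        outcome=outcome,
        ld=exp.ld,
        truth=truth,
        config=config,
    )


def simulate_multi_outcome(
    config: SimulationConfig, outcome_names: list[str]
) -> tuple[SyntheticStudy, dict[str, list[VariantAssociation]]]:
    """One exposure study with independently-noised outcome studies.

    All outcomes share the true per-SNP outcome effects (same causal effect
    and pleiotropy); only the sampling noise differs, as for glioma subtype
    analyses drawn from overlapping case series.
    """
    rng = np.random.default_rng(config.seed)
    exp = _draw_exposure(config, rng)
    outcomes: dict[str, list[VariantAssociation]] = {}
    b_zy_true = None
    for name in outcome_names:
        outcomes[name], b_zy_true = _draw_outcome(config, rng, exp)
    truth = SimulationTruth(
        true_b_xy=config.true_b_xy,
        pleiotropic_snp_ids=tuple(exp.snp_ids[i] for i in exp.pleio_idx),
        b_zx_true={s: float(b) for s, b in zip(exp.snp_ids, exp.b_zx_true)},
        b_zy_true={s: float(b) for s, b in zip(exp.snp_ids, b_zy_true)},
    )
    study = SyntheticStudy(
        exposure=_exposure_records(config, exp),
        outcome=outcomes[outcome_names[0]],
        ld=exp.ld,
        truth=truth,
        config=config,
    )
    return study, outcomes


def write_run(
    out_dir,
    n_traits: int = 10,
    outcome_names: tuple[str, ...] = ("all_glioma", "gbm", "non_gbm"),
    seed: int = 0,
    n_snps: int = 30,
    true_b_xy: float = 0.0,
    heterogeneous: bool = True,
):
    """Write a complete multi-trait, multi-outcome run directory.

    Emulates the design of the glioma analysis: several exposure panels
    tested against one outcome GWAS and its two subtype GWAS (same true
    effects, independent sampling noise). Every exclusion path is exercised:
    each trait's LD has one correlated pair (pruning), the first trait's last
    SNP is absent from the outcome files (missing-in-outcome), and with
    ``heterogeneous`` the second trait is underpowered so part of its panel
    fails genome-wide significance, while the fourth trait is flagged binary.

    Returns the :class:`~summarymr.pipeline.RunConfig` (also written as
    ``config.yaml``).
    """
    from . import pipeline  # deferred: pipeline does not import this module

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traits = []
    outcome_records: dict[str, list[VariantAssociation]] = {name: [] for name in outcome_names}
    base = SimulationConfig()
    for t in range(n_traits):
        pve = base.pve_target
        if heterogeneous and t == 1:
            pve = 0.0045  # per-SNP z near the significance boundary
        config = SimulationConfig(
            n_snps=n_snps,
            true_b_xy=true_b_xy,
            pve_target=pve,
            ld_blocks=((2, 0.6),) + ((1, 0.0),) * (n_snps - 2),
            seed=(seed * 1009 + t) % 2**31,
            snp_prefix=f"t{t:02d}snp",
        )
        study, outcomes = simulate_multi_outcome(config, list(outcome_names))
        exposure_path = out_dir / f"trait{t:02d}_exposure.tsv"
        ld_path = out_dir / f"trait{t:02d}_ld.tsv"
        gwas_io.write_gwas_summary(study.exposure, exposure_path)
        gwas_io.write_ld_matrix(study.ld, ld_path)
        drop = {study.exposure[-1].snp_id} if t == 0 else set()
        for name in outcome_names:
            outcome_records[name].extend(
                r for r in outcomes[name] if r.snp_id not in drop
            )
        traits.append(
            pipeline.TraitSpec(
                name=f"trait{t:02d}",
                exposure=str(exposure_path),
                ld=str(ld_path),
                binary=heterogeneous and t == 3,
                n_exposure=float(config.n_exposure),
            )
        )
    outcome_specs = []
    for name in outcome_names:
        path = out_dir / f"outcome_{name}.tsv"
        gwas_io.write_gwas_summary(outcome_records[name], path)
        outcome_specs.append(
            pipeline.OutcomeSpec(
                name=name, path=str(path), n_cases=base.n_cases, n_controls=base.n_controls
            )
        )
    run_config = pipeline.RunConfig(
        traits=traits,
        outcomes=outcome_specs,
        out_dir=str(out_dir / "report"),
        seed=seed,
    )
    run_config.to_yaml(out_dir / "config.yaml")
    return run_config


def make_fixture_tables(study: SyntheticStudy, out_dir) -> dict[str, Path]:
    """Write a study as the text formats the readers consume, plus truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out_dir / "exposure.ma.tsv",
        "outcome": out_dir / "outcome.ma.tsv",
        "ld": out_dir / "ld.tsv",
        "truth": out_dir / "truth.json",
    }
    gwas_io.write_gwas_summary(study.exposure, paths["exposure"])
    gwas_io.write_gwas_summary(study.outcome, paths["outcome"])
    gwas_io.write_ld_matrix(study.ld, paths["ld"])
    truth = {
        "true_b_xy": study.truth.true_b_xy,
        "pleiotropic_snp_ids": list(study.truth.pleiotropic_snp_ids),
        "b_zx_true": study.truth.b_zx_true,
        "b_zy_true": study.truth.b_zy_true,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(study.config).items()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
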