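"""End-to-end orchestration: instruments -> harmonise -> HEIDI -> GSMR -> evidence.

``run_pipeline`` executes every trait x outcome cell of a run configuration
and writes four tables (instrument panel summary, causal estimates, BFNP
minimum priors, power curves) plus a machine-readable run log in which every
input SNP is accounted for exactly once per cell as used or
excluded-with-a-reason. A failure in one cell is logged and does not abort
the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evidence, gsmr, gwas_io, instruments
from .types import ValidationError, VariantAssociation

__all__ = ["TraitSpec", "OutcomeSpec", "Thresholds", "RunConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class TraitSpec:
    name: str
    exposure: str
    ld: str
    binary: bool = False
    or_max: float = evidence.DEFAULT_OR_MAX
    proxies: str | None = None
    n_exposure: float | None = None


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    path: str
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass(frozen=True)
class Thresholds:
    p_gws: float = instruments.GENOME_WIDE_P
    r2_max: float = instruments.LD_R2_MAX
    p_heidi: float = gsmr.HEIDI_P_THRESHOLD
    alpha: float = 0.05
    tau: float = evidence.DEFAULT_TAU

    def __post_init__(self) -> None:
        for name in ("p_gws", "r2_max", "p_heidi", "alpha", "tau"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"threshold {name} must be in (0, 1), got {v}")


@dataclass
class RunConfig:
    traits: list[TraitSpec]
    outcomes: list[OutcomeSpec]
    out_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @property
    def bonferroni_p(self) -> float:
        """Multiplicity-corrected level: alpha over the number of cells tested."""
        return self.thresholds.alpha / (len(self.traits) * len(self.outcomes))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            traits=[TraitSpec(**t) for t in raw["traits"]],
            outcomes=[OutcomeSpec(**o) for o in raw["outcomes"]],
            out_dir=raw["out_dir"],
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "traits": [asdict(t) for t in self.traits],
            "outcomes": [asdict(o) for o in self.outcomes],
            "thresholds": asdict(self.thresholds),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class RunReport:
    instruments_table: pd.DataFrame
    results_table: pd.DataFrame
    bfnp_table: pd.DataFrame
    power_table: pd.DataFrame
    run_log: list[dict]
    failures: list[dict]

    @property
    def ok(self) -> bool:
        return not self.failures


def _read_proxy_table(path) -> dict[str, tuple[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(row.snp_id): (str(row.proxy_id), float(row.r2)) for row in df.itertuples()
    }


_POWER_OR_GRID = np.round(np.arange(1.05, 2.01, 0.05), 2)


def _cell_accounting(
    all_ids: list[str],
    panel_log,
    harmonise_excl,
    heidi_outliers: list[str],
    used: list[str],
) -> list[dict]:
    """One status record per input SNP: used, or excluded with its reason."""
    status: dict[str, str] = {}
    for entry in panel_log:
        if entry.action == "discarded":
            status[entry.snp_id] = entry.reason
    for excl in harmonise_excl:
        status[excl.snp_id] = excl.reason
    for snp_id in heidi_outliers:
        status[snp_id] = "HEIDI-outlier (pleiotropy)"
    for snp_id in used:
        status[snp_id] = "used"
    missing = [s for s in all_ids if s not in status]
    if missing:
        raise ValidationError(f"SNP accounting incomplete for: {', '.join(missing)}")
    return [
        {"snp_id": s, "status": "used" if status[s] == "used" else "excluded", "reason": status[s]}
        for s in all_ids
    ]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every trait x outcome analysis and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    instrument_rows, result_rows, bfnp_rows, power_rows = [], [], [], []
    run_log: list[dict] = []
    failures: list[dict] = []

    outcome_cache: dict[str, list[VariantAssociation]] = {}
    for out_spec in config.outcomes:
        try:
            outcome_cache[out_spec.name], _ = gwas_io.read_gwas_summary(out_spec.path)
        except Exception as exc:  # logged per cell below
            outcome_cache[out_spec.name] = exc  # type: ignore[assignment]

    for trait in config.traits:
        try:
            exposure, _ = gwas_io.read_gwas_summary(trait.exposure)
            ld = gwas_io.read_ld_matrix(trait.ld)
            proxies = _read_proxy_table(trait.proxies) if trait.proxies else None
            panel = instruments.build_panel(
                trait.name,
                exposure,
                ld,
                p_threshold=th.p_gws,
                r2_max=th.r2_max,
                proxies=proxies,
                n_exposure=trait.n_exposure,
                binary_exposure=trait.binary,
            )
        except Exception as exc:
            for out_spec in config.outcomes:
                failures.append(
                    {"trait": trait.name, "outcome": out_spec.name, "stage": "load/select", "error": str(exc)}
                )
            continue

        instrument_rows.append(
            {
                "trait": trait.name,
                "n_snps_selected": len(panel.records),
                "pve": panel.pve,
                "f_statistic": panel.f_statistic,
                "n_exposure": panel.n_exposure,
            }
        )

        for out_spec in config.outcomes:
            outcome = outcome_cache[out_spec.name]
            if isinstance(outcome, Exception):
                failures.append(
                    {"trait": trait.name, "outcome": out_spec.name, "stage": "load outcome", "error": str(outcome)}
                )
                continue
            try:
                harmonised, excluded = gwas_io.harmonise(panel.records, outcome)
                cell_ld = instruments.effective_ld(
                    [ins.snp_id for ins in harmonised], ld, proxies
                )
                result, heidi_report = gsmr.estimate_with_heidi(
                    harmonised,
                    cell_ld,
                    trait_name=trait.name,
                    outcome_name=out_spec.name,
                    heidi_p=th.p_heidi,
                    bonferroni_p=config.bonferroni_p,
                )
            except Exception as exc:
                failures.append(
                    {"trait": trait.name, "outcome": out_spec.name, "stage": "estimate", "error": str(exc)}
                )
                continue

            result_rows.append(
                {
                    "trait": trait.name,
                    "outcome": out_spec.name,
                    "or": result.or_,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "p": result.pvalue,
                    "n_snps": result.n_snps_used,
                    "outliers": ",".join(result.outliers_removed),
                    "tier": result.evidence_tier,
                }
            )

            bf = evidence.wakefield_bf(result.b_xy_hat, result.se_xy, trait.or_max)
            bfnp_rows.append(
                {
                    "trait": trait.name,
                    "outcome": out_spec.name,
                    "or_max": trait.or_max,
                    "bf": bf,
                    "min_prior": evidence.min_prior_for_bfnp(bf, th.tau),
                }
            )

            n_cases = out_spec.n_cases
            n_controls = out_spec.n_controls
            if panel.pve and n_cases and n_controls:
                for or_alt in _POWER_OR_GRID:
                    power_rows.append(
                        {
                            "trait": trait.name,
                            "outcome": out_spec.name,
                            "or_alt": float(or_alt),
                            "power": evidence.power_binary_mr(
                                evidence.PowerSpec(
                                    n_cases=n_cases,
                                    n_controls=n_controls,
                                    pve=panel.pve,
                                    or_alt=float(or_alt),
                                    alpha=th.alpha,
                                )
                            ),
                        }
                    )

            accounting = _cell_accounting(
                [r.snp_id for r in exposure],
                panel.selection_log,
                excluded,
                result.outliers_removed,
                [ins.snp_id for ins in harmonised if ins.snp_id not in result.outliers_removed],
            )
            run_log.append(
                {
                    "stage": "cell",
                    "trait": trait.name,
                    "outcome": out_spec.name,
                    "n_in": len(exposure),
                    "n_used": result.n_snps_used,
                    "heidi_reference": heidi_report.reference_snp if heidi_report else None,
                    "snps": accounting,
                }
            )

    report = RunReport(
        instruments_table=pd.DataFrame(instrument_rows),
        results_table=pd.DataFrame(result_rows),
        bfnp_table=pd.DataFrame(bfnp_rows),
        power_table=pd.DataFrame(power_rows),
        run_log=run_log,
        failures=failures,
    )
    _write_report(report, out_dir, config)
    return report


def _write_report(report: RunReport, out_dir: Path, config: RunConfig) -> None:
    report.instruments_table.to_csv(out_dir / "instruments.tsv", sep="\t", index=False)
    report.results_table.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    report.bfnp_table.to_csv(out_dir / "bfnp.tsv", sep="\t", index=False)
    report.power_table.to_csv(out_dir / "power_curves.tsv", sep="\t", index=False)
    log = {
        "seed": config.seed,
        "bonferroni_p": config.bonferroni_p,
        "thresholds": asdict(config.thresholds),
        "cells": report.run_log,
        "failures": report.failures,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
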