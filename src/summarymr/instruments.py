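"""Instrument selection and instrument-strength summaries.

Instruments are exposure SNPs at genome-wide significance (P <= 5e-8),
pruned to pairwise LD r^2 < 0.01 by a greedy strongest-first rule, with
instrument strength summarised as the proportion of exposure variance
explained (PVE) and the first-stage F-statistic.

"Strongest" ranks by smallest exposure P value, tie-broken by largest |beta|
then lexicographic SNP id, so selection is a total order and the result is
independent of input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import LDMatrix, ValidationError, VariantAssociation

__all__ = [
    "GENOME_WIDE_P",
    "LD_R2_MAX",
    "InstrumentPanel",
    "SelectionEntry",
    "filter_significant",
    "ld_prune",
    "apply_proxies",
    "compute_pve",
    "f_statistic",
    "build_panel",
]

#: Genome-wide significance threshold (inclusive).
GENOME_WIDE_P = 5.0e-8
#: Pairwise LD pruning threshold: r^2 >= this value is excluded.
LD_R2_MAX = 0.01


@dataclass(frozen=True)
class SelectionEntry:
    snp_id: str
    action: str  # "kept" | "discarded" | "proxied"
    reason: str


@dataclass
class InstrumentPanel:
    """A pruned, genome-wide-significant instrument set for one exposure."""

    trait_name: str
    records: list[VariantAssociation]
    pve: float | None
    f_statistic: float | None
    n_exposure: float | None
    selection_log: list[SelectionEntry] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.snp_id, e.action, e.reason) for e in self.selection_log],
            columns=["snp_id", "action", "reason"],
        )


def filter_significant(
    records: list[VariantAssociation], p_threshold: float = GENOME_WIDE_P
) -> list[VariantAssociation]:
    """Keep records with ``pvalue <= p_threshold`` (inclusive), order preserved."""
    return [r for r in records if r.pvalue <= p_threshold]


def _strength_key(rec: VariantAssociation):
    return (rec.pvalue, -abs(rec.beta), rec.snp_id)


class _LDResolver:
    """LD lookup that routes SNPs without direct entries through proxies."""

    def __init__(self, ld: LDMatrix, proxies: dict[str, tuple[str, float]] | None = None):
        self.ld = ld
        self.proxies = proxies or {}
        self.substitutions: list[SelectionEntry] = []
        self._used: set[str] = set()

    def _resolve(self, snp_id: str) -> str:
        if snp_id in self.ld:
            return snp_id
        if snp_id in self.proxies:
            proxy_id, proxy_r2 = self.proxies[snp_id]
            if proxy_id not in self.ld:
                raise ValidationError(
                    f"proxy {proxy_id} for {snp_id} absent from LD matrix"
                )
            if snp_id not in self._used:
                self._used.add(snp_id)
                self.substitutions.append(
                    SelectionEntry(
                        snp_id,
                        "proxied",
                        f"LD evaluated via proxy {proxy_id} (r2 = {proxy_r2:g})",
                    )
                )
            return proxy_id
        raise ValidationError(f"SNP {snp_id} absent from LD matrix and no proxy supplied")

    def r2(self, a: str, b: str) -> float:
        ra, rb = self._resolve(a), self._resolve(b)
        if ra == rb and a != b:
            # two SNPs mapping onto the same LD row are indistinguishable: treat as fully correlated
            return 1.0
        return self.ld.r2(ra, rb)


def apply_proxies(
    records: list[VariantAssociation],
    ld: LDMatrix,
    proxy_table: dict[str, tuple[str, float]],
) -> tuple[list[VariantAssociation], _LDResolver]:
    """Validate a proxy table against the LD matrix and build the LD resolver.

    Proxies substitute LD rows only; association statistics are never taken
    from the proxy. Every record must resolve to an LD entry either directly
    or through its proxy.
    """
    resolver = _LDResolver(ld, proxy_table)
    for rec in records:
        resolver._resolve(rec.snp_id)  # raises if unresolvable
    return records, resolver


def ld_prune(
    records: list[VariantAssociation],
    ld: LDMatrix,
    r2_max: float = LD_R2_MAX,
    proxies: dict[str, tuple[str, float]] | None = None,
) -> tuple[list[VariantAssociation], list[SelectionEntry]]:
    """Greedy strongest-first LD pruning.

    Rank records by strength; accept the strongest remaining record, discard
    every remaining record with r^2 >= ``r2_max`` against it, repeat. The
    output is pairwise r^2 < ``r2_max``; the log records each kept SNP and,
    for each discard, the accepted SNP that triggered it.
    """
    _, resolver = apply_proxies(records, ld, proxies or {})
    log: list[SelectionEntry] = list(resolver.substitutions)
    remaining = sorted(records, key=_strength_key)
    kept: list[VariantAssociation] = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top)
        log.append(SelectionEntry(top.snp_id, "kept", f"strongest remaining (P = {top.pvalue:g})"))
        survivors = []
        for rec in remaining:
            r2 = resolver.r2(rec.snp_id, top.snp_id)
            if r2 >= r2_max:
                log.append(
                    SelectionEntry(
                        rec.snp_id,
                        "discarded",
                        f"r2 = {r2:.4g} with kept SNP {top.snp_id}",
                    )
                )
            else:
                survivors.append(rec)
        remaining = survivors
    return kept, log


def effective_ld(
    snp_ids: list[str],
    ld: LDMatrix,
    proxies: dict[str, tuple[str, float]] | None = None,
) -> LDMatrix:
    """LD submatrix over ``snp_ids``, routing absent SNPs through their proxies.

    The returned matrix is labelled with the original ids so downstream
    estimators stay proxy-agnostic.
    """
    resolver = _LDResolver(ld, proxies)
    resolved = [resolver._resolve(s) for s in snp_ids]
    sub = ld.submatrix(resolved)
    return LDMatrix(snp_ids, sub.r_matrix)


def compute_pve(records: list[VariantAssociation]) -> float:
    """Proportion of exposure variance explained by independent instruments.

    Sum of 2 * eaf * (1 - eaf) * beta^2 over SNPs, assuming the exposure is
    standardised to unit variance (betas in trait SD units).
    """
    missing = [r.snp_id for r in records if r.eaf is None]
    if missing:
        raise ValidationError(f"eaf required for PVE but missing for: {', '.join(missing)}")
    return float(sum(2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2 for r in records))


def f_statistic(pve: float, n: float, k: int) -> float:
    """First-stage F-statistic for k instruments explaining ``pve`` of the exposure.

    F = ((n - k - 1) / k) * (pve / (1 - pve)). Values below ~10 conventionally
    flag weak-instrument bias.
    """
    if not 0 <= pve < 1:
        raise ValidationError(f"pve must be in [0, 1), got {pve}")
    if not n > k + 1 or k < 1:
        raise ValidationError(f"need n > k + 1 >= 2, got n = {n}, k = {k}")
    return float((n - k - 1) / k * (pve / (1 - pve)))


def build_panel(
    trait_name: str,
    records: list[VariantAssociation],
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_max: float = LD_R2_MAX,
    proxies: dict[str, tuple[str, float]] | None = None,
    n_exposure: float | None = None,
    binary_exposure: bool = False,
) -> InstrumentPanel:
    """Select the instrument panel for one exposure and summarise its strength.

    Binary exposures (effects as log ORs rather than SD units) get no PVE or
    F-statistic, since the variance-explained formula assumes a standardised
    quantitative trait.
    """
    log: list[SelectionEntry] = []
    significant = filter_significant(records, p_threshold)
    dropped = {r.snp_id for r in records} - {r.snp_id for r in significant}
    for snp_id in sorted(dropped):
        log.append(SelectionEntry(snp_id, "discarded", f"P > {p_threshold:g}"))
    pruned, prune_log = ld_prune(significant, ld, r2_max, proxies)
    log.extend(prune_log)

    pve = f_stat = None
    if not binary_exposure and all(r.eaf is not None for r in pruned) and pruned:
        pve = compute_pve(pruned)
        if n_exposure is None:
            n_exposure = _panel_n(pruned)
        if n_exposure is not None and n_exposure > len(pruned) + 1:
            f_stat = f_statistic(pve, n_exposure, len(pruned))
    return InstrumentPanel(
        trait_name=trait_name,
        records=pruned,
        pve=pve,
        f_statistic=f_stat,
        n_exposure=n_exposure,
        selection_log=log,
    )


def _panel_n(records: list[VariantAssociation]) -> float | None:
    ns = [r.n for r in records if r.n is not None]
    return float(min(ns)) if ns else None
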