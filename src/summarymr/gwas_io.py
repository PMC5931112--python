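"""Reading, writing and harmonising GWAS summary statistics and LD matrices.

The default text dialect is the GCTA-COJO ``.ma`` layout — whitespace- or
tab-delimited with header columns ``SNP A1 A2 freq b se p N`` — the de-facto
interchange format for summary-data MR. Column names are remappable via a
:class:`Dialect`.

Harmonisation puts outcome effects on the exposure effect allele, resolving
strand flips by allele complementing and palindromic SNPs by allele-frequency
comparison (dropping them when frequencies are uninformative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    COMPLEMENT,
    HarmonisedInstrument,
    LDMatrix,
    ValidationError,
    VariantAssociation,
)

__all__ = [
    "Dialect",
    "ConfigurationError",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_ld_matrix",
    "write_ld_matrix",
    "harmonise",
    "Exclusion",
]


class ConfigurationError(ValueError):
    """A column mapping does not match the file being read."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping from a summary-statistic header to record fields."""

    snp_id: str = "SNP"
    effect_allele: str = "A1"
    other_allele: str = "A2"
    eaf: str | None = "freq"
    beta: str = "b"
    se: str = "se"
    pvalue: str = "p"
    n: str | None = "N"

    def mandatory(self) -> dict[str, str]:
        return {
            "snp_id": self.snp_id,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
        }

    def optional(self) -> dict[str, str]:
        out = {}
        if self.eaf is not None:
            out["eaf"] = self.eaf
        if self.n is not None:
            out["n"] = self.n
        return out


def read_gwas_summary(
    path,
    dialect: Dialect | None = None,
    on_invalid: str = "raise",
) -> tuple[list[VariantAssociation], list[tuple[int, str]]]:
    """Read a summary-statistic table into validated records.

    Returns ``(records, rejected)`` where ``rejected`` lists ``(row_index,
    reason)`` for rows failing a domain invariant. Row order is preserved.
    Alleles are upper-cased. With ``on_invalid="raise"`` (default) any
    rejected row aborts the read with a report of all offending rows;
    ``on_invalid="report"`` drops them and returns the report.
    """
    if dialect is None:
        dialect = Dialect()
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [col for col in dialect.mandatory().values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mandatory column(s) {missing} absent from header {list(df.columns)}"
        )
    optional_present = {
        fld: col for fld, col in dialect.optional().items() if col in df.columns
    }

    records: list[VariantAssociation] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            kwargs = {
                "snp_id": str(row[dialect.snp_id]),
                "effect_allele": str(row[dialect.effect_allele]).upper(),
                "other_allele": str(row[dialect.other_allele]).upper(),
                "beta": _parse_float(row[dialect.beta], "beta"),
                "se": _parse_float(row[dialect.se], "se"),
                "pvalue": _parse_float(row[dialect.pvalue], "pvalue"),
            }
            for fld, col in optional_present.items():
                val = row[col]
                kwargs[fld] = None if _is_missing(val) else _parse_float(val, fld)
            records.append(VariantAssociation(**kwargs))
        except (ValidationError, ValueError) as exc:
            rejected.append((i, str(exc)))
    if rejected and on_invalid == "raise":
        report = "; ".join(f"row {i}: {msg}" for i, msg in rejected)
        raise ValidationError(f"{path}: {len(rejected)} invalid row(s): {report}")
    return records, rejected


def _is_missing(val) -> bool:
    return val is None or (isinstance(val, float) and math.isnan(val)) or str(val) in (
        "",
        "NA",
        "nan",
        ".",
    )


def _parse_float(val, name: str) -> float:
    try:
        return float(val)
    except (TypeError, ValueError):
        raise ValueError(f"unparsable {name} value {val!r}") from None


def write_gwas_summary(records: list[VariantAssociation], path, dialect: Dialect | None = None) -> None:
    """Write records as a TSV in the given dialect (round-trips through the reader)."""
    if dialect is None:
        dialect = Dialect()
    cols = {
        dialect.snp_id: [r.snp_id for r in records],
        dialect.effect_allele: [r.effect_allele for r in records],
        dialect.other_allele: [r.other_allele for r in records],
    }
    if dialect.eaf is not None:
        cols[dialect.eaf] = [r.eaf if r.eaf is not None else "NA" for r in records]
    cols[dialect.beta] = [repr(r.beta) for r in records]
    cols[dialect.se] = [repr(r.se) for r in records]
    cols[dialect.pvalue] = [repr(r.pvalue) for r in records]
    if dialect.n is not None:
        cols[dialect.n] = [r.n if r.n is not None else "NA" for r in records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD correlation matrix from TSV with SNP ids as header and index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: LD matrix not square ({df.shape[0]}x{df.shape[1]})")
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: LD matrix row and column ids disagree")
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r_matrix, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class Exclusion:
    snp_id: str
    reason: str


# Frequency rules for palindromic (A/T, C/G) SNPs, where complementing cannot
# distinguish strands: only call the orientation when the minor-allele
# frequency is informative in BOTH studies and the frequencies agree after the
# inferred orientation.
_PALINDROMIC_MAF_MAX = 0.42
_PALINDROMIC_FREQ_AGREE = 0.2


def _wald_ratio_fields(b_zx: float, se_zx: float, b_zy: float, se_zy: float) -> tuple[float, float]:
    # local copy of the delta-method ratio to keep gwas_io importable without gsmr
    b_xy = b_zy / b_zx
    var = se_zy**2 / b_zx**2 + b_zy**2 * se_zx**2 / b_zx**4
    return b_xy, math.sqrt(var)


def harmonise(
    exposure: list[VariantAssociation],
    outcome: list[VariantAssociation],
) -> tuple[list[HarmonisedInstrument], list[Exclusion]]:
    """Express outcome effects on the exposure effect allele, SNP by SNP.

    For each exposure SNP found in the outcome study the outcome record is
    aligned to the exposure's effect allele: a swapped allele pair flips the
    sign of ``b_zy`` (and ``eaf`` to ``1 - eaf``); alleles reported on the
    opposite strand are complemented first. Palindromic SNPs are oriented by
    allele frequency where conclusive and dropped otherwise. Exposure SNPs
    absent from the outcome, and SNPs whose allele sets cannot be reconciled,
    are excluded and reported. SNPs with ``b_zx == 0`` cannot form a Wald
    ratio and are excluded.
    """
    outcome_by_id = {r.snp_id: r for r in outcome}
    instruments: list[HarmonisedInstrument] = []
    excluded: list[Exclusion] = []
    for exp in exposure:
        out = outcome_by_id.get(exp.snp_id)
        if out is None:
            excluded.append(Exclusion(exp.snp_id, "missing in outcome"))
            continue
        aligned, reason = _align(exp, out)
        if aligned is None:
            excluded.append(Exclusion(exp.snp_id, reason))
            continue
        if exp.beta == 0:
            excluded.append(Exclusion(exp.snp_id, "null exposure effect (b_zx = 0)"))
            continue
        b_xy, se_xy = _wald_ratio_fields(exp.beta, exp.se, aligned.beta, aligned.se)
        instruments.append(
            HarmonisedInstrument(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                b_zx=exp.beta,
                se_zx=exp.se,
                p_zx=exp.pvalue,
                b_zy=aligned.beta,
                se_zy=aligned.se,
                p_zy=aligned.pvalue,
                b_xy=b_xy,
                se_xy=se_xy,
                eaf=exp.eaf,
            )
        )
    return instruments, excluded


def _flip(rec: VariantAssociation) -> VariantAssociation:
    """Re-express a record on the opposite effect allele."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _complement(rec: VariantAssociation) -> VariantAssociation:
    return replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )


def _align(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[VariantAssociation | None, str]:
    if exp.is_palindromic:
        if out.alleles not in (exp.alleles, exp.alleles[::-1]):
            return None, "allele mismatch"
        return _align_palindromic(exp, out)
    if out.alleles == exp.alleles:
        return out, ""
    if out.alleles == exp.alleles[::-1]:
        return _flip(out), ""
    comp = _complement(out)
    if comp.alleles == exp.alleles:
        return comp, ""
    if comp.alleles == exp.alleles[::-1]:
        return _flip(comp), ""
    return None, "allele mismatch"


def _align_palindromic(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[VariantAssociation | None, str]:
    if exp.eaf is None or out.eaf is None:
        return None, "palindromic SNP without allele frequencies"
    if min(exp.eaf, 1 - exp.eaf) >= _PALINDROMIC_MAF_MAX or min(
        out.eaf, 1 - out.eaf
    ) >= _PALINDROMIC_MAF_MAX:
        return None, "palindromic SNP with uninformative allele frequency"
    # orient the outcome record so its stated effect allele is the exposure's,
    # then pick the strand orientation whose frequency matches the exposure
    candidate = out if out.alleles == exp.alleles else _flip(out)
    if (candidate.eaf < 0.5) != (exp.eaf < 0.5):
        # frequencies disagree as written: the outcome is on the other strand,
        # which for a palindromic SNP swaps the allele labels
        candidate = _flip(candidate)
    if abs(candidate.eaf - exp.eaf) > _PALINDROMIC_FREQ_AGREE:
        return None, "palindromic SNP with discordant allele frequencies"
    return candidate, ""
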