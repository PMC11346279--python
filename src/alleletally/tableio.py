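"""Readers and writers for allele-count tables.

Canonical interchange is a long-format, tab-delimited UTF-8 file with a
header row and one row per (variant, population) cell.  A convenience reader
for VCFs carrying per-population ``AC_<pop>``/``AN_<pop>`` INFO keys (the
gnomAD dialect) is provided; it is not a general VCF toolkit and requires
multi-allelic records to be pre-split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import (
    FrequencyTable,
    InheritanceMode,
    PopCounts,
    VariantRecord,
    validate_table,
)

__all__ = [
    "TableDialect",
    "TableFormatError",
    "read_table_tsv",
    "write_table_tsv",
    "read_vcf_population_counts",
]

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """Raised when an input file violates the table format contract."""


@dataclass(frozen=True)
class TableDialect:
    """Column names of the long-format TSV dialect."""

    variant_id: str = "variant_id"
    gene: str = "gene"
    inheritance_mode: str = "inheritance_mode"
    population: str = "population"
    ac: str = "ac"
    an: str = "an"
    shortlisted: str = "shortlisted"

    def required_columns(self) -> list[str]:
        return [
            self.variant_id,
            self.gene,
            self.inheritance_mode,
            self.population,
            self.ac,
            self.an,
        ]


DEFAULT_DIALECT = TableDialect()

_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _parse_bool(value: str, line: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise TableFormatError(f"line {line}: cannot parse boolean {value!r}")


def read_table_tsv(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    lenient: bool = False,
) -> FrequencyTable:
    """Read a long-format TSV into a validated :class:`FrequencyTable`.

    Errors name 1-based file line numbers (header is line 1).  Structural
    violations found by :func:`validate_table` raise unless ``lenient`` is
    set, in which case they are logged and the table returned as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required_columns() if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required columns: {missing}")
    has_shortlist = dialect.shortlisted in df.columns

    populations: list[str] = []
    records: dict[str, VariantRecord] = {}
    seen_cells: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # 1-based, after header
        vid = getattr(row, dialect.variant_id)
        pop = getattr(row, dialect.population)
        if (vid, pop) in seen_cells:
            raise TableFormatError(
                f"line {line}: duplicate (variant, population) row ({vid!r}, {pop!r})"
            )
        seen_cells.add((vid, pop))
        if pop not in populations:
            populations.append(pop)
        try:
            ac = int(getattr(row, dialect.ac))
            an = int(getattr(row, dialect.an))
        except ValueError:
            raise TableFormatError(
                f"line {line}: non-integer ac/an "
                f"({getattr(row, dialect.ac)!r}, {getattr(row, dialect.an)!r})"
            ) from None
        try:
            mode = InheritanceMode(getattr(row, dialect.inheritance_mode))
        except ValueError:
            raise TableFormatError(
                f"line {line}: unknown inheritance_mode "
                f"{getattr(row, dialect.inheritance_mode)!r}"
            ) from None
        shortlisted = (
            _parse_bool(getattr(row, dialect.shortlisted), line) if has_shortlist else True
        )
        rec = records.get(vid)
        if rec is None:
            rec = VariantRecord(
                variant_id=vid,
                gene=getattr(row, dialect.gene),
                inheritance_mode=mode,
                counts={},
                shortlisted=shortlisted,
            )
            records[vid] = rec
        if ac > an:
            raise TableFormatError(f"line {line}: ac ({ac}) exceeds an ({an})")
        rec.counts[pop] = PopCounts(ac=ac, an=an)

    table = FrequencyTable(populations=populations, records=list(records.values()))
    violations = validate_table(table)
    if violations:
        if lenient:
            for v in violations:
                logger.warning("table violation: %s", v)
        else:
            raise TableFormatError(
                "table violates invariants: " + "; ".join(str(v) for v in violations)
            )
    return table


def write_table_tsv(
    table: FrequencyTable,
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write a table in the long-format TSV dialect (lossless round-trip)."""
    rows = []
    for rec in table.records:
        for pop in table.populations:
            c = rec.counts[pop]
            rows.append(
                {
                    dialect.variant_id: rec.variant_id,
                    dialect.gene: rec.gene,
                    dialect.inheritance_mode: rec.inheritance_mode.value,
                    dialect.population: pop,
                    dialect.ac: c.ac,
                    dialect.an: c.an,
                    dialect.shortlisted: str(rec.shortlisted).lower(),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf_population_counts(
    path: str | Path,
    populations: list[str],
    contig_modes: dict[str, InheritanceMode],
    default_mode: InheritanceMode | None = None,
    gene_info_key: str = "GENE",
    ac_pattern: str = "AC_{pop}",
    an_pattern: str = "AN_{pop}",
) -> FrequencyTable:
    """Read per-population AC/AN INFO fields from a gnomAD-style VCF.

    One :class:`VariantRecord` per VCF record; inheritance mode is inferred
    from the contig via ``contig_modes`` (``default_mode`` applies to contigs
    not in the map; without it an unknown contig is an error).  Records
    lacking a requested AC/AN key are skipped with a warning.  Multi-allelic
    records are rejected — split them first.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    records: list[VariantRecord] = []
    skipped = 0
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            raise TableFormatError(
                f"multi-allelic record at {v.CHROM}:{v.POS}; pre-split the VCF "
                "(e.g. bcftools norm -m-) before reading"
            )
        mode = contig_modes.get(v.CHROM, default_mode)
        if mode is None:
            raise TableFormatError(
                f"contig {v.CHROM!r} has no inheritance mode mapping and no default"
            )
        counts: dict[str, PopCounts] = {}
        ok = True
        for pop in populations:
            ac = v.INFO.get(ac_pattern.format(pop=pop))
            an = v.INFO.get(an_pattern.format(pop=pop))
            if ac is None or an is None:
                logger.warning(
                    "record %s:%s lacks %s/%s; skipped",
                    v.CHROM,
                    v.POS,
                    ac_pattern.format(pop=pop),
                    an_pattern.format(pop=pop),
                )
                ok = False
                break
            counts[pop] = PopCounts(ac=int(ac), an=int(an))
        if not ok:
            skipped += 1
            continue
        gene = v.INFO.get(gene_info_key) or v.CHROM
        vid = v.ID or f"{v.CHROM}-{v.POS}-{v.REF}-{v.ALT[0]}"
        records.append(
            VariantRecord(
                variant_id=vid,
                gene=str(gene),
                inheritance_mode=mode,
                counts=counts,
                shortlisted=True,
            )
        )
    if skipped:
        logger.warning("skipped %d record(s) lacking requested INFO keys", skipped)
    return FrequencyTable(populations=list(populations), records=records)
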