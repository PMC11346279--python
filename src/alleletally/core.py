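"""Core domain types for per-population allele-count tables.

The data model is deliberately summary-level: per variant and per population
we keep only an allele count (AC) and an allele number (AN), plus gene and
inheritance-mode annotation.  Genotype-level storage, phasing and linkage are
out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "InheritanceMode",
    "PresenceStatus",
    "PopCounts",
    "VariantRecord",
    "FrequencyTable",
    "PopulationSpec",
    "Violation",
    "frequency",
    "presence_status",
    "validate_table",
]


class InheritanceMode(str, enum.Enum):
    """Chromosomal inheritance mode of a gene."""

    AUTOSOMAL = "autosomal"
    X_LINKED = "x_linked"


class PresenceStatus(str, enum.Enum):
    """Sampling-aware presence of a variant in one population's data.

    ``ABSENT`` requires a nonzero allele number: a population with no
    genotyped copies at a site has *no data*, which is not absence.
    """

    PRESENT = "present"
    ABSENT = "absent"
    NO_DATA = "no_data"


@dataclass(frozen=True)
class PopCounts:
    """Allele count / allele number pair for one population."""

    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0:
            raise ValueError(f"negative counts: ac={self.ac}, an={self.an}")


@dataclass
class VariantRecord:
    """One variant with per-population AC/AN counts.

    Parameters
    ----------
    variant_id:
        Unique identifier (e.g. an HGVS string or chrom-pos-ref-alt key).
    gene:
        Gene label; inheritance_mode must be constant per gene within a table.
    inheritance_mode:
        :class:`InheritanceMode` of the gene.
    counts:
        Mapping of population label to :class:`PopCounts`.
    shortlisted:
        Externally supplied membership flag for the analyzed shortlist.
        Shortlist construction (functional prediction) is not recomputed here.
    """

    variant_id: str
    gene: str
    inheritance_mode: InheritanceMode
    counts: dict[str, PopCounts] = field(default_factory=dict)
    shortlisted: bool = True

    def populations(self) -> list[str]:
        return list(self.counts)


@dataclass
class FrequencyTable:
    """Ordered collection of :class:`VariantRecord` over a fixed population set."""

    populations: list[str]
    records: list[VariantRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.gene, None)
        return list(seen)

    def get(self, variant_id: str) -> VariantRecord:
        for rec in self.records:
            if rec.variant_id == variant_id:
                return rec
        raise KeyError(variant_id)


@dataclass(frozen=True)
class PopulationSpec:
    """Karyotype composition of a population sample.

    Allele numbers derive from the karyotype mix: autosomal sites have two
    copies per person, X-linked sites two per XX person and one per XY person.
    """

    label: str
    n_xx: int
    n_xy: int

    def __post_init__(self) -> None:
        if self.n_xx < 0 or self.n_xy < 0:
            raise ValueError(f"negative individual counts in {self.label!r}")

    @property
    def n_individuals(self) -> int:
        return self.n_xx + self.n_xy

    def allele_number(self, mode: InheritanceMode) -> int:
        if mode is InheritanceMode.AUTOSOMAL:
            return 2 * (self.n_xx + self.n_xy)
        return 2 * self.n_xx + self.n_xy

    @classmethod
    def half_half(cls, label: str, n_individuals: int) -> "PopulationSpec":
        """Split ``n_individuals`` as evenly as possible into XX and XY."""
        n_xx = n_individuals // 2 + n_individuals % 2
        return cls(label=label, n_xx=n_xx, n_xy=n_individuals - n_xx)


def _require_population(record: VariantRecord, pop: str) -> PopCounts:
    try:
        return record.counts[pop]
    except KeyError:
        raise KeyError(
            f"unknown population label {pop!r} for variant {record.variant_id!r}; "
            f"known labels: {sorted(record.counts)}"
        ) from None


def frequency(record: VariantRecord, pop: str) -> float | None:
    """Sampled allele frequency AC/AN in ``pop``, or ``None`` when AN = 0.

    No data is not a frequency: a zero allele number yields ``None`` rather
    than zero, so callers must decide explicitly how to treat missingness.
    """
    c = _require_population(record, pop)
    if c.an == 0:
        return None
    return c.ac / c.an


def presence_status(record: VariantRecord, pop: str) -> PresenceStatus:
    """Classify a variant's presence in one population's sample data."""
    c = _require_population(record, pop)
    if c.ac >= 1:
        return PresenceStatus.PRESENT
    if c.an > 0:
        return PresenceStatus.ABSENT
    return PresenceStatus.NO_DATA


@dataclass(frozen=True)
class Violation:
    """One broken table invariant; violations are data, not exceptions."""

    variant_id: str | None
    population: str | None
    rule: str

    def __str__(self) -> str:
        where = self.variant_id or "<table>"
        if self.population:
            where += f"/{self.population}"
        return f"{where}: {self.rule}"


def validate_table(table: FrequencyTable) -> list[Violation]:
    """Check all structural invariants of a :class:`FrequencyTable`.

    Returns an empty list iff the table is well formed.  Each violation names
    the variant, the population (when applicable) and the rule broken.
    Pure function: the table is never modified.
    """
    violations: list[Violation] = []
    expected = set(table.populations)
    seen_ids: set[str] = set()
    gene_modes: dict[str, InheritanceMode] = {}

    for rec in table.records:
        if rec.variant_id in seen_ids:
            violations.append(
                Violation(rec.variant_id, None, "duplicate variant_id in table")
            )
        seen_ids.add(rec.variant_id)

        prior = gene_modes.setdefault(rec.gene, rec.inheritance_mode)
        if prior is not rec.inheritance_mode:
            violations.append(
                Violation(
                    rec.variant_id,
                    None,
                    f"inheritance_mode {rec.inheritance_mode.value} conflicts with "
                    f"{prior.value} for gene {rec.gene!r}",
                )
            )

        got = set(rec.counts)
        for missing in sorted(expected - got):
            violations.append(
                Violation(rec.variant_id, missing, "population key missing from counts")
            )
        for extra in sorted(got - expected):
            violations.append(
                Violation(rec.variant_id, extra, "population key not in table populations")
            )
        for pop, c in rec.counts.items():
            if c.ac > c.an:
                violations.append(
                    Violation(rec.variant_id, pop, f"ac ({c.ac}) exceeds an ({c.an})")
                )
    return violations
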