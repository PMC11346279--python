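"""Probability that an individual carries none of a set of variants.

Under independent assortment at sampled frequencies, a person with ``k``
copies of the relevant chromosome avoids a variant of frequency ``p`` with
probability (1-p)^k; the carrier-free probability of a variant set is the
product over variants.  Population estimates average the XX and XY values
with a configurable mix (default half-XX/half-XY).

Variants with no data (AN = 0) in the target population are skipped and
counted, never imputed: silence in the sample is not evidence of absence.
Linkage is ignored; any positive pairwise linkage among the variants would
raise the true carrier-free proportion, so the independence estimate is
conservative in that direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core import FrequencyTable, InheritanceMode, frequency

__all__ = [
    "Karyotype",
    "CarrierFreeEstimate",
    "chromosome_copies",
    "noncarrier_probability",
    "population_noncarrier_percent",
]


class Karyotype(str, enum.Enum):
    XX = "XX"
    XY = "XY"


def chromosome_copies(mode: InheritanceMode, karyotype: Karyotype) -> int:
    """Copies of the relevant chromosome an individual carries."""
    if mode is InheritanceMode.AUTOSOMAL:
        return 2
    return 2 if karyotype is Karyotype.XX else 1


def noncarrier_probability(
    variants: list[tuple[float, InheritanceMode]],
    karyotype: Karyotype,
) -> float:
    """Product over variants of (1-p)^copies for one karyotype."""
    prob = 1.0
    for p, mode in variants:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency must be in [0, 1], got {p}")
        prob *= (1.0 - p) ** chromosome_copies(mode, karyotype)
    return prob


@dataclass(frozen=True)
class CarrierFreeEstimate:
    """Carrier-free summary for one population."""

    population: str
    p_xx: float
    p_xy: float
    percent: float
    n_variants_used: int
    n_variants_skipped_no_data: int


def population_noncarrier_percent(
    table: FrequencyTable,
    pop: str,
    gene: str | None = None,
    variant_ids: set[str] | None = None,
    xx_fraction: float = 0.5,
) -> CarrierFreeEstimate:
    """Estimated percentage of ``pop`` carrying none of the listed variants.

    Uses sampled frequencies AC/AN per variant.  ``gene`` and ``variant_ids``
    restrict the variant set (both optional, intersected); only shortlisted
    records are considered.  ``xx_fraction`` sets the XX share of the
    population mix (default 0.5).
    """
    if pop not in table.populations:
        raise KeyError(f"unknown population {pop!r}; known: {table.populations}")
    if not 0.0 <= xx_fraction <= 1.0:
        raise ValueError(f"xx_fraction must be in [0, 1], got {xx_fraction}")
    chosen: list[tuple[float, InheritanceMode]] = []
    skipped = 0
    for rec in table.records:
        if not rec.shortlisted:
            continue
        if gene is not None and rec.gene != gene:
            continue
        if variant_ids is not None and rec.variant_id not in variant_ids:
            continue
        f = frequency(rec, pop)
        if f is None:
            skipped += 1
            continue
        chosen.append((f, rec.inheritance_mode))
    p_xx = noncarrier_probability(chosen, Karyotype.XX)
    p_xy = noncarrier_probability(chosen, Karyotype.XY)
    percent = 100.0 * (xx_fraction * p_xx + (1.0 - xx_fraction) * p_xy)
    return CarrierFreeEstimate(
        population=pop,
        p_xx=p_xx,
        p_xy=p_xy,
        percent=percent,
        n_variants_used=len(chosen),
        n_variants_skipped_no_data=skipped,
    )
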