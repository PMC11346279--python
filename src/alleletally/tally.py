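"""Per-population shortlisted-variant tallies and through-origin regression.

The tally counts, per population, the shortlisted variants of a gene observed
at least once; the effective sample size is the maximum allele number among
that gene's shortlisted variant positions.  The fit constrains the regression
line through the origin and reports the uncentered coefficient of
determination (Σxy)² / (Σx²·Σy²) — the squared cosine between x and y —
since the centered r² is ill-defined for forced-origin fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import FrequencyTable, PresenceStatus, VariantRecord, presence_status

__all__ = [
    "TallyResult",
    "RegressionFit",
    "is_population_distinctive",
    "tally_per_population",
    "origin_rooted_fit",
    "fit_from_tally",
]

logger = logging.getLogger(__name__)


@dataclass
class TallyResult:
    """Per-population tallies and effective sample sizes for one gene."""

    gene: str
    tallies: dict[str, int]
    sample_sizes: dict[str, int]

    def points(self) -> list[tuple[int, int]]:
        """(sample_size, tally) pairs, dropping populations with no data."""
        pts = []
        for pop in self.tallies:
            x = self.sample_sizes[pop]
            if x == 0:
                logger.warning(
                    "population %r has no sampled alleles for gene %r; "
                    "dropped from regression",
                    pop,
                    self.gene,
                )
                continue
            pts.append((x, self.tallies[pop]))
        return pts


@dataclass(frozen=True)
class RegressionFit:
    """Through-origin least-squares fit summary.

    ``r2_origin`` is ``None`` when all responses are zero (the uncentered
    ratio is 0/0); the slope is still 0 in that case.
    """

    slope: float
    r2_origin: float | None
    n_points: int


def is_population_distinctive(record: VariantRecord) -> bool:
    """True iff the record is present in >= 1 population and absent in >= 1.

    "Absent" requires a nonzero allele number; a population with no data at
    the site counts toward neither side.  This is a sampling-dependent label,
    not a biological property.
    """
    if not record.counts:
        raise ValueError(f"record {record.variant_id!r} has no populations")
    statuses = {presence_status(record, pop) for pop in record.counts}
    return PresenceStatus.PRESENT in statuses and PresenceStatus.ABSENT in statuses


def tally_per_population(
    table: FrequencyTable,
    gene: str,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> TallyResult:
    """Tally shortlisted variants of ``gene`` present in each population.

    ``exclude`` removes variant ids from consideration (both from the tally
    and from the max-AN sample size), so record corrections can be expressed
    as configuration rather than data edits.  The per-population sample size
    is the maximum allele number over the gene's shortlisted, non-excluded
    records; populations where every such record has AN = 0 get sample size 0.
    """
    recs = [
        r
        for r in table.records
        if r.gene == gene and r.shortlisted and r.variant_id not in exclude
    ]
    if not any(r.gene == gene for r in table.records):
        raise ValueError(f"gene {gene!r} not present in table")
    tallies = {pop: 0 for pop in table.populations}
    sample_sizes = {pop: 0 for pop in table.populations}
    for rec in recs:
        for pop in table.populations:
            c = rec.counts[pop]
            if c.an > sample_sizes[pop]:
                sample_sizes[pop] = c.an
            if presence_status(rec, pop) is PresenceStatus.PRESENT:
                tallies[pop] += 1
    return TallyResult(gene=gene, tallies=tallies, sample_sizes=sample_sizes)


def origin_rooted_fit(points: list[tuple[float, float]]) -> RegressionFit:
    """Least-squares line through the origin for (x, y) points.

    slope = Σxy / Σx²; r2_origin = (Σxy)² / (Σx²·Σy²).

    Raises if no point has x ≠ 0 (slope undefined).  When all y = 0 the slope
    is 0 and ``r2_origin`` is ``None`` — a flat response carries no fit
    quality, and reporting 1.0 would overstate it.
    """
    if not points:
        raise ValueError("no points to fit")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("all x values are zero; through-origin slope undefined")
    sxy = float(x @ y)
    syy = float(y @ y)
    slope = sxy / sxx
    r2 = None if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return RegressionFit(slope=slope, r2_origin=r2, n_points=len(points))


def fit_from_tally(result: TallyResult) -> RegressionFit:
    """Fit tally vs sample size for one gene, dropping zero-AN populations."""
    return origin_rooted_fit(result.points())
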