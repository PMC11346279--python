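"""Synthetic allele-count tables with a controlled true frequency structure.

The generator draws true per-variant frequencies from a configurable spectrum
and then binomially samples allele counts at the allele numbers implied by
each population's karyotype mix.  Sampling is at the allele level (draws are
exchangeable); no diploid or Hardy-Weinberg structure is modeled, matching
the summary-level arithmetic of the downstream estimators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import (
    FrequencyTable,
    InheritanceMode,
    PopCounts,
    PopulationSpec,
    VariantRecord,
)

__all__ = [
    "SpectrumKind",
    "SpectrumSpec",
    "SyntheticTruth",
    "draw_truth",
    "sample_table",
    "default_population_specs",
    "default_fixture_table",
]

_SKEW_GRID_SIZE = 10_000


class SpectrumKind(str, enum.Enum):
    POINT_MASS = "point_mass"
    LOG_UNIFORM = "log_uniform"
    CONSTRAINT_SKEWED = "constraint_skewed"


@dataclass(frozen=True)
class SpectrumSpec:
    """True-frequency spectrum a synthetic variant pool is drawn from.

    ``point_mass``: every variant has frequency ``p``.
    ``log_uniform``: log10-frequency uniform on [log10 p_min, log10 p_max].
    ``constraint_skewed``: log-uniform base measure tilted by ``p**(-skew)``
    on a discrete grid of log-spaced support points, shifting mass toward
    rarer frequencies (a proxy for selective constraint, not a population-
    genetic model).
    """

    kind: SpectrumKind
    p: float | None = None
    p_min: float | None = None
    p_max: float | None = None
    skew: float = 1.0

    def __post_init__(self) -> None:
        if self.kind is SpectrumKind.POINT_MASS:
            if self.p is None or not (0.0 < self.p <= 1.0):
                raise ValueError(f"point_mass requires p in (0, 1], got {self.p}")
        else:
            if self.p_min is None or self.p_max is None:
                raise ValueError(f"{self.kind.value} requires p_min and p_max")
            if not (0.0 < self.p_min <= self.p_max <= 1.0):
                raise ValueError(
                    f"need 0 < p_min <= p_max <= 1, got ({self.p_min}, {self.p_max})"
                )
            if self.kind is SpectrumKind.CONSTRAINT_SKEWED and self.skew < 0:
                raise ValueError(f"skew must be >= 0, got {self.skew}")

    @classmethod
    def point_mass(cls, p: float) -> "SpectrumSpec":
        return cls(kind=SpectrumKind.POINT_MASS, p=p)

    @classmethod
    def log_uniform(cls, p_min: float, p_max: float) -> "SpectrumSpec":
        return cls(kind=SpectrumKind.LOG_UNIFORM, p_min=p_min, p_max=p_max)

    @classmethod
    def constraint_skewed(
        cls, p_min: float, p_max: float, skew: float = 1.0
    ) -> "SpectrumSpec":
        return cls(
            kind=SpectrumKind.CONSTRAINT_SKEWED, p_min=p_min, p_max=p_max, skew=skew
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. frequencies from the spectrum."""
        if n < 0:
            raise ValueError(f"n must be >= 0, got {n}")
        if self.kind is SpectrumKind.POINT_MASS:
            return np.full(n, self.p, dtype=float)
        lo, hi = np.log10(self.p_min), np.log10(self.p_max)
        if self.kind is SpectrumKind.LOG_UNIFORM:
            return 10.0 ** rng.uniform(lo, hi, size=n)
        # constraint_skewed: renormalized p**(-skew) tilt on a log-spaced grid
        grid = np.logspace(lo, hi, _SKEW_GRID_SIZE)
        weights = grid ** (-self.skew)
        weights /= weights.sum()
        return rng.choice(grid, size=n, p=weights)


@dataclass
class SyntheticTruth:
    """True (noise-free) frequencies behind a synthetic table.

    ``freqs`` has shape (n_variants, n_populations), aligned with
    ``variant_ids`` and ``populations``.
    """

    variant_ids: list[str]
    genes: list[str]
    inheritance_modes: list[InheritanceMode]
    populations: list[str]
    freqs: np.ndarray
    spectrum: SpectrumSpec
    shared_across_populations: bool
    seed: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.variant_ids), len(self.populations)):
            raise ValueError(
                f"freqs shape {self.freqs.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.populations)} populations"
            )
        if self.freqs.size and (self.freqs.min() < 0 or self.freqs.max() > 1):
            raise ValueError("true frequencies must lie in [0, 1]")


def draw_truth(
    spectrum: SpectrumSpec,
    n_variants: int,
    populations: list[str],
    shared: bool = True,
    seed: int = 0,
    gene: str = "GENE1",
    inheritance_mode: InheritanceMode = InheritanceMode.AUTOSOMAL,
) -> SyntheticTruth:
    """Draw a synthetic truth: one frequency per variant (per population).

    With ``shared=True`` a single frequency is drawn per variant and copied to
    every population — the null of a variant pool identical across
    populations.  With ``shared=False`` each (variant, population) cell is an
    independent draw.  Deterministic given ``seed``.
    """
    if n_variants < 0:
        raise ValueError(f"n_variants must be >= 0, got {n_variants}")
    rng = np.random.default_rng(seed)
    n_pops = len(populations)
    if shared:
        per_variant = spectrum.sample(n_variants, rng)
        freqs = np.repeat(per_variant[:, None], n_pops, axis=1) if n_pops else \
            np.empty((n_variants, 0))
    else:
        freqs = spectrum.sample(n_variants * n_pops, rng).reshape(n_variants, n_pops)
    ids = [f"{gene}_v{i:04d}" for i in range(n_variants)]
    return SyntheticTruth(
        variant_ids=ids,
        genes=[gene] * n_variants,
        inheritance_modes=[inheritance_mode] * n_variants,
        populations=list(populations),
        freqs=freqs,
        spectrum=spectrum,
        shared_across_populations=shared,
        seed=seed,
    )


def sample_table(
    truth: SyntheticTruth,
    pop_specs: list[PopulationSpec],
    seed: int = 0,
) -> FrequencyTable:
    """Binomially sample an allele-count table from a synthetic truth.

    For each variant and population the allele number is the one implied by
    the population's karyotype mix and the variant's inheritance mode, and the
    allele count is Binomial(AN, true frequency).  Deterministic given
    ``seed``.
    """
    labels = [ps.label for ps in pop_specs]
    if labels != truth.populations:
        raise ValueError(
            f"population labels of pop_specs {labels} do not match "
            f"truth populations {truth.populations}"
        )
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    for i, vid in enumerate(truth.variant_ids):
        mode = truth.inheritance_modes[i]
        counts: dict[str, PopCounts] = {}
        for j, ps in enumerate(pop_specs):
            an = ps.allele_number(mode)
            ac = int(rng.binomial(an, truth.freqs[i, j])) if an > 0 else 0
            counts[ps.label] = PopCounts(ac=ac, an=an)
        records.append(
            VariantRecord(
                variant_id=vid,
                gene=truth.genes[i],
                inheritance_mode=mode,
                counts=counts,
                shortlisted=True,
            )
        )
    return FrequencyTable(populations=list(truth.populations), records=records)


# Default fixture: nine unevenly sampled populations, half-XX/half-XY.
# The first six person counts are anchored to published cohort sizes
# (23,000 / 450 / 1,662 / 1,567 / 15,000 / 36,000); the rest are fixture
# choices kept below the 15,000-person bound of the smaller cohorts.
_DEFAULT_PERSON_COUNTS: dict[str, int] = {
    "AFR": 23_000,
    "AMI": 450,
    "ASH": 1_662,
    "EAS": 1_567,
    "SAS": 15_000,
    "EUR": 36_000,
    "FIN": 10_000,
    "AMR": 14_000,
    "oth": 3_000,
}


def default_population_specs() -> list[PopulationSpec]:
    """Nine half-XX/half-XY populations with lopsided person counts."""
    return [
        PopulationSpec.half_half(label, n) for label, n in _DEFAULT_PERSON_COUNTS.items()
    ]


def default_fixture_table(
    seed: int = 0,
    n_variants_x: int = 65,
    n_variants_auto: int = 66,
    spectrum: SpectrumSpec | None = None,
) -> FrequencyTable:
    """Two-gene fixture table: one X-linked gene, one autosomal gene.

    Mirrors the statistical shape of the motivating dataset: ~131 mostly very
    rare variants across 9 unevenly sampled populations, with true
    frequencies shared across populations (the artifact null).
    """
    if spectrum is None:
        spectrum = SpectrumSpec.log_uniform(1e-6, 1e-3)
    pop_specs = default_population_specs()
    labels = [ps.label for ps in pop_specs]
    truth_x = draw_truth(
        spectrum,
        n_variants_x,
        labels,
        shared=True,
        seed=seed,
        gene="ACE2LIKE",
        inheritance_mode=InheritanceMode.X_LINKED,
    )
    truth_a = draw_truth(
        spectrum,
        n_variants_auto,
        labels,
        shared=True,
        seed=seed + 1,
        gene="TMPRSS2LIKE",
        inheritance_mode=InheritanceMode.AUTOSOMAL,
    )
    table_x = sample_table(truth_x, pop_specs, seed=seed + 2)
    table_a = sample_table(truth_a, pop_specs, seed=seed + 3)
    return FrequencyTable(
        populations=labels, records=table_x.records + table_a.records
    )
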