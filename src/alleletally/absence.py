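"""Sample sizes needed to be confident a variant absent from data is rare.

If a variant's true allele frequency is ``p``, the probability that sampling
``n`` further allele copies observes it at least once is 1 - (1-p)^n.  The
inverse question — the smallest ``n`` reaching a target detection probability
``c`` — is answered by an integer search bracketing the closed-form candidate
ceil(ln(1-c)/ln(1-p)), so exact-threshold cases are not lost to floating-point
ceiling artifacts.

The unit throughout is sampled *alleles*, not people; for X-linked genes the
people-to-alleles conversion depends on the karyotype mix and lives in
:class:`~alleletally.core.PopulationSpec`.
"""

from __future__ import annotations

import math

__all__ = ["detection_probability", "min_alleles_for_confidence"]


def detection_probability(p: float, n: int) -> float:
    """Probability of observing >= 1 copy in ``n`` sampled alleles: 1-(1-p)^n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"allele count must be >= 0, got {n}")
    return -math.expm1(n * math.log1p(-p)) if p < 1.0 else (1.0 if n > 0 else 0.0)


def min_alleles_for_confidence(p: float, c: float) -> int:
    """Smallest integer n with detection_probability(p, n) >= c.

    Requires p in (0, 1] and c in [0, 1).  The closed-form candidate is
    verified by direct evaluation at n and n-1 and adjusted within a small
    bracket if needed.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"frequency must be in (0, 1] for a finite answer, got {p}")
    if not 0.0 <= c < 1.0:
        raise ValueError(f"confidence must be in [0, 1), got {c}")
    if c == 0.0:
        return 0
    if p == 1.0:
        return 1
    candidate = math.ceil(math.log1p(-c) / math.log1p(-p))
    lo = max(candidate - 2, 0)
    for n in range(lo, candidate + 3):
        if detection_probability(p, n) >= c:
            break
    else:  # pragma: no cover - bracket always contains the answer
        raise AssertionError("bracket search failed")
    while n > 0 and detection_probability(p, n - 1) >= c:
        n -= 1
    return n
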