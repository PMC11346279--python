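import pytest

from alleletally.core import (
    FrequencyTable,
    InheritanceMode,
    PopCounts,
    VariantRecord,
)


def make_record(
    variant_id="v1",
    gene="G",
    mode=InheritanceMode.AUTOSOMAL,
    counts=None,
    shortlisted=True,
):
    return VariantRecord(
        variant_id=variant_id,
        gene=gene,
        inheritance_mode=mode,
        counts={p: PopCounts(ac, an) for p, (ac, an) in (counts or {}).items()},
        shortlisted=shortlisted,
    )


@pytest.fixture
def toy_table():
    """Two populations, one X-linked and one autosomal gene, mixed presence."""
    pops = ["A", "B"]
    records = [
        make_record("x1", "GX", InheritanceMode.X_LINKED,
                    {"A": (2, 900), "B": (0, 500)}),
        make_record("x2", "GX", InheritanceMode.X_LINKED,
                    {"A": (0, 900), "B": (1, 500)}),
        make_record("a1", "GA", InheritanceMode.AUTOSOMAL,
                    {"A": (3, 1000), "B": (0, 0)}),
        make_record("a2", "GA", InheritanceMode.AUTOSOMAL,
                    {"A": (0, 1000), "B": (5, 600)}),
    ]
    return FrequencyTable(populations=pops, records=records)
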