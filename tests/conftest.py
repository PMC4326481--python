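import numpy as np
import pandas as pd
import pytest

from ripseek import MatureMiRNA, SiteSearchParams

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def let7():
    return MatureMiRNA("let-7", LET7)


@pytest.fixture
def let7_offset_seed():
    """let-7 with the 5'-offset (positions 1-6) seed used for miR-503-style search."""
    return MatureMiRNA("let-7", LET7, seed_interval=(1, 6), three_prime_interval=(11, 18))


@pytest.fixture
def offset_params():
    return SiteSearchParams(seed_interval=(1, 6), three_prime_interval=(11, 18))


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture
def fpkm_fixture_table():
    """A 20-gene four-cell FPKM table with two replicates, fully deterministic.

    Values are chosen so that capping, replicate combining and both ratio
    formulas are all exercised, including a gene engineered to land exactly
    on the score boundary of 1.75 (gene g00).
    """
    rows = []
    # (gene, control_total, control_rip, mirna_total, mirna_rip) cell means
    cells = [
        ("g00", 3.0, 3.0, 2.0, 4.0),      # repression 1.5, enrichment 2.0 -> score 1.75
        ("g01", 10.0, 10.0, 5.0, 20.0),   # planted-style target, score 3.0
        ("g02", 7.0, 7.0, 7.0, 7.0),      # null gene
        ("g03", 0.3, 0.4, 0.2, 0.5),      # everything capped to 1
        ("g04", 1.0, 1.0, 1.0, 1.0),      # boundary fixed point of capping
        ("g05", 1.0, 2.0, 4.0, 2.0),      # de-repressed
        ("g06", 57.2, 3.1, 9.4, 12.8),
        ("g07", 12.0, 0.5, 6.0, 8.0),     # one sub-floor cell
        ("g08", 2.5, 2.5, 0.4, 2.5),      # capped denominator
        ("g09", 100.0, 1.0, 100.0, 1.0),
    ] + [
        (f"g{i:02d}", 5.0 + i, 4.0 + i, 3.0 + 0.5 * i, 6.0 + i) for i in range(10, 20)
    ]
    for gene, ct, cr, mt, mr in cells:
        for (cond, assay, mean) in [
            ("control", "total", ct),
            ("control", "rip", cr),
            ("mirna", "total", mt),
            ("mirna", "rip", mr),
        ]:
            # two replicates straddling the mean so the arithmetic mean is exact
            for rep, value in [(0, mean * 0.5), (1, mean * 1.5)]:
                rows.append(
                    {"gene_id": gene, "condition": cond, "assay": assay,
                     "replicate": rep, "fpkm": value}
                )
    return pd.DataFrame(rows), {c[0]: c[1:] for c in cells}
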