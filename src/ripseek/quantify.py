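"""Expression processing: replicate combining, FPKM capping, ratio measures.

The experimental design crosses two transfections (the miRNA of interest vs
a control duplex) with two assays (total RNA-seq and Ago2 RIP-seq), giving
four FPKM cells per gene.  Two ratios summarise the miRNA's effect:

* repression = control-total FPKM / miRNA-total FPKM  (>1: the miRNA
  lowered the transcript);
* enrichment = (miRNA-RIP / miRNA-total) / (control-RIP / control-total)
  (>1: miRNA-dependent RISC association; RIP FPKMs are normalised to the
  matching total-RNA FPKMs before the ratio).

The target score of a gene is the arithmetic mean of the two ratios.  To
avoid denominator inflation, all FPKMs below a floor (default 1) are hard
capped to the floor before any ratio is formed.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .errors import InputError

CONDITIONS = ("mirna", "control")
ASSAYS = ("total", "rip")
FPKM_COLUMNS = ("gene_id", "condition", "assay", "replicate", "fpkm")

Number = Union[float, np.ndarray, pd.Series]


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format FPKM table schema and invariants.

    Columns: gene_id, condition in {mirna, control}, assay in {total, rip},
    replicate (integer), fpkm (finite, >= 0).  Every gene must cover all
    four condition x assay cells with at least one replicate each.
    """
    missing_cols = set(FPKM_COLUMNS) - set(matrix.columns)
    if missing_cols:
        raise InputError(f"FPKM table is missing columns: {sorted(missing_cols)}")
    bad_cond = set(matrix["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise InputError(f"unknown condition values: {sorted(bad_cond)}")
    bad_assay = set(matrix["assay"].unique()) - set(ASSAYS)
    if bad_assay:
        raise InputError(f"unknown assay values: {sorted(bad_assay)}")
    fpkm = matrix["fpkm"].to_numpy(float)
    if not np.isfinite(fpkm).all():
        gene = matrix.loc[~np.isfinite(fpkm), "gene_id"].iloc[0]
        raise InputError(f"non-finite FPKM for gene {gene!r}")
    if (fpkm < 0).any():
        gene = matrix.loc[fpkm < 0, "gene_id"].iloc[0]
        raise InputError(f"negative FPKM for gene {gene!r}")
    cells = matrix.groupby("gene_id")[["condition", "assay"]].apply(
        lambda df: len(df.drop_duplicates())
    )
    incomplete = cells[cells < 4]
    if len(incomplete):
        gene = incomplete.index[0]
        have = set(
            map(tuple, matrix.loc[matrix["gene_id"] == gene, ["condition", "assay"]].values)
        )
        missing = [c for c in ((x, y) for x in CONDITIONS for y in ASSAYS) if c not in have]
        raise InputError(f"gene {gene!r} is missing cells {missing}")
    return matrix


def combine_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates to one pseudo-replicate per cell (arithmetic mean).

    A single-replicate cell passes through unchanged.  The output has
    ``replicate == 0`` everywhere.
    """
    validate_expression(matrix)
    out = (
        matrix.groupby(["gene_id", "condition", "assay"], as_index=False, sort=True)["fpkm"]
        .mean()
    )
    out["replicate"] = 0
    return out[list(FPKM_COLUMNS)]


def cap_fpkm(matrix: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Hard-cap every FPKM below ``floor`` up to ``floor``.

    Values at or above the floor are unchanged.  Bounds every downstream
    ratio to [floor/max_fpkm, max_fpkm/floor].
    """
    if floor <= 0:
        raise InputError(f"cap floor must be positive, got {floor}")
    validate_expression(matrix)
    out = matrix.copy()
    out["fpkm"] = out["fpkm"].clip(lower=floor)
    return out


def _check_positive(name: str, *values: Number) -> None:
    for v in values:
        arr = np.asarray(v, dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise InputError(
                f"{name} requires strictly positive, capped FPKM inputs; "
                "cap_fpkm must run before ratios"
            )


def compute_repression(control_total: Number, mirna_total: Number) -> Number:
    """Repression ratio: control-total FPKM over miRNA-total FPKM."""
    _check_positive("compute_repression", control_total, mirna_total)
    return control_total / mirna_total


def compute_enrichment(
    mirna_rip: Number, mirna_total: Number, control_rip: Number, control_total: Number
) -> Number:
    """RIP enrichment: total-normalised RIP ratio of miRNA vs control.

    (miRNA-RIP / miRNA-total) / (control-RIP / control-total).  Note the
    coupling with repression: a repressed miRNA-total denominator inflates
    enrichment.
    """
    _check_positive("compute_enrichment", mirna_rip, mirna_total, control_rip, control_total)
    return (mirna_rip / mirna_total) / (control_rip / control_total)


def target_score(enrichment: Number, repression: Number) -> Number:
    """Combined target score: arithmetic mean of enrichment and repression."""
    return (enrichment + repression) / 2


def build_measures(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene repression, enrichment and target score.

    Expects a combined (single pseudo-replicate) and capped table.  Returns
    a frame with columns gene_id, repression, enrichment, score, sorted by
    gene_id; the target flag is set later by the ranking stage.
    """
    validate_expression(matrix)
    reps = matrix.groupby(["gene_id", "condition", "assay"]).size()
    if (reps > 1).any():
        gene, cond, assay = reps[reps > 1].index[0]
        raise InputError(
            f"multiple replicates remain for gene {gene!r} cell ({cond}, {assay}); "
            "run combine_replicates first"
        )
    wide = matrix.pivot_table(
        index="gene_id", columns=["condition", "assay"], values="fpkm", sort=True
    )
    enrichment = compute_enrichment(
        wide[("mirna", "rip")],
        wide[("mirna", "total")],
        wide[("control", "rip")],
        wide[("control", "total")],
    )
    repression = compute_repression(wide[("control", "total")], wide[("mirna", "total")])
    return pd.DataFrame(
        {
            "gene_id": wide.index,
            "repression": repression.to_numpy(float),
            "enrichment": enrichment.to_numpy(float),
            "score": target_score(enrichment, repression).to_numpy(float),
        }
    ).reset_index(drop=True)
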