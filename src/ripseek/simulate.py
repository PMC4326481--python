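"""Synthetic data with known ground truth for the whole pipeline.

Emulates the transfection/RIP experimental design at the gene level: each
gene gets a baseline expression (log-normal across genes), and planted
targets respond to the miRNA multiplicatively — their RIP FPKM under miRNA
transfection is multiplied by ``enrichment_effect`` and their total FPKM
under miRNA transfection is divided by ``repression_effect``.  Replicates
carry independent log-normal noise.  3'UTRs are i.i.d. random background
(uniform or GC-controlled) with at most one pairing site planted per target
at a known coordinate.

Because the repression effect acts on the total-RNA denominator of the
enrichment ratio, a noise-free planted target measures enrichment
``enrichment_effect * repression_effect`` and repression
``repression_effect`` exactly — a useful closed form for tests.

Everything is deterministic under ``rng_seed``; UTR generation and
expression simulation use independent child streams so either can be
re-run alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError, InputError
from .pairing import (
    MatureMiRNA,
    SiteSearchParams,
    classify_gene_pairing,
    reverse_complement,
)

RNA_BASES = np.array(list("ACGU"))

PLANTABLE_SITE_TYPES = ("none", "canonical7mer", "supplementary", "compensatory")

TRUTH_COLUMNS = ("gene_id", "is_target", "site_type", "site_start", "site_end")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic transfection/RIP experiment.

    Defaults describe a mid-sized transcriptome slice with strong planted
    effects: 2,000 genes of which 400 are targets carrying supplementary
    sites, 3-fold RIP enrichment, 2-fold repression, 0.25 log2 units of
    replicate noise, and typical human 3'UTR lengths (~800 nt).
    """

    n_genes: int = 2000
    n_targets: int = 400
    utr_length_mean: float = 800.0
    utr_length_sd: float = 150.0
    background_model: str = "uniform"
    gc_fraction: float = 0.5
    site_plan: Mapping[str, int] = field(default_factory=lambda: {"supplementary": 400})
    enrichment_effect: float = 3.0
    repression_effect: float = 2.0
    baseline_log2fpkm_mean: float = 5.0
    baseline_log2fpkm_sd: float = 2.0
    noise_log2_sd: float = 0.25
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_targets < 0:
            raise ConfigError("gene and target counts must be non-negative")
        if self.n_targets > self.n_genes:
            raise ConfigError(
                f"n_targets ({self.n_targets}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("utr_length_sd", "baseline_log2fpkm_sd", "noise_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.enrichment_effect < 1 or self.repression_effect < 1:
            raise ConfigError("effect sizes are fold changes and must be >= 1")
        if self.utr_length_mean <= 30:
            raise ConfigError("utr_length_mean must exceed 30 nt to hold a planted site")
        if self.background_model not in ("uniform", "fixed-gc"):
            raise ConfigError(f"unknown background model {self.background_model!r}")
        if not 0 <= self.gc_fraction <= 1:
            raise ConfigError("gc_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        bad = set(self.site_plan) - set(PLANTABLE_SITE_TYPES)
        if bad:
            raise ConfigError(f"unknown site types in site_plan: {sorted(bad)}")
        if any(v < 0 for v in self.site_plan.values()):
            raise ConfigError("site_plan counts must be >= 0")
        if sum(self.site_plan.values()) > self.n_genes:
            raise ConfigError("site_plan counts exceed n_genes")

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


def make_ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene table: target flags and planned site types.

    The first ``n_targets`` genes are expression targets; planted sites are
    assigned to the lowest-index genes in ``site_plan`` order, so a plan
    whose counts sum to ``n_targets`` puts a site on every target and only
    on targets.  Coordinates are filled in by :func:`generate_utrs`.
    """
    ids = _gene_ids(config.n_genes)
    site_types = []
    plan = [(t, int(c)) for t, c in config.site_plan.items() for _ in range(int(c))]
    for i in range(config.n_genes):
        site_types.append(plan[i][0] if i < len(plan) else "none")
    return pd.DataFrame(
        {
            "gene_id": ids,
            "is_target": [i < config.n_targets for i in range(config.n_genes)],
            "site_type": site_types,
            "site_start": pd.array([pd.NA] * config.n_genes, dtype="Int64"),
            "site_end": pd.array([pd.NA] * config.n_genes, dtype="Int64"),
        }
    )


def _base_probabilities(config: SimulationConfig) -> np.ndarray:
    if config.background_model == "uniform":
        return np.full(4, 0.25)
    gc = config.gc_fraction
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U


def _random_rna(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    return "".join(rng.choice(RNA_BASES, size=length, p=p))


def _planted_site(
    rng: np.random.Generator,
    mirna: MatureMiRNA,
    site_type: str,
    params: SiteSearchParams,
    p: np.ndarray,
) -> str:
    """The exact UTR-sense subsequence to insert for one planted site."""
    if site_type == "canonical7mer":
        # 7mer-m8: reverse complement of miRNA positions 2-8
        return reverse_complement(mirna.segment((2, 8)))
    seed_match = reverse_complement(mirna.segment(params.seed_interval))
    tp_match = reverse_complement(mirna.segment(params.three_prime_interval))
    spacer = _random_rna(rng, params.nominal_spacer, p)
    if site_type == "compensatory":
        pos = int(rng.integers(len(seed_match)))
        alternatives = [b for b in "ACGU" if b != seed_match[pos]]
        sub = alternatives[int(rng.integers(3))]
        seed_match = seed_match[:pos] + sub + seed_match[pos + 1 :]
    return tp_match + spacer + seed_match


def generate_utrs(
    config: SimulationConfig,
    mirna: MatureMiRNA,
    params: Optional[SiteSearchParams] = None,
    clean_background: bool = False,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random 3'UTRs with planted sites; returns (UTRs, ground truth).

    Each UTR is drawn from the background model; genes with a planned site
    get the exact reverse-complement segment(s) inserted at a random
    position, recorded as a 0-based half-open interval in the truth table.
    One site per gene; sites never cross UTR boundaries.

    ``clean_background=True`` re-draws the background of any gene whose
    chance sequence content would change its pairing-type label (e.g. a
    spurious seed match in a "none" gene), guaranteeing that labels equal
    plants exactly; leave off when unbiased background statistics matter.
    """
    if len(mirna) < 20:
        raise InputError("generator requires a mature miRNA of >= 20 nt")
    if params is None:
        params = SiteSearchParams.for_mirna(mirna)
    truth = make_ground_truth(config)
    rng = np.random.default_rng([config.rng_seed % (2**31), 11])
    p = _base_probabilities(config)

    lengths = np.maximum(
        np.rint(rng.normal(config.utr_length_mean, config.utr_length_sd, config.n_genes)),
        1,
    ).astype(int)

    expected_label = {
        "none": "none",
        "canonical7mer": "canonical_seed",
        "supplementary": "supplementary",
        "compensatory": "compensatory",
    }

    utrs: dict[str, str] = {}
    starts = truth["site_start"].copy()
    ends = truth["site_end"].copy()
    for i, row in truth.iterrows():
        gene, site_type = row["gene_id"], row["site_type"]
        length = lengths[i]
        insert = (
            _planted_site(rng, mirna, site_type, params, p) if site_type != "none" else ""
        )
        if insert and length < len(insert):
            raise GenerationError(
                f"UTR of gene {gene!r} (length {length}) is too short for a "
                f"{site_type} site of {len(insert)} nt"
            )
        for attempt in range(1000):
            seq = _random_rna(rng, length, p)
            if insert:
                start = int(rng.integers(length - len(insert) + 1))
                seq = seq[:start] + insert + seq[start + len(insert) :]
            if not clean_background:
                break
            if classify_gene_pairing(seq, mirna, params) == expected_label[site_type]:
                break
        else:
            raise GenerationError(
                f"could not draw a clean background for gene {gene!r} in 1000 attempts"
            )
        utrs[gene] = seq
        if insert:
            starts.iloc[i] = start
            ends.iloc[i] = start + len(insert)
    truth["site_start"] = starts
    truth["site_end"] = ends
    return utrs, truth


def simulate_expression(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Long-format FPKM table for the four condition x assay cells.

    Non-targets share one baseline across all cells; targets get the
    multiplicative enrichment/repression effects under miRNA transfection.
    Each replicate value is the cell mean times independent log-normal
    noise (sd ``noise_log2_sd`` on the log2 scale).  FPKMs are emitted
    pre-capping; capping is the quantify stage's job.
    """
    if truth.empty:
        raise InputError("ground truth is empty; nothing to simulate")
    rng = np.random.default_rng([config.rng_seed % (2**31), 23])
    n = len(truth)
    baseline = 2.0 ** rng.normal(
        config.baseline_log2fpkm_mean, config.baseline_log2fpkm_sd, n
    )
    is_target = truth["is_target"].to_numpy(bool)

    cell_means = {
        ("control", "total"): baseline,
        ("control", "rip"): baseline,
        ("mirna", "total"): np.where(is_target, baseline / config.repression_effect, baseline),
        ("mirna", "rip"): np.where(is_target, baseline * config.enrichment_effect, baseline),
    }
    frames = []
    for (condition, assay), means in cell_means.items():
        for rep in range(config.n_replicates):
            noise = 2.0 ** rng.normal(0.0, config.noise_log2_sd, n)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": truth["gene_id"].to_numpy(),
                        "condition": condition,
                        "assay": assay,
                        "replicate": rep,
                        "fpkm": means * noise,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["gene_id", "condition", "assay", "replicate"], kind="mergesort"
    ).reset_index(drop=True)


def simulate_dataset(
    config: SimulationConfig,
    mirna: MatureMiRNA,
    params: Optional[SiteSearchParams] = None,
    clean_background: bool = False,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (UTRs, ground truth, FPKM table) in one call."""
    utrs, truth = generate_utrs(config, mirna, params, clean_background)
    fpkm = simulate_expression(truth, config)
    return utrs, truth, fpkm
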