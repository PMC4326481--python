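"""End-to-end pipeline: quantify -> ranking -> pairing, with a run report.

The report records input checksums, all parameters, the seed, and gene
counts at every stage, so that an identical configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import io as rio
from . import pairing, quantify, ranking
from .errors import InputError
from .pairing import SiteSearchParams

logger = logging.getLogger("ripseek")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    fpkm_path: str
    utr_path: str
    mirna_path: str
    out_dir: str
    floor: float = 1.0
    score_threshold: float = 1.75
    group_size: int = 250
    seed_interval: tuple[int, int] = (2, 7)
    three_prime_interval: tuple[int, int] = (11, 18)
    three_prime_max_mismatches: int = 3
    spacer_wobble: int = 1
    seed_match_positions: tuple[int, int] = (2, 8)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.score_threshold <= 0:
            raise InputError("score_threshold must be > 0")
        if self.group_size < 1:
            raise InputError("group_size must be >= 1")
        for p in (self.fpkm_path, self.utr_path, self.mirna_path):
            if not Path(p).exists():
                raise InputError(f"input path does not exist: {p}")

    def site_params(self) -> SiteSearchParams:
        return SiteSearchParams(
            seed_interval=tuple(self.seed_interval),
            three_prime_interval=tuple(self.three_prime_interval),
            three_prime_max_mismatches=self.three_prime_max_mismatches,
            spacer_wobble=self.spacer_wobble,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs plus ``report.json``.

    Genes present in the FPKM table but absent from the UTR FASTA stay in
    the expression analyses and are excluded from sequence analyses; the
    count is logged and reported, never silently dropped.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fpkm = rio.read_fpkm_tsv(config.fpkm_path)
    utrs = rio.read_utr_fasta(config.utr_path)
    mirna = rio.read_mirna_fasta(
        config.mirna_path,
        seed_interval=tuple(config.seed_interval),
        three_prime_interval=tuple(config.three_prime_interval),
    )[0]
    params = config.site_params()

    # --- quantify ---
    combined = quantify.combine_replicates(fpkm)
    capped = quantify.cap_fpkm(combined, floor=config.floor)
    measures = quantify.build_measures(capped)
    rio.write_measures_tsv(
        ranking.flag_targets(measures, config.score_threshold), out_dir / "measures.tsv"
    )

    # --- ranking ---
    targets = ranking.select_target_set(measures, config.score_threshold)
    rio.write_measures_tsv(targets, out_dir / "targets.tsv")

    genes_with_utr = [g for g in measures["gene_id"] if g in utrs]
    n_missing_utr = len(measures) - len(genes_with_utr)
    if n_missing_utr:
        logger.info(
            "%d gene(s) in the FPKM table have no UTR sequence; kept for "
            "expression analyses, excluded from sequence analyses",
            n_missing_utr,
        )

    seed_motif = pairing.reverse_complement(mirna.segment(config.seed_match_positions))
    seed_genes = {g for g in genes_with_utr if seed_motif in utrs[g]}
    grouped = ranking.make_ranked_groups(
        measures[measures["gene_id"].isin(genes_with_utr)], "by_score", config.group_size
    )
    if seed_genes:
        freqs = ranking.group_feature_frequency(grouped, seed_genes, genes_with_utr)
        pd.DataFrame(
            {
                "group": range(1, len(freqs) + 1),
                "group_size": [len(g) for g in grouped.groups],
                "seed_match_relative_frequency": freqs,
            }
        ).to_csv(out_dir / "ranked_group_seed_frequency.tsv", sep="\t", index=False,
                 float_format="%.10g")
    correlation = (
        ranking.enrichment_repression_correlation(measures) if len(measures) >= 3 else None
    )

    # --- pairing ---
    target_ids = set(targets["gene_id"])
    target_utrs = {g: utrs[g] for g in genes_with_utr if g in target_ids}
    background_utrs = {g: utrs[g] for g in genes_with_utr}
    if target_utrs and background_utrs:
        profile = pairing.kmer_offset_enrichment(target_utrs, background_utrs, mirna)
        rio.write_kmer_profile_tsv(profile, out_dir / "kmer_profile.tsv")
    all_sites = []
    for gene in genes_with_utr:
        seq = utrs[gene]
        all_sites.extend(pairing.find_seed_matches(seq, mirna, config.seed_match_positions, gene))
        all_sites.extend(pairing.find_supplementary_sites(seq, mirna, params, gene))
        all_sites.extend(pairing.find_compensatory_sites(seq, mirna, params, gene))
    rio.write_sites_tsv(all_sites, out_dir / "sites.tsv")
    labels = pairing.classify_genes(background_utrs, mirna, params)
    type_counts = {
        t: sum(lab == t for lab in labels.values()) for t in pairing.SITE_TYPES
    }

    report = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
        "inputs": {
            "fpkm_sha256": _sha256(config.fpkm_path),
            "utr_sha256": _sha256(config.utr_path),
            "mirna_sha256": _sha256(config.mirna_path),
        },
        "mirna": {"name": mirna.name, "length": len(mirna)},
        "counts": {
            "n_genes": int(len(measures)),
            "n_targets_selected": int(len(targets)),
            "n_genes_without_utr": int(n_missing_utr),
            "n_sites": int(len(all_sites)),
            "pairing_type_counts": type_counts,
        },
        "enrichment_repression_pearson_r_log2": correlation,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
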