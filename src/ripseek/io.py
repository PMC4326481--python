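"""Readers and writers for the package's on-disk formats.

FASTA via Biopython (RNA alphabet on output; T is silently converted to U
on input, with a count available to callers for logging).  Tables are plain
TSV with fixed schemas:

* FPKM:     gene_id, condition, assay, replicate, fpkm
* measures: gene_id, repression, enrichment, score [, is_target]
* truth:    gene_id, is_target, site_type, site_start, site_end
* sites:    gene_id, start, end, site_type, seed_mm, tp_mm, spacer
            (BED-like; start/end are 0-based half-open UTR coordinates)
* k-mer profile: offset, kmer, target_freq, background_freq, ratio
            (offset is a 1-based miRNA position)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .pairing import MatureMiRNA, SiteMatch
from .quantify import FPKM_COLUMNS, validate_expression

logger = logging.getLogger("ripseek")

PathLike = Union[str, Path]


def _to_rna(seq: str) -> tuple[str, int]:
    upper = seq.upper()
    n_t = upper.count("T")
    return upper.replace("T", "U"), n_t


def read_utr_fasta(path: PathLike) -> dict[str, str]:
    """3'UTR sequences keyed by gene ID (FASTA header up to first space)."""
    utrs: dict[str, str] = {}
    converted = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in utrs:
            raise InputError(f"duplicate gene ID {record.id!r} in {path}")
        seq, n_t = _to_rna(str(record.seq))
        converted += n_t
        utrs[record.id] = seq
    if converted:
        logger.info("converted %d T bases to U while reading %s", converted, path)
    return utrs


def read_mirna_fasta(path: PathLike, **mirna_kwargs) -> list[MatureMiRNA]:
    """Mature miRNAs from FASTA (5'->3'; T converted to U)."""
    mirnas = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq, n_t = _to_rna(str(record.seq))
        if n_t:
            logger.info("converted %d T bases to U in miRNA %s", n_t, record.id)
        mirnas.append(MatureMiRNA(name=record.id, sequence=seq, **mirna_kwargs))
    if not mirnas:
        raise InputError(f"no miRNA records found in {path}")
    return mirnas


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fpkm_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return validate_expression(df)


def write_fpkm_tsv(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix[list(FPKM_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_measures_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "repression", "enrichment", "score"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"measures table {path} is missing columns {sorted(missing)}")
    return df


def write_measures_tsv(measures: pd.DataFrame, path: PathLike) -> None:
    measures.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "site_type": str, "site_start": "Int64", "site_end": "Int64"},
    )


def write_truth_tsv(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def sites_to_frame(sites: Iterable[SiteMatch]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "start": s.start,
            "end": s.end,
            "site_type": s.site_type,
            "seed_mm": s.seed_mismatches,
            "tp_mm": s.three_prime_mismatches,
            "spacer": s.spacer_length,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "site_type", "seed_mm", "tp_mm", "spacer"]
    )


def write_sites_tsv(sites: Iterable[SiteMatch], path: PathLike) -> None:
    """BED-like site table; coordinates are 0-based half-open on the UTR."""
    with open(path, "w") as fh:
        fh.write("# UTR coordinates: 0-based half-open; miRNA positions: 1-based inclusive\n")
        sites_to_frame(sites).to_csv(fh, sep="\t", index=False)


def read_sites_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})


def write_kmer_profile_tsv(profile: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# offset: 1-based miRNA start position of the k-mer\n")
        profile.to_csv(fh, sep="\t", index=False, float_format="%.10g")
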