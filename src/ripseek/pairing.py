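"""Sequence-side analysis: miRNA-target pairing in 3'UTRs.

A mature miRNA pairs its target antiparallel: the miRNA 5' seed pairs the
3'-most part of the site on the mRNA.  All matching here is Watson-Crick
reverse complement on the given (sense) strand of the UTR; G:U wobble pairs
count as mismatches unless explicitly enabled.

Coordinate conventions (documented in every output header):

* miRNA positions are 1-based inclusive, counted from the 5' end, matching
  the field's "position 2-7" language;
* UTR coordinates are 0-based half-open.

Site classes:

* ``canonical_seed`` - a perfect match to the reverse complement of the
  seed region alone;
* ``supplementary`` - a perfect seed-region match plus an additional
  3'-region match (default: miRNA positions 11-18, up to 3 mismatches)
  located 5' of the seed match on the UTR, separated by a spacer whose
  length may deviate from the duplex-geometry nominal by at most
  ``spacer_wobble`` nucleotides;
* ``compensatory`` - same geometry, but the seed block carries exactly one
  mismatch, compensated by the 3'-region pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_RC_TABLE = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("supplementary", "compensatory", "canonical_seed", "none")
#: classification precedence, strongest pairing first
SITE_PRECEDENCE = ("supplementary", "compensatory", "canonical_seed")


def _validate_rna(seq: str, what: str = "sequence") -> None:
    for i, base in enumerate(seq):
        if base not in _COMPLEMENT:
            raise InputError(
                f"invalid character {base!r} at position {i} in {what}; "
                f"expected RNA alphabet {RNA_BASES}"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string (A<->U, G<->C).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _validate_rna(seq)
    return seq.translate(_RC_TABLE)[::-1]


def _pairs(mirna_base: str, target_base: str, allow_gu: bool) -> bool:
    if _COMPLEMENT[mirna_base] == target_base:
        return True
    if allow_gu:
        return (mirna_base, target_base) in (("G", "U"), ("U", "G"))
    return False


def pairing_mismatches(utr_window: str, mirna_segment: str, allow_gu: bool = False) -> int:
    """Mismatch count when ``mirna_segment`` (5'->3') pairs ``utr_window`` (5'->3').

    Pairing is antiparallel, so the miRNA segment is read 3'->5' against the
    UTR window.  Substitution mismatches only; lengths must agree.
    """
    if len(utr_window) != len(mirna_segment):
        raise ValueError("windows of unequal length cannot be paired")
    return sum(
        not _pairs(m, t, allow_gu)
        for m, t in zip(reversed(mirna_segment), utr_window)
    )


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA, 5'->3', with seed and 3'-segment definitions.

    Intervals are 1-based inclusive miRNA positions.  Defaults follow the
    common convention: 6-mer seed at 2-7 and 3'-supplementary region 11-18.
    """

    name: str
    sequence: str
    seed_interval: tuple[int, int] = (2, 7)
    three_prime_interval: tuple[int, int] = (11, 18)

    def __post_init__(self) -> None:
        _validate_rna(self.sequence, f"miRNA {self.name!r}")
        if len(self.sequence) < 20:
            raise InputError(
                f"miRNA {self.name!r} has length {len(self.sequence)}; "
                "a mature miRNA of at least 20 nt is required"
            )
        for lo, hi in (self.seed_interval, self.three_prime_interval):
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise InputError(
                    f"interval {lo}-{hi} outside miRNA {self.name!r} "
                    f"(length {len(self.sequence)})"
                )
        if self.seed_interval[1] >= self.three_prime_interval[0]:
            raise InputError("seed interval must end before the 3' interval starts")

    def __len__(self) -> int:
        return len(self.sequence)

    def segment(self, interval: tuple[int, int]) -> str:
        """Subsequence at 1-based inclusive miRNA positions."""
        lo, hi = interval
        if not (1 <= lo <= hi <= len(self.sequence)):
            raise InputError(f"interval {lo}-{hi} outside miRNA {self.name!r}")
        return self.sequence[lo - 1 : hi]

    @property
    def seed(self) -> str:
        return self.segment(self.seed_interval)

    @property
    def three_prime_segment(self) -> str:
        return self.segment(self.three_prime_interval)


@dataclass(frozen=True)
class SiteSearchParams:
    """Geometry and tolerances of the supplementary/compensatory site search.

    ``nominal_spacer`` is fixed by duplex geometry: the unpaired miRNA gap
    between the seed and the 3' segment (4 nt for seed 1-6 with 3' 11-18,
    5 nt for seed 2-7 with 3' 13-20).  The UTR spacer may deviate from it by
    at most ``spacer_wobble`` nt.
    """

    seed_interval: tuple[int, int] = (2, 7)
    three_prime_interval: tuple[int, int] = (11, 18)
    three_prime_max_mismatches: int = 3
    spacer_wobble: int = 1
    allow_gu: bool = False

    def __post_init__(self) -> None:
        if self.three_prime_max_mismatches < 0 or self.spacer_wobble < 0:
            raise InputError("mismatch allowance and spacer wobble must be >= 0")
        if self.seed_interval[1] >= self.three_prime_interval[0]:
            raise InputError("seed interval must end before the 3' interval starts")

    @property
    def nominal_spacer(self) -> int:
        return self.three_prime_interval[0] - self.seed_interval[1] - 1

    @classmethod
    def for_mirna(cls, mirna: MatureMiRNA, **overrides) -> "SiteSearchParams":
        params = cls(
            seed_interval=mirna.seed_interval,
            three_prime_interval=mirna.three_prime_interval,
        )
        return replace(params, **overrides) if overrides else params


# Search criteria as used for the two miRNAs whose 3'-pairing pattern this
# package characterizes: miR-503 uses a 5'-offset seed (1-6); miR-103 uses a
# canonical 2-7 seed with 3' 13-20 for supplementary and 11-18 for
# compensatory sites.
MIR503_PARAMS = SiteSearchParams(seed_interval=(1, 6), three_prime_interval=(11, 18))
MIR103_SUPPLEMENTARY_PARAMS = SiteSearchParams(seed_interval=(2, 7), three_prime_interval=(13, 20))
MIR103_COMPENSATORY_PARAMS = SiteSearchParams(seed_interval=(2, 7), three_prime_interval=(11, 18))


@dataclass(frozen=True)
class SiteMatch:
    """One annotated pairing site on a UTR (0-based half-open interval)."""

    gene_id: str
    site_type: str
    start: int
    end: int
    seed_mismatches: int
    three_prime_mismatches: Optional[int] = None
    spacer_length: Optional[int] = None


def find_seed_matches(
    utr: str,
    mirna: MatureMiRNA,
    seed_positions: tuple[int, int] = (2, 8),
    gene_id: str = "",
) -> list[SiteMatch]:
    """All exact occurrences of the seed match in a UTR, overlaps allowed.

    The seed match is the reverse complement of the miRNA ``seed_positions``
    segment (default 2-8, the 7mer-m8 convention).  Returned left-to-right.
    """
    _validate_rna(utr, f"UTR {gene_id!r}" if gene_id else "UTR")
    motif = reverse_complement(mirna.segment(seed_positions))
    sites = []
    pos = utr.find(motif)
    while pos != -1:
        sites.append(
            SiteMatch(gene_id, "canonical_seed", pos, pos + len(motif), seed_mismatches=0)
        )
        pos = utr.find(motif, pos + 1)
    return sites


def _scan_mismatch_positions(utr: str, segment_rc: str, max_mm: int) -> dict[int, int]:
    """Start -> mismatch count for every window within ``max_mm`` of the motif."""
    k = len(segment_rc)
    out: dict[int, int] = {}
    for start in range(len(utr) - k + 1):
        mm = 0
        for a, b in zip(utr[start : start + k], segment_rc):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            out[start] = mm
    return out


def _find_two_block_sites(
    utr: str,
    mirna: MatureMiRNA,
    params: SiteSearchParams,
    seed_mismatches_required: int,
    site_type: str,
    gene_id: str = "",
) -> list[SiteMatch]:
    _validate_rna(utr, f"UTR {gene_id!r}" if gene_id else "UTR")
    seed_rc = reverse_complement(mirna.segment(params.seed_interval))
    tp_segment = mirna.segment(params.three_prime_interval)
    tp_rc = reverse_complement(tp_segment)
    tp_len = len(tp_rc)
    nominal = params.nominal_spacer

    if params.allow_gu:
        # G:U-aware matching cannot use plain string comparison
        seed_loci = {
            s: pairing_mismatches(utr[s : s + len(seed_rc)], mirna.segment(params.seed_interval), True)
            for s in range(len(utr) - len(seed_rc) + 1)
        }
        seed_loci = {s: mm for s, mm in seed_loci.items() if mm == seed_mismatches_required}
    else:
        seed_loci = {
            s: mm
            for s, mm in _scan_mismatch_positions(utr, seed_rc, seed_mismatches_required).items()
            if mm == seed_mismatches_required
        }

    sites = []
    for seed_start in sorted(seed_loci):
        best: Optional[SiteMatch] = None
        for spacer in range(max(nominal - params.spacer_wobble, 0), nominal + params.spacer_wobble + 1):
            tp_end = seed_start - spacer
            tp_start = tp_end - tp_len
            if tp_start < 0:
                continue
            window = utr[tp_start:tp_end]
            if params.allow_gu:
                tp_mm = pairing_mismatches(window, tp_segment, True)
            else:
                tp_mm = sum(a != b for a, b in zip(window, tp_rc))
            if tp_mm > params.three_prime_max_mismatches:
                continue
            candidate = SiteMatch(
                gene_id,
                site_type,
                tp_start,
                seed_start + len(seed_rc),
                seed_mismatches=seed_loci[seed_start],
                three_prime_mismatches=tp_mm,
                spacer_length=spacer,
            )
            # keep the minimal-mismatch site per seed locus; ties resolved
            # toward the nominal spacer, then the shorter spacer
            if best is None or (
                candidate.three_prime_mismatches,
                abs(spacer - nominal),
                spacer,
            ) < (best.three_prime_mismatches, abs(best.spacer_length - nominal), best.spacer_length):
                best = candidate
        if best is not None:
            sites.append(best)
    return sites


def find_supplementary_sites(
    utr: str, mirna: MatureMiRNA, params: Optional[SiteSearchParams] = None, gene_id: str = ""
) -> list[SiteMatch]:
    """Supplementary sites: perfect seed block plus a nearby 3'-region match.

    The 3'-region match lies 5' of the seed match on the UTR (antiparallel
    duplex geometry), separated by a spacer of nominal length +/- the wobble.
    A UTR too short to hold any site yields an empty list.
    """
    if params is None:
        params = SiteSearchParams.for_mirna(mirna)
    return _find_two_block_sites(utr, mirna, params, 0, "supplementary", gene_id)


def find_compensatory_sites(
    utr: str, mirna: MatureMiRNA, params: Optional[SiteSearchParams] = None, gene_id: str = ""
) -> list[SiteMatch]:
    """Compensatory sites: seed block with exactly one mismatch plus 3' match.

    Loci whose seed block pairs perfectly qualify as supplementary and are
    never reported here, keeping the two classes disjoint.
    """
    if params is None:
        params = SiteSearchParams.for_mirna(mirna)
    return _find_two_block_sites(utr, mirna, params, 1, "compensatory", gene_id)


def classify_gene_pairing(
    utr: str, mirna: MatureMiRNA, params: Optional[SiteSearchParams] = None
) -> str:
    """Best pairing type present in a UTR.

    Precedence: supplementary > compensatory > canonical_seed > none; a gene
    is counted once regardless of how many sites it holds.  The canonical
    class is a perfect match to the seed-interval reverse complement alone.
    """
    if params is None:
        params = SiteSearchParams.for_mirna(mirna)
    if find_supplementary_sites(utr, mirna, params):
        return "supplementary"
    if find_compensatory_sites(utr, mirna, params):
        return "compensatory"
    if reverse_complement(mirna.segment(params.seed_interval)) in utr:
        return "canonical_seed"
    return "none"


def classify_genes(
    utrs: Mapping[str, str], mirna: MatureMiRNA, params: Optional[SiteSearchParams] = None
) -> dict[str, str]:
    """Pairing-type label per gene for a whole UTR set."""
    return {g: classify_gene_pairing(seq, mirna, params) for g, seq in utrs.items()}


def kmer_offset_enrichment(
    target_utrs: Mapping[str, str],
    background_utrs: Mapping[str, str],
    mirna: MatureMiRNA,
    k: int = 6,
    mode: str = "gene",
) -> pd.DataFrame:
    """Stepwise k-mer enrichment profile along the miRNA.

    For each 1-based offset ``p`` in ``1..L-k+1``, take the miRNA k-mer at
    positions ``p..p+k-1`` and measure how often its reverse complement
    occurs in target UTRs relative to background UTRs.

    ``mode="gene"`` (default): fraction of genes whose UTR contains the
    match at least once.  ``mode="occurrence"``: mean number of
    (overlapping) occurrences per gene.  Offsets where the background
    frequency is zero get ratio NaN (undefined, not zero).

    Returns a frame with columns offset, kmer, target_freq,
    background_freq, ratio.
    """
    if not target_utrs or not background_utrs:
        raise InputError("target and background UTR sets must be nonempty")
    missing = set(target_utrs) - set(background_utrs)
    if missing:
        raise InputError(
            f"{len(missing)} target gene(s) absent from background, e.g. {sorted(missing)[0]!r}"
        )
    if mode not in ("gene", "occurrence"):
        raise InputError(f"unknown mode {mode!r}")

    def freq(utrs: Mapping[str, str], motif: str) -> float:
        if mode == "gene":
            return sum(motif in s for s in utrs.values()) / len(utrs)
        total = 0
        for s in utrs.values():
            pos = s.find(motif)
            while pos != -1:
                total += 1
                pos = s.find(motif, pos + 1)
        return total / len(utrs)

    rows = []
    for p in range(1, len(mirna) - k + 2):
        kmer = mirna.segment((p, p + k - 1))
        motif = reverse_complement(kmer)
        tf = freq(target_utrs, motif)
        bf = freq(background_utrs, motif)
        rows.append(
            {
                "offset": p,
                "kmer": kmer,
                "target_freq": tf,
                "background_freq": bf,
                "ratio": tf / bf if bf > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pairing_type_relative_frequency(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    labels: Mapping[str, str],
) -> dict[str, float]:
    """Per-type frequency in targets relative to background.

    For each site type, (fraction of targets labeled with the type) /
    (fraction of background so labeled); NaN where the background fraction
    is zero.
    """
    targets = list(target_genes)
    background = list(background_genes)
    if not set(targets) <= set(background):
        raise InputError("target genes must be a subset of background genes")
    if not background:
        raise InputError("background gene set is empty")
    out = {}
    for site_type in SITE_PRECEDENCE:
        tf = sum(labels.get(g) == site_type for g in targets) / len(targets) if targets else 0.0
        bf = sum(labels.get(g) == site_type for g in background) / len(background)
        out[site_type] = tf / bf if bf > 0 else np.nan
    return out


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_fence = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "n": int(values.size),
        "whisker_low": float(in_fence.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_high": float(in_fence.max()),
        "n_outliers": int(values.size - in_fence.size),
    }


def expression_by_pairing_type(
    measures: pd.DataFrame,
    labels: Mapping[str, str],
    classes: Optional[Mapping[str, Sequence[str]]] = None,
    value: str = "repression",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot summary of log2 repression (or enrichment) per pairing type.

    ``classes`` maps class name -> gene IDs; by default one class per
    pairing type found in ``labels``.  Whiskers are the extrema after
    excluding points beyond 1.5 x IQR from the box (outliers are excluded
    from whiskers only, not from the quartiles).  Returns (summary frame,
    pairwise two-sided Welch t-test frame on the log2 values); a class with
    fewer than two members is summarised but not tested.
    """
    if value not in ("repression", "enrichment"):
        raise InputError(f"value must be 'repression' or 'enrichment', got {value!r}")
    by_gene = measures.set_index("gene_id")[value]
    if classes is None:
        classes = {
            t: [g for g, lab in labels.items() if lab == t]
            for t in SITE_PRECEDENCE + ("none",)
        }
    vectors = {}
    summaries = []
    for name, genes in classes.items():
        vals = np.log2(by_gene.loc[[g for g in genes if g in by_gene.index]].to_numpy(float))
        vectors[name] = vals
        if vals.size == 0:
            summaries.append({"class": name, "n": 0, "degenerate": True})
            continue
        row = {"class": name, "degenerate": vals.size < 2, **_box_stats(vals)}
        summaries.append(row)
    tests = []
    names = list(classes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ok = vectors[a].size >= 2 and vectors[b].size >= 2
            if ok:
                t, p = stats.ttest_ind(vectors[a], vectors[b], equal_var=False)
            tests.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "t": float(t) if ok else np.nan,
                    "p_value": float(p) if ok else np.nan,
                    "computed": ok,
                }
            )
    return pd.DataFrame(summaries), pd.DataFrame(tests)
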