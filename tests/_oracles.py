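"""Independent brute-force oracles used to check the site-search code.

Everything here is written as plain position-by-position enumeration with
explicit loops, deliberately sharing no code with the package internals.
"""

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def naive_rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def naive_exact_occurrences(utr, motif):
    hits = []
    for i in range(len(utr) - len(motif) + 1):
        if all(utr[i + j] == motif[j] for j in range(len(motif))):
            hits.append((i, i + len(motif)))
    return hits


def naive_two_block_sites(utr, mirna_seq, seed_interval, tp_interval,
                          seed_mm_required, tp_max_mm, wobble):
    """All (tp_start, site_end, seed_mm, tp_mm, spacer) tuples, deduplicated.

    Enumerates every possible seed locus and every possible 3'-block locus
    and keeps, per seed locus, the site with the fewest 3' mismatches
    (ties: spacer closest to nominal, then shorter spacer).
    """
    seed_rc = naive_rc(mirna_seq[seed_interval[0] - 1:seed_interval[1]])
    tp_rc = naive_rc(mirna_seq[tp_interval[0] - 1:tp_interval[1]])
    nominal = tp_interval[0] - seed_interval[1] - 1

    sites = []
    for seed_start in range(len(utr) - len(seed_rc) + 1):
        seed_mm = sum(
            utr[seed_start + j] != seed_rc[j] for j in range(len(seed_rc))
        )
        if seed_mm != seed_mm_required:
            continue
        candidates = []
        for tp_start in range(len(utr) - len(tp_rc) + 1):
            spacer = seed_start - (tp_start + len(tp_rc))
            if spacer < 0 or abs(spacer - nominal) > wobble:
                continue
            tp_mm = sum(utr[tp_start + j] != tp_rc[j] for j in range(len(tp_rc)))
            if tp_mm > tp_max_mm:
                continue
            candidates.append((tp_mm, abs(spacer - nominal), spacer, tp_start))
        if candidates:
            tp_mm, _, spacer, tp_start = min(candidates)
            sites.append(
                (tp_start, seed_start + len(seed_rc), seed_mm, tp_mm, spacer)
            )
    return sites


def site_tuples(sites):
    """Normalise package SiteMatch objects to the oracle's tuple form."""
    return [
        (s.start, s.end, s.seed_mismatches, s.three_prime_mismatches, s.spacer_length)
        for s in sites
    ]
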