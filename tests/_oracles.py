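"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — character-by-character scans,
explicit hypergeometric enumeration with integer combinatorics, exhaustive
sliding-window search — and shares no code with the package internals it
checks.
"""

from math import comb


def naive_homopolymers(seq: str, min_run: int) -> list[tuple[int, int, str]]:
    """(start, length, base) of every maximal run >= min_run."""
    out = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            out.append((i, j - i, seq[i]))
        i = j
    return out


def fisher_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] with fixed margins,
    by explicit enumeration of the hypergeometric support."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    col1 = a + b  # WGA diploid total
    alts = a + c  # total alternate alleles
    denom = comb(n, alts)
    p = 0
    for x in range(a, min(col1, alts) + 1):
        if alts - x > n - col1:
            continue
        p += comb(col1, x) * comb(n - col1, alts - x)
    return p / denom


def naive_indel_category(
    seq: str, vcf_pos: int, changed: str, is_insertion: bool
) -> str:
    """Re-derive the homopolymer+/large/other category by direct scanning."""
    if len(changed) >= 15:
        return "LARGE"
    if len(set(changed)) != 1:
        return "OTHER"
    base = changed[0]
    start0 = vcf_pos  # 0-based index of the first changed base
    for s in (start0 - 1, start0, start0 + 1):
        if s < 0 or s >= len(seq) or seq[s] != base:
            continue
        run = 0
        while s + run < len(seq) and seq[s + run] == base:
            run += 1
        if run >= 4:
            return "HOMOPOLYMER_PLUS"
    return "OTHER"


def naive_best_match(
    seq: str,
    query: str,
    center: int,
    window: int,
    excluded: tuple[int, int] | None = None,
) -> tuple[int | None, float]:
    """Exhaustive early-exit sliding scan: (best position, best identity).

    Ties broken by distance to ``center``; candidates overlapping
    ``excluded`` are skipped.
    """
    L = len(query)
    lo = max(0, center - window)
    hi = min(len(seq) - L, center + window)
    best_pos, best_ident = None, -1.0
    for p in range(lo, hi + 1):
        if excluded is not None and not (p + L <= excluded[0] or p >= excluded[1]):
            continue
        matches = 0
        # early exit once this candidate can no longer beat the best
        need = best_ident * L
        for i in range(L):
            if seq[p + i] == query[i]:
                matches += 1
            elif matches + (L - i - 1) < need:
                break
        else:
            ident = matches / L
            if ident > best_ident or (
                ident == best_ident and abs(p - center) < abs(best_pos - center)
            ):
                best_pos, best_ident = p, ident
            continue
        # break path: candidate provably cannot beat the current best
    return best_pos, best_ident
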