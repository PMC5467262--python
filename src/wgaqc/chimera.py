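"""Copy-origin search for large indels (MDA chimera detection).

Multiple displacement amplification produces chimeric DNA whose junctions
appear in variant calls as large insertions copied from nearby reference
sequence. For each large (>= 15 bp) indel, the inserted (insertion) or
deleted (deletion) sequence is aligned ungapped against the reference
within +/- 10 kb of the indel start; a hit at identity >= min_identity
marks the indel as a putative chimera. For deletions, candidate positions
overlapping the deleted span itself are excluded so the trivial self-match
never counts.

Ungapped sliding-window identity replaces a gapped aligner: simulated
chimeric insertions are verbatim reference copies, for which exact matching
is sufficient; ``min_identity`` < 1 tolerates point mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceSequence
from .variants import VariantAllele

DEFAULT_WINDOW = 10_000
NEAR_CIS_BP = 2_000


@dataclass(frozen=True)
class ChimeraHit:
    """Best local match of one large indel's changed sequence."""

    key: tuple  # (contig, pos, ref, alt)
    matched: bool
    match_pos: int | None  # 0-based reference position of best match
    distance: int | None  # |match_pos - indel start| in bp
    identity: float
    is_insertion: bool


def find_origin(
    allele: VariantAllele,
    ref: ReferenceSequence,
    window: int = DEFAULT_WINDOW,
    min_identity: float = 0.9,
    search_revcomp: bool = False,
) -> ChimeraHit:
    """Locate the best copy-origin of a large indel's changed sequence.

    Scans every alignment start within ``window`` bp of the indel start
    (clipped at contig ends), scoring ungapped identity. Best match =
    highest identity, ties broken by smallest distance to the indel start.
    ``search_revcomp=True`` additionally scans the reverse complement
    (forward-strand hits win ties).
    """
    if allele.indel_len < 15:
        raise ValueError("find_origin requires a large indel (>= 15 changed bases)")
    query = allele.changed_bases
    is_ins = allele.type == "insertion"
    start0 = allele.pos  # 0-based position of first changed base
    L = len(query)
    n = len(ref)

    lo = max(0, start0 - window)
    hi = min(n - L, start0 + window)
    excluded: tuple[int, int] | None = None
    if not is_ins:
        # deleted reference span (0-based half-open)
        excluded = (start0, start0 + L)

    best_identity, best_pos = -1.0, None
    if hi >= lo:
        seq_arr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(seq_arr, L)[lo : hi + 1]
        queries = [np.frombuffer(query.encode(), dtype=np.uint8)]
        if search_revcomp:
            queries.append(
                np.frombuffer(_revcomp(query).encode(), dtype=np.uint8)
            )
        identity = np.zeros(windows.shape[0])
        for q in queries:
            identity = np.maximum(identity, (windows == q).mean(axis=1))
        positions = np.arange(lo, hi + 1)
        if excluded is not None:
            keep = (positions + L <= excluded[0]) | (positions >= excluded[1])
            positions, identity = positions[keep], identity[keep]
        if len(positions):
            dist = np.abs(positions - start0)
            order = np.lexsort((dist, -identity))
            best_pos = int(positions[order[0]])
            best_identity = float(identity[order[0]])

    matched = best_identity >= min_identity and best_pos is not None
    return ChimeraHit(
        key=allele.key,
        matched=matched,
        match_pos=best_pos if matched else None,
        distance=abs(best_pos - start0) if matched else None,
        identity=max(best_identity, 0.0),
        is_insertion=is_ins,
    )


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def origin_distance_summary(
    hits: Sequence[ChimeraHit],
    enriched: dict[tuple, bool] | None = None,
    near_cis_bp: int = NEAR_CIS_BP,
) -> pd.DataFrame:
    """Match rate and distance distribution, split by enrichment and type.

    One row per (enrichment flag, insertion/deletion) stratum plus an
    overall row: match rate, distance quartiles among matches, and the
    fraction of matches within ``near_cis_bp`` of the indel start.
    """
    rows = []
    strata: dict[str, list[ChimeraHit]] = {"all": list(hits)}
    if enriched is not None:
        for h in hits:
            flag = enriched.get(h.key)
            if flag is None:
                continue
            kind = "insertion" if h.is_insertion else "deletion"
            strata.setdefault(f"{'enriched' if flag else 'non_enriched'}:{kind}", []).append(h)
            strata.setdefault("enriched" if flag else "non_enriched", []).append(h)
    for name, grp in strata.items():
        if not grp:
            continue
        dists = np.array([h.distance for h in grp if h.matched], dtype=float)
        row = {
            "stratum": name,
            "n": len(grp),
            "match_rate": len(dists) / len(grp),
            "frac_within_near_cis": float((dists <= near_cis_bp).mean()) if len(dists) else np.nan,
        }
        for q, label in [(0.25, "q25"), (0.5, "median"), (0.75, "q75")]:
            row[f"distance_{label}"] = float(np.quantile(dists, q)) if len(dists) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def hits_to_frame(hits: Sequence[ChimeraHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        contig, pos, ref, alt = h.key
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "matched": h.matched,
                "match_pos": h.match_pos,
                "distance": h.distance,
                "identity": h.identity,
                "is_insertion": h.is_insertion,
            }
        )
    return pd.DataFrame(rows)
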