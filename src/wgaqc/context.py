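"""Indel context taxonomy: homopolymer+, large, other.

A *large* indel has >= 15 inserted or deleted bases. Among the remaining
(< 15 bp) indels, only single-base indels or multi-base indels of a single
repeated base are homopolymer-eligible; an eligible indel is *homopolymer+*
when a run of >= 4 consecutive copies of that base starts within +/- 1 bp
of the indel start in the reference sequence. Everything else is *other*.
The three categories are mutually exclusive and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome import ReferenceSequence, window_gc
from .variants import VariantAllele

LARGE_MIN_LEN = 15
HOMOPOLYMER_MIN_RUN = 4

HOMOPOLYMER_PLUS = "HOMOPOLYMER_PLUS"
LARGE = "LARGE"
OTHER = "OTHER"
CATEGORIES = (HOMOPOLYMER_PLUS, LARGE, OTHER)


@dataclass(frozen=True)
class IndelContext:
    """Taxonomy record for one indel allele."""

    key: tuple  # (contig, pos, ref, alt)
    category: str
    homopolymer_eligible: bool
    gc10: float
    mod3: bool
    is_insertion: bool
    length: int


def classify_indel(
    allele: VariantAllele,
    ref: ReferenceSequence,
    min_run: int = HOMOPOLYMER_MIN_RUN,
    large_min_len: int = LARGE_MIN_LEN,
) -> IndelContext:
    """Classify one normalized indel allele against its reference contig.

    Length takes precedence: an indel of >= ``large_min_len`` changed bases
    is LARGE regardless of context. The proximal-run search is performed in
    the reference sequence only (not the alternate haplotype), anchored
    within +/- 1 bp of the indel start (the first changed base).
    """
    if not allele.is_indel:
        raise ValueError("classify_indel requires an indel allele")
    length = allele.indel_len
    changed = allele.changed_bases
    gc10 = window_gc(ref, min(allele.pos - 1, len(ref) - 1), flank=10)
    mod3 = length % 3 == 0
    is_ins = allele.type == "insertion"

    if length >= large_min_len:
        return IndelContext(allele.key, LARGE, False, gc10, mod3, is_ins, length)

    eligible = len(set(changed)) == 1
    category = OTHER
    if eligible and _run_near(ref.seq, allele.pos, changed[0], min_run):
        category = HOMOPOLYMER_PLUS
    return IndelContext(allele.key, category, eligible, gc10, mod3, is_ins, length)


def _run_near(seq: str, vcf_pos: int, base: str, min_run: int) -> bool:
    """Does a run of >= min_run copies of ``base`` begin within +/-1 bp of
    the indel start position?

    The indel start is the first changed base: 0-based ``vcf_pos`` (the
    anchor base is at vcf_pos - 1, changed bases begin right after it).
    """
    start0 = vcf_pos  # first inserted/deleted reference-coordinate position
    n = len(seq)
    for s in (start0 - 1, start0, start0 + 1):
        if s < 0 or s >= n:
            continue
        if seq[s] != base:
            continue
        run = 0
        i = s
        while i < n and seq[i] == base:
            run += 1
            i += 1
        if run >= min_run:
            return True
    return False


def classify_all(
    alleles: Sequence[VariantAllele], ref: ReferenceSequence, **kwargs
) -> dict[tuple, IndelContext]:
    """Classify every indel allele; keyed by allele key."""
    return {
        a.key: classify_indel(a, ref, **kwargs) for a in alleles if a.is_indel
    }


def taxonomy_summary(
    contexts: Sequence[IndelContext],
    labels: Sequence[bool] | None = None,
    label_names: tuple[str, str] = ("enriched", "non_enriched"),
) -> pd.DataFrame:
    """Per-label-group category fractions, insertion and mod-3 fractions.

    ``labels`` flags each context (e.g. WGA-enriched yes/no); when omitted
    all contexts form one group. Returns one row per group with columns
    frac_homopolymer_plus / frac_large / frac_other (summing to 1),
    frac_insertion, frac_mod3, n, plus a size histogram serialized as a
    dict column.
    """
    if len(contexts) == 0:
        raise ValueError("taxonomy_summary requires at least one context")
    if labels is None:
        groups = {"all": list(contexts)}
    else:
        labels = list(labels)
        if len(labels) != len(contexts):
            raise ValueError("labels and contexts length mismatch")
        groups = {
            label_names[0]: [c for c, l in zip(contexts, labels) if l],
            label_names[1]: [c for c, l in zip(contexts, labels) if not l],
        }
    rows = []
    for name, grp in groups.items():
        n = len(grp)
        if n == 0:
            continue
        cats = [c.category for c in grp]
        sizes = pd.Series([c.length for c in grp])
        rows.append(
            {
                "group": name,
                "n": n,
                "frac_homopolymer_plus": cats.count(HOMOPOLYMER_PLUS) / n,
                "frac_large": cats.count(LARGE) / n,
                "frac_other": cats.count(OTHER) / n,
                "frac_insertion": sum(c.is_insertion for c in grp) / n,
                "frac_mod3": sum(c.mod3 for c in grp) / n,
                "size_histogram": sizes.value_counts().sort_index().to_dict(),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def contexts_to_frame(
    contexts: Sequence[IndelContext], enriched: dict[tuple, bool] | None = None
) -> pd.DataFrame:
    """TSV-ready table: one row per indel with its taxonomy fields."""
    rows = []
    for c in contexts:
        contig, pos, ref_a, alt = c.key
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref_a,
                "alt": alt,
                "category": c.category,
                "homopolymer_eligible": c.homopolymer_eligible,
                "gc10": c.gc10,
                "mod3": c.mod3,
                "is_insertion": c.is_insertion,
                "length": c.length,
                "enriched": (enriched or {}).get(c.key, pd.NA),
            }
        )
    return pd.DataFrame(rows)
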