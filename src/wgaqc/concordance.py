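"""Genotype discordance between repeated samples of one individual.

Variant calls from two samples are matched by (contig, position, alternate
base), disregarding zygosity; discordance is 1 minus the Jaccard similarity
of the two call sets. Because calls with missing genotypes count as absent,
coverage dropout — the WGA failure mode — drives discordance directly.
Filter quality is scored on the concordant/discordant partition of the
pooled pair calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantAllele


@dataclass(frozen=True)
class ReplicatePair:
    individual_id: str
    sample_a: str
    sample_b: str
    pair_type: str  # {"DNA:DNA", "WGA:DNA", "WGA:WGA"}

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("replicate pair must contain distinct samples")


@dataclass(frozen=True)
class FilterEvaluation:
    """Concordance-based quality metrics for one filter tier."""

    label: str
    n_lof_indel_sites: int
    median_lof_indel_burden: float
    frac_discordant_removed: float
    frac_concordant_removed: float
    truth_panel_overlap: float  # NaN when nothing retained


def discordance(calls_a: set, calls_b: set) -> float:
    """1 - |A ∩ B| / |A ∪ B| over call keys (contig, pos, alt)."""
    union = calls_a | calls_b
    if not union:
        raise ValueError("discordance undefined: both call sets empty")
    return 1.0 - len(calls_a & calls_b) / len(union)


def sample_calls(
    alleles: Sequence[VariantAllele], sample_index: int
) -> set[tuple[str, int, str]]:
    """Call set of one sample: keys of alleles with dosage >= 1.

    Missing genotypes count as absent, matching joint-calling semantics
    where a dropout site contributes no call.
    """
    return {
        (a.contig, a.pos, a.alt)
        for a in alleles
        if a.genotypes[sample_index] not in (0, MISSING)
    }


def pairs_from_meta(meta: pd.DataFrame) -> list[ReplicatePair]:
    """Derive replicate pairs from metadata rows sharing an individual_id."""
    pairs: list[ReplicatePair] = []
    for ind, grp in meta.groupby("individual_id", sort=False):
        rows = list(grp.itertuples())
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                n_wga = int(a.wga) + int(b.wga)
                pair_type = {0: "DNA:DNA", 1: "WGA:DNA", 2: "WGA:WGA"}[n_wga]
                pairs.append(ReplicatePair(str(ind), a.sample_id, b.sample_id, pair_type))
    return pairs


def pairwise_discordance(
    pairs: Sequence[ReplicatePair],
    alleles: Sequence[VariantAllele],
    samples: Sequence[str],
    contexts: Mapping[tuple, "IndelContext"] | None = None,
    max_discordance: float | None = None,
) -> pd.DataFrame:
    """Per-pair discordance, overall and per variant class.

    Columns: overall, snv, indel, and per indel-context category when
    ``contexts`` is supplied (category columns use only the indels carrying
    that category). ``max_discordance`` flags pairs exceeding a ceiling for
    exclusion (e.g. suspected sample-label mismatches) without dropping
    them. Classes with an empty pooled call set yield NaN.
    """
    sample_pos = {s: i for i, s in enumerate(samples)}
    subsets: dict[str, list[VariantAllele]] = {
        "overall": list(alleles),
        "snv": [a for a in alleles if not a.is_indel],
        "indel": [a for a in alleles if a.is_indel],
    }
    if contexts is not None:
        from .context import CATEGORIES

        for cat in CATEGORIES:
            subsets[f"indel_{cat.lower()}"] = [
                a
                for a in alleles
                if a.is_indel and a.key in contexts and contexts[a.key].category == cat
            ]
    rows = []
    for pair in pairs:
        ia, ib = sample_pos[pair.sample_a], sample_pos[pair.sample_b]
        row: dict = {
            "individual_id": pair.individual_id,
            "sample_a": pair.sample_a,
            "sample_b": pair.sample_b,
            "pair_type": pair.pair_type,
        }
        for name, subset in subsets.items():
            ca, cb = sample_calls(subset, ia), sample_calls(subset, ib)
            row[name] = discordance(ca, cb) if (ca | cb) else np.nan
        if max_discordance is not None:
            row["flagged"] = bool(row["overall"] > max_discordance)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_pair_type(table: pd.DataFrame) -> pd.DataFrame:
    """Median discordance per pair type for each variant class column."""
    value_cols = [
        c
        for c in table.columns
        if c not in ("individual_id", "sample_a", "sample_b", "pair_type", "flagged")
    ]
    return table.groupby("pair_type")[value_cols].median()


def evaluate_filter(
    label: str,
    kept_alleles: Sequence[VariantAllele],
    all_alleles: Sequence[VariantAllele],
    pairs: Sequence[ReplicatePair],
    samples: Sequence[str],
    truth_panel: set[tuple] | None = None,
    lof_indel_burden: pd.Series | None = None,
) -> FilterEvaluation:
    """Score one filter tier on the replicate pairs.

    Discordant alleles: present in exactly one member of some pair (pooled
    over pairs, pre-filter); concordant: present in both members of some
    pair. The evaluation reports the fraction of each removed by the
    filter, plus the truth-panel overlap of retained indels (NaN and
    flagged when the filter retains nothing).
    """
    if not pairs:
        raise ValueError("evaluate_filter requires at least one replicate pair")
    sample_pos = {s: i for i, s in enumerate(samples)}
    indels_all = [a for a in all_alleles if a.is_indel]
    discordant: set[tuple] = set()
    concordant: set[tuple] = set()
    for pair in pairs:
        ia, ib = sample_pos[pair.sample_a], sample_pos[pair.sample_b]
        ca, cb = sample_calls(indels_all, ia), sample_calls(indels_all, ib)
        discordant |= ca ^ cb
        concordant |= ca & cb
    discordant -= concordant  # concordant in any pair wins
    kept_keys = {(a.contig, a.pos, a.alt) for a in kept_alleles if a.is_indel}
    frac_disc = (
        sum(1 for k in discordant if k not in kept_keys) / len(discordant)
        if discordant
        else 0.0
    )
    frac_conc = (
        sum(1 for k in concordant if k not in kept_keys) / len(concordant)
        if concordant
        else 0.0
    )
    kept_indels = [a for a in kept_alleles if a.is_indel]
    if truth_panel is not None and kept_indels:
        overlap = sum(1 for a in kept_indels if a.key in truth_panel) / len(kept_indels)
    else:
        overlap = float("nan")
    return FilterEvaluation(
        label=label,
        n_lof_indel_sites=len(kept_indels),
        median_lof_indel_burden=(
            float(lof_indel_burden.median()) if lof_indel_burden is not None else float("nan")
        ),
        frac_discordant_removed=frac_disc,
        frac_concordant_removed=frac_conc,
        truth_panel_overlap=overlap,
    )
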