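"""One-way Fisher screening for WGA-enriched indel alleles.

For each indel, a 2x2 table of alternate vs reference allele counts in the
WGA vs non-WGA (DNA) groups is tested with a one-sided Fisher's exact test
toward WGA excess. The significance threshold is the p-value of a singleton
present only in the WGA group — the weakest signal the design can ever
flag — so the screen is calibrated to cohort composition rather than to a
fixed alpha. No multiple-testing correction is applied: this is a screening
rule, not inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .variants import MISSING, VariantAllele, allele_counts


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher screen outcome for one indel allele."""

    key: tuple  # (contig, pos, ref, alt)
    alt_wga: int
    ref_wga: int
    alt_dna: int
    ref_dna: int
    p: float
    enriched: bool


def fisher_one_sided(alt_wga: int, ref_wga: int, alt_dna: int, ref_dna: int) -> float:
    """Upper-tail hypergeometric p for WGA excess of the alternate allele.

    P(X >= alt_wga) where X is the count of alternate alleles falling in the
    WGA column when the table margins are fixed. The all-zero table returns
    1 by convention.
    """
    for v in (alt_wga, ref_wga, alt_dna, ref_dna):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    total = alt_wga + ref_wga + alt_dna + ref_dna
    if total == 0:
        return 1.0
    n_alt = alt_wga + alt_dna
    n_wga = alt_wga + ref_wga
    # survival function is P(X > k), so shift by one
    return float(hypergeom.sf(alt_wga - 1, total, n_alt, n_wga))


def singleton_threshold(n_wga: int, n_dna: int) -> float:
    """Fisher p of a singleton alternate allele found only in WGA samples.

    With diploid totals 2*n_wga and 2*n_dna this equals
    2*n_wga / (2*n_wga + 2*n_dna) in closed form: the probability that the
    single alternate allele lands in the WGA column.
    """
    if n_wga < 1 or n_dna < 1:
        raise ValueError("both groups need at least one sample")
    return fisher_one_sided(1, 2 * n_wga - 1, 0, 2 * n_dna)


def call_enriched(
    alleles: Sequence[VariantAllele],
    wga_mask: np.ndarray,
    strict: bool = False,
) -> list[EnrichmentResult]:
    """Screen indel alleles for WGA enrichment.

    ``wga_mask`` is a boolean mask over the cohort sample order. The
    threshold is the exactly computed singleton p for the cohort sizes; by
    default an allele is enriched when p <= threshold, so a WGA-only
    singleton — sitting exactly at the boundary — is flagged. ``strict=True``
    switches to p < threshold (under which a lone singleton is not
    enriched).

    Group diploid totals shrink with missing genotypes; with no missing
    genotypes the fixed 2N accounting is recovered exactly.
    """
    wga_mask = np.asarray(wga_mask, dtype=bool)
    n_wga = int(wga_mask.sum())
    n_dna = int((~wga_mask).sum())
    if n_wga == 0:
        raise ValueError("no WGA samples in cohort")
    if n_dna == 0:
        raise ValueError("no non-WGA samples in cohort")
    threshold = singleton_threshold(n_wga, n_dna)
    groups = {"wga": wga_mask, "dna": ~wga_mask}
    results: list[EnrichmentResult] = []
    for a in alleles:
        if not a.is_indel:
            continue
        counts = allele_counts(a, groups)
        aw, rw = counts["wga"]
        ad, rd = counts["dna"]
        p = fisher_one_sided(aw, rw, ad, rd)
        enriched = (p < threshold) if strict else (p <= threshold)
        results.append(EnrichmentResult(a.key, aw, rw, ad, rd, p, enriched))
    return results


def enrichment_af_contrast(
    alleles: Sequence[VariantAllele],
    contexts: Mapping[tuple, "IndelContext"],
    wga_mask: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """WGA allele-frequency contrast: homopolymer+ vs non-homopolymer indels.

    Returns mean WGA AF in each class, their difference, and a basic
    bootstrap CI for the difference (degenerate inputs are flagged rather
    than erroring).
    """
    from .context import HOMOPOLYMER_PLUS

    wga_mask = np.asarray(wga_mask, dtype=bool)
    hp_afs, other_afs = [], []
    for a in alleles:
        if not a.is_indel or a.key not in contexts:
            continue
        g = a.genotypes[wga_mask]
        nonmiss = g != MISSING
        if nonmiss.sum() == 0:
            continue
        af = float(g[nonmiss].sum()) / (2 * int(nonmiss.sum()))
        if contexts[a.key].category == HOMOPOLYMER_PLUS:
            hp_afs.append(af)
        else:
            other_afs.append(af)
    hp_afs = np.asarray(hp_afs)
    other_afs = np.asarray(other_afs)
    out = {
        "n_homopolymer_plus": len(hp_afs),
        "n_other": len(other_afs),
        "mean_af_homopolymer_plus": float(hp_afs.mean()) if len(hp_afs) else np.nan,
        "mean_af_other": float(other_afs.mean()) if len(other_afs) else np.nan,
    }
    out["contrast"] = out["mean_af_homopolymer_plus"] - out["mean_af_other"]
    degenerate = len(hp_afs) < 2 or len(other_afs) < 2
    out["degenerate"] = degenerate
    if not degenerate:
        rng = np.random.default_rng(seed)
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            diffs[b] = (
                rng.choice(hp_afs, size=len(hp_afs)).mean()
                - rng.choice(other_afs, size=len(other_afs)).mean()
            )
        obs = out["contrast"]
        lo, hi = np.quantile(diffs, [0.975, 0.025])
        out["ci"] = (2 * obs - lo, 2 * obs - hi)
    else:
        out["ci"] = (np.nan, np.nan)
    return out


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        contig, pos, ref, alt = r.key
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_wga": r.alt_wga,
                "ref_wga": r.ref_wga,
                "alt_dna": r.alt_dna,
                "ref_dna": r.ref_dna,
                "p": r.p,
                "enriched": r.enriched,
            }
        )
    return pd.DataFrame(rows)
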