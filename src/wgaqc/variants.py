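"""VCF-backed variant model.

Each multi-allelic VCF record is split into one :class:`VariantAllele` per
ALT allele, normalized (left-aligned and parsimonious), with per-sample
alt-allele dosages in {0, 1, 2, missing}. Allele-level rather than
site-level representation is deliberate: quality filtering and enrichment
screening both operate per allele.

Parsing goes through pysam; writing emits VCFv4.2 text directly (the body
is line-based TSV) and is validated by pysam read-back in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for no-call genotypes

#: columns of the sample-metadata TSV schema
META_COLUMNS = [
    "sample_id",
    "individual_id",
    "group",
    "wga",
    "center",
    "bwa_version",
    "c20x",
    "race",
    "age",
    "sex",
]


@dataclass
class VariantAllele:
    """One normalized (contig, pos, ref, alt) allele with diploid dosages.

    ``pos`` is the 1-based VCF position; ``genotypes`` holds the per-sample
    alt-allele dosage (0/1/2, or -1 for missing) in cohort sample order.
    ``qs`` is the site quality score used by the tiered quality filter.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    qs: float = float("nan")

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)

    @property
    def type(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_indel(self) -> bool:
        return self.type != "SNV"

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def changed_bases(self) -> str:
        """The inserted (insertion) or deleted (deletion) bases."""
        if self.type == "insertion":
            return self.alt[len(self.ref) :]
        if self.type == "deletion":
            return self.ref[len(self.alt) :]
        return self.alt


def normalize(
    contig: str, pos: int, ref: str, alt: str, seq: str
) -> tuple[int, str, str]:
    """Left-align and trim an allele against its contig sequence.

    ``pos`` is 1-based; ``seq`` is the full contig sequence. Returns the
    normalized (pos, ref, alt). Follows the standard algorithm: strip the
    shared suffix (prepending the preceding reference base whenever either
    allele would empty), then strip the shared prefix keeping one anchor.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    start0 = pos - 1
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (len(ref) == 1 or len(alt) == 1) and ref[-1] == alt[-1] and start0 > 0:
            start0 -= 1
            prev = seq[start0]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start0 += 1
    return start0 + 1, ref, alt


def read_vcf(path, seq_by_contig: Mapping[str, str] | None = None):
    """Read a VCF into (list of VariantAllele, sample order).

    Multi-allelic records are split; if ``seq_by_contig`` provides contig
    sequences, each split allele is re-normalized against them. Dosage per
    allele counts only that ALT; other ALTs at the same site contribute to
    their own records. Any sample whose GT includes another ALT still has
    its own dosage of this allele counted (a 1/2 genotype yields dosage 1
    for each allele). Non-diploid genotypes raise.
    """
    import pysam

    alleles: list[VariantAllele] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        has_qs = "QS" in vcf.header.info
        for rec in vcf:
            if rec.alts is None:
                continue
            gts = []
            for s in samples:
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None:
                    gt = (None, None)
                if len(gt) != 2:
                    raise ValueError(
                        f"non-diploid genotype at {rec.contig}:{rec.pos} sample {s}"
                    )
                gts.append(gt)
            qs = rec.info.get("QS", None) if has_qs else None
            qs = float(qs) if qs is not None else float("nan")
            for ai, alt in enumerate(rec.alts, start=1):
                dosages = np.empty(len(samples), dtype=np.int16)
                for si, gt in enumerate(gts):
                    if gt[0] is None or gt[1] is None:
                        dosages[si] = MISSING
                    else:
                        dosages[si] = (gt[0] == ai) + (gt[1] == ai)
                pos, ref, alt_n = rec.pos, rec.ref, alt
                if seq_by_contig is not None and rec.contig in seq_by_contig:
                    pos, ref, alt_n = normalize(
                        rec.contig, rec.pos, rec.ref, alt, seq_by_contig[rec.contig]
                    )
                else:
                    pos, ref, alt_n = _trim(rec.pos, rec.ref, alt)
                alleles.append(
                    VariantAllele(rec.contig, pos, ref, alt_n, dosages, qs=qs)
                )
    return alleles, samples


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony trim without a reference (no left-shifting)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def write_vcf(path, alleles: Sequence[VariantAllele], samples: Sequence[str],
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write alleles as VCFv4.2, merging alleles that share (contig,pos,ref).

    Merged sites become multi-allelic records; per-sample GTs are rebuilt
    from the per-allele dosages (total dosage at a site must not exceed 2).
    """
    by_site: dict[tuple[str, int, str], list[VariantAllele]] = {}
    for a in alleles:
        by_site.setdefault((a.contig, a.pos, a.ref), []).append(a)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QS,Number=1,Type=Float,Description="Simulated site quality score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (contig, pos, ref), site in sorted(by_site.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
            alts = [a.alt for a in site]
            qs = np.nanmean([a.qs for a in site])
            info = f"QS={qs:.4f}" if np.isfinite(qs) else "."
            gt_col = []
            dosage = np.stack([a.genotypes for a in site])  # (n_alt, n_samp)
            for si in range(len(samples)):
                d = dosage[:, si]
                if np.any(d == MISSING):
                    gt_col.append("./.")
                    continue
                total = int(d.sum())
                if total > 2:
                    raise ValueError(
                        f"total alt dosage {total} > 2 at {contig}:{pos} sample {samples[si]}"
                    )
                calls = []
                for ai, dk in enumerate(d, start=1):
                    calls.extend([ai] * int(dk))
                calls = [0] * (2 - len(calls)) + calls
                gt_col.append(f"{calls[0]}/{calls[1]}")
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gt_col) + "\n"
            )


# ---------------------------------------------------------------------------
# Allele counting


def allele_counts(
    allele: VariantAllele, groups: Mapping[str, np.ndarray]
) -> dict[str, tuple[int, int]]:
    """Per-group (alt_count, ref_count) over non-missing genotypes.

    ``groups`` maps group label to a boolean mask (or index array) over the
    cohort sample order; the masks must partition the sample set.
    ref_count = 2 * (non-missing group size) - alt_count, so missing
    genotypes drop out of both counts.
    """
    _check_partition(groups, len(allele.genotypes))
    out: dict[str, tuple[int, int]] = {}
    for label, mask in groups.items():
        g = allele.genotypes[mask]
        nonmiss = g != MISSING
        alt = int(g[nonmiss].sum())
        out[label] = (alt, 2 * int(nonmiss.sum()) - alt)
    return out


def _check_partition(groups: Mapping[str, np.ndarray], n: int) -> None:
    cover = np.zeros(n, dtype=int)
    for mask in groups.values():
        m = np.asarray(mask)
        if m.dtype == bool:
            cover += m.astype(int)
        else:
            cover[m] += 1
    if not np.all(cover == 1):
        raise ValueError("groups do not partition the sample set")


def allele_frequency(allele: VariantAllele, mask: np.ndarray | None = None) -> float:
    """Alt-allele frequency over non-missing genotypes (optionally masked)."""
    g = allele.genotypes if mask is None else allele.genotypes[mask]
    nonmiss = g != MISSING
    n = int(nonmiss.sum())
    if n == 0:
        raise ValueError("allele frequency undefined: all genotypes missing")
    return float(g[nonmiss].sum()) / (2 * n)


def apply_quality_filter(
    alleles: Sequence[VariantAllele],
    stringency: float,
    calibration_qs: Sequence[float],
) -> list[VariantAllele]:
    """Tiered truth-sensitivity filter on the simulated quality score.

    Retains alleles whose qs is at or above the ``(1 - stringency)``
    quantile of ``calibration_qs`` (the quality scores of a designated
    truth-calibration allele set). ``stringency=0.99`` keeps 99% of the
    calibration set — a lenient tier; lower values are stricter. Tiers are
    nested: the kept set at a lower stringency is a subset of the kept set
    at any higher one. Filtering is per-allele, not per-site.
    """
    if not 0 < stringency <= 1:
        raise ValueError("stringency must be in (0, 1]")
    if len(calibration_qs) == 0:
        raise ValueError("empty calibration set")
    if stringency == 1.0:
        return list(alleles)
    cutoff = float(np.quantile(np.asarray(calibration_qs, dtype=float),
                               1.0 - stringency))
    return [a for a in alleles if a.qs >= cutoff]


# ---------------------------------------------------------------------------
# Sample metadata


def read_meta(path) -> pd.DataFrame:
    """Read the sample-metadata TSV (schema in META_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad = ~df["c20x"].between(0, 1)
    if bad.any():
        raise ValueError("c20x outside [0, 1]")
    df["wga"] = df["wga"].astype(bool)
    return df


def write_meta(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)
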