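"""Synthetic diploid exome cohort with WGA/MDA artifact injection.

The simulator emulates a joint-called exome cohort in which a subgroup of
samples was whole-genome amplified (multiple displacement amplification)
before sequencing. All samples share true variants drawn from a rare-skewed
allele-frequency spectrum; WGA samples additionally carry three artifact
classes, each recorded in a truth ledger:

* slippage indels — single-base-type indels at homopolymer tracts, made
  recurrent across WGA samples by tract-specific error propensities;
* chimeric large insertions — >= 15 bp insertions whose sequence is a
  verbatim forward-strand copy of reference starting within ~2 kb
  (exponentially distributed, capped below 10 kb) of the insertion point;
* coverage dropout — per-gene read depth with much higher variance in WGA
  samples, with all genotypes in a low-depth gene set to missing.

True coding indels are biased toward lengths divisible by 3 (purifying
selection on frameshifts); artifacts carry no frame bias. Replicate
samples of one individual share true genotypes but re-draw artifacts and
missingness independently. One global seed drives named substreams so each
stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, ReferenceSequence, scan_homopolymers
from .variants import MISSING, VariantAllele, normalize

TRUE_VARIANT = "true_variant"
HP_ARTIFACT = "hp_artifact"
CHIMERA_ARTIFACT = "chimera_artifact"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults describe a desk-scale cohort of ~2000 exome samples over 200
    single-exon genes with a WGA fraction, replicate structure, depth model
    (mean 165x; SD 140x amplified vs 40x unamplified) and per-sample
    zero-coverage gene counts patterned on a large amplified pan-cancer
    germline cohort.
    """

    seed: int = 0
    # reference / gene model
    n_genes: int = 200
    gene_length: int = 1500
    intergenic: int = 200
    hp_tract_density: float = 0.012  # tracts per bp, planted over run-capped background
    # cohort composition
    n_dna_samples: int = 1800
    n_wga_samples: int = 200
    n_replicate_pairs: dict = field(
        default_factory=lambda: {"DNA:DNA": 40, "WGA:DNA": 8, "WGA:WGA": 12}
    )
    # true variation
    true_snv_rate: float = 0.0075  # cohort site rate per bp
    true_indel_rate: float = 0.0015
    af_beta: tuple = (0.25, 8.0)  # rare-skewed AF spectrum
    inframe_bias: float = 0.6  # P(true coding indel length % 3 == 0)
    true_large_frac: float = 0.05  # fraction of true indels >= 15 bp
    # WGA artifacts
    hp_error_rate: float = 0.0035  # marginal slippage rate per tract per WGA sample
    hp_recurrence: float = 0.04  # fraction of tracts that are slippage-prone
    chimera_rate: float = 3.0  # expected large artifacts per WGA sample
    chimera_origin_scale: float = 1500.0  # bp; exponential scale of copy distance
    chimera_origin_cap: float = 9500.0
    chimera_deletion_frac: float = 0.1
    # depth / missingness
    depth_mean: float = 165.0
    depth_sd_dna: float = 40.0
    depth_sd_wga: float = 140.0
    missing_threshold: float = 10.0
    # quality-score model (filter stand-in)
    qs_true_mean: float = 8.0
    qs_true_sd: float = 1.0
    qs_artifact_mean: float = 5.5
    qs_artifact_sd: float = 1.5
    # phenotype structure
    groups: tuple = ("G1", "G2", "G3", "G4")
    confounded_group: str = "G1"
    confounded_group_size: int = 250  # individuals
    phenotype_confound: float = 0.6  # WGA fraction within the confounded group

    def validate(self) -> None:
        probs = [
            self.inframe_bias,
            self.hp_error_rate,
            self.true_large_frac,
            self.chimera_deletion_frac,
            self.phenotype_confound,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probability parameters must lie in [0, 1]")
        counts = [self.n_genes, self.n_dna_samples, self.n_wga_samples,
                  *self.n_replicate_pairs.values()]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.depth_sd_dna < 0 or self.depth_sd_wga < 0:
            raise ValueError("depth SDs must be non-negative")


@dataclass
class SimResult:
    """In-memory simulated cohort."""

    ref: ReferenceSequence
    genes: list
    alleles: list
    samples: list
    meta: pd.DataFrame
    ledger: pd.DataFrame

    @property
    def wga_mask(self) -> np.ndarray:
        return self.meta.set_index("sample_id").loc[self.samples, "wga"].to_numpy(bool)


def _streams(seed: int, names: Sequence[str]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Reference simulation


def _random_seq_capped(rng: np.random.Generator, length: int, max_run: int = 3) -> np.ndarray:
    """Uniform A/C/G/T sequence with single-base runs capped at ``max_run``."""
    seq = rng.integers(0, 4, size=length, dtype=np.int8)
    run = 1
    for i in range(1, length):
        if seq[i] == seq[i - 1]:
            run += 1
            if run > max_run:
                seq[i] = (seq[i] + 1 + rng.integers(0, 3)) % 4
                run = 1
        else:
            run = 1
    return seq


def simulate_reference(cfg: SimConfig) -> tuple[ReferenceSequence, list[GeneModel]]:
    """One contig of non-overlapping single-exon genes with planted
    homopolymer tracts at ``hp_tract_density`` per bp.

    The background sequence caps natural runs at 3 bases, so the realized
    tract density is binomial around the requested value. Deterministic
    given the seed.
    """
    cfg.validate()
    rng = _streams(cfg.seed, ["ref"])["ref"]
    length = cfg.intergenic + cfg.n_genes * (cfg.gene_length + cfg.intergenic)
    if cfg.n_genes > 0 and cfg.gene_length < 3:
        raise ValueError("gene_length must be >= 3")
    seq = _random_seq_capped(rng, length)

    # plant tracts on a slot grid so placements never overlap
    slot = 40
    n_slots = length // slot
    p_plant = min(cfg.hp_tract_density * slot, 1.0)
    plant = rng.random(n_slots) < p_plant
    for k in np.flatnonzero(plant):
        tract_len = 4 + int(rng.integers(0, 5))  # 4..8
        start = k * slot + 8  # away from slot edges
        if start + tract_len + 1 >= length or start < 1:
            continue
        base = int(rng.integers(0, 4))
        seq[start : start + tract_len] = base
        # enforce maximality at both flanks
        for edge in (start - 1, start + tract_len):
            if seq[edge] == base:
                seq[edge] = (base + 1 + int(rng.integers(0, 3))) % 4

    ref = ReferenceSequence("chr_sim", seq.astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")).decode())
    genes = []
    pos = cfg.intergenic
    for i in range(cfg.n_genes):
        end = pos + cfg.gene_length
        if end > length:
            raise ValueError("genes exceed contig length")
        genes.append(
            GeneModel(f"GENE{i+1:04d}", ref.name, ((pos, end),), "+")
        )
        pos = end + cfg.intergenic
    return ref, genes


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Simulate the full cohort: VCF-ready alleles, metadata, truth ledger."""
    cfg.validate()
    ref, genes = simulate_reference(cfg)
    streams = _streams(
        cfg.seed, ["ref", "meta", "truth", "hp", "chimera", "depth", "qs"]
    )
    meta, samples, ind_of_sample = _build_samples(cfg, streams["meta"])
    n_samples = len(samples)
    n_ind = int(ind_of_sample.max()) + 1 if n_samples else 0
    wga = meta["wga"].to_numpy(bool)

    alleles: list[VariantAllele] = []
    ledger_rows: list[dict] = []
    seen_keys: set = set()

    def emit(pos, ref_a, alt_a, genotypes, origin, qs, copy_origin=None) -> bool:
        pos, ref_a, alt_a = normalize(ref.name, pos, ref_a, alt_a, ref.seq)
        key = (ref.name, pos, ref_a, alt_a)
        if key in seen_keys:
            return False
        seen_keys.add(key)
        alleles.append(VariantAllele(ref.name, pos, ref_a, alt_a, genotypes, qs=qs))
        ledger_rows.append(
            {
                "contig": ref.name,
                "pos": pos,
                "ref": ref_a,
                "alt": alt_a,
                "origin": origin,
                "copy_origin": -1 if copy_origin is None else int(copy_origin),
            }
        )
        return True

    _inject_true_variants(cfg, ref, genes, streams["truth"], streams["qs"],
                          n_ind, ind_of_sample, emit)
    artifact_rates = cfg.hp_error_rate > 0 or cfg.chimera_rate > 0
    if cfg.n_wga_samples == 0 and artifact_rates:
        warnings.warn("no WGA samples: artifact injection skipped")
    elif cfg.n_wga_samples > 0:
        _inject_hp_artifacts(cfg, ref, streams["hp"], streams["qs"], wga, n_samples, emit)
        _inject_chimeras(cfg, ref, streams["chimera"], streams["qs"], wga, n_samples, emit)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["contig", "pos", "ref", "alt", "origin", "copy_origin"],
    )
    alleles, ledger = _resolve_site_conflicts(alleles, ledger)
    _apply_missingness(cfg, genes, streams["depth"], meta, alleles)
    # drop alleles left with no observable carrier (all-missing or no alt)
    alleles, ledger = _drop_uncalled(alleles, ledger)
    ledger["carriers"] = [
        ";".join(np.array(samples)[np.flatnonzero(a.genotypes > 0)]) for a in alleles
    ]
    alleles.sort(key=lambda a: (a.pos, a.ref, a.alt))
    ledger = ledger.set_index(["pos", "ref", "alt"]).loc[
        [(a.pos, a.ref, a.alt) for a in alleles]
    ].reset_index()
    ledger = ledger[["contig", "pos", "ref", "alt", "origin", "copy_origin", "carriers"]]
    return SimResult(ref=ref, genes=genes, alleles=alleles, samples=samples,
                     meta=meta, ledger=ledger)


def _build_samples(cfg: SimConfig, rng: np.random.Generator):
    """Sample sheet with replicate structure and a WGA-confounded group."""
    pairs = {k: int(v) for k, v in cfg.n_replicate_pairs.items()}
    need_dna = 2 * pairs.get("DNA:DNA", 0) + pairs.get("WGA:DNA", 0)
    need_wga = 2 * pairs.get("WGA:WGA", 0) + pairs.get("WGA:DNA", 0)
    if need_dna > cfg.n_dna_samples or need_wga > cfg.n_wga_samples:
        raise ValueError("replicate pairs exceed available samples")

    rows = []  # (individual_idx, wga_flag)
    ind = 0
    for _ in range(pairs.get("DNA:DNA", 0)):
        rows += [(ind, False), (ind, False)]
        ind += 1
    for _ in range(pairs.get("WGA:DNA", 0)):
        rows += [(ind, True), (ind, False)]
        ind += 1
    for _ in range(pairs.get("WGA:WGA", 0)):
        rows += [(ind, True), (ind, True)]
        ind += 1
    for _ in range(cfg.n_dna_samples - need_dna):
        rows.append((ind, False))
        ind += 1
    for _ in range(cfg.n_wga_samples - need_wga):
        rows.append((ind, True))
        ind += 1
    n_ind = ind

    # individual-level WGA status: any amplified sample
    ind_wga = np.zeros(n_ind, dtype=bool)
    for i, w in rows:
        ind_wga[i] |= w
    # pure-WGA individuals can carry the phenotype confound
    ind_has_dna = np.zeros(n_ind, dtype=bool)
    for i, w in rows:
        ind_has_dna[i] |= not w
    pure_wga = np.flatnonzero(ind_wga & ~ind_has_dna)
    others = np.flatnonzero(~(ind_wga & ~ind_has_dna))

    group_of_ind = np.empty(n_ind, dtype=object)
    gsize = min(cfg.confounded_group_size, n_ind)
    n_conf_wga = min(int(round(cfg.phenotype_confound * gsize)), len(pure_wga))
    conf_members = list(rng.choice(pure_wga, size=n_conf_wga, replace=False))
    pool = np.array([i for i in others] + [i for i in pure_wga if i not in set(conf_members)])
    pool = rng.permutation(pool)
    conf_members += list(pool[: gsize - n_conf_wga])
    rest = [i for i in pool[gsize - n_conf_wga :]]
    group_of_ind[np.array(conf_members, dtype=int)] = cfg.confounded_group
    other_groups = [g for g in cfg.groups if g != cfg.confounded_group]
    for k, i in enumerate(rest):
        group_of_ind[i] = other_groups[k % len(other_groups)] if other_groups else cfg.confounded_group

    n_samples = len(rows)
    ind_of_sample = np.array([i for i, _ in rows], dtype=int)
    wga_flags = np.array([w for _, w in rows], dtype=bool)
    samples = [f"S{k+1:05d}" for k in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "individual_id": [f"I{i+1:05d}" for i in ind_of_sample],
            "group": [group_of_ind[i] for i in ind_of_sample],
            "wga": wga_flags,
            "center": rng.choice(["C1", "C2", "C3"], size=n_samples, p=[0.5, 0.3, 0.2]),
            "bwa_version": rng.choice(["0.7.10", "0.7.12"], size=n_samples, p=[0.4, 0.6]),
            "c20x": np.nan,  # filled from the depth model
            "race": None,
            "age": np.clip(rng.normal(60, 10, size=n_samples), 20, 90).round(1),
            "sex": None,
        }
    )
    # demographics are per individual, shared across replicates
    race_of_ind = rng.choice(
        ["white", "black", "asian", "hispanic"], size=n_ind, p=[0.7, 0.12, 0.1, 0.08]
    )
    sex_of_ind = rng.choice(["female", "male"], size=n_ind)
    age_of_ind = np.clip(rng.normal(60, 10, size=n_ind), 20, 90).round(1)
    meta["race"] = race_of_ind[ind_of_sample]
    meta["sex"] = sex_of_ind[ind_of_sample]
    meta["age"] = age_of_ind[ind_of_sample]
    return meta, samples, ind_of_sample


def _draw_indel_length(cfg: SimConfig, rng: np.random.Generator, coding: bool) -> int:
    if rng.random() < cfg.true_large_frac:
        return int(rng.integers(15, 61))
    if coding and rng.random() < cfg.inframe_bias:
        return int(rng.choice([3, 6, 9, 12]))
    k = int(rng.integers(1, 13))
    if coding:
        while k % 3 == 0:
            k = int(rng.integers(1, 13))
    return k


def _inject_true_variants(cfg, ref, genes, rng, qs_rng, n_ind, ind_of_sample, emit):
    length = len(ref)
    seq = ref.seq
    in_gene = np.zeros(length, dtype=bool)
    for g in genes:
        for s, e in g.exons:
            in_gene[s:e] = True

    def genotypes_for(af: float) -> np.ndarray | None:
        g_ind = rng.binomial(2, af, size=n_ind).astype(np.int16)
        if g_ind.sum() == 0:
            return None
        return g_ind[ind_of_sample]

    n_snv = rng.poisson(cfg.true_snv_rate * length)
    positions = rng.choice(np.arange(1, length - 1), size=n_snv, replace=False)
    afs = rng.beta(*cfg.af_beta, size=n_snv)
    for pos0, af in zip(positions, afs):
        gts = genotypes_for(af)
        if gts is None:
            continue
        ref_b = seq[pos0]
        alt_b = "ACGT".replace(ref_b, "")[rng.integers(0, 3)]
        emit(pos0 + 1, ref_b, alt_b, gts, TRUE_VARIANT,
             qs_rng.normal(cfg.qs_true_mean, cfg.qs_true_sd))

    n_indel = rng.poisson(cfg.true_indel_rate * length)
    for _ in range(n_indel):
        pos0 = int(rng.integers(1, length - 70))
        coding = bool(in_gene[pos0])
        L = _draw_indel_length(cfg, rng, coding)
        af = float(rng.beta(*cfg.af_beta))
        gts = genotypes_for(af)
        if gts is None:
            continue
        anchor = seq[pos0]
        qs = qs_rng.normal(cfg.qs_true_mean, cfg.qs_true_sd)
        if rng.random() < 0.5:  # insertion of novel sequence
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=L))
            emit(pos0 + 1, anchor, anchor + ins, gts, TRUE_VARIANT, qs)
        else:  # deletion
            if pos0 + 1 + L >= length:
                continue
            emit(pos0 + 1, seq[pos0 : pos0 + 1 + L], anchor, gts, TRUE_VARIANT, qs)


def _inject_hp_artifacts(cfg, ref, rng, qs_rng, wga, n_samples, emit):
    """Slippage indels at homopolymer tracts, recurrent across WGA samples.

    A sparse exchangeable propensity scheme: a fraction ``hp_recurrence``
    of tracts is slippage-prone; each prone tract draws a per-WGA-sample
    error probability from a Beta with mean hp_error_rate / hp_recurrence,
    the rest never slip. Concentrating the marginal rate on few tracts
    makes slippage indels recur across amplified samples, so homopolymer+
    artifact alleles reach markedly higher allele frequencies in the WGA
    group than other variant classes. The indel identity (insertion or
    deletion of 1-6 copies of the tract base) is fixed per tract; carriers
    are heterozygous and re-drawn independently per WGA sample.
    """
    if cfg.hp_error_rate <= 0:
        return
    tracts = scan_homopolymers(ref)
    wga_idx = np.flatnonzero(wga)
    seq = ref.seq
    f = min(max(cfg.hp_recurrence, 1e-9), 1.0)
    mean_prone = min(cfg.hp_error_rate / f, 0.9)
    shape_a = 1.2
    shape_b = shape_a * (1.0 / mean_prone - 1.0)
    prone = rng.random(len(tracts)) < f
    prop = np.where(
        prone, rng.beta(shape_a, max(shape_b, 1e-6), size=len(tracts)), 0.0
    )
    carrier_draws = rng.random((len(tracts), len(wga_idx)))
    for ti, tract in enumerate(tracts):
        carriers = wga_idx[carrier_draws[ti] < prop[ti]]
        if len(carriers) == 0 or tract.start == 0:
            continue
        L = int(rng.integers(1, 7))
        is_del = rng.random() < 0.3 and L <= tract.length
        anchor0 = tract.start - 1
        anchor = seq[anchor0]
        gts = np.zeros(n_samples, dtype=np.int16)
        gts[carriers] = 1
        qs = qs_rng.normal(cfg.qs_artifact_mean, cfg.qs_artifact_sd)
        if is_del:
            emit(anchor0 + 1, anchor + tract.base * L, anchor, gts, HP_ARTIFACT, qs)
        else:
            emit(anchor0 + 1, anchor, anchor + tract.base * L, gts, HP_ARTIFACT, qs)


def _inject_chimeras(cfg, ref, rng, qs_rng, wga, n_samples, emit):
    """Large near-cis chimeric indels, independent per WGA sample."""
    if cfg.chimera_rate <= 0:
        return
    seq = ref.seq
    length = len(ref)
    for si in np.flatnonzero(wga):
        for _ in range(rng.poisson(cfg.chimera_rate)):
            L = int(rng.integers(15, 61))
            gts = np.zeros(n_samples, dtype=np.int16)
            gts[si] = 1
            qs = qs_rng.normal(cfg.qs_artifact_mean, cfg.qs_artifact_sd)
            if rng.random() < cfg.chimera_deletion_frac:
                pos0 = int(rng.integers(1, length - L - 2))
                emit(pos0 + 1, seq[pos0 : pos0 + 1 + L], seq[pos0], gts,
                     CHIMERA_ARTIFACT, qs)
                continue
            for _attempt in range(20):
                pos0 = int(rng.integers(1, length - 2))
                d = 1 + int(min(rng.exponential(cfg.chimera_origin_scale),
                                cfg.chimera_origin_cap))
                origin = pos0 + 1 + (d if rng.random() < 0.5 else -d)
                origin = int(np.clip(origin, 0, length - L - 1))
                copy = seq[origin : origin + L]
                # keep the emitted allele left-aligned as constructed
                if copy[-1] != seq[pos0] and copy[0] != seq[pos0 + 1]:
                    break
            else:
                continue
            emit(pos0 + 1, seq[pos0], seq[pos0] + copy, gts, CHIMERA_ARTIFACT,
                 qs, copy_origin=origin)


def _resolve_site_conflicts(alleles, ledger):
    """Cap per-sample total dosage at 2 within each (contig,pos,ref) site.

    Artifact dosages are zeroed before true-variant dosages; alleles left
    with no carriers are dropped together with their ledger rows.
    """
    by_site: dict[tuple, list[int]] = {}
    for idx, a in enumerate(alleles):
        by_site.setdefault((a.contig, a.pos, a.ref), []).append(idx)
    for site, idxs in by_site.items():
        if len(idxs) < 2:
            continue
        dosage = np.stack([np.maximum(alleles[i].genotypes, 0) for i in idxs])
        over = np.flatnonzero(dosage.sum(axis=0) > 2)
        if len(over) == 0:
            continue
        order = sorted(
            range(len(idxs)),
            key=lambda k: ledger.iloc[idxs[k]]["origin"] == TRUE_VARIANT,
        )  # artifacts first
        for si in over:
            excess = int(dosage[:, si].sum()) - 2
            for k in order:
                if excess <= 0:
                    break
                take = min(excess, int(dosage[k, si]))
                if take:
                    alleles[idxs[k]].genotypes[si] -= take
                    excess -= take
    return alleles, ledger


def _drop_uncalled(alleles, ledger):
    keep = [i for i, a in enumerate(alleles) if np.any(a.genotypes > 0)]
    return [alleles[i] for i in keep], ledger.iloc[keep].reset_index(drop=True)


def _apply_missingness(cfg, genes, rng, meta, alleles):
    """Per-gene depth model; genotypes in low-depth genes become missing.

    Also fills the c20x metadata column as the realized fraction of genes
    covered at >= 20x for each sample.
    """
    n_samples = len(meta)
    wga = meta["wga"].to_numpy(bool)
    sd = np.where(wga, cfg.depth_sd_wga, cfg.depth_sd_dna)
    depth = rng.normal(cfg.depth_mean, sd[:, None], size=(n_samples, max(len(genes), 1)))
    depth = np.maximum(depth, 0.0)
    meta["c20x"] = (depth >= 20).mean(axis=1).round(4)
    if not genes:
        return
    low = depth < cfg.missing_threshold  # (samples, genes)
    starts = np.array([g.span[0] for g in genes])
    ends = np.array([g.span[1] for g in genes])
    for a in alleles:
        pos0 = a.pos - 1
        gi = int(np.searchsorted(starts, pos0, side="right")) - 1
        if gi < 0 or pos0 >= ends[gi]:
            continue
        mask = low[:, gi]
        if mask.any():
            a.genotypes[mask] = MISSING


def select_association_samples(meta: pd.DataFrame) -> list[str]:
    """One sample per individual: prefer unamplified, then highest c20x."""
    chosen = []
    for _, grp in meta.groupby("individual_id", sort=False):
        grp = grp.sort_values(["wga", "c20x"], ascending=[True, False])
        chosen.append(grp.iloc[0]["sample_id"])
    order = {s: i for i, s in enumerate(meta["sample_id"])}
    return sorted(chosen, key=order.get)
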