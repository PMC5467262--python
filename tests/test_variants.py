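import numpy as np
import pytest

from wgaqc.genome import write_fasta
from wgaqc.variants import (
    MISSING,
    VariantAllele,
    allele_counts,
    allele_frequency,
    apply_quality_filter,
    normalize,
    read_vcf,
    write_vcf,
)


def _write_minimal_vcf(path, body_lines, samples=("S1", "S2")):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=c,length=1000>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for line in body_lines:
            fh.write(line + "\n")


class TestReadVcf:
    def test_multiallelic_split_dosages(self, tmp_path):
        p = tmp_path / "m.vcf"
        _write_minimal_vcf(p, ["c\t5\t.\tA\tT,G\t.\tPASS\t.\tGT\t1/2\t0/1"])
        alleles, samples = read_vcf(p)
        assert samples == ["S1", "S2"]
        assert len(alleles) == 2
        by_alt = {a.alt: a for a in alleles}
        assert list(by_alt["T"].genotypes) == [1, 1]
        assert list(by_alt["G"].genotypes) == [1, 0]

    def test_deletion_type_and_length(self, tmp_path):
        p = tmp_path / "d.vcf"
        _write_minimal_vcf(p, ["c\t5\t.\tCA\tC\t.\tPASS\t.\tGT\t0/1\t./."])
        alleles, _ = read_vcf(p)
        (a,) = alleles
        assert a.type == "deletion" and a.indel_len == 1
        assert list(a.genotypes) == [1, MISSING]

    def test_haploid_gt_rejected(self, tmp_path):
        p = tmp_path / "h.vcf"
        _write_minimal_vcf(p, ["c\t5\t.\tA\tT\t.\tPASS\t.\tGT\t1\t0/0"])
        with pytest.raises(ValueError, match="non-diploid"):
            read_vcf(p)

    def test_round_trip_preserves_allele_set(self, tmp_path, tiny_sim):
        out = tmp_path / "rt.vcf"
        write_vcf(out, tiny_sim.alleles, tiny_sim.samples,
                  {tiny_sim.ref.name: len(tiny_sim.ref)})
        back, samples = read_vcf(out, {tiny_sim.ref.name: tiny_sim.ref.seq})
        assert samples == tiny_sim.samples
        orig = {a.key: a for a in tiny_sim.alleles}
        assert {a.key for a in back} == set(orig)
        for a in back:
            np.testing.assert_array_equal(a.genotypes, orig[a.key].genotypes)
            assert a.qs == pytest.approx(orig[a.key].qs, abs=5e-4)

    def test_split_conserves_total_dosage(self, tmp_path):
        # re-merging split alleles recovers each sample's total alt dosage
        p = tmp_path / "m2.vcf"
        _write_minimal_vcf(
            p, ["c\t5\t.\tA\tT,G,C\t.\tPASS\t.\tGT\t1/2\t3/3"], samples=("S1", "S2")
        )
        alleles, _ = read_vcf(p)
        total = np.sum([a.genotypes for a in alleles], axis=0)
        assert list(total) == [2, 2]


class TestNormalize:
    def test_left_aligns_deletion_in_repeat(self):
        #      0123456789
        seq = "GCATATATGC"
        # deleting the last AT (pos 7, ref TAT->T) shifts to pos 2 CAT->C
        pos, ref, alt = normalize("c", 6, "TATAT", "TAT", seq)
        assert (pos, ref, alt) == (2, "CAT", "C")

    def test_trims_to_parsimonious_form(self):
        seq = "GATTACA"
        pos, ref, alt = normalize("c", 2, "ATTA", "AGGTA", seq)
        assert (pos, ref, alt) == (3, "T", "GG")

    def test_snv_unchanged(self):
        assert normalize("c", 3, "T", "G", "ACTGA") == (3, "T", "G")

    def test_simulated_alleles_already_normalized(self, tiny_sim):
        seq = tiny_sim.ref.seq
        for a in tiny_sim.alleles:
            assert normalize(a.contig, a.pos, a.ref, a.alt, seq) == (
                a.pos, a.ref, a.alt,
            )


class TestAlleleCounts:
    def test_single_het_among_614(self):
        g = np.zeros(614, dtype=int)
        g[17] = 1
        a = VariantAllele("c", 1, "A", "AT", g)
        counts = allele_counts(a, {"wga": np.ones(614, dtype=bool)})
        assert counts["wga"] == (1, 1227)

    def test_all_missing(self):
        a = VariantAllele("c", 1, "A", "T", np.full(10, MISSING))
        counts = allele_counts(a, {"g": np.ones(10, dtype=bool)})
        assert counts["g"] == (0, 0)

    def test_matches_per_sample_summation(self, rng):
        for _ in range(50):
            g = rng.choice([MISSING, 0, 1, 2], size=40, p=[0.1, 0.6, 0.2, 0.1])
            mask = rng.random(40) < 0.5
            a = VariantAllele("c", 1, "A", "T", g)
            counts = allele_counts(a, {"x": mask, "y": ~mask})
            for label, m in (("x", mask), ("y", ~mask)):
                alt = sum(int(v) for v in g[m] if v != MISSING)
                nm = sum(1 for v in g[m] if v != MISSING)
                assert counts[label] == (alt, 2 * nm - alt)
                assert sum(counts[label]) == 2 * nm

    def test_non_partition_rejected(self):
        a = VariantAllele("c", 1, "A", "T", np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="partition"):
            allele_counts(a, {"x": np.ones(4, dtype=bool), "y": np.ones(4, dtype=bool)})


class TestAlleleFrequency:
    def test_one_het_in_ten(self):
        g = np.zeros(10, dtype=int)
        g[0] = 1
        assert allele_frequency(VariantAllele("c", 1, "A", "T", g)) == 0.05

    def test_hom_alt_everywhere(self):
        assert allele_frequency(VariantAllele("c", 1, "A", "T", np.full(5, 2))) == 1.0

    def test_all_missing_undefined(self):
        with pytest.raises(ValueError):
            allele_frequency(VariantAllele("c", 1, "A", "T", np.full(3, MISSING)))

    def test_missing_excluded_from_denominator(self, rng):
        g = rng.choice([MISSING, 0, 1, 2], size=30)
        if np.all(g == MISSING):
            g[0] = 1
        a = VariantAllele("c", 1, "A", "T", g)
        nm = g[g != MISSING]
        assert allele_frequency(a) == pytest.approx(nm.sum() / (2 * len(nm)))


class TestQualityFilter:
    def _alleles(self, qs_values):
        return [
            VariantAllele("c", i + 1, "A", "T", np.array([1]), qs=q)
            for i, q in enumerate(qs_values)
        ]

    def test_stringency_one_keeps_all(self, rng):
        alleles = self._alleles(rng.normal(0, 1, size=50))
        assert apply_quality_filter(alleles, 1.0, [0.0]) == alleles

    def test_tiers_are_nested(self, rng):
        alleles = self._alleles(rng.normal(5, 2, size=200))
        calib = list(rng.normal(6, 1, size=500))
        kept = {
            s: {a.key for a in apply_quality_filter(alleles, s, calib)}
            for s in (0.99, 0.95, 0.90, 0.5)
        }
        assert kept[0.5] <= kept[0.90] <= kept[0.95] <= kept[0.99]

    def test_artifact_removal_monotone_in_stringency(self, tiny_sim):
        truth_qs = [
            a.qs
            for a, o in zip(tiny_sim.alleles, tiny_sim.ledger["origin"])
            if o == "true_variant"
        ]
        artifact_keys = {
            (r.contig, r.pos, r.ref, r.alt)
            for r in tiny_sim.ledger.itertuples()
            if r.origin != "true_variant"
        }
        removed = []
        for s in (0.99, 0.95, 0.90, 0.8):
            kept = {
                a.key for a in apply_quality_filter(tiny_sim.alleles, s, truth_qs)
            }
            removed.append(len(artifact_keys - kept) / len(artifact_keys))
        assert removed == sorted(removed)
        assert removed[-1] > removed[0]

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            apply_quality_filter([], 0.9, [])
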