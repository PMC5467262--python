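import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from wgaqc.genome import scan_homopolymers, write_fasta
from wgaqc.pipeline import annotate_consequences
from wgaqc.simulate import (
    SimConfig,
    select_association_samples,
    simulate_cohort,
    simulate_reference,
)
from wgaqc.variants import MISSING

from conftest import tiny_config


class TestSimulateReference:
    def test_same_seed_same_fasta(self, tmp_path):
        cfg = tiny_config(seed=5)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        for p in (p1, p2):
            ref, _ = simulate_reference(cfg)
            write_fasta(p, [ref])
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_genes(self):
        ref, genes = simulate_reference(tiny_config(n_genes=0))
        assert genes == [] and len(ref) > 0

    def test_genes_non_overlapping_and_in_bounds(self):
        ref, genes = simulate_reference(tiny_config())
        prev_end = 0
        for g in genes:
            s, e = g.span
            assert prev_end <= s < e <= len(ref)
            prev_end = e

    @pytest.mark.parametrize("density", [0.005, 0.012, 0.02])
    def test_tract_density_tracks_request(self, density):
        cfg = tiny_config(seed=11, n_genes=60, gene_length=1500,
                          hp_tract_density=density)
        ref, _ = simulate_reference(cfg)
        observed = len(scan_homopolymers(ref))
        # planted on a slot grid: Binomial(n_slots, density * slot)
        slot = 40
        n_slots = len(ref) // slot
        p = density * slot
        sd = np.sqrt(n_slots * p * (1 - p))
        assert abs(observed - n_slots * p) <= 3 * sd


class TestSimulateCohort:
    def test_same_seed_identical_output(self):
        cfg = tiny_config(seed=13)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert [x.key for x in a.alleles] == [x.key for x in b.alleles]
        for x, y in zip(a.alleles, b.alleles):
            np.testing.assert_array_equal(x.genotypes, y.genotypes)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_ledger_complete_and_exclusive(self, tiny_sim):
        vcf_keys = [(a.contig, a.pos, a.ref, a.alt) for a in tiny_sim.alleles]
        led_keys = list(
            zip(tiny_sim.ledger.contig, tiny_sim.ledger.pos,
                tiny_sim.ledger.ref, tiny_sim.ledger.alt)
        )
        assert sorted(vcf_keys) == sorted(set(led_keys))
        assert len(led_keys) == len(set(led_keys))

    def test_artifacts_confined_to_wga_samples(self, tiny_sim):
        wga = tiny_sim.wga_mask
        for a, origin in zip(tiny_sim.alleles, tiny_sim.ledger["origin"]):
            if origin == "true_variant":
                continue
            assert not np.any(a.genotypes[~wga] > 0)

    def test_no_injection_null_burdens_match(self):
        """Without artifact injection, WGA and DNA indel burdens are
        exchangeable."""
        cfg = tiny_config(seed=21, hp_error_rate=0.0, chimera_rate=0.0,
                          n_dna_samples=120, n_wga_samples=120,
                          depth_sd_wga=40.0)
        sim = simulate_cohort(cfg)
        wga = sim.wga_mask
        indels = [a for a in sim.alleles if a.is_indel]
        burden = np.sum(
            [np.maximum(a.genotypes, 0) for a in indels], axis=0
        )
        p = mannwhitneyu(burden[wga], burden[~wga]).pvalue
        assert p > 0.01

    def test_wga_lof_indel_burden_exceeds_dna(self, tiny_sim):
        cons = annotate_consequences(tiny_sim.alleles, tiny_sim.genes, tiny_sim.ref)
        from wgaqc.burden import build_burden

        table = build_burden(tiny_sim.alleles, tiny_sim.samples, cons)
        wga = tiny_sim.wga_mask
        vals = table.per_sample["lof_indel"]
        assert vals[wga].median() > vals[~wga].median()

    def test_chimera_origins_near_cis(self, tiny_sim):
        led = tiny_sim.ledger
        chim = led[(led.origin == "chimera_artifact") & (led.copy_origin >= 0)]
        dist = np.abs(chim.copy_origin - chim.pos)
        assert (dist <= 10_000).all()
        assert (dist <= 2_000).mean() >= 0.5

    def test_no_wga_samples_warns_and_skips_artifacts(self):
        cfg = tiny_config(seed=23, n_wga_samples=0, n_replicate_pairs={})
        with pytest.warns(UserWarning, match="artifact injection skipped"):
            sim = simulate_cohort(cfg)
        assert (sim.ledger["origin"] == "true_variant").all()

    def test_replicate_pairs_exceeding_samples_rejected(self):
        with pytest.raises(ValueError, match="replicate pairs"):
            simulate_cohort(tiny_config(n_wga_samples=1))

    def test_missingness_follows_depth_model(self, tiny_sim):
        """Amplified samples lose whole genes; unamplified barely any."""
        wga = tiny_sim.wga_mask
        miss = np.stack([a.genotypes == MISSING for a in tiny_sim.alleles])
        frac_wga = miss[:, wga].mean()
        frac_dna = miss[:, ~wga].mean()
        assert frac_wga > 5 * max(frac_dna, 1e-9)
        # and c20x reflects it
        m = tiny_sim.meta
        assert m.loc[m.wga, "c20x"].mean() < m.loc[~m.wga, "c20x"].mean()

    def test_confounded_group_is_wga_heavy(self, tiny_sim):
        m = tiny_sim.meta
        frac = m.groupby("group")["wga"].mean()
        assert frac["G1"] == frac.max()
        assert frac["G1"] > 0.4

    def test_association_sample_selection_prefers_dna(self, tiny_sim):
        chosen = set(select_association_samples(tiny_sim.meta))
        m = tiny_sim.meta.set_index("sample_id")
        for ind, grp in tiny_sim.meta.groupby("individual_id"):
            picked = [s for s in grp["sample_id"] if s in chosen]
            assert len(picked) == 1
            if (~grp["wga"]).any():
                assert not m.loc[picked[0], "wga"]

    def test_mod3_fractions_by_origin(self):
        """Frame bias in true coding indels; none in artifacts."""
        cfg = tiny_config(seed=31, n_genes=60, gene_length=1500,
                          n_dna_samples=300, n_wga_samples=80,
                          n_replicate_pairs={}, confounded_group_size=60,
                          true_indel_rate=0.004)
        sim = simulate_cohort(cfg)
        in_gene = np.zeros(len(sim.ref), dtype=bool)
        for g in sim.genes:
            s, e = g.span
            in_gene[s:e] = True
        true_coding, artifact = [], []
        for a, origin in zip(sim.alleles, sim.ledger["origin"]):
            if not a.is_indel:
                continue
            if origin == "true_variant" and in_gene[a.pos]:
                true_coding.append(a.indel_len % 3 == 0)
            elif origin != "true_variant":
                artifact.append(a.indel_len % 3 == 0)
        assert np.mean(artifact) == pytest.approx(1 / 3, abs=0.1)
        assert np.mean(true_coding) == pytest.approx(cfg.inframe_bias, abs=0.1)
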