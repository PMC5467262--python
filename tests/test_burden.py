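import numpy as np
import pandas as pd
import pytest

from wgaqc.burden import (
    anova_decomposition,
    bootstrap_ci,
    build_burden,
)
from wgaqc.genome import GeneModel
from wgaqc.pipeline import annotate_consequences
from wgaqc.variants import MISSING, VariantAllele


def _meta(n, rng=None, **cols):
    rng = rng or np.random.default_rng(1)
    base = {
        "sample_id": [f"S{i}" for i in range(n)],
        "individual_id": [f"I{i}" for i in range(n)],
        "group": "G1",
        "wga": rng.random(n) < 0.3,
        "center": rng.choice(["C1", "C2"], size=n),
        "bwa_version": rng.choice(["a", "b"], size=n),
        "c20x": rng.uniform(0.7, 1.0, size=n),
        "race": rng.choice(["white", "black"], size=n),
        "age": rng.normal(60, 8, size=n),
        "sex": rng.choice(["female", "male"], size=n),
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestBuildBurden:
    def _setup(self):
        genes = [
            GeneModel("X", "c", ((0, 30),)),
            GeneModel("Y", "c", ((40, 70),)),
        ]
        samples = [f"S{i}" for i in range(25)]
        # S0: het frameshift in X and hom frameshift in Y; rare in the cohort
        g1 = np.zeros(25, dtype=int)
        g1[0] = 1
        g2 = np.zeros(25, dtype=int)
        g2[0] = 2
        a1 = VariantAllele("c", 5, "A", "AT", g1)
        a2 = VariantAllele("c", 45, "A", "ATTTT", g2)
        cons = {a1.key: "frameshift", a2.key: "frameshift"}
        return genes, samples, [a1, a2], cons

    def test_dosage_counting_per_gene(self):
        genes, samples, alleles, cons = self._setup()
        table = build_burden(alleles, samples, cons, genes=genes, per_gene=True)
        assert table.per_gene.loc["S0"].to_dict() == {"X": 1, "Y": 2}
        assert table.per_sample.loc["S0", "lof_indel"] == 3

    def test_af_zero_empties_table(self):
        genes, samples, alleles, cons = self._setup()
        table = build_burden(alleles, samples, cons, genes=genes, af_max=0.0)
        assert (table.per_sample[["lof_snv", "lof_indel"]] == 0).all().all()

    def test_af_filter_is_strict(self):
        # cohort AF exactly at af_max is excluded
        samples = [f"S{i}" for i in range(10)]
        g = np.zeros(10, dtype=int)
        g[0] = 1  # AF = 0.05
        a = VariantAllele("c", 5, "A", "AT", g)
        table = build_burden([a], samples, {a.key: "frameshift"}, af_max=0.05)
        assert table.per_sample["lof_indel"].sum() == 0
        table = build_burden([a], samples, {a.key: "frameshift"}, af_max=0.051)
        assert table.per_sample.loc["S0", "lof_indel"] == 1

    def test_matches_brute_force_recount(self, tiny_sim):
        cons = annotate_consequences(tiny_sim.alleles, tiny_sim.genes, tiny_sim.ref)
        table = build_burden(
            tiny_sim.alleles, tiny_sim.samples, cons, genes=tiny_sim.genes
        )
        # independent recount: loop samples x alleles
        af_ok = {}
        for a in tiny_sim.alleles:
            g = a.genotypes[a.genotypes != MISSING]
            af_ok[a.key] = len(g) > 0 and g.sum() / (2 * len(g)) < 0.05
        for si in [0, 7, len(tiny_sim.samples) - 1]:
            exp_snv = exp_indel = 0
            for a in tiny_sim.alleles:
                if cons[a.key] not in ("frameshift", "stop_gained") or not af_ok[a.key]:
                    continue
                d = a.genotypes[si]
                if d == MISSING:
                    continue
                if a.is_indel:
                    exp_indel += d
                else:
                    exp_snv += d
            row = table.per_sample.iloc[si]
            assert (row["lof_snv"], row["lof_indel"]) == (exp_snv, exp_indel)

    def test_category_counts_sum_to_indel_total(self, tiny_sim):
        from wgaqc.context import classify_all

        cons = annotate_consequences(tiny_sim.alleles, tiny_sim.genes, tiny_sim.ref)
        contexts = classify_all(tiny_sim.alleles, tiny_sim.ref)
        table = build_burden(
            tiny_sim.alleles, tiny_sim.samples, cons, genes=tiny_sim.genes,
            contexts=contexts,
        )
        cats = table.per_sample[
            ["lof_indel_homopolymer_plus", "lof_indel_large", "lof_indel_other"]
        ].sum(axis=1)
        assert (cats == table.per_sample["lof_indel"]).all()


class TestAnovaDecomposition:
    def test_pure_binary_factor_explains_everything(self):
        meta = _meta(80)
        y = pd.Series(
            meta["wga"].astype(int).to_numpy(), index=meta["sample_id"], dtype=float
        )
        dec = anova_decomposition(y, meta)
        assert dec.pct_var("wga") == pytest.approx(1.0, abs=1e-10)
        assert dec.top_factor == "wga"

    def test_shares_sum_to_one(self, tiny_sim):
        from wgaqc.burden import build_burden as bb

        cons = annotate_consequences(tiny_sim.alleles, tiny_sim.genes, tiny_sim.ref)
        table = bb(tiny_sim.alleles, tiny_sim.samples, cons)
        y = table.per_sample["lof_indel"].astype(float)
        dec = anova_decomposition(y, tiny_sim.meta)
        assert dec.table["pct_var_explained"].sum() == pytest.approx(1.0)
        assert (dec.table["pct_var_explained"] >= 0).all()

    def test_type_ii_equals_sequential_in_balanced_design(self):
        # balanced orthogonal 2x2 design: Type II == sequential sums of squares
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(4)
        f1 = np.repeat(["a", "b"], 40)
        f2 = np.tile(np.repeat(["x", "y"], 20), 2)
        y = (f1 == "b") * 2.0 + (f2 == "y") * 1.0 + rng.normal(0, 1, 80)
        meta = _meta(80, center=f1, bwa_version=f2)
        dec = anova_decomposition(
            pd.Series(y, index=meta["sample_id"]), meta,
            factors=("center", "bwa_version"),
        )
        df = pd.DataFrame({"y": y, "f1": f1, "f2": f2})
        seq = sm.stats.anova_lm(smf.ols("y ~ C(f1) + C(f2)", df).fit(), typ=1)
        assert dec.table.loc["center", "sum_sq"] == pytest.approx(
            seq.loc["C(f1)", "sum_sq"]
        )
        assert dec.table.loc["bwa_version", "sum_sq"] == pytest.approx(
            seq.loc["C(f2)", "sum_sq"]
        )

    def test_aliased_factors_named(self):
        meta = _meta(40)
        meta["bwa_version"] = meta["center"]  # perfectly confounded
        y = pd.Series(np.arange(40, dtype=float), index=meta["sample_id"])
        with pytest.raises(ValueError, match="center.*bwa_version"):
            anova_decomposition(y, meta, factors=("center", "bwa_version", "wga"))

    def test_more_df_than_samples_rejected(self):
        meta = _meta(4)
        y = pd.Series(np.ones(4), index=meta["sample_id"])
        with pytest.raises(ValueError):
            anova_decomposition(y, meta)


class TestBootstrapCI:
    def test_constant_vector(self):
        lo, hi = bootstrap_ci([5.0] * 20, seed=0)
        assert lo == hi == 5.0

    def test_contains_observed_mean_for_symmetric_data(self, rng):
        x = rng.normal(10, 2, size=300)
        lo, hi = bootstrap_ci(x, seed=1)
        assert lo <= x.mean() <= hi

    def test_deterministic_given_seed(self, rng):
        x = rng.exponential(1, size=50)
        assert bootstrap_ci(x, seed=42) == bootstrap_ci(x, seed=42)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])

    def test_coverage_near_nominal(self):
        """Basic bootstrap 95% CI covers the true mean ~95% of the time."""
        rng = np.random.default_rng(2024)
        n_outer, covered = 300, 0
        for rep in range(n_outer):
            x = rng.normal(0, 1, size=200)
            lo, hi = bootstrap_ci(x, reps=500, seed=rep)
            covered += lo <= 0 <= hi
        assert covered / n_outer == pytest.approx(0.95, abs=0.03)
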