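"""Per-sample LOF burden and variance decomposition over technical factors.

The burden of a sample is its summed alt-allele dosage over rare
(cohort AF < 0.05) loss-of-function sites, totalled and broken out by
variant class and indel-context category, optionally per gene. A Type II
ANOVA then attributes burden variance to technical covariates (WGA status,
sequencing center, aligner version, capture efficiency) alongside ancestry,
reporting each factor's share of the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .genome import GeneModel, is_lof
from .variants import MISSING, VariantAllele, allele_frequency

DEFAULT_FACTORS = ("c20x", "wga", "center", "bwa_version", "race")
CATEGORICAL_FACTORS = frozenset({"wga", "center", "bwa_version", "race", "sex", "group"})


@dataclass
class BurdenTable:
    """Per-sample LOF burden counts plus the optional per-gene matrix."""

    per_sample: pd.DataFrame  # index sample_id; lof_snv, lof_indel, lof_indel_<cat>
    per_gene: pd.DataFrame | None = None  # samples x genes LOF counts


def build_burden(
    alleles: Sequence[VariantAllele],
    samples: Sequence[str],
    consequences: Mapping[tuple, str],
    genes: Sequence[GeneModel] | None = None,
    contexts: Mapping[tuple, "IndelContext"] | None = None,
    af_max: float = 0.05,
    per_gene: bool = False,
) -> BurdenTable:
    """Count rare LOF alleles per sample.

    ``consequences`` maps allele key to its coding consequence; only LOF
    sites (stop_gained, frameshift) with cohort AF strictly below ``af_max``
    contribute. Missing genotypes contribute zero dosage. Per-category
    columns sum to the indel total.
    """
    from .context import CATEGORIES

    n = len(samples)
    lof_snv = np.zeros(n, dtype=int)
    lof_indel = np.zeros(n, dtype=int)
    by_cat = {cat: np.zeros(n, dtype=int) for cat in CATEGORIES}
    gene_lookup = _GeneLookup(genes) if genes is not None else None
    gene_counts: dict[str, np.ndarray] = {}

    for a in alleles:
        cons = consequences.get(a.key)
        if cons is None or not is_lof(cons):
            continue
        if np.all(a.genotypes == MISSING):
            continue
        if allele_frequency(a) >= af_max:
            continue
        dosage = np.where(a.genotypes == MISSING, 0, a.genotypes)
        if a.is_indel:
            lof_indel += dosage
            if contexts is not None and a.key in contexts:
                by_cat[contexts[a.key].category] += dosage
        else:
            lof_snv += dosage
        if per_gene and gene_lookup is not None:
            gid = gene_lookup.gene_at(a.contig, a.pos - 1)
            if gid is not None:
                gene_counts.setdefault(gid, np.zeros(n, dtype=int))
                gene_counts[gid] += dosage

    per_sample = pd.DataFrame(
        {
            "lof_snv": lof_snv,
            "lof_indel": lof_indel,
            **{f"lof_indel_{c.lower()}": by_cat[c] for c in CATEGORIES},
        },
        index=pd.Index(samples, name="sample_id"),
    )
    per_gene_df = None
    if per_gene:
        per_gene_df = pd.DataFrame(
            gene_counts, index=pd.Index(samples, name="sample_id")
        ).astype(int)
    return BurdenTable(per_sample=per_sample, per_gene=per_gene_df)


class _GeneLookup:
    """Position -> gene_id lookup over sorted non-overlapping gene spans."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_contig: dict[str, list] = {}
        for g in genes:
            per_contig.setdefault(g.contig, []).append(g)
        for contig, gs in per_contig.items():
            gs = sorted(gs, key=lambda g: g.span[0])
            starts = np.array([g.span[0] for g in gs])
            ends = np.array([g.span[1] for g in gs])
            self._by_contig[contig] = (starts, ends, [g.gene_id for g in gs])

    def gene_at(self, contig: str, pos0: int) -> str | None:
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return ids[i]
        return None


# ---------------------------------------------------------------------------
# Type II ANOVA variance decomposition


@dataclass
class AnovaDecomposition:
    """Type II ANOVA table with percent variance explained per factor.

    ``table`` has one row per factor plus 'Residual'; percent variance is
    each row's sum of squares divided by the decomposition total (factor
    sums of squares plus residual), so the shares sum to 1.
    """

    table: pd.DataFrame

    def pct_var(self, factor: str) -> float:
        return float(self.table.loc[factor, "pct_var_explained"])

    @property
    def top_factor(self) -> str:
        factors = self.table.drop(index="Residual")
        return str(factors["pct_var_explained"].idxmax())


def anova_decomposition(
    response: pd.Series,
    meta: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
) -> AnovaDecomposition:
    """Type II ANOVA of a burden response on technical factors.

    Each factor's sum of squares compares the full main-effects model
    against the model omitting that factor (no interactions). Categorical
    factors are dummy-coded with a first-level reference; c20x (and any
    non-categorical column) enters as a continuous covariate. A perfectly
    aliased factor pair raises, naming the pair.
    """
    if float(np.var(np.asarray(response, dtype=float))) == 0.0:
        raise ValueError("response has zero variance; decomposition undefined")
    df = meta.set_index("sample_id").loc[response.index, list(factors)].copy()
    for f in factors:
        if f in CATEGORICAL_FACTORS or df[f].dtype == object or df[f].dtype == bool:
            df[f] = df[f].astype(str)
    if int(len(df)) <= _model_df(df, factors):
        raise ValueError("more model degrees of freedom than samples")
    _check_aliasing(df, factors)
    df = df.assign(_y=np.asarray(response, dtype=float))
    terms = " + ".join(
        f"C({f})" if df[f].dtype == object else f for f in factors
    )
    fit = smf.ols(f"_y ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(
        index={f"C({f})": f for f in factors},
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"},
    )
    total = table["sum_sq"].sum()
    table["pct_var_explained"] = table["sum_sq"] / total
    return AnovaDecomposition(table=table)


def _model_df(df: pd.DataFrame, factors: Sequence[str]) -> int:
    k = 1
    for f in factors:
        k += df[f].nunique() - 1 if df[f].dtype == object else 1
    return k


def _check_aliasing(df: pd.DataFrame, factors: Sequence[str]) -> None:
    mats = {}
    for f in factors:
        if df[f].dtype == object:
            d = pd.get_dummies(df[f], drop_first=True).to_numpy(dtype=float)
        else:
            d = df[[f]].to_numpy(dtype=float)
        mats[f] = d - d.mean(axis=0)

    def rank(m: np.ndarray) -> int:
        return int(np.linalg.matrix_rank(m)) if m.size else 0

    full = np.hstack(list(mats.values()))
    if rank(full) == sum(rank(m) for m in mats.values()):
        return
    for i, fi in enumerate(factors):
        for fj in factors[i + 1 :]:
            pair = np.hstack([mats[fi], mats[fj]])
            if rank(pair) < rank(mats[fi]) + rank(mats[fj]):
                raise ValueError(
                    f"factors {fi!r} and {fj!r} are collinear (aliased); "
                    "drop one before decomposition"
                )
    raise ValueError("design matrix is rank deficient across >2 factors")


def bootstrap_ci(
    values: Sequence[float],
    reps: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Basic bootstrap CI for the mean.

    (2m - q_hi, 2m - q_lo) where m is the observed mean and q_lo/q_hi are
    the (1-level)/2 and (1+level)/2 quantiles of the bootstrap means.
    Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("bootstrap_ci requires at least two values")
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(reps, len(x)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    q_lo, q_hi = np.quantile(means, [alpha, 1.0 - alpha])
    m = x.mean()
    return float(2 * m - q_hi), float(2 * m - q_lo)
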