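"""SNP-panel diversity statistics under partial selfing.

Selfing restructures diversity in two visible ways: genotypes lose
heterozygotes (excess homozygosity F, at equilibrium F = S/(2-S) for
selfing rate S) and unphased genotypes develop strong inter-locus
associations.  Both are summarised here from plain diploid genotype
codes (0/1/2 copies of the reference allele, NaN missing):

* ``1 - Ho`` — one minus the mean observed heterozygote proportion
  across SNPs;
* mean composite linkage disequilibrium r^2 — Burrows' composite
  disequilibrium, which needs no Hardy-Weinberg assumption (crucial
  under selfing) and no phasing: for loci A, B on pairwise-complete
  individuals,

      Delta = mean(X*Y)/2 - 2*pA*pB
      r = Delta / sqrt[(pA(1-pA) + D_A)(pB(1-pB) + D_B)]

  with D_L = (observed reference-homozygote frequency) - pL^2 the
  within-locus disequilibrium.

Loci with minor allele frequency < 0.05 are removed before either
statistic by default; populations left with fewer than two usable loci
get no r^2 (this is a real outcome for highly selfed, low-diversity
samples, not an error).  The ANCOVA of fitness responses on a diversity
covariate uses sequential (Type I) sums of squares with the covariate
entered before the reproduction-system factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SNPGenotypeMatrix",
    "DiversitySummary",
    "homozygosity",
    "maf_filter",
    "minor_allele_frequencies",
    "composite_ld_r2_pairs",
    "composite_ld_mean_r2",
    "staged_missingness_clean",
    "diversity_fitness_ancova",
    "equilibrium_inbreeding",
]


@dataclass
class SNPGenotypeMatrix:
    """Individuals x loci diploid genotype codes with missing values.

    ``genotypes`` is a float array with values in {0, 1, 2, NaN}
    (count of the reference allele); ``populations`` labels rows,
    ``loci`` names columns (chromosome:position labels).
    """

    genotypes: np.ndarray
    populations: np.ndarray
    loci: list[str]
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.populations = np.asarray(self.populations)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n, L = self.genotypes.shape
        if self.populations.shape != (n,):
            raise ValueError("populations must label every individual")
        if len(self.loci) != L:
            raise ValueError("loci must name every column")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        valid = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype code {self.genotypes[tuple(bad)]} at row {bad[0]}, "
                f"locus {self.loci[bad[1]]} not in {{0, 1, 2, NA}}"
            )
        if np.isnan(self.genotypes).all(axis=0).any():
            raise ValueError("all-missing locus column")

    def restrict(self, population: str) -> "SNPGenotypeMatrix":
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"no individuals from population {population!r}")
        return SNPGenotypeMatrix(
            genotypes=self.genotypes[mask],
            populations=self.populations[mask],
            loci=list(self.loci),
            individual_ids=[i for i, keep in zip(self.individual_ids, mask) if keep],
        )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class DiversitySummary:
    population: str
    one_minus_ho: float
    mean_r2: float | None
    n_loci_used: int


def homozygosity(genotypes: np.ndarray | SNPGenotypeMatrix) -> float:
    """1 - Ho: one minus the mean heterozygote proportion across SNPs.

    Per locus, the heterozygote proportion is computed among non-missing
    calls; loci with no calls are skipped.
    """
    g = genotypes.genotypes if isinstance(genotypes, SNPGenotypeMatrix) else np.asarray(genotypes, float)
    called = ~np.isnan(g)
    n_called = called.sum(axis=0)
    usable = n_called > 0
    if not usable.any():
        raise ValueError("no locus has any non-missing genotype")
    het = np.nansum(g == 1.0, axis=0)[usable] / n_called[usable]
    return float(1.0 - het.mean())


def minor_allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes, float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def maf_filter(
    genotypes: np.ndarray | SNPGenotypeMatrix, threshold: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Drop loci with minor allele frequency strictly below ``threshold``.

    Returns the filtered genotype array and the dropped column indices.
    """
    g = genotypes.genotypes if isinstance(genotypes, SNPGenotypeMatrix) else np.asarray(genotypes, float)
    maf = minor_allele_frequencies(g)
    drop = np.where(np.isnan(maf) | (maf < threshold))[0]
    keep = np.setdiff1d(np.arange(g.shape[1]), drop)
    return g[:, keep], drop.tolist()


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Composite r^2 for one locus pair on pairwise-complete individuals;
    None when a variance or the normaliser vanishes."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return None
    x, y = x[ok], y[ok]
    pa = x.mean() / 2.0
    pb = y.mean() / 2.0
    delta = (x * y).mean() / 2.0 - 2.0 * pa * pb
    da = (x == 2.0).mean() - pa * pa
    db = (y == 2.0).mean() - pb * pb
    na = pa * (1 - pa) + da
    nb = pb * (1 - pb) + db
    if na <= 0 or nb <= 0:
        return None
    r = delta / np.sqrt(na * nb)
    return float(np.clip(r * r, 0.0, 1.0))


def composite_ld_r2_pairs(
    genotypes: np.ndarray | SNPGenotypeMatrix, maf_threshold: float = 0.05
) -> tuple[list[tuple[int, int, float]], int]:
    """All pairwise composite r^2 values after MAF filtering.

    Returns ``(pairs, n_skipped)`` where each element of ``pairs`` is
    (column i, column j, r^2) in the filtered matrix and ``n_skipped``
    counts degenerate pairs.
    """
    g, _ = maf_filter(genotypes, maf_threshold)
    pairs: list[tuple[int, int, float]] = []
    skipped = 0
    for i, j in combinations(range(g.shape[1]), 2):
        r2 = _pair_r2(g[:, i], g[:, j])
        if r2 is None:
            skipped += 1
        else:
            pairs.append((i, j, r2))
    return pairs, skipped


def composite_ld_mean_r2(
    genotypes: np.ndarray | SNPGenotypeMatrix, maf_threshold: float = 0.05
) -> float | None:
    """Mean pairwise composite r^2; None when < 2 loci survive the MAF
    filter or no pair is computable."""
    g, _ = maf_filter(genotypes, maf_threshold)
    if g.shape[1] < 2:
        return None
    pairs, _ = composite_ld_r2_pairs(g, maf_threshold=0.0)
    if not pairs:
        return None
    return float(np.mean([r2 for _, _, r2 in pairs]))


def staged_missingness_clean(
    matrix: SNPGenotypeMatrix,
    locus_stage1: float = 0.80,
    individual_stage: float = 0.60,
    locus_stage2: float = 0.50,
) -> SNPGenotypeMatrix:
    """Load-time cleaning: drop loci with > 80% missing calls, then
    individuals with > 60% missing, then loci with > 50% missing."""
    g = matrix.genotypes
    keep_loci = np.isnan(g).mean(axis=0) <= locus_stage1
    g = g[:, keep_loci]
    loci = [l for l, k in zip(matrix.loci, keep_loci) if k]
    keep_ind = np.isnan(g).mean(axis=1) <= individual_stage
    g = g[keep_ind]
    keep_loci2 = np.isnan(g).mean(axis=0) <= locus_stage2
    return SNPGenotypeMatrix(
        genotypes=g[:, keep_loci2],
        populations=matrix.populations[keep_ind],
        loci=[l for l, k in zip(loci, keep_loci2) if k],
        individual_ids=[
            i for i, k in zip(matrix.individual_ids, keep_ind) if k
        ],
    )


def equilibrium_inbreeding(selfing_rate: float) -> float:
    """Wright's equilibrium inbreeding coefficient F = S/(2 - S)."""
    if not 0.0 <= selfing_rate <= 1.0:
        raise ValueError("selfing rate must lie in [0, 1]")
    return selfing_rate / (2.0 - selfing_rate)


def diversity_fitness_ancova(rows: pd.DataFrame) -> pd.DataFrame:
    """ANCOVA of fitness responses on a diversity covariate.

    ``rows`` needs columns ``delta_w_t``, ``covariate`` and ``system``
    (the reproduction system, a 3-level factor).  Sequential (Type I)
    sums of squares with the covariate entered first, then the factor;
    F statistics against the residual mean square.  Returns the
    statsmodels ANOVA table (SS, df, F, P per term).
    """
    rows = rows.dropna(subset=["delta_w_t", "covariate", "system"])
    if rows["system"].nunique() < 2:
        raise ValueError("need >= 2 reproduction systems")
    if rows["covariate"].nunique() < 2:
        raise ValueError("covariate is constant; its term is undefined")
    y = rows["delta_w_t"].to_numpy(float)
    n = len(y)
    systems = sorted(rows["system"].unique())
    intercept = np.ones((n, 1))
    x_cov = np.column_stack([intercept, rows["covariate"].to_numpy(float)])
    dummies = np.column_stack(
        [(rows["system"] == s).to_numpy(float) for s in systems[1:]]
    )
    x_full = np.column_stack([x_cov, dummies])
    # nested OLS fits give the sequential (Type I) decomposition in the
    # printed order: covariate first, then the reproduction-system factor
    rss = [float(sm.OLS(y, x).fit().ssr) for x in (intercept, x_cov, x_full)]
    df_sys = len(systems) - 1
    df_err = n - 2 - df_sys
    if df_err <= 0:
        raise ValueError("not enough observations for the residual term")
    ss = {
        "covariate": rss[0] - rss[1],
        "C(system)": rss[1] - rss[2],
        "Residual": rss[2],
    }
    dfs = {"covariate": 1, "C(system)": df_sys, "Residual": df_err}
    ms_err = ss["Residual"] / df_err
    table = pd.DataFrame(index=list(ss), columns=["df", "sum_sq", "mean_sq", "F", "PR(>F)"], dtype=float)
    for term in ss:
        table.loc[term, "df"] = dfs[term]
        table.loc[term, "sum_sq"] = ss[term]
        table.loc[term, "mean_sq"] = ss[term] / dfs[term]
        if term != "Residual":
            f_val = table.loc[term, "mean_sq"] / ms_err
            table.loc[term, "F"] = f_val
            table.loc[term, "PR(>F)"] = float(stats.f.sf(f_val, dfs[term], df_err))
    return table
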