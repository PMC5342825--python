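"""Genetics and expression statistics.

Covers the statistical machinery of a conditional gene-disruption study:

* Mendelian survival expectation for balancer complementation crosses
  (the 33% null for a lethal-allele cross).
* One-proportion z-test of an observed survival fraction against that
  expectation.
* Two-tailed Fisher's exact test for paralysis counts.
* ΔΔCt relative transcript quantification with a Student's t-test on the
  per-replicate ΔCt values.
* One-way ANOVA plus Bonferroni-corrected post-hoc t-tests with the
  both-controls display rule used for the imaging group comparisons.

Standard tests are delegated to scipy.stats; the surrounding conventions
(two-tailed p by the probability-mass method for Fisher, pooled-variance
t-tests by default, tier cutoffs 0.05/0.01/0.001) follow the study's usage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALLELES = ("FlpStop_ND", "FlpStop_D", "Null", "Balancer", "WT")

GenotypeClass = tuple[str, str]


def genotype_class(allele1: str, allele2: str) -> GenotypeClass:
    """Canonical (sorted) unordered allele pair."""
    return tuple(sorted((allele1, allele2)))  # type: ignore[return-value]


@dataclass
class CrossSpec:
    """A cross between two heterozygous parents, with lethal classes.

    ``parent1`` and ``parent2`` are allele pairs; ``lethal_genotypes`` are
    unordered allele pairs that do not survive to adulthood (the balancer
    homozygote is lethal by construction); ``scored_class`` is the genotype
    whose frequency among survivors is scored.
    """

    parent1: tuple[str, str]
    parent2: tuple[str, str]
    scored_class: GenotypeClass
    lethal_genotypes: set[GenotypeClass] = field(default_factory=set)
    include_balancer_lethality: bool = True

    def __post_init__(self) -> None:
        self.scored_class = genotype_class(*self.scored_class)
        self.lethal_genotypes = {genotype_class(*g) for g in self.lethal_genotypes}
        if self.include_balancer_lethality:
            self.lethal_genotypes.add(genotype_class("Balancer", "Balancer"))

    def zygote_classes(self) -> list[GenotypeClass]:
        """The four equiprobable zygote classes of the cross."""
        return [genotype_class(a, b) for a in self.parent1 for b in self.parent2]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    n: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def tier(self) -> str:
        return significance_tier(self.p_adjusted if self.p_adjusted is not None else self.p_value)


def significance_tier(p: float) -> str:
    """Asterisk tier: *p<0.05, **p<0.01, ***p<0.001, 'ns' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Mendelian expectation and count tests


def expected_survival(cross: CrossSpec) -> float:
    """Expected fraction of the scored genotype among surviving progeny.

    Enumerates the four equiprobable zygote classes of a cross between two
    heterozygous parents, removes lethal classes, and returns the scored
    class's probability among survivors.  For the standard complementation
    cross ND/Bal × Null/Bal with the balancer homozygote lethal, the
    FlpStop/Null class is 1 of the 3 surviving zygote classes: 1/3 (the 33%
    null expectation).
    """
    zygotes = cross.zygote_classes()
    survivors = [z for z in zygotes if z not in cross.lethal_genotypes]
    if not survivors:
        raise ValueError("all zygote classes are lethal")
    return survivors.count(cross.scored_class) / len(survivors)


def surviving_class_probabilities(cross: CrossSpec) -> dict[GenotypeClass, float]:
    """Probability of each surviving genotype class (sums to 1)."""
    zygotes = cross.zygote_classes()
    survivors = [z for z in zygotes if z not in cross.lethal_genotypes]
    if not survivors:
        raise ValueError("all zygote classes are lethal")
    out: dict[GenotypeClass, float] = {}
    for z in survivors:
        out[z] = out.get(z, 0.0) + 1.0 / len(survivors)
    return out


def one_proportion_ztest(k: int, n: int, p0: float) -> TestResult:
    """Two-sided one-proportion z-test of k/n against the null proportion p0.

    z = (k/n − p0) / sqrt(p0(1 − p0)/n), p from the normal tail (no
    continuity correction).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be strictly between 0 and 1")
    phat = k / n
    z = (phat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=z, p_value=min(p, 1.0), test="one-proportion z-test", n=n)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-tailed Fisher's exact test on a 2×2 count table.

    Two-tailed p is the sum of hypergeometric probabilities, over all tables
    with the observed margins, that are no more probable than the observed
    table (the probability-mass convention of standard statistical software).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table margins must be positive")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p),
                      test="Fisher's exact test (two-tailed)", n=int(t.sum()))


# ---------------------------------------------------------------------------
# ΔΔCt relative transcript quantification

CT_COLUMNS = ("genotype", "gene", "biological_replicate", "technical_replicate", "ct")


def delta_delta_ct(
    ct: pd.DataFrame,
    target_gene: str = "target",
    reference_gene: str = "reference",
    nd_genotype: str = "ND",
    d_genotype: str = "D",
) -> dict:
    """Relative transcript level of the disrupting vs non-disrupting genotype.

    Technical replicates are averaged per biological replicate; per replicate
    ΔCt = Ct(target) − Ct(reference); the point estimate is

        % transcript = 100 · 2^(mean ΔCt_ND − mean ΔCt_D),

    i.e. 2 raised to the difference of the genotype mean ΔCt values, and an
    unpaired two-tailed Student's t-test on the per-replicate ΔCt values
    assesses significance.  Per-replicate display values are normalized to
    the ND group mean (100 · 2^(mean ΔCt_ND − ΔCt_rep)).
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    for g in (nd_genotype, d_genotype):
        sub = ct[ct["genotype"] == g]
        if sub.empty:
            raise ValueError(f"genotype {g!r} missing from Ct table")
        for gene in (target_gene, reference_gene):
            if sub[sub["gene"] == gene].empty:
                raise ValueError(f"gene {gene!r} missing for genotype {g!r}")

    tech_mean = (
        ct.groupby(["genotype", "gene", "biological_replicate"], sort=True)["ct"]
        .mean()
        .unstack("gene")
    )
    dct = (tech_mean[target_gene] - tech_mean[reference_gene]).rename("delta_ct")
    dct_nd = dct.loc[nd_genotype]
    dct_d = dct.loc[d_genotype]
    percent = 100.0 * 2.0 ** (dct_nd.mean() - dct_d.mean())

    if dct_nd.std(ddof=0) == 0 and dct_d.std(ddof=0) == 0:
        # identical-samples contract: no variance, equal means -> p = 1
        equal = math.isclose(dct_nd.mean(), dct_d.mean(), abs_tol=1e-12)
        test = TestResult(statistic=0.0 if equal else math.inf,
                          p_value=1.0 if equal else 0.0,
                          test="Student's t-test on ΔCt", n=len(dct_nd) + len(dct_d))
    else:
        tstat, p = sps.ttest_ind(dct_nd, dct_d, equal_var=True)
        test = TestResult(statistic=float(tstat), p_value=float(p),
                          test="Student's t-test on ΔCt", n=len(dct_nd) + len(dct_d))

    per_rep = 100.0 * 2.0 ** (dct_nd.mean() - dct)
    return {
        "percent_transcript": float(percent),
        "delta_ct": dct,
        "per_replicate_percent": per_rep,
        "test": test,
    }


# ---------------------------------------------------------------------------
# imaging group statistics


def anova_oneway(groups: Sequence[np.ndarray]) -> TestResult:
    """One-way ANOVA across genotype groups of peak values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(g) == 0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
        # identical constant groups: no variance anywhere -> F = 0, p = 1
        return TestResult(statistic=0.0, p_value=1.0, test="one-way ANOVA",
                          n=sum(len(g) for g in groups))
    f, p = sps.f_oneway(*groups)
    return TestResult(statistic=float(f), p_value=float(p), test="one-way ANOVA",
                      n=sum(len(g) for g in groups))


def _ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float]:
    t, p = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=equal_var)
    return float(t), float(p)


def posthoc_bonferroni(
    experimental: np.ndarray,
    control_a: np.ndarray,
    control_b: np.ndarray,
    m: int = 2,
    equal_var: bool = True,
) -> dict:
    """Post-hoc t-tests of the experimental group against each control.

    Unpaired two-sample t-tests (pooled variance by default; Welch with
    ``equal_var=False``), Bonferroni-adjusted p = min(1, m·p).  Asterisks are
    displayed only when the experimental group differs from *both* controls
    (both adjusted p < 0.05); when the two comparisons have different
    p-values the less significant one sets the displayed tier.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for g in (experimental, control_a, control_b):
        if len(np.asarray(g)) < 2:
            raise ValueError("each group needs n >= 2")
    results = []
    for ctrl, name in ((control_a, "vs control_a"), (control_b, "vs control_b")):
        t, p = _ttest(experimental, ctrl, equal_var)
        res = TestResult(statistic=t, p_value=p, test=f"Student's t-test {name}",
                         n=len(np.asarray(experimental)) + len(np.asarray(ctrl)),
                         p_adjusted=min(1.0, m * p))
        results.append(res)
    worst = max(r.p_adjusted for r in results)
    significant = all(r.p_adjusted < 0.05 for r in results)
    display = significance_tier(worst) if significant else "ns"
    return {
        "vs_control_a": results[0],
        "vs_control_b": results[1],
        "significant_vs_both": significant,
        "display_tier": display,
    }
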