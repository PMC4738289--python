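"""Gene-set mutation-burden comparison between trait groups.

Counts, per sequenced individual, the qualifying variants (rare exonic
protein-altering, i.e. survivors of the exonic + novelty + consequence
gates — the co-segregation gate is deliberately NOT applied, since the
burden test compares individuals) that fall in an interactor gene set,
then compares the affected and unaffected groups with a two-sample
t-test. High- and low-confidence interaction tiers are tested
separately. Welch's unequal-variance form is the default; with groups
of 2 and 4 the pooled Student form can differ noticeably and is
available by flag.

Statistical caveat: group members are relatives, so the independence
assumption of the t-test is only approximate — the test is a screen,
not a calibrated association test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pedigree import Pedigree, affected_partition
from .segregation import (
    Annotation,
    FilterConfig,
    VariantSite,
    consequence_filter,
    exonic_filter,
    novelty_filter,
    site_quality_filter,
)


@dataclass(frozen=True)
class InteractorSet:
    tier: str  # "high" | "low"
    genes: frozenset[str]


@dataclass
class BurdenResult:
    """Per-tier burden comparison between trait groups."""

    tier: str
    group_trait_counts: dict[str, int]
    group_other_counts: dict[str, int]
    t_statistic: float
    df: float
    p_value: float
    test: str = "welch"

    @property
    def mean_trait(self) -> float:
        return float(np.mean(list(self.group_trait_counts.values())))

    @property
    def mean_other(self) -> float:
        return float(np.mean(list(self.group_other_counts.values())))

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "test": self.test,
            "group_trait_counts": self.group_trait_counts,
            "group_other_counts": self.group_other_counts,
            "mean_trait": self.mean_trait,
            "mean_other": self.mean_other,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


class DegenerateVarianceError(ValueError):
    pass


def welch_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test returning (t, df, p).

    Welch's unequal-variance statistic with Welch–Satterthwaite degrees
    of freedom by default; ``equal_var=True`` gives the pooled Student
    form. Identical constant groups return (0, n1+n2-2, 1); constant
    groups with different means have no finite t and raise
    :class:`DegenerateVarianceError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise DegenerateVarianceError(
            "both groups constant with unequal means: t is unbounded"
        )
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def qualifying_variants(
    variants: Sequence[tuple[VariantSite, Annotation]],
    panels: Sequence[set],
    cfg: FilterConfig = FilterConfig(),
) -> list[tuple[VariantSite, Annotation]]:
    """Rare exonic protein-altering variants, per record.

    Applies the site-quality, exonic, novelty and consequence gates only
    — no pedigree segregation — so each individual's carried subset can
    be counted.
    """
    out = []
    for v, a in variants:
        if not site_quality_filter(v):
            continue
        if not exonic_filter(a):
            continue
        if not novelty_filter(v, panels, cfg):
            continue
        if not consequence_filter(a):
            continue
        out.append((v, a))
    return out


def count_burden(
    qualifying: Sequence[tuple[VariantSite, Annotation]],
    gene_set: InteractorSet,
    samples: Sequence[str],
) -> dict[str, int]:
    """Per-sample count of carried qualifying variants in the gene set.

    A sample counts a variant when its called genotype carries the alt
    allele (het or hom-alt). Samples with nothing qualifying get 0.
    """
    counts = {s: 0 for s in samples}
    for v, a in qualifying:
        if a.gene not in gene_set.genes:
            continue
        for s, call in v.genotypes.items():
            if s not in counts:
                raise KeyError(f"unknown sample id {s!r}")
            if call.carries_alt:
                counts[s] += 1
    return counts


def run_burden(
    variants: Sequence[tuple[VariantSite, Annotation]],
    ped: Pedigree,
    interactors: Sequence[InteractorSet],
    panels: Sequence[set] = (),
    filter_cfg: FilterConfig = FilterConfig(),
    test: str = "welch",
) -> list[BurdenResult]:
    """One burden comparison per interaction-confidence tier.

    Groups are the affected/unaffected partition of the pedigree,
    restricted to genotyped samples; both groups must be non-empty.
    """
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}")
    if not variants:
        raise ValueError("no variants supplied")
    samples = list(variants[0][0].genotypes)
    affected, _ = affected_partition(ped)
    trait = [s for s in samples if s in affected]
    other = [s for s in samples if s not in affected]
    if not trait or not other:
        raise ValueError("both trait groups must be non-empty")
    qual = qualifying_variants(variants, panels, filter_cfg)
    results = []
    for iset in interactors:
        counts = count_burden(qual, iset, samples)
        x = [counts[s] for s in trait]
        y = [counts[s] for s in other]
        t, df, p = welch_t_test(x, y, equal_var=(test == "student"))
        results.append(
            BurdenResult(
                tier=iset.tier,
                group_trait_counts={s: counts[s] for s in trait},
                group_other_counts={s: counts[s] for s in other},
                t_statistic=t,
                df=df,
                p_value=p,
                test=test,
            )
        )
    return results


def load_interactors(path) -> list[InteractorSet]:
    """Read a (gene, tier) TSV into disjoint per-tier gene sets."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    sets = []
    seen: dict[str, str] = {}
    for tier in ("high", "low"):
        genes = frozenset(df.loc[df.tier == tier, "gene"])
        for g in genes:
            if g in seen:
                raise ValueError(f"gene {g!r} appears in tiers {seen[g]} and {tier}")
            seen[g] = tier
        sets.append(InteractorSet(tier=tier, genes=genes))
    return sets


def write_burden(results: Sequence[BurdenResult], path) -> None:
    payload = {"schema_version": 1, "results": [r.to_dict() for r in results]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
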