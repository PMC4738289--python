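"""Independent reference implementations used only to check the package.

Everything here is deliberately written as plain brute force —
per-variant rule re-checks, per-base interval arithmetic, explicit
Welch formulas, exhaustive genotype enumeration — so the tests compare
two unrelated code paths.
"""

from __future__ import annotations

import itertools
import math

from scipy import stats


# ---------------------------------------------------------------------------
# Cascade: independent per-variant rule check
# ---------------------------------------------------------------------------

def brute_force_candidates(variants, annotations, panels, ped, min_called):
    """Re-derive the cascade's candidate set rule by rule, per variant."""
    affected = {i.id for i in ped if i.affected}
    keep = []
    panel_keys = set()
    for p in panels:
        panel_keys |= {tuple(rec) for rec in p}
    for v in variants:
        if not v.site_pass:
            continue
        zyg = {s: g.zygosity.value for s, g in v.genotypes.items()}
        if sum(1 for z in zyg.values() if z != "missing") < min_called:
            continue
        ok = True
        for s, z in zyg.items():
            if s in affected:
                if z != "het":
                    ok = False
            else:
                if z in ("het", "hom_alt"):
                    ok = False
        if not ok or not (affected & set(zyg)):
            continue
        a = annotations[(v.chrom, v.pos, v.ref, v.alt)]
        if a.region_class.value != "exonic":
            continue
        if (v.chrom, v.pos, v.ref, v.alt) in panel_keys:
            continue
        if a.consequence.value not in (
            "nonsynonymous_snv", "stopgain", "stoploss", "frameshift_indel",
        ):
            continue
        keep.append((v.chrom, v.pos, v.ref, v.alt))
    return set(keep)


# ---------------------------------------------------------------------------
# Intervals: per-base set arithmetic
# ---------------------------------------------------------------------------

def per_base_overlap_fractions(a, b):
    """(shared/len(a), shared/len(b)) via explicit base sets."""
    chrom_a, sa, ea = a
    chrom_b, sb, eb = b
    if chrom_a != chrom_b:
        return (0.0, 0.0)
    bases_a = set(range(sa, ea + 1))
    bases_b = set(range(sb, eb + 1))
    shared = len(bases_a & bases_b)
    return (shared / len(bases_a), shared / len(bases_b))


# ---------------------------------------------------------------------------
# Welch: closed-form evaluation
# ---------------------------------------------------------------------------

def closed_form_welch(x, y):
    """Welch t, Welch–Satterthwaite df, two-sided p — explicit formulas."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# Transmission-pattern enumeration
# ---------------------------------------------------------------------------

def _transmission_prob(child, father, mother):
    """P(child dosage | parent dosages) under Mendelian segregation."""
    pf, pm = father / 2.0, mother / 2.0
    return {
        0: (1 - pf) * (1 - pm),
        1: pf * (1 - pm) + (1 - pf) * pm,
        2: pf * pm,
    }[child]


def enumerate_pattern_probability(ped, freq, het_ids, clear_ids, given_het_ids=()):
    """Exact P(pattern | condition) by summing over all genotype vectors.

    ``pattern``: every id in ``het_ids`` is heterozygous and every id in
    ``clear_ids`` is hom-ref. ``given_het_ids`` conditions on those ids
    being heterozygous. Founders follow Hardy–Weinberg at ``freq``.
    """
    order = ped.topological_order()
    ids = [i.id for i in order]
    hw = {0: (1 - freq) ** 2, 1: 2 * freq * (1 - freq), 2: freq**2}
    p_pattern = 0.0
    p_given = 0.0
    for combo in itertools.product((0, 1, 2), repeat=len(order)):
        g = dict(zip(ids, combo))
        prob = 1.0
        for ind in order:
            if ind.is_founder:
                prob *= hw[g[ind.id]]
            else:
                prob *= _transmission_prob(
                    g[ind.id], g[ind.father_id], g[ind.mother_id]
                )
            if prob == 0.0:
                break
        if prob == 0.0:
            continue
        if all(g[i] == 1 for i in given_het_ids):
            p_given += prob
            if all(g[i] == 1 for i in het_ids) and all(g[i] == 0 for i in clear_ids):
                p_pattern += prob
    if not given_het_ids:
        return p_pattern
    return p_pattern / p_given
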