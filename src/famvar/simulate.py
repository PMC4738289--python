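"""Synthetic family-exome study generator.

Gene-dropping simulation of a multi-sample exome VCF for an arbitrary
pedigree, with a planted heterozygous trait variant, per-variant
annotation tables (gene, region class, consequence, PhyloP/SIFT/
PolyPhen2-HDIV scores, amino-acid change), reference-panel known-site
lists, dual-caller CNV call sets with per-sample array QC metrics, a
DGV-like structural-variant catalogue and tiered interactor gene lists.

Founder genotypes are drawn in Hardy–Weinberg proportions at each site
and sites are simulated independently (no linkage): the downstream
filter cascade operates per site, so LD is irrelevant to its
correctness. Every output is a plain-text file (VCF v4.2 / TSV / JSON)
and is byte-identical for a fixed configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pedigree import Individual, Pedigree, Sex

MISSING = -1  # genotype code; 0/1/2 = alt-allele dosage

_BASES = np.array(list("ACGT"))
_AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

#: exonic consequence mix (fractions of exonic SNV/indel records)
DEFAULT_CONSEQUENCE_WEIGHTS = {
    "nonsynonymous_snv": 0.50,
    "synonymous_snv": 0.40,
    "stopgain": 0.02,
    "stoploss": 0.005,
    "frameshift_indel": 0.035,
    "nonframeshift_indel": 0.04,
}

#: score sampling specs: (family, *params)
DEFAULT_SCORE_DISTRIBUTIONS = {
    "phylop": ("normal", 0.5, 1.5),
    "sift": ("beta", 1.0, 1.0),
    "polyphen_hdiv": ("beta", 0.6, 0.6),  # bimodal, like real HDIV output
}

#: reference-panel depth emulated by the known-site lists (individuals)
PANEL_INDIVIDUALS = 4769


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    The defaults emulate the study family's data at reduced scale:
    allele frequencies skewed rare, ~63% of raw records failing caller
    quality filters, ~15% of variants exonic, and interactor tiers of
    5961 high- / 2178 low-confidence genes.
    """

    seed: int = 0
    n_variants: int = 2000
    allele_frequency_distribution: tuple = ("beta", 0.3, 3.0)
    missing_call_rate: float = 0.0
    site_fail_rate: float = 0.63
    false_positive_indel_rate: float = 0.0
    planted_carriers: tuple[str, ...] = ("II.3", "III.3")
    fraction_exonic: float = 0.15
    consequence_class_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_WEIGHTS)
    )
    score_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTRIBUTIONS)
    )
    n_genes: int = 12000
    cnv_segments_per_sample: int = 5
    boundary_jitter_sd: float = 500.0
    split_call_probability: float = 0.1
    low_quality_call_rate: float = 0.1
    qc_fail_samples: tuple[str, ...] = ()
    dgv_records: int = 200
    interactor_counts: tuple[int, int] = (5961, 2178)

    def __post_init__(self) -> None:
        for name in (
            "missing_call_rate",
            "site_fail_rate",
            "false_positive_indel_rate",
            "fraction_exonic",
            "split_call_probability",
            "low_quality_call_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_variants", "n_genes", "cnv_segments_per_sample", "dgv_records"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = sum(self.consequence_class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"consequence_class_weights sum to {total}, expected 1")


def family_pedigree(connector_sex: str = "male") -> Pedigree:
    """The six-exome study family plus its ungenotyped connectors.

    Three generations: grandparents I.1 x I.2 have two children — the
    affected father II.3 and an ungenotyped sibling II.2 whose two
    children III.1/III.2 are the sequenced paternal cousins. The father
    and mother II.4 have the affected proband III.3 and her unaffected
    sister III.4. ``connector_sex`` chooses whether the cousins descend
    from the father's brother or sister (autosomal analyses are
    invariant to the choice).
    """
    if connector_sex not in ("male", "female"):
        raise ValueError("connector_sex must be 'male' or 'female'")
    sib_is_male = connector_sex == "male"
    sib = Individual(
        "II.2", father_id="I.1", mother_id="I.2",
        sex=Sex.MALE if sib_is_male else Sex.FEMALE,
    )
    spouse = Individual("II.1", sex=Sex.FEMALE if sib_is_male else Sex.MALE)
    cousin_parents = dict(
        father_id="II.2" if sib_is_male else "II.1",
        mother_id="II.1" if sib_is_male else "II.2",
    )
    inds = [
        Individual("I.1", sex=Sex.MALE),
        Individual("I.2", sex=Sex.FEMALE),
        spouse,
        sib,
        Individual("II.3", father_id="I.1", mother_id="I.2", sex=Sex.MALE, affected=True),
        Individual("II.4", sex=Sex.FEMALE),
        Individual("III.1", sex=Sex.FEMALE, **cousin_parents),
        Individual("III.2", sex=Sex.MALE, **cousin_parents),
        Individual("III.3", father_id="II.3", mother_id="II.4", sex=Sex.FEMALE, affected=True),
        Individual("III.4", father_id="II.3", mother_id="II.4", sex=Sex.FEMALE),
    ]
    return Pedigree(inds, name="FAM1")


#: the six sequenced members of the study family
SEQUENCED_SAMPLES = ("II.3", "II.4", "III.1", "III.2", "III.3", "III.4")


@dataclass
class VariantTable:
    """In-memory multi-sample variant matrix plus truth metadata.

    ``genotypes`` holds alt-allele dosages (0/1/2) or ``MISSING`` for the
    genotyped ``samples`` only; ``full_genotypes`` keeps the pre-missing
    dosages of every pedigree member (columns ``pedigree_ids``) so tests
    can verify Mendelian consistency.
    """

    samples: list[str]
    chrom: list[str]
    pos: list[int]
    ref: list[str]
    alt: list[str]
    freqs: np.ndarray
    genotypes: np.ndarray  # (n_variants, n_samples) int8
    site_pass: np.ndarray  # bool
    is_indel: np.ndarray  # bool
    pedigree_ids: list[str]
    full_genotypes: np.ndarray  # (n_variants, n_pedigree) int8, pre-missing
    planted: np.ndarray  # bool
    false_positive: np.ndarray  # bool

    @property
    def n_variants(self) -> int:
        return len(self.pos)


def _draw_frequencies(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    kind, *params = cfg.allele_frequency_distribution
    if kind == "beta":
        return rng.beta(params[0], params[1], size=n)
    if kind == "fixed":
        return np.full(n, float(params[0]))
    if kind == "uniform":
        return rng.uniform(params[0], params[1], size=n)
    raise ValueError(f"unknown allele frequency distribution {kind!r}")


def _site_coordinates(
    n: int, rng: np.random.Generator
) -> tuple[list[str], list[int], list[str], list[str]]:
    chroms, poss, refs, alts = [], [], [], []
    per_chrom = max(1, -(-n // 22))
    pos = 0
    for i in range(n):
        c = i // per_chrom + 1
        if i % per_chrom == 0:
            pos = 0
        pos += int(rng.integers(100, 5000))
        chroms.append(f"chr{c}")
        poss.append(pos)
        r, a = rng.choice(4, size=2, replace=False)
        refs.append(str(_BASES[r]))
        alts.append(str(_BASES[a]))
    return chroms, poss, refs, alts


def gene_drop(
    ped: Pedigree, freqs: np.ndarray, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Drop founder alleles down the pedigree at independent sites.

    Founders are drawn Binomial(2, f) per site (Hardy–Weinberg);
    each non-founder receives one allele from each parent, chosen
    uniformly from the parent's two alleles. Returns the pedigree ids in
    topological order and the (n_sites, n_individuals) dosage matrix.
    """
    order = ped.topological_order()
    n = len(freqs)
    col = {ind.id: k for k, ind in enumerate(order)}
    G = np.zeros((n, len(order)), dtype=np.int8)
    for ind in order:
        k = col[ind.id]
        if ind.is_founder:
            G[:, k] = rng.binomial(2, freqs).astype(np.int8)
        else:
            # P(transmit alt) = dosage/2 for each parent independently
            gf = G[:, col[ind.father_id]]
            gm = G[:, col[ind.mother_id]]
            G[:, k] = (
                rng.random(n) < gf / 2.0
            ).astype(np.int8) + (rng.random(n) < gm / 2.0).astype(np.int8)
    return [ind.id for ind in order], G


def simulate_genotypes(
    ped: Pedigree,
    cfg: SimulationConfig,
    samples: Sequence[str] = SEQUENCED_SAMPLES,
    rng: Optional[np.random.Generator] = None,
) -> VariantTable:
    """Simulate a multi-sample variant table by gene dropping.

    ``samples`` names the genotyped subset of the pedigree (the exomes);
    every named sample must belong to the pedigree. Missing calls are
    injected at ``missing_call_rate`` per genotype after transmission,
    and each site fails the caller quality filter independently with
    probability ``site_fail_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    for s in samples:
        if s not in ped:
            raise ValueError(f"sample {s!r} is not in the pedigree")
    n = cfg.n_variants
    freqs = _draw_frequencies(cfg, n, rng)
    chroms, poss, refs, alts = _site_coordinates(n, rng)
    ids, G = gene_drop(ped, freqs, rng)
    cols = [ids.index(s) for s in samples]
    gt = G[:, cols].copy()
    if cfg.missing_call_rate > 0:
        mask = rng.random(gt.shape) < cfg.missing_call_rate
        gt[mask] = MISSING
    site_pass = rng.random(n) >= cfg.site_fail_rate
    is_indel = np.zeros(n, dtype=bool)
    table = VariantTable(
        samples=list(samples),
        chrom=chroms,
        pos=poss,
        ref=refs,
        alt=alts,
        freqs=freqs,
        genotypes=gt,
        site_pass=site_pass,
        is_indel=is_indel,
        pedigree_ids=ids,
        full_genotypes=G,
        planted=np.zeros(n, dtype=bool),
        false_positive=np.zeros(n, dtype=bool),
    )
    if cfg.false_positive_indel_rate > 0:
        _inject_false_positive_indels(table, ped, cfg, rng)
    return table


def _inject_false_positive_indels(
    table: VariantTable, ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Convert a random subset of records into caller-artifact indels.

    The artifacts mimic the co-segregation genotype pattern (so they
    survive the cascade, as a wet-lab validation step would later
    reveal) and are flagged in the truth metadata.
    """
    affected = [s for s in table.samples if ped[s].affected]
    idx = np.where(rng.random(table.n_variants) < cfg.false_positive_indel_rate)[0]
    for i in idx:
        table.is_indel[i] = True
        table.false_positive[i] = True
        table.site_pass[i] = True
        table.alt[i] = table.ref[i] + "".join(
            rng.choice(list("ACGT"), size=int(rng.integers(1, 6)))
        )
        table.genotypes[i, :] = 0
        for s in affected:
            table.genotypes[i, table.samples.index(s)] = 1
        table.full_genotypes[i, :] = 0
        for s in affected:
            table.full_genotypes[i, table.pedigree_ids.index(s)] = 1


def plant_trait_variant(
    table: VariantTable, ped: Pedigree, carriers: set[str] | Sequence[str]
) -> VariantTable:
    """Append the planted trait variant: het in exactly ``carriers``.

    The record is fully called, site-PASS, and flagged in truth metadata
    so the annotation and panel simulators make it exonic nonsynonymous
    and panel-absent.
    """
    carriers = set(carriers)
    if not carriers:
        raise ValueError("carrier set must be non-empty")
    unknown = carriers - set(ped.ids)
    if unknown:
        raise ValueError(f"carriers not in pedigree: {sorted(unknown)}")
    gt = np.array([1 if s in carriers else 0 for s in table.samples], dtype=np.int8)
    full = np.array(
        [1 if s in carriers else 0 for s in table.pedigree_ids], dtype=np.int8
    )
    last_on_contig = max(
        (p for c, p in zip(table.chrom, table.pos) if c == "chr22"), default=0
    )
    table.samples = list(table.samples)
    table.chrom.append("chr22")
    table.pos.append(last_on_contig + 1000)
    table.ref.append("G")
    table.alt.append("A")
    table.freqs = np.append(table.freqs, 0.0)
    table.genotypes = np.vstack([table.genotypes, gt])
    table.site_pass = np.append(table.site_pass, True)
    table.is_indel = np.append(table.is_indel, False)
    table.full_genotypes = np.vstack([table.full_genotypes, full])
    table.planted = np.append(table.planted, True)
    table.false_positive = np.append(table.false_positive, False)
    return table


def _draw_scores(
    spec: tuple, n: int, rng: np.random.Generator
) -> np.ndarray:
    kind, *params = spec
    if kind == "normal":
        return rng.normal(params[0], params[1], size=n)
    if kind == "beta":
        return rng.beta(params[0], params[1], size=n)
    if kind == "uniform":
        return rng.uniform(params[0], params[1], size=n)
    raise ValueError(f"unknown score distribution {kind!r}")


_PROTEIN_CHANGING = {"nonsynonymous_snv", "stopgain", "stoploss"}


def _random_aa_change(rng: np.random.Generator) -> str:
    ref, alt = rng.choice(_AMINO_ACIDS, size=2, replace=False)
    pos = int(rng.integers(1, 1500))
    return f"p.{ref}{pos}{alt}"


def simulate_annotations(
    table: VariantTable,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Build the per-variant annotation table (one row per record).

    Gene symbols are drawn from a shared universe of ``cfg.n_genes``
    genes; region class is exonic with probability ``fraction_exonic``;
    exonic SNV consequences follow ``consequence_class_weights``
    (indel records take the matching indel class); scores are sampled
    from ``score_distributions``, with SIFT/PolyPhen left null on indels
    as substitution predictors do not score them. Planted records are
    forced exonic nonsynonymous.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = table.n_variants
    genes = [f"GENE{int(g):05d}" for g in rng.integers(0, cfg.n_genes, size=n)]
    exonic = rng.random(n) < cfg.fraction_exonic
    nonexonic_classes = np.array(["intronic", "intergenic", "utr", "splicing", "other"])
    nonexonic_w = np.array([0.5, 0.25, 0.15, 0.05, 0.05])
    region = np.where(
        exonic, "exonic", rng.choice(nonexonic_classes, size=n, p=nonexonic_w)
    )
    snv_classes = [c for c in cfg.consequence_class_weights if "indel" not in c]
    snv_w = np.array([cfg.consequence_class_weights[c] for c in snv_classes])
    snv_w = snv_w / snv_w.sum()
    indel_classes = [c for c in cfg.consequence_class_weights if "indel" in c]
    indel_w = np.array([cfg.consequence_class_weights.get(c, 0.5) for c in indel_classes])
    indel_w = (
        indel_w / indel_w.sum() if indel_w.sum() > 0 else np.ones(len(indel_classes))
    )
    phylop = _draw_scores(cfg.score_distributions["phylop"], n, rng)
    sift = _draw_scores(cfg.score_distributions["sift"], n, rng)
    polyphen = _draw_scores(cfg.score_distributions["polyphen_hdiv"], n, rng)
    consequence: list[Optional[str]] = []
    aa_change: list[Optional[str]] = []
    for i in range(n):
        if region[i] != "exonic":
            consequence.append(None)
            aa_change.append(None)
            continue
        if table.is_indel[i]:
            cons = str(rng.choice(indel_classes, p=indel_w))
            if table.false_positive[i]:
                cons = "frameshift_indel"
        else:
            cons = str(rng.choice(snv_classes, p=snv_w))
        consequence.append(cons)
        aa_change.append(_random_aa_change(rng) if cons in _PROTEIN_CHANGING else None)
    df = pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "ref": table.ref,
            "alt": table.alt,
            "gene": genes,
            "region_class": region,
            "consequence": consequence,
            "phylop": np.round(phylop, 4),
            "sift": np.round(sift, 4),
            "polyphen_hdiv": np.round(polyphen, 4),
            "aa_change": aa_change,
        }
    )
    # substitution predictors do not score indels
    df.loc[table.is_indel, ["sift", "polyphen_hdiv"]] = np.nan
    planted = np.where(table.planted)[0]
    for i in planted:
        df.loc[i, ["region_class", "consequence"]] = ["exonic", "nonsynonymous_snv"]
        df.loc[i, ["phylop", "sift", "polyphen_hdiv"]] = [2.5, 0.01, 0.99]
        df.loc[i, "aa_change"] = "p.G88R"
    return df


def simulate_panel_sites(
    table: VariantTable,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Known-site lists emulating two public reference panels.

    A site enters the combined panel with probability
    ``1 - (1 - f)^(2 * 4769)`` — the chance at least one of the panels'
    chromosomes carries the alt allele at population frequency ``f``.
    Known sites are then scattered over the two panel tables (each picks
    a known site with probability 0.7, forced into at least one).
    Planted and artifact records never enter a panel.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    p_known = 1.0 - (1.0 - table.freqs) ** (2 * PANEL_INDIVIDUALS)
    known = rng.random(table.n_variants) < p_known
    known &= ~table.planted
    known &= ~table.false_positive
    rows_a, rows_b = [], []
    for i in np.where(known)[0]:
        rec = (table.chrom[i], table.pos[i], table.ref[i], table.alt[i])
        in_a = rng.random() < 0.7
        in_b = rng.random() < 0.7
        if not (in_a or in_b):
            (rows_a if rng.random() < 0.5 else rows_b).append(rec)
        else:
            if in_a:
                rows_a.append(rec)
            if in_b:
                rows_b.append(rec)
    cols = ["chrom", "pos", "ref", "alt"]
    return (
        pd.DataFrame(rows_a, columns=cols),
        pd.DataFrame(rows_b, columns=cols),
    )


# ---------------------------------------------------------------------------
# CNV callers, QC metrics, DGV catalogue, interactors
# ---------------------------------------------------------------------------

_CHROM_LENGTH = 100_000_000  # synthetic contig span used for CNV placement


def simulate_cnv_callsets(
    ped: Pedigree,
    cfg: SimulationConfig,
    samples: Sequence[str] = SEQUENCED_SAMPLES,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate true CNV segments and two callers' views of them.

    Each true segment appears in both callers with independent boundary
    jitter (Gaussian, sd ``boundary_jitter_sd``, truncated to under a
    quarter of the segment length so the reciprocal-overlap consensus is
    attainable); with ``split_call_probability`` a caller reports a
    segment as two adjacent calls; ``low_quality_call_rate`` adds
    caller-private noise calls that fail the SNP-count/confidence
    filter. Returns (calls_A, calls_B, qc_metrics, truth_segments),
    calls as pandas DataFrames with 1-based inclusive coordinates.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    truth_rows = []
    rows = {"A": [], "B": []}
    for sample in samples:
        for _ in range(cfg.cnv_segments_per_sample):
            chrom = f"chr{int(rng.integers(1, 23))}"
            length = int(rng.lognormal(mean=10.5, sigma=0.6))  # ~20–120 kb
            length = max(length, 2000)
            start = int(rng.integers(1, _CHROM_LENGTH - length))
            end = start + length - 1
            state = "deletion" if rng.random() < 0.5 else "duplication"
            n_snps = max(3, length // 2000)
            truth_rows.append((sample, chrom, start, end, state, n_snps))
            for caller in ("A", "B"):
                max_shift = 0.24 * length
                js = float(np.clip(rng.normal(0, cfg.boundary_jitter_sd), -max_shift, max_shift))
                je = float(np.clip(rng.normal(0, cfg.boundary_jitter_sd), -max_shift, max_shift))
                s = max(1, int(round(start + js)))
                e = max(s, int(round(end + je)))
                conf = float(np.round(rng.uniform(12, 60), 2))
                if rng.random() < cfg.split_call_probability and e - s > 200:
                    cut = int(rng.integers(s + 50, e - 50))
                    gap = int(rng.integers(1, 50))
                    left_snps = max(1, n_snps // 2)
                    rows[caller].append(
                        (sample, caller, chrom, s, cut, state, left_snps, conf)
                    )
                    rows[caller].append(
                        (
                            sample,
                            caller,
                            chrom,
                            min(cut + gap, e),
                            e,
                            state,
                            max(1, n_snps - left_snps),
                            float(np.round(rng.uniform(12, 60), 2)),
                        )
                    )
                else:
                    rows[caller].append((sample, caller, chrom, s, e, state, n_snps, conf))
        # caller-private low-quality noise calls
        for caller in ("A", "B"):
            if rng.random() < cfg.low_quality_call_rate:
                chrom = f"chr{int(rng.integers(1, 23))}"
                length = int(rng.integers(500, 5000))
                start = int(rng.integers(1, _CHROM_LENGTH - length))
                bad_snps = int(rng.integers(1, 3))
                rows[caller].append(
                    (
                        sample,
                        caller,
                        chrom,
                        start,
                        start + length - 1,
                        "deletion" if rng.random() < 0.5 else "duplication",
                        bad_snps,
                        float(np.round(rng.uniform(0, 9.9), 2)),
                    )
                )
    qc_rows = []
    for sample in samples:
        if sample in cfg.qc_fail_samples:
            qc_rows.append(
                (
                    sample,
                    float(np.round(rng.uniform(0.4, 0.6), 4)),
                    float(np.round(rng.uniform(0.003, 0.01), 6)),
                    float(np.round(rng.uniform(0.05, 0.08), 4)),
                    float(np.round(rng.uniform(0.2, 0.3), 4)),
                )
            )
        else:
            qc_rows.append(
                (
                    sample,
                    float(np.round(rng.uniform(0.10, 0.30), 4)),
                    float(np.round(rng.uniform(0.0, 0.0015), 6)),
                    float(np.round(rng.uniform(-0.03, 0.03), 4)),
                    float(np.round(rng.uniform(0.05, 0.12), 4)),
                )
            )
    call_cols = ["sample", "caller", "chrom", "start", "end", "state", "n_snps", "confidence"]
    calls_a = pd.DataFrame(rows["A"], columns=call_cols)
    calls_b = pd.DataFrame(rows["B"], columns=call_cols)
    qc = pd.DataFrame(qc_rows, columns=["sample", "lrr_sd", "baf_drift", "waviness", "baf_sd"])
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "chrom", "start", "end", "state", "n_snps"]
    )
    return calls_a, calls_b, qc, truth


def simulate_sv_database(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
):
    """DGV-like structural-variant catalogue with supporting counts."""
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 4)
    rows = []
    for _ in range(cfg.dgv_records):
        chrom = f"chr{int(rng.integers(1, 23))}"
        length = int(rng.lognormal(mean=11.0, sigma=1.0))
        start = int(rng.integers(1, _CHROM_LENGTH - length))
        rows.append((chrom, start, start + length - 1, int(rng.integers(1, 60))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_supporting"])


def simulate_interactors(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
):
    """Tiered interactor gene lists (disjoint high/low confidence)."""
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 5)
    n_high, n_low = cfg.interactor_counts
    universe = max(cfg.n_genes, n_high + n_low)
    picks = rng.choice(universe, size=n_high + n_low, replace=False)
    rows = [(f"GENE{int(g):05d}", "high") for g in picks[:n_high]]
    rows += [(f"GENE{int(g):05d}", "low") for g in picks[n_high:]]
    return pd.DataFrame(rows, columns=["gene", "tier"])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write the table as a VCF v4.2 with GT and DP per sample.

    One ALT per record; DP is a fixed nominal depth (30) for called
    genotypes and 0 for missing ones — the downstream filters only use
    whether a genotype was called.
    """
    order = np.lexsort(
        (np.asarray(table.pos), np.array([int(c[3:]) for c in table.chrom]))
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famvar-simulate\n")
        for c in range(1, 23):
            fh.write(f"##contig=<ID=chr{c}>\n")
        fh.write('##FILTER=<ID=lowqual,Description="Failed caller quality filters">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in order:
            filt = "PASS" if table.site_pass[i] else "lowqual"
            cells = []
            for j in range(len(table.samples)):
                g = int(table.genotypes[i, j])
                dp = 0 if g == MISSING else 30
                cells.append(f"{_GT_STRING[g]}:{dp}")
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t{table.alt[i]}"
                f"\t.\t{filt}\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def write_truth(table: VariantTable, path: str | Path) -> None:
    """JSON truth sidecar: planted/false-positive flags and frequencies."""
    payload = {
        "samples": table.samples,
        "planted": [
            {"chrom": table.chrom[i], "pos": table.pos[i], "ref": table.ref[i], "alt": table.alt[i]}
            for i in np.where(table.planted)[0]
        ],
        "false_positive_indels": [
            {"chrom": table.chrom[i], "pos": table.pos[i]}
            for i in np.where(table.false_positive)[0]
        ],
        "n_variants": int(table.n_variants),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def simulate_study(
    outdir: str | Path,
    cfg: SimulationConfig,
    ped: Optional[Pedigree] = None,
    samples: Sequence[str] = SEQUENCED_SAMPLES,
) -> dict[str, Path]:
    """Generate and write a complete synthetic study into ``outdir``.

    Emits the pedigree (PED), multi-sample VCF, annotation TSV, two
    panel TSVs, two CNV call TSVs, QC TSV, DGV TSV, interactor TSV and
    truth JSON. Returns the path of every file written.
    """
    from .pedigree import write_pedigree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = ped if ped is not None else family_pedigree()
    rng = np.random.default_rng(cfg.seed)
    table = simulate_genotypes(ped, cfg, samples=samples, rng=rng)
    if cfg.planted_carriers:
        plant_trait_variant(table, ped, set(cfg.planted_carriers))
    ann = simulate_annotations(table, cfg)
    panel_a, panel_b = simulate_panel_sites(table, cfg)
    calls_a, calls_b, qc, cnv_truth = simulate_cnv_callsets(ped, cfg, samples=samples)
    dgv = simulate_sv_database(cfg)
    interactors = simulate_interactors(cfg)
    paths = {
        "pedigree": outdir / "family.ped",
        "vcf": outdir / "variants.vcf",
        "annotations": outdir / "annotations.tsv",
        "panel_a": outdir / "panel_a.tsv",
        "panel_b": outdir / "panel_b.tsv",
        "cnv_calls_a": outdir / "cnv_calls_a.tsv",
        "cnv_calls_b": outdir / "cnv_calls_b.tsv",
        "cnv_qc": outdir / "cnv_qc.tsv",
        "dgv": outdir / "dgv.tsv",
        "interactors": outdir / "interactors.tsv",
        "truth": outdir / "truth.json",
        "cnv_truth": outdir / "cnv_truth.tsv",
    }
    write_pedigree(ped, paths["pedigree"])
    write_vcf(table, paths["vcf"])
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    panel_a.to_csv(paths["panel_a"], sep="\t", index=False)
    panel_b.to_csv(paths["panel_b"], sep="\t", index=False)
    calls_a.to_csv(paths["cnv_calls_a"], sep="\t", index=False)
    calls_b.to_csv(paths["cnv_calls_b"], sep="\t", index=False)
    qc.to_csv(paths["cnv_qc"], sep="\t", index=False)
    dgv.to_csv(paths["dgv"], sep="\t", index=False)
    interactors.to_csv(paths["interactors"], sep="\t", index=False)
    write_truth(table, paths["truth"])
    cnv_truth.to_csv(paths["cnv_truth"], sep="\t", index=False)
    return paths
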