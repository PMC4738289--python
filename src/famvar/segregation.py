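"""Dominant co-segregation filter cascade for family exomes.

Six gates applied in order, each recording its survivor count:

1. site quality   — the caller's FILTER field is PASS;
2. coverage       — genotype called in at least ``min_called_samples``
                    of the sequenced samples (default n − 1);
3. segregation    — heterozygous in every affected sequenced member,
                    no alt allele in any called unaffected member;
4. exonic         — annotation region class is exonic;
5. novelty        — absent from every reference-panel known-site list;
6. consequence    — protein-altering (nonsynonymous, stop gain/loss,
                    frameshift); synonymous and in-frame indels drop.

The gates commute: only the per-stage counts depend on the order, the
surviving candidate set does not.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .pedigree import Pedigree, affected_partition


class Zygosity(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


_DOSAGE_TO_ZYGOSITY = {0: Zygosity.HOM_REF, 1: Zygosity.HET, 2: Zygosity.HOM_ALT}


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    zygosity: Zygosity

    @property
    def called(self) -> bool:
        return self.zygosity is not Zygosity.MISSING

    @property
    def carries_alt(self) -> bool:
        return self.zygosity in (Zygosity.HET, Zygosity.HOM_ALT)


class RegionClass(Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "utr"
    OTHER = "other"


class Consequence(Enum):
    SYNONYMOUS_SNV = "synonymous_snv"
    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    UNKNOWN = "unknown"


#: consequence classes retained by the cascade's final gate
DAMAGING_CONSEQUENCES = frozenset(
    {
        Consequence.NONSYNONYMOUS_SNV,
        Consequence.STOPGAIN,
        Consequence.STOPLOSS,
        Consequence.FRAMESHIFT_INDEL,
    }
)


@dataclass
class Annotation:
    """Functional annotation of one variant allele."""

    gene: str
    region_class: RegionClass
    consequence: Consequence = Consequence.UNKNOWN
    phylop: Optional[float] = None
    sift: Optional[float] = None
    polyphen_hdiv: Optional[float] = None
    aa_change: Optional[str] = None
    panel_known: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen_hdiv"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score {v} outside [0, 1]")


@dataclass
class VariantSite:
    """One biallelic VCF record with its per-sample genotype calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    site_pass: bool
    genotypes: dict[str, GenotypeCall]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_called(self) -> int:
        return sum(1 for g in self.genotypes.values() if g.called)


class PanelMatchMode(Enum):
    SITE = "site"
    ALLELE = "allele"


@dataclass(frozen=True)
class FilterConfig:
    """Tunable knobs of the cascade.

    ``min_called_samples=None`` means n_samples − 1, the study's
    5-of-6 convention generalised to any family size.
    """

    min_called_samples: Optional[int] = None
    allow_missing_in_unaffected: bool = True
    inheritance_model: str = "dominant"
    panel_match_mode: PanelMatchMode = PanelMatchMode.ALLELE

    def resolved_min_called(self, n_samples: int) -> int:
        m = self.min_called_samples
        if m is None:
            m = max(1, n_samples - 1)
        if m > n_samples:
            raise ValueError(
                f"min_called_samples={m} exceeds sample count {n_samples}"
            )
        return m


@dataclass
class FilterReport:
    """Survivor counts after each cascade stage, in application order."""

    n_input: int
    n_site_pass: int
    n_coverage_pass: int
    n_segregating: int
    n_exonic: int
    n_novel: int
    n_consequence_pass: int

    _STAGES = (
        "n_input",
        "n_site_pass",
        "n_coverage_pass",
        "n_segregating",
        "n_exonic",
        "n_novel",
        "n_consequence_pass",
    )

    def __post_init__(self) -> None:
        counts = self.counts()
        for a, b in zip(counts, counts[1:]):
            if b > a:
                raise ValueError(f"non-monotone cascade counts {counts}")

    def counts(self) -> list[int]:
        return [getattr(self, s) for s in self._STAGES]

    def to_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in self._STAGES}


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------

def site_quality_filter(v: VariantSite) -> bool:
    """Keep records whose FILTER field was PASS."""
    return v.site_pass


def coverage_filter(v: VariantSite, cfg: FilterConfig) -> bool:
    """Keep records genotype-called in at least ``min_called_samples``."""
    return v.n_called >= cfg.resolved_min_called(len(v.genotypes))


def segregation_pattern(v: VariantSite, ped: Pedigree, cfg: FilterConfig) -> bool:
    """Dominant co-segregation: het in all affected, alt-free unaffected.

    Only genotyped individuals are consulted (ungenotyped pedigree
    connectors are ignored). A missing genotype in an affected member
    fails the pattern; a missing genotype in an unaffected member is
    tolerated when ``allow_missing_in_unaffected`` (the coverage gate
    already bounds how many genotypes can be missing).
    """
    if cfg.inheritance_model != "dominant":
        raise NotImplementedError(
            f"inheritance model {cfg.inheritance_model!r} not implemented"
        )
    affected, _ = affected_partition(ped)
    saw_affected = False
    for sample_id, call in v.genotypes.items():
        if sample_id in affected:
            saw_affected = True
            if call.zygosity is not Zygosity.HET:
                return False
        else:
            if call.carries_alt:
                return False
            if not call.called and not cfg.allow_missing_in_unaffected:
                return False
    return saw_affected


def exonic_filter(a: Annotation) -> bool:
    """Keep exonic records."""
    return a.region_class is RegionClass.EXONIC


def novelty_filter(
    v: VariantSite,
    panels: Sequence[set],
    cfg: FilterConfig,
) -> bool:
    """Keep records absent from every panel known-site set.

    Panels are sets of ``(chrom, pos, ref, alt)`` tuples; in SITE mode
    only ``(chrom, pos)`` is compared.
    """
    if cfg.panel_match_mode is PanelMatchMode.ALLELE:
        key = v.key
        return not any(key in p for p in panels)
    site = (v.chrom, v.pos)
    for p in panels:
        for rec in p:
            if (rec[0], rec[1]) == site:
                return False
    return True


def consequence_filter(a: Annotation) -> bool:
    """Keep protein-altering consequences; drop variants of unknown
    significance (synonymous, in-frame indels, unclassified)."""
    return a.consequence in DAMAGING_CONSEQUENCES


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

class MissingAnnotationError(KeyError):
    pass


def _site_panels(panels: Sequence[Iterable[tuple]]) -> list[set]:
    return [set(map(tuple, p)) for p in panels]


def run_cascade(
    variants: Sequence[VariantSite],
    annotations: dict[tuple, Annotation],
    panels: Sequence[Iterable[tuple]],
    ped: Pedigree,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[tuple[VariantSite, Annotation]], FilterReport]:
    """Apply the six gates in cascade order and count survivors.

    ``annotations`` maps ``(chrom, pos, ref, alt)`` to an
    :class:`Annotation`; a variant reaching the exonic gate without one
    raises :class:`MissingAnnotationError`. Panel tables may be any
    iterables of ``(chrom, pos, ref, alt)`` rows.
    """
    if variants:
        vcf_samples = set(variants[0].genotypes)
        unknown = vcf_samples - set(ped.ids)
        if unknown:
            raise ValueError(
                f"VCF samples not in pedigree: {sorted(unknown)}"
            )
    panel_sets = _site_panels(panels)
    n_input = len(variants)
    stage = [v for v in variants if site_quality_filter(v)]
    n_site = len(stage)
    stage = [v for v in stage if coverage_filter(v, cfg)]
    n_cov = len(stage)
    stage = [v for v in stage if segregation_pattern(v, ped, cfg)]
    n_seg = len(stage)
    annotated = []
    for v in stage:
        a = annotations.get(v.key)
        if a is None:
            raise MissingAnnotationError(
                f"no annotation for variant {v.chrom}:{v.pos} {v.ref}>{v.alt}"
            )
        annotated.append((v, a))
    annotated = [(v, a) for v, a in annotated if exonic_filter(a)]
    n_exonic = len(annotated)
    kept = []
    for v, a in annotated:
        novel = novelty_filter(v, panel_sets, cfg)
        a.panel_known = not novel
        if novel:
            kept.append((v, a))
    n_novel = len(kept)
    candidates = [(v, a) for v, a in kept if consequence_filter(a)]
    report = FilterReport(
        n_input=n_input,
        n_site_pass=n_site,
        n_coverage_pass=n_cov,
        n_segregating=n_seg,
        n_exonic=n_exonic,
        n_novel=n_novel,
        n_consequence_pass=len(candidates),
    )
    return candidates, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read a multi-sample VCF into biallelic :class:`VariantSite`s.

    Multi-allelic records are split into one record per ALT, genotypes
    recoded against that ALT (other alt alleles count as non-carrier);
    a genotype with any missing allele is treated as uncalled.
    """
    import pysam

    out: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            site_pass = "PASS" in rec.filter or len(rec.filter) == 0
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                genotypes = {}
                for s in samples:
                    alleles = rec.samples[s].get("GT")
                    if alleles is None or any(a is None for a in alleles):
                        zyg = Zygosity.MISSING
                    else:
                        dosage = sum(1 for a in alleles if a == alt_index)
                        zyg = _DOSAGE_TO_ZYGOSITY[min(dosage, 2)]
                    genotypes[s] = GenotypeCall(s, zyg)
                out.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        site_pass=site_pass,
                        genotypes=genotypes,
                    )
                )
    return out


def load_annotations(path: str | Path) -> dict[tuple, Annotation]:
    """Load an annotation TSV keyed by (chrom, pos, ref, alt)."""
    import math

    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[tuple, Annotation] = {}

    def _num(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)

    for row in df.itertuples(index=False):
        cons = getattr(row, "consequence", None)
        if cons is None or (isinstance(cons, float) and math.isnan(cons)):
            cons = "unknown"
        aa = getattr(row, "aa_change", None)
        if isinstance(aa, float) and math.isnan(aa):
            aa = None
        out[(row.chrom, int(row.pos), row.ref, row.alt)] = Annotation(
            gene=row.gene,
            region_class=RegionClass(row.region_class),
            consequence=Consequence(cons),
            phylop=_num(row.phylop),
            sift=_num(row.sift),
            polyphen_hdiv=_num(row.polyphen_hdiv),
            aa_change=aa,
        )
    return out


def load_panel(path: str | Path) -> set[tuple]:
    """Load a panel known-site TSV into a set of (chrom,pos,ref,alt)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (row.chrom, int(row.pos), row.ref, row.alt)
        for row in df.itertuples(index=False)
    }


def variants_from_table(table) -> list[VariantSite]:
    """Convert an in-memory simulated :class:`~famvar.simulate.VariantTable`
    to :class:`VariantSite` records without a VCF round trip."""
    out = []
    for i in range(table.n_variants):
        genotypes = {
            s: GenotypeCall(
                s, _DOSAGE_TO_ZYGOSITY.get(int(table.genotypes[i, j]), Zygosity.MISSING)
            )
            for j, s in enumerate(table.samples)
        }
        out.append(
            VariantSite(
                chrom=table.chrom[i],
                pos=int(table.pos[i]),
                ref=table.ref[i],
                alt=table.alt[i],
                site_pass=bool(table.site_pass[i]),
                genotypes=genotypes,
            )
        )
    return out


def annotations_from_frame(df) -> dict[tuple, Annotation]:
    """Build the annotation lookup from an in-memory DataFrame."""
    import io

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return load_annotations(buf)


def write_candidates(
    candidates: Sequence[tuple[VariantSite, Annotation]], path: str | Path
) -> None:
    """Write surviving candidates as a TSV."""
    import pandas as pd

    rows = []
    for v, a in candidates:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": a.gene,
                "consequence": a.consequence.value,
                "aa_change": a.aa_change,
                "phylop": a.phylop,
                "sift": a.sift,
                "polyphen_hdiv": a.polyphen_hdiv,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence",
            "aa_change", "phylop", "sift", "polyphen_hdiv",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_report(report: FilterReport, path: str | Path, **metadata) -> None:
    payload = {"schema_version": 1, **metadata, "stages": report.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
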