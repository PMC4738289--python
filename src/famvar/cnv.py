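"""SNP-array CNV consensus between two callers, with rarity labelling.

All coordinates are 1-based inclusive (PennCNV convention); the length
of an interval is ``end - start + 1``.

Pipeline per sample: (1) drop samples failing array QC; (2) drop calls
with fewer than 3 consecutive SNPs or a confidence / log Bayes Factor
below 10; (3) merge same-state adjacent calls split by one caller;
(4) keep only segments seen by both callers with reciprocal overlap of
at least 50%, reported at the innermost (intersection) boundaries;
(5) label each consensus CNV rare or common against a DGV-like
structural-variant catalogue: common iff some catalogue record covers
at least half the CNV, or the catalogue records overlapping it carry
at least 20 supporting structural variants in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

DEFAULT_MIN_SNPS = 3
DEFAULT_MIN_CONFIDENCE = 10.0
DEFAULT_MIN_OVERLAP = 0.5
DGV_COMMON_OVERLAP = 0.5
DGV_COMMON_SUPPORT = 20


@dataclass(frozen=True)
class SampleQcMetrics:
    """Per-sample array noise statistics gating CNV calling."""

    sample_id: str
    lrr_sd: float
    baf_drift: float
    waviness: float
    baf_sd: float


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV call, 1-based inclusive."""

    sample_id: str
    caller: str  # "A" (PennCNV-style) or "B" (QuantiSNP-style)
    chrom: str
    start: int
    end: int
    state: str  # "deletion" | "duplication"
    n_snps: int
    confidence: float
    merged_from_split: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusCnv:
    """Innermost-boundary consensus of overlapping calls from both callers."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    source_calls: tuple[CnvCall, ...]
    merged_from_split: bool = False
    rarity: str = "unassessed"  # "rare" | "common" | "unassessed"

    def __post_init__(self) -> None:
        callers = {c.caller for c in self.source_calls}
        if not {"A", "B"} <= callers:
            raise ValueError("consensus requires contributing calls from both callers")
        for c in self.source_calls:
            if not (c.start <= self.start and self.end <= c.end):
                raise ValueError(
                    f"consensus [{self.start},{self.end}] not contained in "
                    f"source call [{c.start},{c.end}]"
                )
        if any(c.state != self.state for c in self.source_calls):
            raise ValueError("source call states disagree")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SvDatabaseRecord:
    chrom: str
    start: int
    end: int
    n_supporting: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_supporting < 1:
            raise ValueError("n_supporting must be >= 1")


# ---------------------------------------------------------------------------
# QC and call-level filtering
# ---------------------------------------------------------------------------

def sample_qc(metrics: SampleQcMetrics, caller: str) -> bool:
    """Sample-level array QC.

    Caller A (PennCNV rule): LRR SD < 0.35 AND BAF drift < 0.002 AND
    waviness strictly between -0.04 and 0.04. Caller B (QuantiSNP
    rule): LRR SD < 0.3 OR BAF SD < 0.15.
    """
    if caller == "A":
        return (
            metrics.lrr_sd < 0.35
            and metrics.baf_drift < 0.002
            and -0.04 < metrics.waviness < 0.04
        )
    if caller == "B":
        return metrics.lrr_sd < 0.3 or metrics.baf_sd < 0.15
    raise ValueError(f"unknown caller {caller!r}")


def call_filter(
    c: CnvCall,
    min_snps: int = DEFAULT_MIN_SNPS,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> bool:
    """Keep calls spanning >= 3 SNPs with confidence/log-BF >= 10."""
    return c.n_snps >= min_snps and c.confidence >= min_confidence


def merge_adjacent(calls: Sequence[CnvCall], max_gap: int = 1000) -> list[CnvCall]:
    """Union same-state adjacent calls split by one caller.

    Calls must belong to one sample and caller. Two same-state calls on
    one chromosome whose gap is at most ``max_gap`` bp merge into one
    call spanning their union, with summed SNP counts and the maximum
    confidence. Overlapping calls of opposite state are an input error.
    """
    if not calls:
        return []
    ids = {(c.sample_id, c.caller) for c in calls}
    if len(ids) > 1:
        raise ValueError(f"merge_adjacent expects one sample+caller, got {ids}")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start <= a.end and a.state != b.state:
            raise ValueError(
                f"overlapping opposite-state calls at {a.chrom}:{a.start}-{a.end}"
                f" / {b.start}-{b.end}"
            )
    out: list[CnvCall] = []
    cur = ordered[0]
    for nxt in ordered[1:]:
        same_run = (
            nxt.chrom == cur.chrom
            and nxt.state == cur.state
            and nxt.start - cur.end - 1 <= max_gap
        )
        if same_run:
            cur = replace(
                cur,
                end=max(cur.end, nxt.end),
                n_snps=cur.n_snps + nxt.n_snps,
                confidence=max(cur.confidence, nxt.confidence),
                merged_from_split=True,
            )
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


# ---------------------------------------------------------------------------
# Overlap and consensus
# ---------------------------------------------------------------------------

def overlap_fraction(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> tuple[float, float]:
    """Shared bases of two 1-based inclusive intervals as fractions.

    Returns (shared/len(a), shared/len(b)); (0, 0) when the intervals
    are disjoint or on different chromosomes.
    """
    chrom_a, sa, ea = a
    chrom_b, sb, eb = b
    if sa > ea or sb > eb:
        raise ValueError("interval start exceeds end")
    if chrom_a != chrom_b:
        return (0.0, 0.0)
    shared = min(ea, eb) - max(sa, sb) + 1
    if shared <= 0:
        return (0.0, 0.0)
    return (shared / (ea - sa + 1), shared / (eb - sb + 1))


def consensus(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    reciprocal: bool = True,
) -> list[ConsensusCnv]:
    """Two-caller consensus at innermost boundaries.

    A pair (a, b) with matching sample, chromosome and state whose
    overlap meets ``min_overlap`` — reciprocally (both fractions) by
    default, or in either direction with ``reciprocal=False`` — yields
    one consensus CNV spanning the intersection ``[max(starts),
    min(ends)]``. Calls supported by a single caller are dropped.
    Inputs should already be call-filtered and split-merged.
    """
    out = []
    for a in sorted(calls_a, key=lambda c: (c.sample_id, c.chrom, c.start)):
        for b in calls_b:
            if (
                a.sample_id != b.sample_id
                or a.chrom != b.chrom
                or a.state != b.state
            ):
                continue
            fa, fb = overlap_fraction(
                (a.chrom, a.start, a.end), (b.chrom, b.start, b.end)
            )
            ok = (
                fa >= min_overlap and fb >= min_overlap
                if reciprocal
                else fa >= min_overlap or fb >= min_overlap
            )
            if not ok:
                continue
            out.append(
                ConsensusCnv(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    start=max(a.start, b.start),
                    end=min(a.end, b.end),
                    state=a.state,
                    source_calls=(a, b),
                    merged_from_split=a.merged_from_split or b.merged_from_split,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Rarity against a DGV-like catalogue
# ---------------------------------------------------------------------------

def rarity(
    cnv: ConsensusCnv,
    dgv: Sequence[SvDatabaseRecord],
    per_record_support: bool = False,
) -> str:
    """Label a consensus CNV rare or common against the SV catalogue.

    Overlap is measured one-way as the fraction of the family CNV
    covered by a catalogue record (catalogue records vary hugely in
    size; reciprocal overlap would misclassify CNVs nested inside large
    records). Common iff best coverage >= 0.5 OR supporting-variant
    count >= 20, summed over overlapping records by default
    (``per_record_support=True`` asks any single record to reach 20).
    """
    tree = IntervalTree()
    for rec in dgv:
        if rec.chrom == cnv.chrom:
            tree.addi(rec.start, rec.end + 1, rec.n_supporting)  # half-open
    hits = tree.overlap(cnv.start, cnv.end + 1)
    best_cov = 0.0
    total_support = 0
    max_support = 0
    for hit in hits:
        frac_cnv, _ = overlap_fraction(
            (cnv.chrom, cnv.start, cnv.end), (cnv.chrom, hit.begin, hit.end - 1)
        )
        best_cov = max(best_cov, frac_cnv)
        total_support += hit.data
        max_support = max(max_support, hit.data)
    support = max_support if per_record_support else total_support
    common = best_cov >= DGV_COMMON_OVERLAP or support >= DGV_COMMON_SUPPORT
    return "common" if common else "rare"


def run_cnv_pipeline(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    qc: dict[str, SampleQcMetrics],
    dgv: Sequence[SvDatabaseRecord],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    max_gap: int = 1000,
    reciprocal: bool = True,
    per_record_support: bool = False,
) -> list[ConsensusCnv]:
    """QC → call filter → split-merge → consensus → rarity, per sample."""
    pass_a = {s for s, m in qc.items() if sample_qc(m, "A")}
    pass_b = {s for s, m in qc.items() if sample_qc(m, "B")}
    keep = pass_a & pass_b
    out: list[ConsensusCnv] = []
    samples = sorted(
        {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    )
    for sample in samples:
        if sample not in keep:
            continue
        merged = {}
        for caller, calls in (("A", calls_a), ("B", calls_b)):
            mine = [c for c in calls if c.sample_id == sample and call_filter(c)]
            per_state = []
            for chrom in sorted({c.chrom for c in mine}):
                for state in ("deletion", "duplication"):
                    group = [c for c in mine if c.chrom == chrom and c.state == state]
                    per_state.extend(merge_adjacent(group, max_gap=max_gap))
            merged[caller] = per_state
        for cns in consensus(
            merged["A"], merged["B"], min_overlap=min_overlap, reciprocal=reciprocal
        ):
            out.append(
                replace(cns, rarity=rarity(cns, dgv, per_record_support=per_record_support))
            )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_calls(path: str | Path, caller: str) -> list[CnvCall]:
    """Read a caller's call TSV (1-based inclusive coordinates)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CnvCall(
            sample_id=row.sample,
            caller=caller,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            state=row.state,
            n_snps=int(row.n_snps),
            confidence=float(row.confidence),
        )
        for row in df.itertuples(index=False)
    ]


def load_qc(path: str | Path) -> dict[str, SampleQcMetrics]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        row.sample: SampleQcMetrics(
            sample_id=row.sample,
            lrr_sd=float(row.lrr_sd),
            baf_drift=float(row.baf_drift),
            waviness=float(row.waviness),
            baf_sd=float(row.baf_sd),
        )
        for row in df.itertuples(index=False)
    }


def load_dgv(path: str | Path) -> list[SvDatabaseRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SvDatabaseRecord(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            n_supporting=int(row.n_supporting),
        )
        for row in df.itertuples(index=False)
    ]


def write_consensus(cnvs: Sequence[ConsensusCnv], path: str | Path) -> None:
    """Write consensus CNVs as a BED-like TSV (1-based inclusive)."""
    import pandas as pd

    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.chrom,
            "start_1based": c.start,
            "end_1based": c.end,
            "state": c.state,
            "rarity": c.rarity,
            "merged_from_split": c.merged_from_split,
            "n_source_calls": len(c.source_calls),
        }
        for c in cnvs
    ]
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        pd.DataFrame(
            rows,
            columns=[
                "sample", "chrom", "start_1based", "end_1based",
                "state", "rarity", "merged_from_split", "n_source_calls",
            ],
        ).to_csv(fh, sep="\t", index=False)


def summary_json(cnvs: Sequence[ConsensusCnv]) -> str:
    by_rarity = {"rare": 0, "common": 0, "unassessed": 0}
    for c in cnvs:
        by_rarity[c.rarity] += 1
    return json.dumps(
        {"schema_version": 1, "n_consensus": len(cnvs), "by_rarity": by_rarity},
        indent=2,
    )
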