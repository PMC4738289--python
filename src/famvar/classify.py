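"""Deleteriousness classification and the lysine-change screen.

Thresholds follow the standard interpretation of each score: SIFT
substitution-tolerance scores at or below 0.05 are deleterious,
PolyPhen2-HDIV probabilities at or above 0.95 are damaging, and a
strictly positive PhyloP score marks a conserved base. Only the two
protein-level predictors (SIFT, PolyPhen2) feed ``any_deleterious``;
PhyloP conservation is reported alongside but base-level conservation
alone is not evidence of protein damage. A null score yields a null
call and never counts toward ``any_deleterious``.

The lysine screen flags amino-acid substitutions that remove or
introduce a lysine (K) — the acceptor residue of ubiquitination — as a
fast surrogate for a full ubiquitination-site prediction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .segregation import Annotation

SIFT_DELETERIOUS_MAX = 0.05
POLYPHEN_DAMAGING_MIN = 0.95

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_AA_CHANGE_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class DeleteriousnessCall:
    """Per-variant verdicts of the three annotation scores."""

    sift_deleterious: Optional[bool]
    polyphen_damaging: Optional[bool]
    phylop_conserved: Optional[bool]

    @property
    def any_deleterious(self) -> bool:
        return self.sift_deleterious is True or self.polyphen_damaging is True


def classify_scores(a: Annotation) -> DeleteriousnessCall:
    """Apply the score thresholds to one annotation.

    Pure function; thresholds are inclusive exactly as conventionally
    printed (SIFT <= 0.05, PolyPhen2 >= 0.95, PhyloP > 0).
    """
    for name in ("sift", "polyphen_hdiv"):
        v = getattr(a, name)
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} score {v} outside [0, 1]")
    return DeleteriousnessCall(
        sift_deleterious=None if a.sift is None else a.sift <= SIFT_DELETERIOUS_MAX,
        polyphen_damaging=(
            None if a.polyphen_hdiv is None else a.polyphen_hdiv >= POLYPHEN_DAMAGING_MIN
        ),
        phylop_conserved=None if a.phylop is None else a.phylop > 0,
    )


def count_any_deleterious(calls: Iterable[DeleteriousnessCall]) -> int:
    """Number of calls flagged deleterious by at least one protein-level
    predictor."""
    return sum(1 for c in calls if c.any_deleterious)


@dataclass(frozen=True)
class AminoAcidChange:
    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in _STANDARD_AA:
                raise ValueError(f"non-standard amino acid code {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"no change: {self.ref_aa}{self.position}{self.alt_aa}")
        if self.position < 1:
            raise ValueError(f"residue position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


def parse_aa_change(s: str) -> AminoAcidChange:
    """Parse a one-letter substitution string like ``p.G88R``."""
    m = _AA_CHANGE_RE.match(s.strip())
    if m is None:
        raise ValueError(f"malformed amino-acid change {s!r}")
    return AminoAcidChange(ref_aa=m.group(1), position=int(m.group(2)), alt_aa=m.group(3))


def lysine_change_flag(c: AminoAcidChange) -> bool:
    """True iff the substitution removes or introduces a lysine."""
    return c.ref_aa == "K" or c.alt_aa == "K"


def classify_candidates(candidates) -> list[dict]:
    """Classify a list of (VariantSite, Annotation) cascade survivors.

    Returns one row per candidate with score verdicts and the lysine
    flag (null when no amino-acid change is annotated).
    """
    rows = []
    for v, a in candidates:
        call = classify_scores(a)
        lys = None
        if a.aa_change:
            lys = lysine_change_flag(parse_aa_change(a.aa_change))
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": a.gene,
                "aa_change": a.aa_change,
                "sift_deleterious": call.sift_deleterious,
                "polyphen_damaging": call.polyphen_damaging,
                "phylop_conserved": call.phylop_conserved,
                "any_deleterious": call.any_deleterious,
                "lysine_change": lys,
            }
        )
    return rows
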