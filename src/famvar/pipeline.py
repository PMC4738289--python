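"""End-to-end orchestration: cascade → classification → CNV → burden.

Takes a directory of study inputs (as written by
:func:`famvar.simulate.simulate_study` or assembled from real caller
outputs), runs every analysis stage, and writes a reproducible report
bundle. All randomness lives in the simulator; given fixed inputs the
pipeline is deterministic and reruns produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import burden as burden_mod
from . import classify as classify_mod
from . import cnv as cnv_mod
from . import segregation as seg
from .pedigree import load_pedigree

log = logging.getLogger("famvar")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and options for one full run."""

    pedigree: Path
    vcf: Path
    annotations: Path
    panels: list[Path]
    cnv_calls_a: Optional[Path] = None
    cnv_calls_b: Optional[Path] = None
    cnv_qc: Optional[Path] = None
    dgv: Optional[Path] = None
    interactors: Optional[Path] = None
    out_dir: Path = Path("famvar-out")
    filter_config: seg.FilterConfig = field(default_factory=seg.FilterConfig)
    min_overlap: float = 0.5
    max_gap: int = 1000
    reciprocal_overlap: bool = True
    per_record_support: bool = False
    burden_test: str = "welch"
    seed: Optional[int] = None

    @classmethod
    def from_dir(cls, indir: str | Path, out_dir: str | Path, **options) -> "PipelineConfig":
        """Configuration for a directory laid out by ``simulate_study``."""
        indir = Path(indir)
        return cls(
            pedigree=indir / "family.ped",
            vcf=indir / "variants.vcf",
            annotations=indir / "annotations.tsv",
            panels=[indir / "panel_a.tsv", indir / "panel_b.tsv"],
            cnv_calls_a=indir / "cnv_calls_a.tsv",
            cnv_calls_b=indir / "cnv_calls_b.tsv",
            cnv_qc=indir / "cnv_qc.tsv",
            dgv=indir / "dgv.tsv",
            interactors=indir / "interactors.tsv",
            out_dir=Path(out_dir),
            **options,
        )

    def validate(self) -> None:
        required = [self.pedigree, self.vcf, self.annotations, *self.panels]
        optional = [
            self.cnv_calls_a, self.cnv_calls_b, self.cnv_qc, self.dgv, self.interactors,
        ]
        for p in required:
            if not Path(p).exists():
                raise ConfigError(f"required input missing: {p}")
        for p in optional:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input missing: {p}")

    def content_hash(self) -> str:
        digest = hashlib.sha256()
        for p in [self.pedigree, self.vcf, self.annotations, *self.panels]:
            digest.update(Path(p).read_bytes())
        digest.update(
            json.dumps(
                {
                    "min_overlap": self.min_overlap,
                    "max_gap": self.max_gap,
                    "reciprocal": self.reciprocal_overlap,
                    "burden_test": self.burden_test,
                },
                sort_keys=True,
            ).encode()
        )
        return digest.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``cfg.out_dir``.

    Returns the summary dictionary that is also written to
    ``report.json``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "famvar_version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
    }

    log.info("loading pedigree %s", cfg.pedigree)
    ped = load_pedigree(cfg.pedigree)
    variants = seg.read_vcf(cfg.vcf)
    annotations = seg.load_annotations(cfg.annotations)
    panels = [seg.load_panel(p) for p in cfg.panels]

    log.info("running filter cascade on %d records", len(variants))
    candidates, report = seg.run_cascade(
        variants, annotations, panels, ped, cfg.filter_config
    )
    seg.write_candidates(candidates, out / "candidates.tsv")
    seg.write_report(report, out / "filter_report.json", **meta)

    classification = classify_mod.classify_candidates(candidates)
    import pandas as pd

    pd.DataFrame(
        classification,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "aa_change",
            "sift_deleterious", "polyphen_damaging", "phylop_conserved",
            "any_deleterious", "lysine_change",
        ],
    ).to_csv(out / "classification.tsv", sep="\t", index=False)

    summary: dict = {
        "schema_version": 1,
        **meta,
        "filter_report": report.to_dict(),
        "n_candidates": len(candidates),
        "n_any_deleterious": sum(1 for r in classification if r["any_deleterious"]),
        "n_lysine_change": sum(1 for r in classification if r["lysine_change"]),
    }

    if cfg.cnv_calls_a and cfg.cnv_calls_b and cfg.cnv_qc and cfg.dgv:
        log.info("running CNV consensus")
        consensus_cnvs = cnv_mod.run_cnv_pipeline(
            cnv_mod.load_calls(cfg.cnv_calls_a, "A"),
            cnv_mod.load_calls(cfg.cnv_calls_b, "B"),
            cnv_mod.load_qc(cfg.cnv_qc),
            cnv_mod.load_dgv(cfg.dgv),
            min_overlap=cfg.min_overlap,
            max_gap=cfg.max_gap,
            reciprocal=cfg.reciprocal_overlap,
            per_record_support=cfg.per_record_support,
        )
        cnv_mod.write_consensus(consensus_cnvs, out / "cnv_consensus.tsv")
        summary["cnv"] = json.loads(cnv_mod.summary_json(consensus_cnvs))

    if cfg.interactors:
        log.info("running burden test")
        annotated = []
        for v in variants:
            a = annotations.get(v.key)
            if a is not None:
                annotated.append((v, a))
        results = []
        skipped = []
        for iset in burden_mod.load_interactors(cfg.interactors):
            try:
                results.extend(
                    burden_mod.run_burden(
                        annotated,
                        ped,
                        [iset],
                        panels=panels,
                        filter_cfg=cfg.filter_config,
                        test=cfg.burden_test,
                    )
                )
            except burden_mod.DegenerateVarianceError as exc:
                log.warning("burden tier %s degenerate: %s", iset.tier, exc)
                skipped.append({"tier": iset.tier, "error": str(exc)})
        burden_mod.write_burden(results, out / "burden.json")
        summary["burden"] = [r.to_dict() for r in results]
        if skipped:
            summary["burden_skipped"] = skipped

    (out / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "report.txt").write_text(render_text_report(summary))
    return summary


_STAGE_LABELS = [
    ("n_input", "input records"),
    ("n_site_pass", "site quality PASS"),
    ("n_coverage_pass", "coverage (min called samples)"),
    ("n_segregating", "dominant co-segregation"),
    ("n_exonic", "exonic"),
    ("n_novel", "novel (panel-absent)"),
    ("n_consequence_pass", "protein-altering"),
]


def render_text_report(summary: dict) -> str:
    """Human-readable cascade report in fixed stage order."""
    head = f"config hash: {summary.get('config_hash')}"
    if summary.get("seed") is not None:
        head += f"  seed: {summary['seed']}"
    lines = [
        f"famvar {summary.get('famvar_version', '?')} report",
        head,
        "",
        "Filter cascade:",
    ]
    stages = summary["filter_report"]
    for key, label in _STAGE_LABELS:
        lines.append(f"  {label:<32} {stages[key]:>8}")
    lines.append("")
    lines.append(f"{summary['n_candidates']} candidates")
    lines.append(
        f"  deleterious by >=1 protein-level predictor: {summary['n_any_deleterious']}"
    )
    lines.append(f"  lysine-affecting changes: {summary['n_lysine_change']}")
    if "cnv" in summary:
        c = summary["cnv"]
        lines.append("")
        lines.append(
            f"CNV consensus: {c['n_consensus']} calls "
            f"({c['by_rarity']['rare']} rare, {c['by_rarity']['common']} common)"
        )
    if "burden" in summary:
        lines.append("")
        lines.append("Burden test (affected vs unaffected):")
        for r in summary["burden"]:
            lines.append(
                f"  {r['tier']}-confidence tier: "
                f"mean {r['mean_trait']:.2f} vs {r['mean_other']:.2f}, "
                f"t={r['t_statistic']:.3f}, df={r['df']:.2f}, p={r['p_value']:.4f}"
            )
        for r in summary.get("burden_skipped", ()):
            lines.append(
                f"  {r['tier']}-confidence tier: no finite t ({r['error']})"
            )
    return "\n".join(lines) + "\n"
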