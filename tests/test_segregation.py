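"""Filter cascade: individual gates, worked genotype patterns, oracle
equivalence, planted-variant recovery and leakage."""

import numpy as np
import pytest

from famvar.segregation import (
    FilterConfig,
    FilterReport,
    MissingAnnotationError,
    PanelMatchMode,
    annotations_from_frame,
    consequence_filter,
    coverage_filter,
    exonic_filter,
    novelty_filter,
    read_vcf,
    run_cascade,
    segregation_pattern,
    site_quality_filter,
    variants_from_table,
)
from famvar.simulate import (
    SimulationConfig,
    plant_trait_variant,
    simulate_annotations,
    simulate_genotypes,
    simulate_panel_sites,
    simulate_study,
)

from ._oracles import brute_force_candidates
from .conftest import make_annotation, make_variant

CFG = FilterConfig()


class TestGates:
    def test_site_quality(self):
        assert site_quality_filter(make_variant({}, site_pass=True))
        assert not site_quality_filter(make_variant({}, site_pass=False))

    @pytest.mark.parametrize(
        "n_missing,expected", [(0, True), (1, True), (2, False)]
    )
    def test_coverage_five_of_six(self, n_missing, expected):
        samples = ["III.1", "III.2"][:n_missing]
        v = make_variant({s: "missing" for s in samples})
        assert coverage_filter(v, CFG) is expected

    def test_exonic(self):
        assert exonic_filter(make_annotation(region="exonic"))
        assert not exonic_filter(make_annotation(region="intronic"))
        toy = [make_annotation(region=r) for r in ("exonic", "utr", "exonic")]
        assert sum(exonic_filter(a) for a in toy) == 2

    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("nonsynonymous_snv", True),
            ("stopgain", True),
            ("stoploss", True),
            ("frameshift_indel", True),
            ("synonymous_snv", False),
            ("nonframeshift_indel", False),
            ("unknown", False),
        ],
    )
    def test_consequence(self, consequence, expected):
        assert consequence_filter(make_annotation(consequence=consequence)) is expected

    def test_novelty_allele_vs_site_mode(self):
        v = make_variant({}, chrom="chr1", pos=100, ref="A", alt="G")
        panel = {("chr1", 100, "A", "T")}  # same site, different alt
        assert novelty_filter(v, [panel], CFG)  # allele mode: still novel
        site_cfg = FilterConfig(panel_match_mode=PanelMatchMode.SITE)
        assert not novelty_filter(v, [panel], site_cfg)
        assert not novelty_filter(v, [{v.key}], CFG)
        assert novelty_filter(v, [], CFG)  # empty panels: everything novel


class TestSegregationPattern:
    def test_co_segregating_pattern_passes(self, sequenced_family):
        v = make_variant({"II.3": "het", "III.3": "het"})
        assert segregation_pattern(v, sequenced_family, CFG)

    def test_unaffected_carrier_fails(self, sequenced_family):
        v = make_variant({"II.3": "het", "III.3": "het", "III.4": "het"})
        assert not segregation_pattern(v, sequenced_family, CFG)

    def test_proband_only_fails_co_segregation(self, sequenced_family):
        # the pattern of the variant validated only in the proband
        v = make_variant({"III.3": "het"})
        assert not segregation_pattern(v, sequenced_family, CFG)

    def test_hom_alt_affected_fails(self, sequenced_family):
        v = make_variant({"II.3": "hom_alt", "III.3": "het"})
        assert not segregation_pattern(v, sequenced_family, CFG)

    def test_missing_affected_fails(self, sequenced_family):
        v = make_variant({"II.3": "missing", "III.3": "het"})
        assert not segregation_pattern(v, sequenced_family, CFG)

    def test_missing_unaffected_tolerated_by_default(self, sequenced_family):
        v = make_variant({"II.3": "het", "III.3": "het", "III.1": "missing"})
        assert segregation_pattern(v, sequenced_family, CFG)
        strict = FilterConfig(allow_missing_in_unaffected=False)
        assert not segregation_pattern(v, sequenced_family, strict)

    def test_ungenotyped_pedigree_members_ignored(self, family):
        # full pedigree has ungenotyped connectors (I.1, II.2, ...)
        v = make_variant({"II.3": "het", "III.3": "het"})
        assert segregation_pattern(v, family, CFG)


class TestValidatedPatternsWorkedExample:
    """The four wet-lab-validated genotype patterns: three het in father
    and proband only, one het in the proband only."""

    def variants(self):
        co_seg = {"II.3": "het", "III.3": "het"}
        return [
            make_variant(co_seg, chrom="chr11", pos=8161603, ref="C", alt="T"),
            make_variant(co_seg, chrom="chr6", pos=3105973, ref="C", alt="G"),
            make_variant(co_seg, chrom="chr11", pos=10874596, ref="G", alt="A"),
            make_variant({"III.3": "het"}, chrom="chr15", pos=28491062, ref="T", alt="A"),
        ]

    def test_three_pass_one_fails(self, sequenced_family):
        flags = [
            segregation_pattern(v, sequenced_family, CFG) for v in self.variants()
        ]
        assert sum(flags) == 3
        assert flags[-1] is False  # the proband-only variant

    def test_cascade_keeps_three(self, sequenced_family):
        variants = self.variants()
        annotations = {
            v.key: make_annotation(gene=g, aa_change=aa)
            for v, g, aa in zip(
                variants,
                ["RIC3", "RIPK1", "ZBED5", "HERC2"],
                ["p.G88R", "p.Q422E", "p.R633C", "p.D1181V"],
            )
        }
        candidates, report = run_cascade(
            variants, annotations, [], sequenced_family, CFG
        )
        assert len(candidates) == 3
        assert report.n_segregating == 3


class TestFilterReport:
    def test_monotone_enforced(self):
        with pytest.raises(ValueError, match="non-monotone"):
            FilterReport(10, 12, 8, 5, 4, 3, 2)

    def test_counts_order(self):
        r = FilterReport(200, 150, 140, 40, 12, 9, 5)
        assert r.counts() == [200, 150, 140, 40, 12, 9, 5]


class TestCascade:
    def _study(self, seed, **kw):
        kw.setdefault("n_variants", 150)
        kw.setdefault("site_fail_rate", 0.3)
        kw.setdefault("missing_call_rate", 0.05)
        cfg = SimulationConfig(seed=seed, **kw)
        ped = __import__("famvar.simulate", fromlist=["family_pedigree"]).family_pedigree()
        t = simulate_genotypes(ped, cfg)
        plant_trait_variant(t, ped, {"II.3", "III.3"})
        ann_df = simulate_annotations(t, cfg)
        pa, pb = simulate_panel_sites(t, cfg)
        variants = variants_from_table(t)
        annotations = annotations_from_frame(ann_df)
        panels = [
            set(map(tuple, pa.itertuples(index=False))),
            set(map(tuple, pb.itertuples(index=False))),
        ]
        return ped, t, variants, annotations, panels

    def test_planted_variant_survives(self):
        ped, t, variants, annotations, panels = self._study(3)
        candidates, _ = run_cascade(variants, annotations, panels, ped, CFG)
        keys = {v.key for v, _ in candidates}
        i = int(np.where(t.planted)[0][0])
        assert (t.chrom[i], t.pos[i], t.ref[i], t.alt[i]) in keys

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        """Candidate set identical to an independent per-variant rule check."""
        ped, _, variants, annotations, panels = self._study(seed)
        candidates, report = run_cascade(variants, annotations, panels, ped, CFG)
        got = {v.key for v, _ in candidates}
        expected = brute_force_candidates(variants, annotations, panels, ped, 5)
        assert got == expected
        assert report.counts() == sorted(report.counts(), reverse=True)

    @pytest.mark.parametrize("seed", range(100))
    def test_planted_recovery_clean_runs(self, seed):
        """100% recovery with no missingness; no unaffected-carrier leak."""
        ped, t, variants, annotations, panels = self._study(
            1000 + seed, missing_call_rate=0.0, n_variants=60,
        )
        candidates, _ = run_cascade(variants, annotations, panels, ped, CFG)
        keys = {v.key for v, _ in candidates}
        i = int(np.where(t.planted)[0][0])
        assert (t.chrom[i], t.pos[i], t.ref[i], t.alt[i]) in keys
        unaffected = {"II.4", "III.1", "III.2", "III.4"}
        for v, _ in candidates:
            for s in unaffected:
                assert not v.genotypes[s].carries_alt

    def test_order_invariance_of_membership(self):
        """Gate order changes per-stage counts, never the candidate set."""
        import itertools

        ped, _, variants, annotations, panels = self._study(5)
        from famvar import segregation as sg

        gates = {
            "site": lambda v, a: sg.site_quality_filter(v),
            "cov": lambda v, a: sg.coverage_filter(v, CFG),
            "seg": lambda v, a: sg.segregation_pattern(v, ped, CFG),
            "exon": lambda v, a: sg.exonic_filter(a),
            "novel": lambda v, a: sg.novelty_filter(v, panels, CFG),
            "cons": lambda v, a: sg.consequence_filter(a),
        }
        reference = None
        for order in itertools.islice(itertools.permutations(gates), 0, 720, 103):
            kept = {
                v.key
                for v in variants
                if all(gates[g](v, annotations[v.key]) for g in order)
            }
            if reference is None:
                reference = kept
            assert kept == reference

    def test_sample_mismatch_rejected(self, sequenced_family):
        v = make_variant({"II.3": "het"})
        v.genotypes["GHOST"] = v.genotypes.pop("III.4")
        with pytest.raises(ValueError, match="GHOST"):
            run_cascade([v], {}, [], sequenced_family, CFG)

    def test_missing_annotation_names_variant(self, sequenced_family):
        v = make_variant({"II.3": "het", "III.3": "het"}, chrom="chr5", pos=42)
        with pytest.raises(MissingAnnotationError, match="chr5:42"):
            run_cascade([v], {}, [], sequenced_family, CFG)


class TestVcfRoundTrip:
    def test_vcf_read_back_matches_table(self, tmp_path, family):
        cfg = SimulationConfig(seed=9, n_variants=120, missing_call_rate=0.05)
        paths = simulate_study(tmp_path, cfg, ped=family)
        variants = read_vcf(paths["vcf"])
        assert len(variants) == 121  # planted record included
        t_pass = sum(v.site_pass for v in variants)
        assert 0 < t_pass < len(variants)
        by_key = {v.key: v for v in variants}
        assert len(by_key) == len(variants)

    def test_multiallelic_split(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        )
        variants = read_vcf(vcf)
        assert len(variants) == 2
        first, second = variants
        assert (first.alt, second.alt) == ("G", "T")
        assert first.genotypes["S1"].zygosity.value == "het"
        assert first.genotypes["S2"].zygosity.value == "het"
        assert second.genotypes["S1"].zygosity.value == "hom_ref"
        assert second.genotypes["S2"].zygosity.value == "het"
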