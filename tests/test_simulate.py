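"""Synthetic-study generator: Mendelian consistency, planting, determinism."""

import numpy as np
import pytest

from famvar.pedigree import Individual, Pedigree
from famvar.simulate import (
    MISSING,
    SEQUENCED_SAMPLES,
    SimulationConfig,
    family_pedigree,
    gene_drop,
    plant_trait_variant,
    simulate_annotations,
    simulate_cnv_callsets,
    simulate_genotypes,
    simulate_interactors,
    simulate_panel_sites,
    simulate_study,
    simulate_sv_database,
)

from ._oracles import enumerate_pattern_probability


def small_cfg(**kw):
    defaults = dict(seed=7, n_variants=300, site_fail_rate=0.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGeneDrop:
    def test_monomorphic_site_all_hom_ref(self, family):
        cfg = small_cfg(allele_frequency_distribution=("fixed", 0.0))
        t = simulate_genotypes(family, cfg)
        assert np.all(t.genotypes == 0)

    def test_fixed_site_all_hom_alt(self, family):
        cfg = small_cfg(allele_frequency_distribution=("fixed", 1.0))
        t = simulate_genotypes(family, cfg)
        assert np.all(t.genotypes == 2)

    def test_mendelian_consistency_exhaustive(self, family, rng):
        """Every child dosage must be constructible from its parents'."""
        cfg = small_cfg(n_variants=2000, allele_frequency_distribution=("fixed", 0.4))
        t = simulate_genotypes(family, cfg, rng=rng)
        col = {s: k for k, s in enumerate(t.pedigree_ids)}
        for ind in family:
            if ind.is_founder:
                continue
            gc = t.full_genotypes[:, col[ind.id]]
            gf = t.full_genotypes[:, col[ind.father_id]]
            gm = t.full_genotypes[:, col[ind.mother_id]]
            # allele from father in {0,1} iff gf/2 allows it, same for mother
            min_child = (gf == 2).astype(int) + (gm == 2).astype(int)
            max_child = (gf > 0).astype(int) + (gm > 0).astype(int)
            assert np.all(gc >= min_child)
            assert np.all(gc <= max_child)

    def test_founder_allele_frequency_recovery(self, rng):
        """Founder alt-allele fraction converges on the drawn frequency."""
        founders = Pedigree([Individual(f"F{i}") for i in range(200)])
        cfg = small_cfg(n_variants=200, allele_frequency_distribution=("beta", 2, 2))
        ids, G = gene_drop(founders, np.full(500, 0.3), rng)
        freq_hat = G.mean() / 2.0
        se = np.sqrt(0.3 * 0.7 / (2 * 200 * 500))
        assert abs(freq_hat - 0.3) < 4 * se

    def test_sample_not_in_pedigree_rejected(self, family):
        with pytest.raises(ValueError, match="not in the pedigree"):
            simulate_genotypes(family, small_cfg(), samples=("II.3", "GHOST"))

    def test_missingness_rate_applied(self, family):
        cfg = small_cfg(n_variants=3000, missing_call_rate=0.1)
        t = simulate_genotypes(family, cfg)
        frac = np.mean(t.genotypes == MISSING)
        assert 0.08 < frac < 0.12

    def test_sharing_fraction_matches_enumeration(self, family):
        """Fraction of father-het sites with the father+proband-only
        pattern agrees with exact transmission-pattern enumeration."""
        freq = 0.1
        cfg = SimulationConfig(
            seed=11,
            n_variants=50_000,
            site_fail_rate=0.0,
            allele_frequency_distribution=("fixed", freq),
        )
        t = simulate_genotypes(family, cfg)
        idx = {s: t.samples.index(s) for s in SEQUENCED_SAMPLES}
        father_het = t.genotypes[:, idx["II.3"]] == 1
        pattern = (
            father_het
            & (t.genotypes[:, idx["III.3"]] == 1)
            & (t.genotypes[:, idx["II.4"]] == 0)
            & (t.genotypes[:, idx["III.4"]] == 0)
            & (t.genotypes[:, idx["III.1"]] == 0)
            & (t.genotypes[:, idx["III.2"]] == 0)
        )
        observed = pattern.sum() / father_het.sum()
        expected = enumerate_pattern_probability(
            family,
            freq,
            het_ids=("II.3", "III.3"),
            clear_ids=("II.4", "III.4", "III.1", "III.2"),
            given_het_ids=("II.3",),
        )
        se = np.sqrt(expected * (1 - expected) / father_het.sum())
        assert abs(observed - expected) < 3 * se


class TestPlanting:
    def test_planted_het_in_carriers_only(self, family):
        t = simulate_genotypes(family, small_cfg())
        plant_trait_variant(t, family, {"II.3", "III.3"})
        g = t.genotypes[-1]
        for j, s in enumerate(t.samples):
            assert g[j] == (1 if s in ("II.3", "III.3") else 0)
        assert t.planted[-1]
        assert t.site_pass[-1]

    def test_planted_in_everyone(self, family):
        t = simulate_genotypes(family, small_cfg())
        plant_trait_variant(t, family, set(SEQUENCED_SAMPLES))
        assert np.all(t.genotypes[-1] == 1)

    def test_empty_carriers_rejected(self, family):
        t = simulate_genotypes(family, small_cfg())
        with pytest.raises(ValueError, match="non-empty"):
            plant_trait_variant(t, family, set())

    def test_planted_satisfies_cascade_preconditions(self, family):
        """Planted record: fully called, exonic nonsynonymous, panel-absent."""
        cfg = small_cfg(missing_call_rate=0.05)
        t = simulate_genotypes(family, cfg)
        plant_trait_variant(t, family, {"II.3", "III.3"})
        ann = simulate_annotations(t, cfg)
        pa, pb = simulate_panel_sites(t, cfg)
        i = int(np.where(t.planted)[0][0])
        assert np.all(t.genotypes[i] != MISSING)
        assert ann.loc[i, "region_class"] == "exonic"
        assert ann.loc[i, "consequence"] == "nonsynonymous_snv"
        key = (t.chrom[i], t.pos[i])
        for panel in (pa, pb):
            assert not ((panel.chrom == key[0]) & (panel.pos == key[1])).any()


class TestAnnotations:
    def test_fraction_exonic_one(self, family):
        cfg = small_cfg(fraction_exonic=1.0)
        t = simulate_genotypes(family, cfg)
        ann = simulate_annotations(t, cfg)
        assert (ann.region_class == "exonic").all()

    def test_degenerate_consequence_weights(self, family):
        cfg = small_cfg(
            fraction_exonic=1.0,
            consequence_class_weights={"synonymous_snv": 1.0},
        )
        t = simulate_genotypes(family, cfg)
        ann = simulate_annotations(t, cfg)
        snvs = ann.loc[~t.is_indel]
        assert (snvs.consequence == "synonymous_snv").all()

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            small_cfg(consequence_class_weights={"synonymous_snv": 0.5})

    def test_aa_change_only_on_protein_changing(self, family):
        cfg = small_cfg(fraction_exonic=1.0)
        t = simulate_genotypes(family, cfg)
        ann = simulate_annotations(t, cfg)
        has_aa = ann.aa_change.notna()
        protein_changing = ann.consequence.isin(
            ["nonsynonymous_snv", "stopgain", "stoploss"]
        )
        assert (has_aa == protein_changing).all()


class TestCnvSimulation:
    def test_no_jitter_no_split_callers_match_truth(self, family):
        cfg = small_cfg(boundary_jitter_sd=0.0, split_call_probability=0.0,
                        low_quality_call_rate=0.0)
        a, b, qc, truth = simulate_cnv_callsets(family, cfg)
        cols = ["sample", "chrom", "start", "end", "state", "n_snps"]
        pa = a[cols].sort_values(cols).reset_index(drop=True)
        pb = b[cols].sort_values(cols).reset_index(drop=True)
        pt = truth[cols].sort_values(cols).reset_index(drop=True)
        assert pa.equals(pt)
        assert pb.equals(pt)

    def test_split_probability_one_merges_back_to_truth(self, family):
        cfg = small_cfg(
            boundary_jitter_sd=0.0,
            split_call_probability=1.0,
            low_quality_call_rate=0.0,
            cnv_segments_per_sample=3,
        )
        _, b, _, truth = simulate_cnv_callsets(family, cfg)
        for row in truth.itertuples(index=False):
            mine = b[
                (b["sample"] == row.sample)
                & (b.chrom == row.chrom)
                & (b.start >= row.start)
                & (b.end <= row.end)
            ]
            assert len(mine) >= 2
            assert mine.start.min() == row.start
            assert mine.end.max() == row.end

    def test_qc_fail_subset(self, family):
        cfg = small_cfg(qc_fail_samples=("III.4",))
        _, _, qc, _ = simulate_cnv_callsets(family, cfg)
        bad = qc.set_index("sample").loc["III.4"]
        assert bad.lrr_sd >= 0.35 or bad.baf_drift >= 0.002


class TestAuxTables:
    def test_empty_dgv(self):
        assert len(simulate_sv_database(small_cfg(dgv_records=0))) == 0

    def test_interactor_tier_counts(self):
        df = simulate_interactors(small_cfg(interactor_counts=(2, 0)))
        assert (df.tier == "high").sum() == 2
        assert (df.tier == "low").sum() == 0

    def test_full_scale_tier_sizes(self):
        df = simulate_interactors(small_cfg(interactor_counts=(5961, 2178)))
        assert (df.tier == "high").sum() == 5961
        assert (df.tier == "low").sum() == 2178
        assert not set(df[df.tier == "high"].gene) & set(df[df.tier == "low"].gene)


def test_seed_determinism_byte_identical(tmp_path, family):
    cfg = small_cfg(
        n_variants=150, missing_call_rate=0.05, false_positive_indel_rate=0.01,
        interactor_counts=(50, 20), dgv_records=30,
    )
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = simulate_study(d1, cfg, ped=family)
    p2 = simulate_study(d2, cfg, ped=family)
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes(), name


def test_false_positive_indels_flagged_and_cosegregating(family):
    cfg = small_cfg(n_variants=2000, false_positive_indel_rate=0.01)
    t = simulate_genotypes(family, cfg)
    n_fp = int(t.false_positive.sum())
    assert n_fp > 0
    idx = {s: t.samples.index(s) for s in SEQUENCED_SAMPLES}
    for i in np.where(t.false_positive)[0]:
        assert t.is_indel[i]
        assert len(t.alt[i]) > len(t.ref[i])
        assert t.genotypes[i, idx["II.3"]] == 1
        assert t.genotypes[i, idx["III.3"]] == 1
        assert t.genotypes[i, idx["III.4"]] == 0
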