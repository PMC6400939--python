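"""Synthetic cohort generator: determinism, configured orderings, contracts."""

import numpy as np
import pytest
from scipy import stats as sps

from hs27pipe.synthetic import (
    GeneratorConfig,
    SiteAnnotation,
    circular_mask,
    generate_cohort,
    generate_paired_agent_biopsies,
    generate_site_frame,
    site_mean_intensity,
    til_density,
)
from .conftest import small_generator_config


def tumor_annotation(til=10.0, cell=40.0, pta=50.0):
    return SiteAnnotation(
        percent_tumor_area=pta, tumor_cellularity=cell,
        stromal_percent=100.0 - cell, til_percent_of_stroma=til,
    )


class TestSiteFrame:
    def test_fixed_seed_is_bit_identical(self, small_config):
        ann = tumor_annotation()
        f1 = generate_site_frame(small_config, "tumor", "TNBC", ann,
                                 np.random.default_rng(7))
        f2 = generate_site_frame(small_config, "tumor", "TNBC", ann,
                                 np.random.default_rng(7))
        np.testing.assert_array_equal(f1.pixels, f2.pixels)
        np.testing.assert_array_equal(f1.mask, f2.mask)

    def test_noise_free_frame_is_constant_at_model_mean(self):
        cfg = small_generator_config(noise_sd=0.0, til_slope=0.0)
        # zero heterogeneity for every class
        from hs27pipe.synthetic import ClassParams
        cfg.class_params = {
            k: ClassParams(v.baseline_mean, 0.0, v.heterogeneity_scale, 0.0)
            for k, v in cfg.class_params.items()
        }
        ann = tumor_annotation()
        frame = generate_site_frame(cfg, "tumor", "Her2+", ann,
                                    np.random.default_rng(0))
        expected = cfg.class_params["tumor"].baseline_mean + cfg.subtype_offsets["Her2+"]
        inside = frame.pixels[frame.mask]
        assert np.allclose(inside, expected)
        assert np.all(frame.pixels[~frame.mask] == 0)

    def test_empirical_class_ordering_tumor_above_mammoplasty(self, small_config):
        rng = np.random.default_rng(3)
        ann = tumor_annotation(til=0.0)
        benign_ann = SiteAnnotation(0, 0, 100, 0)
        t_means = [
            generate_site_frame(small_config, "tumor", "ER+", ann, rng).masked_pixels.mean()
            for _ in range(200)
        ]
        m_means = [
            generate_site_frame(small_config, "mammoplasty", "none", benign_ann, rng)
            .masked_pixels.mean()
            for _ in range(200)
        ]
        assert np.mean(t_means) > np.mean(m_means)

    def test_all_pixels_nonnegative_and_masks_shared(self, small_config):
        rng = np.random.default_rng(0)
        frames = [
            generate_site_frame(small_config, "tumor", "TNBC", tumor_annotation(), rng)
            for _ in range(5)
        ]
        for f in frames:
            assert np.all(f.pixels >= 0)
            np.testing.assert_array_equal(f.mask, frames[0].mask)
        np.testing.assert_array_equal(
            frames[0].mask, circular_mask(small_config.frame_height, small_config.frame_width)
        )

    def test_zero_stroma_with_tils_is_rejected(self, small_config):
        ann = SiteAnnotation(percent_tumor_area=50, tumor_cellularity=100,
                             stromal_percent=0, til_percent_of_stroma=5)
        with pytest.raises(ValueError, match="stromal"):
            site_mean_intensity(small_config, "tumor", "TNBC", ann)
        with pytest.raises(ValueError):
            til_density(ann)


class TestCohort:
    def test_count_bookkeeping(self, small_config):
        cohort = generate_cohort(
            small_config, {"tumor": 2, "benign": 1, "mammoplasty": 1}, seed=7
        )
        labels = sorted(b.tissue_class for b in cohort)
        assert labels == ["benign", "mammoplasty", "tumor", "tumor"]
        for b in cohort:
            assert len(b.frames) == len(b.annotations) == small_config.frames_per_biopsy
            assert (b.subtype == "none") == (b.tissue_class != "tumor")

    def test_default_subtype_split_mirrors_clinical_cohort(self, small_config):
        cohort = generate_cohort(small_config, {"tumor": 27}, seed=0)
        subtypes = [b.subtype for b in cohort]
        assert subtypes.count("ER+") == 18
        assert subtypes.count("Her2+") == 5
        assert subtypes.count("TNBC") == 4

    def test_seed_contract(self, small_config):
        a = generate_cohort(small_config, {"tumor": 2, "benign": 1}, seed=5)
        b = generate_cohort(small_config, {"tumor": 2, "benign": 1}, seed=5)
        c = generate_cohort(small_config, {"tumor": 2, "benign": 1}, seed=6)
        for ba, bb in zip(a, b):
            for fa, fb in zip(ba.frames, bb.frames):
                np.testing.assert_array_equal(fa.pixels, fb.pixels)
        assert any(
            not np.array_equal(fa.pixels, fc.pixels)
            for ba, bc in zip(a, c)
            for fa, fc in zip(ba.frames, bc.frames)
        )

    def test_til_slope_sign_recovered_by_regression(self):
        # 100+ tumor biopsies at tiny frame size: biopsy mean fluorescence
        # must decrease with biopsy mean TIL density by construction.
        cfg = small_generator_config(frame_height=32, frame_width=32,
                                     frames_per_biopsy=2)
        cohort = generate_cohort(cfg, {"tumor": 120}, seed=11)
        means = np.array([b.pooled_pixels.mean() for b in cohort])
        dens = np.array([
            np.mean([til_density(a) for a in b.annotations]) for b in cohort
        ])
        slope = sps.linregress(dens, means).slope
        assert slope < 0

    def test_empty_request_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_cohort(small_config, {"tumor": 0, "benign": 0}, seed=1)


class TestPairedAgents:
    def test_identity_factor_with_noise_off_gives_equal_means(self):
        from hs27pipe.synthetic import ClassParams
        cfg = small_generator_config(noise_sd=0.0)
        cfg.class_params = {
            k: ClassParams(v.baseline_mean, 0.0, v.heterogeneity_scale, 0.0)
            for k, v in cfg.class_params.items()
        }
        pairs = generate_paired_agent_biopsies(cfg, specificity_factor=1.0,
                                               n_pairs=2, seed=3)
        for spec, ctrl in pairs:
            assert spec.pooled_pixels.mean() == pytest.approx(ctrl.pooled_pixels.mean())

    def test_monte_carlo_factor_recovery(self, small_config):
        pairs = generate_paired_agent_biopsies(small_config, specificity_factor=3.0,
                                               n_pairs=12, seed=9)
        spec_mean = np.mean([p[0].pooled_pixels.mean() for p in pairs])
        ctrl_mean = np.mean([p[1].pooled_pixels.mean() for p in pairs])
        assert spec_mean / ctrl_mean == pytest.approx(3.0, rel=0.1)

    def test_paper_scale_design_accepted(self, small_config):
        pairs = generate_paired_agent_biopsies(small_config, 3.0, n_pairs=4, seed=0)
        assert len(pairs) == 4
        assert all(s.agent == "specific" and c.agent == "nonspecific" for s, c in pairs)

    def test_invalid_inputs_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_paired_agent_biopsies(small_config, 0.0, 4)
        with pytest.raises(ValueError):
            generate_paired_agent_biopsies(small_config, 2.0, 0)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(frames_per_biopsy=0)
    with pytest.raises(ValueError):
        GeneratorConfig(noise_sd=-1.0)
    cfg = GeneratorConfig()
    # defaults encode the documented orderings
    cp = cfg.class_params
    assert cp["tumor"].baseline_mean > cp["benign"].baseline_mean > cp["mammoplasty"].baseline_mean
    off = cfg.subtype_offsets
    assert off["Her2+"] > off["TNBC"] > off["ER+"]
    assert cfg.til_slope < 0
    assert cp["mammoplasty"].heterogeneity_amp < cp["tumor"].heterogeneity_amp
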