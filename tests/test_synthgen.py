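"""Generator determinism, calibration and ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats as sps

from raredrop import synthgen
from raredrop.phenotype import PHENOTYPE_CLASSES
from raredrop.synthgen import CohortConfig, SampleSpec


class TestSampleSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            SampleSpec(n_background_cells=-1)
        with pytest.raises(ValueError):
            SampleSpec(blood_volume_ml=0)
        with pytest.raises(ValueError):
            SampleSpec(class_incidence={"no-such-class": 1.0})
        with pytest.raises(ValueError):
            SampleSpec(disease_state="CLL")

    def test_effective_volume_default_geometry(self):
        # 2 slides x 3e6 cells over 6e6 nucleated/mL -> 1 mL analyzed
        assert SampleSpec().effective_volume_ml == pytest.approx(1.0)

    def test_presets_cover_all_classes_and_states(self):
        for state in synthgen.DISEASE_STATES:
            assert set(synthgen.INCIDENCE_PRESETS[state]) == set(PHENOTYPE_CLASSES)
        key = "D | 138 | BCMA-Memb"
        vals = [synthgen.INCIDENCE_PRESETS[s][key] for s in ("MGUS", "SMM", "NDMM")]
        assert vals == sorted(vals)  # burden rises toward overt disease


class TestEventTables:
    def test_fixed_seed_is_bit_identical(self):
        spec = SampleSpec.from_preset("SMM", n_background_cells=500)
        ev1, tr1 = synthgen.generate_event_table(spec, seed=42)
        ev2, tr2 = synthgen.generate_event_table(spec, seed=42)
        assert_frame_equal(ev1, ev2)
        assert_frame_equal(tr1, tr2)

    def test_all_background_when_nothing_planted(self):
        spec = SampleSpec(n_background_cells=300, class_incidence={}, artifact_rate=0.0)
        _, truth = synthgen.generate_event_table(spec, seed=1)
        assert (truth["true_class"] == "BACKGROUND").all()

    def test_planted_counts_follow_poisson_mean(self):
        lam = 4.0
        spec = SampleSpec(
            n_background_cells=0,
            class_incidence={"D | 138": lam},
            artifact_rate=0.0,
        )
        root = np.random.SeedSequence(0)
        counts = [
            len(synthgen.generate_event_table(spec, s)[0]) for s in root.spawn(1000)
        ]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 1000)

    def test_planted_counts_pass_poisson_gof(self):
        lam = 3.0
        spec = SampleSpec(
            n_background_cells=0,
            class_incidence={"D | BCMA-Memb": lam},
            artifact_rate=0.0,
        )
        root = np.random.SeedSequence(7)
        counts = np.array(
            [len(synthgen.generate_event_table(spec, s)[0]) for s in root.spawn(250)]
        )
        # bin 0..6 plus tail, chi-square against the Poisson pmf
        edges = list(range(7))
        obs = np.array([np.sum(counts == k) for k in edges] + [np.sum(counts > 6)])
        pmf = np.array([sps.poisson.pmf(k, lam) for k in edges])
        pmf = np.append(pmf, 1 - pmf.sum())
        stat, p = sps.chisquare(obs, pmf * len(counts))
        assert p > 0.01

    def test_artifact_rate_binomial(self):
        spec = SampleSpec(n_background_cells=50, class_incidence={}, artifact_rate=0.1)
        _, tr = synthgen.generate_event_table(spec, seed=7)
        n7 = int((tr["true_class"] == "ARTIFACT").sum())
        _, tr_again = synthgen.generate_event_table(spec, seed=7)
        assert int((tr_again["true_class"] == "ARTIFACT").sum()) == n7
        root = np.random.SeedSequence(123)
        total = sum(
            int((synthgen.generate_event_table(spec, s)[1]["true_class"] == "ARTIFACT").sum())
            for s in root.spawn(200)
        )
        lo, hi = sps.binom.interval(0.99, 200 * 50, 0.1)
        assert lo <= total <= hi

    def test_direction_between_presets(self):
        # mean planted D | 138 | BCMA-Memb count is higher under the NDMM
        # preset than the MGUS preset
        key = "D | 138 | BCMA-Memb"
        means = {}
        for state in ("MGUS", "NDMM"):
            spec = SampleSpec(
                n_background_cells=0,
                class_incidence={key: synthgen.INCIDENCE_PRESETS[state][key]},
                artifact_rate=0.0,
            )
            root = np.random.SeedSequence(99)
            means[state] = np.mean(
                [len(synthgen.generate_event_table(spec, s)[0]) for s in root.spawn(200)]
            )
        assert means["NDMM"] > means["MGUS"]


class TestFrames:
    def test_empty_frame_is_constant_background(self):
        spec = SampleSpec(n_background_cells=0, class_incidence={}, artifact_rate=0.0)
        img, truths = synthgen.generate_frame(
            spec, seed=0, noise_sd=0, frame_shape=(128, 128)
        )
        assert truths == []
        assert np.all(img == synthgen.LOW_LEVEL)

    def test_fixed_seed_identical_pixels(self):
        spec = SampleSpec(n_background_cells=5, artifact_rate=0.0)
        img1, _ = synthgen.generate_frame(spec, seed=4, frame_shape=(256, 256))
        img2, _ = synthgen.generate_frame(spec, seed=4, frame_shape=(256, 256))
        assert np.array_equal(img1, img2)

    @pytest.mark.parametrize("cls", ["D | 138 | BCMA-Memb", "D | 138 | BCMA-Peri"])
    def test_bcma_band_contrast(self, cls):
        spec = SampleSpec(n_background_cells=0, artifact_rate=0.0)
        img, truths = synthgen.generate_frame(
            spec, seed=2, class_counts={cls: 1}, noise_sd=0, frame_shape=(256, 256)
        )
        t = truths[0]
        cx, cy = t.true_center
        yy, xx = np.mgrid[0 : img.shape[1], 0 : img.shape[2]]
        r = np.hypot(xx - cx, yy - cy)
        memb_band = (r >= t.true_cell_radius - 2) & (r <= t.true_cell_radius + 2)
        peri_band = (r >= t.true_nuclear_radius + 1) & (r <= t.true_nuclear_radius + 3)
        memb_mean = img[2][memb_band].mean()
        peri_mean = img[2][peri_band].mean()
        if "Memb" in cls:
            assert memb_mean > peri_mean
        else:
            assert peri_mean > memb_mean

    def test_capacity_exceeded_raises_with_count(self):
        spec = SampleSpec(n_background_cells=500, artifact_rate=0.0)
        with pytest.raises(RuntimeError, match="placing"):
            synthgen.generate_frame(spec, seed=0, frame_shape=(128, 128))

    def test_truth_class_recoverable_from_levels(self):
        spec = SampleSpec(n_background_cells=3, artifact_rate=0.0)
        _, truths = synthgen.generate_frame(
            spec,
            seed=9,
            class_counts={"BACKGROUND": 2, "D | 138 | BCMA-Memb": 1, "D": 1},
            frame_shape=(512, 512),
        )
        for t in truths:
            implied = synthgen.true_phenotype(t.true_class)
            lv = t.true_channel_levels
            expect_138 = lv["cd138"] > synthgen.LOW_LEVEL
            expect_45 = lv["cd45"] > synthgen.LOW_LEVEL
            assert ("138" in implied) == expect_138
            assert implied.endswith("45") == expect_45


class TestCohort:
    def test_cohort_layout_totals_68(self):
        assert sum(synthgen.COHORT_LAYOUT_TEXT.values()) == 68
        assert sum(synthgen.COHORT_LAYOUT_TABLE.values()) == 68
        cfg = CohortConfig(n_background_cells=30)
        samples, clinical = synthgen.generate_cohort(cfg)
        assert len(samples) == 68
        assert len(clinical) == 68
        assert clinical["disease_state"].value_counts().to_dict() == {
            "SMM": 21,
            "NDMM": 19,
            "RRMM": 17,
            "MGUS": 11,
        }

    def test_cohort_determinism(self):
        cfg = CohortConfig(n_background_cells=30, seed=5)
        s1, c1 = synthgen.generate_cohort(cfg)
        s2, c2 = synthgen.generate_cohort(cfg)
        assert_frame_equal(c1, c2)
        sid = next(iter(s1))
        assert_frame_equal(s1[sid][0], s2[sid][0])

    def test_zero_correlation_knob(self):
        # covariate decoupled from planted burden: |rho| small
        rhos = []
        for seed in range(3):
            cfg = CohortConfig(
                state_counts={"NDMM": 500},
                n_background_cells=10,
                covariate_correlation=0.0,
                seed=seed,
            )
            samples, clinical = synthgen.generate_cohort(cfg)
            planted = [
                int((tr["true_class"] == "D | 138 | BCMA-Memb").sum())
                for _, tr in samples.values()
            ]
            rho, _ = sps.spearmanr(planted, clinical["m_spike"])
            rhos.append(abs(rho))
        assert np.mean(np.array(rhos) < 0.1) >= 0.66

    def test_positive_correlation_knob_recoverable(self):
        cfg = CohortConfig(
            state_counts={"NDMM": 300},
            n_background_cells=10,
            covariate_correlation=0.8,
            seed=1,
        )
        samples, clinical = synthgen.generate_cohort(cfg)
        planted = [
            int((tr["true_class"] == "D | 138 | BCMA-Memb").sum())
            for _, tr in samples.values()
        ]
        rho, p = sps.spearmanr(planted, clinical["m_spike"])
        assert rho > 0.3 and p < 0.001


class TestCurationSet:
    def test_labels_and_sizes(self, curation_training):
        df = curation_training
        assert len(df) == 600
        assert set(df["label"]) == {"cell", "artifact"}
        assert int((df["label"] == "artifact").sum()) == 180
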