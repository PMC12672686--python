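"""Enumeration arithmetic, rank tests, correlations and demographics."""

import itertools
import logging
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from raredrop import synthgen
from raredrop.enumstats import (
    EVENT_TYPES,
    STUDY_DEMOGRAPHICS,
    cohort_demographic_summary,
    clinical_correlations,
    density_summaries,
    enumerate_sample,
    enumeration_table,
    morphometric_umap,
    pairwise_state_tests,
    rank_sum_test,
)
from raredrop.phenotype import phenotype_events


def _events_with_classes(classes):
    return pd.DataFrame({"class": classes})


class TestEnumeration:
    def test_worked_example_ten_cells_per_ml(self):
        ev = _events_with_classes(["D | 138"] * 10)
        e = enumerate_sample(ev, "s", "NDMM", 6e6, 4.8e7, 8.0)
        assert e.cells_per_ml["D | 138"] == 10.0
        assert e.cells_per_ml["Total Cells"] == 10.0

    def test_zero_events_zero_everywhere(self):
        e = enumerate_sample(_events_with_classes([]), "s", "MGUS", 6e6, 4.8e7, 8.0)
        assert (e.cells_per_ml == 0).all()

    def test_doubling_volume_halves_concentration(self):
        ev = _events_with_classes(["D"] * 6)
        e1 = enumerate_sample(ev, "s", "SMM", 6e6, 4.8e7, 8.0)
        e2 = enumerate_sample(ev, "s", "SMM", 6e6, 4.8e7, 16.0)
        assert e2.cells_per_ml["D"] == e1.cells_per_ml["D"] / 2

    def test_identity_exact_on_integer_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            count = int(rng.integers(0, 500))
            analyzed = int(rng.integers(1, 10**7))
            cbc = int(rng.integers(1, 10**9))
            vol = int(rng.integers(1, 20))
            ev = _events_with_classes(["D | 45"] * count)
            e = enumerate_sample(ev, "s", "RRMM", analyzed, cbc, vol)
            expected = float(Fraction(count) * Fraction(cbc, analyzed) / vol)
            assert e.cells_per_ml["D | 45"] == expected

    def test_invalid_metadata_raises(self):
        ev = _events_with_classes(["D"])
        with pytest.raises(ValueError, match="analyzed"):
            enumerate_sample(ev, "s", "MGUS", 0, 1e7, 8.0)
        with pytest.raises(ValueError, match="CBC"):
            enumerate_sample(ev, "s", "MGUS", 1e6, 0, 8.0)


def brute_force_p(x, y):
    m = len(x)
    combined = np.concatenate([x, y])
    r = sps.rankdata(combined)
    n = len(combined)
    w = r[:m].sum()
    e = m * (n + 1) / 2
    d = abs(w - e)
    hits = total = 0
    for c in itertools.combinations(range(n), m):
        if abs(r[list(c)].sum() - e) >= d - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_extreme_arrangement_exact_p(self):
        # most extreme of C(6,3)=20 assignments, two-sided: p = 2/20
        r = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert r.p_value == pytest.approx(0.1, abs=1e-15)
        assert r.method == "exact-dp"
        assert r.z < 0

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            assert rank_sum_test(x, y).p_value == rank_sum_test(y, x).p_value

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            y = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            r = rank_sum_test(x, y)
            assert abs(r.p_value - brute_force_p(x, y)) < 1e-12

    def test_normal_branch_for_large_samples(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(1.0, size=40)
        r = rank_sum_test(x, y)
        assert r.method == "normal"
        assert 0 <= r.p_value <= 1
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


@pytest.fixture(scope="module")
def enum_df():
    rng = np.random.default_rng(5)
    rows = []
    for state, shift in (("MGUS", 0.0), ("NDMM", 3.0)):
        for i in range(10):
            row = {"sample_id": f"{state}{i}", "disease_state": state}
            for et in EVENT_TYPES:
                row[et] = rng.poisson(1.0 + (shift if "BCMA-Memb" in et else 0))
            rows.append(row)
    return pd.DataFrame(rows)


class TestPairwiseTests:
    def test_shifted_class_detected(self, enum_df):
        out = pairwise_state_tests(enum_df)
        row = out[out["event_type"] == "D | 138 | BCMA-Memb"].iloc[0]
        assert row["p_value"] < 0.05 and row["significant"]
        assert row["mean2"] > row["mean1"]

    def test_six_pairs_when_four_states(self, enum_df):
        df = enum_df.copy()
        extra = []
        for state in ("SMM", "RRMM"):
            for i in range(3):
                row = {"sample_id": f"{state}{i}", "disease_state": state}
                row.update({et: float(i) for et in EVENT_TYPES})
                extra.append(row)
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
        out = pairwise_state_tests(df)
        assert out.groupby(["group1", "group2"]).ngroups == 6

    def test_single_sample_group_raises(self, enum_df):
        df = pd.concat(
            [enum_df, enum_df.iloc[[0]].assign(disease_state="SMM")], ignore_index=True
        )
        with pytest.raises(ValueError, match="2 samples"):
            pairwise_state_tests(df)


class TestClinicalCorrelations:
    def _enum(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "disease_state": "NDMM",
                "D | 138": rng.poisson(3.0, n).astype(float),
            }
        )
        return df

    def test_perfect_monotone_gives_rho_one(self):
        enum_df = self._enum()
        enum_df["D | 138"] = np.arange(len(enum_df), dtype=float)
        clinical = pd.DataFrame(
            {"sample_id": enum_df["sample_id"], "marker": np.arange(len(enum_df)) ** 2}
        )
        out = clinical_correlations(
            enum_df, clinical, {"marker": "continuous"}, event_types=["D | 138"]
        )
        assert out["correlation_value"].iloc[0] == pytest.approx(1.0)
        assert out["p_value"].iloc[0] < 1e-10

    def test_spearman_equals_rank_then_pearson(self):
        rng = np.random.default_rng(7)
        enum_df = self._enum(40, seed=7)
        clinical = pd.DataFrame(
            {"sample_id": enum_df["sample_id"], "marker": rng.integers(0, 5, 40)}
        )
        out = clinical_correlations(
            enum_df, clinical, {"marker": "ordinal"}, event_types=["D | 138"]
        )
        rho_manual = np.corrcoef(
            sps.rankdata(enum_df["D | 138"]), sps.rankdata(clinical["marker"])
        )[0, 1]
        assert out["correlation_value"].iloc[0] == pytest.approx(rho_manual, abs=1e-12)

    def test_binary_variable_uses_wilcoxon_z(self):
        enum_df = self._enum(30, seed=1)
        flag = np.array([1] * 15 + [0] * 15)
        enum_df["D | 138"] = np.where(flag == 1, 10.0, 1.0) + np.arange(30) * 0.01
        clinical = pd.DataFrame({"sample_id": enum_df["sample_id"], "flag": flag})
        out = clinical_correlations(
            enum_df, clinical, {"flag": "binary"}, event_types=["D | 138"]
        )
        assert out["method"].iloc[0] == "Wilcoxon"
        assert out["correlation_value"].iloc[0] > 0  # higher burden in flag==1

    def test_constant_variable_skipped_with_log(self, caplog):
        enum_df = self._enum()
        clinical = pd.DataFrame(
            {"sample_id": enum_df["sample_id"], "marker": 1.0}
        )
        with caplog.at_level(logging.WARNING):
            out = clinical_correlations(enum_df, clinical, {"marker": "continuous"})
        assert len(out) == 0
        assert "constant" in caplog.text

    def test_independent_variable_small_rho(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            enum_df = self._enum(500, seed=seed)
            clinical = pd.DataFrame(
                {"sample_id": enum_df["sample_id"], "marker": rng.normal(size=500)}
            )
            out = clinical_correlations(
                enum_df, clinical, {"marker": "continuous"}, event_types=["D | 138"]
            )
            hits += abs(out["correlation_value"].iloc[0]) < 0.1
        assert hits >= 4


@pytest.fixture(scope="module")
def two_population_events():
    spec = synthgen.SampleSpec(
        n_background_cells=40,
        class_incidence={"D | 138 | BCMA-Memb": 40.0},
        artifact_rate=0.0,
    )
    ev, tr = synthgen.generate_event_table(spec, seed=9)
    return phenotype_events(ev), tr


class TestVisualization:
    def test_embedding_is_deterministic(self, two_population_events):
        ev, _ = two_population_events
        e1 = morphometric_umap(ev, seed=1)
        e2 = morphometric_umap(ev, seed=1)
        assert np.array_equal(e1[["umap_x", "umap_y"]], e2[["umap_x", "umap_y"]])

    def test_separated_populations_separate_in_embedding(self, two_population_events):
        from sklearn.metrics import silhouette_score

        ev, tr = two_population_events
        emb = morphometric_umap(ev, seed=0)
        labels = (tr.set_index("cell_id").loc[emb["cell_id"], "true_class"]
                  != "BACKGROUND").to_numpy()
        score = silhouette_score(emb[["umap_x", "umap_y"]].to_numpy(), labels)
        assert score > 0.5

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError, match=">= 20"):
            morphometric_umap(pd.DataFrame({"nuclear_area": np.arange(5.0)}))

    def test_density_summaries_cover_parameters(self, two_population_events):
        ev, _ = two_population_events
        dens = density_summaries(ev)
        assert {"median_cd138", "nuclear_area"} <= set(dens)
        for df in dens.values():
            assert (df["density"] >= 0).all()


class TestDemographics:
    def test_overall_percentages(self):
        out = cohort_demographic_summary()
        male = out[out["category"] == "Male"].iloc[0]
        white = out[out["category"] == "White or Caucasian"].iloc[0]
        assert male["total"] == 32 and male["percent"] == 47.06
        assert white["total"] == 54 and white["percent"] == 79.41

    def test_custom_table(self):
        df = pd.DataFrame(
            [("Gender", "Male", 1, 1), ("Gender", "Female", 1, 1)],
            columns=["variable", "category", "A", "B"],
        )
        out = cohort_demographic_summary(df)
        assert (out["percent"] == 50.0).all()

    def test_state_columns_total_68(self):
        states = ["MGUS", "SMM", "NDMM", "RRMM"]
        gender = STUDY_DEMOGRAPHICS[STUDY_DEMOGRAPHICS["variable"] == "Gender"]
        assert int(gender[states].to_numpy().sum()) == 68
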