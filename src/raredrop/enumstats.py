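"""Cells/mL enumeration, cohort statistics and morphometric visualization.

Enumeration converts per-class event counts into blood concentrations via

    cells/mL = count x (CBC nucleated cells / analyzed cells) / blood volume,

i.e. the detected count scaled by the fraction of the draw's nucleated
cells actually plated and analyzed.  The identity is evaluated in exact
rational arithmetic before conversion to float.

Group comparisons use the two-sided Wilcoxon rank-sum test (exact null
distribution where tractable, tie-corrected normal approximation
otherwise) and clinical associations use Spearman rank correlation for
continuous/ordinal variables and the standardized Wilcoxon statistic for
binary ones.  Comparisons are reported independently, without multiplicity
correction; a Benjamini-Hochberg column is emitted alongside purely as a
convenience and is not part of the reference procedure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb, erfc, sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phenotype import AGGREGATE_CATEGORIES, PHENOTYPE_CLASSES, aggregate_counts

logger = logging.getLogger(__name__)

__all__ = [
    "SampleEnumeration",
    "RankSumResult",
    "rank_sum_test",
    "enumerate_sample",
    "enumeration_table",
    "pairwise_state_tests",
    "clinical_correlations",
    "morphometric_umap",
    "density_summaries",
    "STUDY_DEMOGRAPHICS",
    "cohort_demographic_summary",
]

EVENT_TYPES: tuple[str, ...] = tuple(PHENOTYPE_CLASSES) + tuple(AGGREGATE_CATEGORIES)

MORPHOMETRIC_PARAMETERS = (
    "median_cd138",
    "median_bcma",
    "median_cd45",
    "nuclear_area",
    "nuclear_eccentricity",
    "cellular_area",
    "cellular_eccentricity",
)


# --------------------------------------------------------------------------
# Enumeration


@dataclass
class SampleEnumeration:
    """Per-sample event counts and cells/mL for every class and aggregate."""

    sample_id: str
    disease_state: str
    counts: pd.Series  # indexed by EVENT_TYPES, integers
    cells_per_ml: pd.Series  # same index, floats
    n_analyzed_cells: float
    cbc_total_nucleated: float
    blood_volume_ml: float


def _cells_per_ml(
    count: int, cbc_total: float, analyzed: float, volume_ml: float
) -> float:
    # exact rational arithmetic; float conversion happens once at the end
    value = (
        Fraction(count)
        * (Fraction(cbc_total) / Fraction(analyzed))
        / Fraction(volume_ml)
    )
    return float(value)


def enumerate_sample(
    phenotyped_events: pd.DataFrame,
    sample_id: str,
    disease_state: str,
    n_analyzed_cells: float,
    cbc_total_nucleated: float,
    blood_volume_ml: float,
) -> SampleEnumeration:
    """Convert a phenotyped event table into per-class cells/mL.

    ``phenotyped_events`` must carry a ``class`` column (see
    :func:`raredrop.phenotype.phenotype_events`).
    """
    if n_analyzed_cells <= 0:
        raise ValueError("n_analyzed_cells must be > 0")
    if cbc_total_nucleated <= 0:
        raise ValueError("cbc_total_nucleated must be > 0 (missing CBC?)")
    if blood_volume_ml <= 0:
        raise ValueError("blood_volume_ml must be > 0")
    counts = aggregate_counts(phenotyped_events["class"]) if len(phenotyped_events) else (
        aggregate_counts([])
    )
    cpm = pd.Series(
        {
            k: _cells_per_ml(int(c), cbc_total_nucleated, n_analyzed_cells, blood_volume_ml)
            for k, c in counts.items()
        }
    )
    return SampleEnumeration(
        sample_id=sample_id,
        disease_state=disease_state,
        counts=counts,
        cells_per_ml=cpm,
        n_analyzed_cells=n_analyzed_cells,
        cbc_total_nucleated=cbc_total_nucleated,
        blood_volume_ml=blood_volume_ml,
    )


def enumeration_table(enumerations: Iterable[SampleEnumeration]) -> pd.DataFrame:
    """Wide per-sample cells/mL table (one column per class/aggregate)."""
    rows = []
    for e in enumerations:
        row = {"sample_id": e.sample_id, "disease_state": e.disease_state}
        row.update({k: e.cells_per_ml[k] for k in EVENT_TYPES})
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum test


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum result.

    ``statistic`` is the rank sum W of the first sample; ``z`` the
    tie-corrected standardized statistic (positive when the first sample
    tends larger); ``p_value`` two-sided from the exact null distribution
    when available, else from the normal approximation with continuity
    correction.
    """

    statistic: float
    z: float
    p_value: float
    method: str  # "exact-dp", "exact-enum" or "normal"
    mean1: float
    mean2: float


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_p_no_ties(m: int, n_total: int, w2_obs: int) -> float:
    """Exact two-sided tail P(|W - E| >= |w - E|), distinct values.

    Dynamic program over the count of rank subsets of size ``m`` from ranks
    1..N attaining each rank sum (all counts exact integers).  ``w2_obs``
    is twice the observed rank sum.
    """
    max_sum = sum(range(n_total - m + 1, n_total + 1))
    # f[j][s] = number of j-subsets with rank sum s
    f = [np.zeros(max_sum + 1, dtype=object) for _ in range(m + 1)]
    f[0][0] = 1
    for r in range(1, n_total + 1):
        for j in range(min(r, m), 0, -1):
            shifted = np.zeros(max_sum + 1, dtype=object)
            shifted[r:] = f[j - 1][: max_sum + 1 - r]
            f[j] = f[j] + shifted
    counts = f[m]
    e2 = m * (n_total + 1)  # 2E, an integer
    d_obs = abs(w2_obs - e2)
    total = comb(n_total, m)
    tail = sum(int(c) for s, c in enumerate(counts) if abs(2 * s - e2) >= d_obs)
    return tail / total


def _exact_p_enum(ranks2: np.ndarray, m: int, w2_obs: int) -> float:
    """Exact two-sided tail by full enumeration over assignments (handles ties).

    ``ranks2`` are doubled midranks (integers)."""
    n_total = len(ranks2)
    e2_frac = m * (n_total + 1)  # 2E
    d_obs = abs(w2_obs - e2_frac)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n_total), m):
        w2 = int(ranks2[list(combo)].sum())
        if abs(w2 - e2_frac) >= d_obs:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 50,
    enum_max_n: int = 16,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Route selection: exact dynamic program when there are no ties and the
    combined size is at most ``exact_max_n``; exact full enumeration when
    ties are present and the combined size is at most ``enum_max_n``;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    w = float(ranks[:m].sum())
    n_total = m + n
    e = m * (n_total + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = m * n / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    z = 0.0 if var == 0 else (w - e) / sqrt(var)

    ranks2 = np.rint(2 * ranks).astype(np.int64)
    w2_obs = int(np.rint(2 * w))
    if var == 0:  # every value identical: the test is degenerate
        p, method = 1.0, "exact-enum"
    elif not has_ties and n_total <= exact_max_n:
        p, method = _exact_p_no_ties(m, n_total, w2_obs), "exact-dp"
    elif has_ties and n_total <= enum_max_n:
        p, method = _exact_p_enum(ranks2, m, w2_obs), "exact-enum"
    else:
        zc = max(0.0, abs(w - e) - 0.5) / sqrt(var)
        p, method = min(1.0, erfc(zc / sqrt(2.0))), "normal"
    return RankSumResult(
        statistic=w,
        z=z,
        p_value=p,
        method=method,
        mean1=float(x.mean()),
        mean2=float(y.mean()),
    )


# --------------------------------------------------------------------------
# Cohort comparisons


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0, 1)
    return out


def pairwise_state_tests(
    enum_df: pd.DataFrame,
    states: Sequence[str] | None = None,
    event_types: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of cells/mL between disease-state pairs.

    One row per (state pair, event type) with the two-sided p-value, group
    means on the cells/mL scale, the standardized statistic and a
    significance flag at ``alpha``.  Each comparison stands on its own; the
    ``bh_q`` column is an added convenience, not part of the reference
    procedure.
    """
    if states is None:
        states = [s for s in ("MGUS", "SMM", "NDMM", "RRMM") if s in set(enum_df["disease_state"])]
    if event_types is None:
        event_types = [c for c in EVENT_TYPES if c in enum_df.columns]
    rows = []
    for s1, s2 in itertools.combinations(states, 2):
        g1 = enum_df.loc[enum_df["disease_state"] == s1]
        g2 = enum_df.loc[enum_df["disease_state"] == s2]
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(f"need >= 2 samples per group ({s1}: {len(g1)}, {s2}: {len(g2)})")
        for et in event_types:
            r = rank_sum_test(g1[et].to_numpy(), g2[et].to_numpy())
            rows.append(
                {
                    "group1": s1,
                    "group2": s2,
                    "event_type": et,
                    "method": "Wilcoxon",
                    "statistic": r.statistic,
                    "z": r.z,
                    "p_value": r.p_value,
                    "mean1": r.mean1,
                    "mean2": r.mean2,
                    "significant": r.p_value < alpha,
                }
            )
    out = pd.DataFrame(rows)
    out["bh_q"] = _bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["group1", "group2", "p_value"], kind="mergesort").reset_index(
        drop=True
    )


def clinical_correlations(
    enum_df: pd.DataFrame,
    clinical: pd.DataFrame,
    variable_types: Mapping[str, str],
    event_types: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate per-sample cells/mL with clinical variables.

    Continuous/ordinal variables use Spearman rank correlation with
    average-rank ties; binary variables use the standardized Wilcoxon
    statistic, with a positive sign meaning higher cell burden in the
    variable's reference (== 1) category.  Constant or all-missing
    variables are skipped with a log entry.  Output is sorted by p-value.
    """
    if event_types is None:
        event_types = [c for c in EVENT_TYPES if c in enum_df.columns]
    merged = enum_df.merge(clinical, on="sample_id", suffixes=("", "_clin"))
    rows = []
    for var, vtype in variable_types.items():
        if vtype not in ("continuous", "ordinal", "binary"):
            raise ValueError(f"unknown variable type {vtype!r} for {var!r}")
        v = merged[var]
        valid = v.notna()
        if valid.sum() == 0:
            logger.warning("clinical variable %r is all-missing: skipped", var)
            continue
        if v[valid].nunique() < 2:
            logger.warning("clinical variable %r is constant: skipped", var)
            continue
        for et in event_types:
            burden = merged.loc[valid, et].to_numpy(dtype=float)
            vv = v[valid].to_numpy()
            if vtype == "binary":
                ref = burden[vv == 1]
                other = burden[vv != 1]
                r = rank_sum_test(ref, other)
                rows.append(
                    {
                        "analyte": et,
                        "clinical_variable": var,
                        "method": "Wilcoxon",
                        "correlation_value": r.z,
                        "p_value": r.p_value,
                    }
                )
            else:
                if np.ptp(burden) == 0:  # analyte constant across samples
                    continue
                rho, p = sps.spearmanr(burden, vv.astype(float))
                rows.append(
                    {
                        "analyte": et,
                        "clinical_variable": var,
                        "method": "Spearman",
                        "correlation_value": float(rho),
                        "p_value": float(p),
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p_value"] < alpha
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out


# --------------------------------------------------------------------------
# Morphometric visualization


def morphometric_umap(
    events: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """2-D UMAP embedding of the per-cell morphometric feature space.

    Returns the input's identifying columns with ``umap_x``/``umap_y``
    appended.  Deterministic for a fixed seed (single-threaded exact mode).
    """
    if len(events) < 20:
        raise ValueError("need >= 20 events for an embedding")
    import umap

    if feature_columns is None:
        feature_columns = [c for c in MORPHOMETRIC_PARAMETERS if c in events.columns]
    X = events[list(feature_columns)].to_numpy(float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(events) - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(X)
    out = events.copy()
    out["umap_x"] = coords[:, 0]
    out["umap_y"] = coords[:, 1]
    return out


def density_summaries(
    events: pd.DataFrame,
    parameters: Sequence[str] = MORPHOMETRIC_PARAMETERS,
    n_grid: int = 256,
) -> dict[str, pd.DataFrame]:
    """Kernel-density summaries of the morphometric parameter distributions."""
    out = {}
    for p in parameters:
        if p not in events.columns:
            continue
        x = events[p].to_numpy(float)
        if len(x) < 3 or x.std() == 0:
            continue
        kde = sps.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), n_grid)
        out[p] = pd.DataFrame({"value": grid, "density": kde(grid)})
    return out


# --------------------------------------------------------------------------
# Cohort demographics

#: Printed per-state demographic counts of the 68-patient study cohort
#: (state columns as tabulated: MGUS 11, SMM 20, NDMM 19, RRMM 18).
STUDY_DEMOGRAPHICS: pd.DataFrame = pd.DataFrame(
    [
        ("Gender", "Male", 3, 7, 10, 12),
        ("Gender", "Female", 8, 13, 9, 6),
        ("Race", "American Indian or Alaskan Native", 0, 0, 0, 1),
        ("Race", "Asian", 0, 0, 0, 1),
        ("Race", "Black or African American", 0, 2, 4, 2),
        ("Race", "Native Hawaiian or Other Pacific Islander", 0, 1, 0, 0),
        ("Race", "Other", 0, 1, 0, 2),
        ("Race", "White or Caucasian", 11, 16, 15, 12),
    ],
    columns=["variable", "category", "MGUS", "SMM", "NDMM", "RRMM"],
)


def cohort_demographic_summary(demographics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summarize per-state demographic counts into overall counts and percent.

    Each (variable, category) row gains ``total`` (sum over states) and
    ``percent`` (share of the cohort, in percent, rounded to two decimals
    as conventionally printed).  Defaults to the bundled study cohort.
    """
    df = STUDY_DEMOGRAPHICS if demographics is None else demographics
    states = [c for c in df.columns if c not in ("variable", "category")]
    out = df.copy()
    out["total"] = out[states].sum(axis=1)
    cohort_n = int(out.groupby("variable")["total"].sum().iloc[0])
    for var, grp in out.groupby("variable"):
        n = int(grp["total"].sum())
        if n != cohort_n:
            logger.warning("variable %r totals %d, cohort n is %d", var, n, cohort_n)
    out["percent"] = (100.0 * out["total"] / cohort_n).round(2)
    return out
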