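"""Synthetic slide, event-table and cohort generator with full ground truth.

Emulates the data structure of a non-enrichment slide-based liquid biopsy
for plasma-cell disorders: every nucleated cell from a blood draw is plated
(about 3 million cells per slide, two slides analyzed per sample), imaged
in four immunofluorescence channels (DAPI, CD138, BCMA, CD45), and a small
planted population of circulating plasma cells sits inside a dominant
white-blood-cell background, together with technical artifacts (anuclear
debris and saturated speckles).

Two generation routes share one generative model:

* :func:`generate_frame` renders multichannel fields of view (nuclei as
  filled ellipses in DAPI, cytoplasmic CD138/CD45 fills, BCMA as a
  membrane ring or perinuclear annulus) for exercising segmentation and
  feature extraction.
* :func:`generate_event_table` samples per-cell morphometric/intensity
  feature tables directly, so detection and cohort statistics can be
  exercised at scales where rendering every cell would be wasteful.

Rare-event counts are Poisson with mean ``incidence [cells/mL] x effective
analyzed volume [mL]``, where the effective volume is the analyzed cell
count divided by the blood's nucleated-cell concentration.  Disease-state
incidence presets for the 12 phenotype classes follow the published
cohort's direction of effects (e.g. the D | 138 | BCMA-Memb burden rising
from MGUS through SMM to overt myeloma); magnitudes are calibration
choices of this package.  All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning, so a fixed seed reproduces frames
and tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .phenotype import PHENOTYPE_CLASSES

__all__ = [
    "SampleSpec",
    "CellTruth",
    "CohortConfig",
    "INCIDENCE_PRESETS",
    "COHORT_LAYOUT_TEXT",
    "COHORT_LAYOUT_TABLE",
    "DISEASE_STATES",
    "generate_frame",
    "generate_event_table",
    "generate_cohort",
    "generate_curation_set",
    "true_phenotype",
    "write_frame_tiff",
]

DISEASE_STATES = ("MGUS", "SMM", "NDMM", "RRMM")

#: Cohort layout as enumerated in the study text (n = 68 total).
COHORT_LAYOUT_TEXT: dict[str, int] = {"MGUS": 11, "SMM": 21, "NDMM": 19, "RRMM": 17}
#: Alternative layout as tabulated in the demographic table (also n = 68).
COHORT_LAYOUT_TABLE: dict[str, int] = {"MGUS": 11, "SMM": 20, "NDMM": 19, "RRMM": 18}

# Per-state expected cells/mL for the 12 phenotype classes.  Values for the
# comparisons reported as significant follow the published group means
# (D | 138 | BCMA-Memb rising 1.0 -> 2.7 -> 3.5 -> 3.6 across MGUS, SMM,
# NDMM, RRMM; D | 138 rising with overt disease; BCMA-Peri classes higher
# in NDMM than RRMM); the remaining entries are this package's calibration
# choices, kept at the same order of magnitude.
INCIDENCE_PRESETS: dict[str, dict[str, float]] = {
    "MGUS": {
        "D": 1.0,
        "D | 45": 2.0,
        "D | 138": 0.1888,
        "D | 138 | 45": 0.5,
        "D | BCMA-Memb": 0.8,
        "D | BCMA-Memb | 45": 1.5441,
        "D | BCMA-Peri": 0.8,
        "D | BCMA-Peri | 45": 2.0,
        "D | 138 | BCMA-Memb": 1.0026,
        "D | 138 | BCMA-Memb | 45": 0.5,
        "D | 138 | BCMA-Peri": 0.3,
        "D | 138 | BCMA-Peri | 45": 0.3,
    },
    "SMM": {
        "D": 1.0,
        "D | 45": 2.0,
        "D | 138": 0.8,
        "D | 138 | 45": 0.7,
        "D | BCMA-Memb": 1.0,
        "D | BCMA-Memb | 45": 1.8338,
        "D | BCMA-Peri": 1.0,
        "D | BCMA-Peri | 45": 2.7677,
        "D | 138 | BCMA-Memb": 2.7346,
        "D | 138 | BCMA-Memb | 45": 0.8,
        "D | 138 | BCMA-Peri": 0.5,
        "D | 138 | BCMA-Peri | 45": 0.5,
    },
    "NDMM": {
        "D": 1.0,
        "D | 45": 2.0,
        "D | 138": 1.8354,
        "D | 138 | 45": 1.0,
        "D | BCMA-Memb": 1.3,
        "D | BCMA-Memb | 45": 3.0236,
        "D | BCMA-Peri": 1.5,
        "D | BCMA-Peri | 45": 4.1726,
        "D | 138 | BCMA-Memb": 3.4532,
        "D | 138 | BCMA-Memb | 45": 1.2,
        "D | 138 | BCMA-Peri": 0.8,
        "D | 138 | BCMA-Peri | 45": 0.9,
    },
    "RRMM": {
        "D": 1.0,
        "D | 45": 2.0,
        "D | 138": 2.3244,
        "D | 138 | 45": 0.8,
        "D | BCMA-Memb": 1.5,
        "D | BCMA-Memb | 45": 1.8540,
        "D | BCMA-Peri": 0.8,
        "D | BCMA-Peri | 45": 2.0,
        "D | 138 | BCMA-Memb": 3.6084,
        "D | 138 | BCMA-Memb | 45": 1.0,
        "D | 138 | BCMA-Peri": 0.8,
        "D | 138 | BCMA-Peri | 45": 0.5,
    },
}

# --------------------------------------------------------------------------
# Intensity / morphology model (arbitrary fluorescence units, pixels).
# Background pixel level is LOW_LEVEL; a positive marker paints HIGH_LEVEL.
LOW_LEVEL = 100.0
HIGH_LEVEL = 800.0
DAPI_LEVEL = 1000.0
BCMA_BLEED = 200.0  # off-band BCMA signal inside a BCMA+ cell
BCMA_MEDIAN = 500.0  # whole-cell BCMA median for a BCMA+ cell
ARTIFACT_LEVEL = 1800.0  # saturated debris
REL_NOISE = 0.12  # per-event intensity s.d. as a fraction of the mean

CHANNELS = ("dapi", "cd138", "bcma", "cd45")


def _channel_levels(true_class: str) -> dict[str, float]:
    """Mean intensity model per truth label (whole-cell medians + BCMA bands)."""
    if true_class == "ARTIFACT":
        return {
            "dapi": 40.0,
            "cd138": ARTIFACT_LEVEL,
            "bcma": ARTIFACT_LEVEL,
            "cd45": 300.0,
            "bcma_memb": ARTIFACT_LEVEL,
            "bcma_peri": ARTIFACT_LEVEL,
        }
    name = "D | 45" if true_class == "BACKGROUND" else true_class
    has138 = "138" in name
    has45 = "45" in name
    memb = "BCMA-Memb" in name
    peri = "BCMA-Peri" in name
    return {
        "dapi": DAPI_LEVEL,
        "cd138": HIGH_LEVEL if has138 else LOW_LEVEL,
        "bcma": BCMA_MEDIAN if (memb or peri) else LOW_LEVEL,
        "cd45": HIGH_LEVEL if has45 else LOW_LEVEL,
        "bcma_memb": HIGH_LEVEL if memb else (BCMA_BLEED if peri else LOW_LEVEL),
        "bcma_peri": HIGH_LEVEL if peri else (BCMA_BLEED if memb else LOW_LEVEL),
    }


def true_phenotype(true_class: str) -> str | None:
    """Phenotype class implied by a truth label (BACKGROUND leukocytes are
    CD45+ nucleated cells, hence 'D | 45'); None for artifacts."""
    if true_class == "ARTIFACT":
        return None
    if true_class == "BACKGROUND":
        return "D | 45"
    return true_class


@dataclass(frozen=True)
class SampleSpec:
    """One blood sample's generative parameters.

    ``class_incidence`` maps phenotype-class names to expected cells/mL in
    the blood; expected planted counts are ``incidence x
    effective_volume_ml``.  ``n_background_cells`` is the number of
    white-blood-cell background events entering the analysis at desk scale
    (the real assay analyzes ~6 million; feature distributions, not volume,
    are what downstream stages consume).
    """

    sample_id: str = "S0"
    disease_state: str = "NDMM"
    n_background_cells: int = 5000
    class_incidence: Mapping[str, float] = field(default_factory=dict)
    artifact_rate: float = 0.02
    cbc_nucleated_per_ml: float = 6.0e6
    blood_volume_ml: float = 8.0
    n_slides: int = 2
    cells_per_slide: float = 3.0e6
    frames_per_slide: int = 4

    def __post_init__(self) -> None:
        if self.disease_state not in DISEASE_STATES:
            raise ValueError(f"disease_state must be one of {DISEASE_STATES}")
        if self.n_background_cells < 0:
            raise ValueError("n_background_cells must be >= 0")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")
        if self.blood_volume_ml <= 0:
            raise ValueError("blood_volume_ml must be > 0")
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        if self.cbc_nucleated_per_ml <= 0 or self.cells_per_slide <= 0:
            raise ValueError("cell counts must be > 0")
        for cls, inc in self.class_incidence.items():
            if cls not in PHENOTYPE_CLASSES:
                raise ValueError(f"unknown phenotype class {cls!r}")
            if inc < 0:
                raise ValueError("incidences must be >= 0")

    @property
    def n_analyzed_cells(self) -> float:
        return self.n_slides * self.cells_per_slide

    @property
    def effective_volume_ml(self) -> float:
        """Blood volume equivalent of the analyzed cells (mL)."""
        return self.n_analyzed_cells / self.cbc_nucleated_per_ml

    @classmethod
    def from_preset(cls, disease_state: str, sample_id: str = "S0", **kw) -> "SampleSpec":
        return cls(
            sample_id=sample_id,
            disease_state=disease_state,
            class_incidence=dict(INCIDENCE_PRESETS[disease_state]),
            **kw,
        )


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one generated event."""

    cell_id: str
    true_class: str  # phenotype class name, "BACKGROUND" or "ARTIFACT"
    true_center: tuple[float, float]  # (x, y) = (column, row), 0-based
    true_nuclear_radius: float
    true_cell_radius: float
    true_channel_levels: dict[str, float]
    bcma_localization: str  # none / membrane / perinuclear

    def __post_init__(self) -> None:
        if not self.true_cell_radius >= self.true_nuclear_radius > 0:
            raise ValueError("need cell_radius >= nuclear_radius > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout, presets, noise and covariate model for a full run."""

    state_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(COHORT_LAYOUT_TEXT)
    )
    incidence_presets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in INCIDENCE_PRESETS.items()}
    )
    n_background_cells: int = 5000
    artifact_rate: float = 0.02
    covariate_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for s, n in self.state_counts.items():
            if s not in DISEASE_STATES or n < 0:
                raise ValueError(f"bad cohort layout entry {s!r}: {n}")
        if not -1 <= self.covariate_correlation <= 1:
            raise ValueError("covariate_correlation must be in [-1, 1]")


# --------------------------------------------------------------------------
# Event-table generation (vectorized; no rendering)


def _sample_truth_labels(spec: SampleSpec, rng: np.random.Generator) -> np.ndarray:
    """Truth label per event: background + Poisson planted rare + artifacts."""
    labels = ["BACKGROUND"] * spec.n_background_cells
    v_eff = spec.effective_volume_ml
    for cls in PHENOTYPE_CLASSES:  # fixed iteration order for determinism
        inc = spec.class_incidence.get(cls, 0.0)
        if inc > 0:
            labels.extend([cls] * int(rng.poisson(inc * v_eff)))
    labels = np.array(labels, dtype=object)
    # each biological event is replaced by debris with prob artifact_rate
    is_art = rng.random(len(labels)) < spec.artifact_rate
    labels[is_art] = "ARTIFACT"
    return labels


_MORPH_KEYS = (
    "nuclear_radius_mean",
    "cell_ratio_mean",
    "ecc_mean",
    "solidity_mean",
)


def _morphology_params(true_class: str) -> dict[str, float]:
    if true_class == "ARTIFACT":
        return {
            "nuclear_radius_mean": 3.0,
            "cell_ratio_mean": 1.2,
            "ecc_mean": 0.85,
            "solidity_mean": 0.6,
        }
    if true_class == "BACKGROUND" or true_class == "D | 45":
        return {
            "nuclear_radius_mean": 8.5,
            "cell_ratio_mean": 1.35,
            "ecc_mean": 0.30,
            "solidity_mean": 0.95,
        }
    # plasma cells and other rare nucleated classes: larger nucleus and a
    # wide cytoplasmic rim (keeps the membrane band clear of the
    # perinuclear annulus at this pixel scale)
    return {
        "nuclear_radius_mean": 10.5,
        "cell_ratio_mean": 2.0,
        "ecc_mean": 0.40,
        "solidity_mean": 0.95,
    }


def generate_event_table(
    spec: SampleSpec, seed: int | np.random.SeedSequence = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a per-cell feature table plus ground truth for one sample.

    Returns ``(events, truth)``: the event table follows the documented
    CellEvent schema; the truth table carries ``true_class`` and
    ``bcma_localization`` per ``cell_id``.
    """
    rng = np.random.default_rng(seed)
    labels = _sample_truth_labels(spec, rng)
    return _features_from_labels(spec, labels, rng)


def _features_from_labels(
    spec: SampleSpec, labels: np.ndarray, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(labels)
    if n == 0:
        cols = _event_columns()
        return (
            pd.DataFrame(columns=cols),
            pd.DataFrame(columns=["cell_id", "true_class", "bcma_localization"]),
        )

    level_keys = ("dapi", "cd138", "bcma", "cd45", "bcma_memb", "bcma_peri")
    level_tab = {
        lab: _channel_levels(lab) for lab in np.unique(labels.astype(str))
    }
    morph_tab = {lab: _morphology_params(lab) for lab in level_tab}
    means = {
        k: np.array([level_tab[lab][k] for lab in labels]) for k in level_keys
    }
    morph = {
        k: np.array([morph_tab[lab][k] for lab in labels]) for k in _MORPH_KEYS
    }

    def noisy(mean: np.ndarray) -> np.ndarray:
        return np.clip(rng.normal(mean, REL_NOISE * mean), 0.0, None)

    nuc_r = np.clip(rng.normal(morph["nuclear_radius_mean"], 1.0), 1.5, None)
    cell_r = nuc_r * np.clip(rng.normal(morph["cell_ratio_mean"], 0.08), 1.05, None)
    ecc = np.clip(rng.normal(morph["ecc_mean"], 0.08), 0.0, 0.98)
    solidity = np.clip(rng.normal(morph["solidity_mean"], 0.03), 0.2, 1.0)
    nuclear_area = np.pi * nuc_r**2 * np.sqrt(1 - ecc**2)
    cellular_area = np.pi * cell_r**2 * np.sqrt(1 - ecc**2)

    total_frames = spec.n_slides * spec.frames_per_slide
    frame_idx = rng.integers(0, total_frames, size=n)
    ids = np.arange(n)
    events = pd.DataFrame(
        {
            "cell_id": [f"{spec.sample_id}:{i}" for i in ids],
            "sample_id": spec.sample_id,
            "slide": frame_idx // spec.frames_per_slide,
            "frame": frame_idx % spec.frames_per_slide,
            "x": rng.uniform(0, 1024, size=n),
            "y": rng.uniform(0, 1024, size=n),
            "nuclear_area": nuclear_area,
            "nuclear_eccentricity": ecc,
            "cellular_area": cellular_area,
            "cellular_eccentricity": np.clip(ecc + rng.normal(0, 0.03, n), 0, 0.98),
            "nuclear_perimeter": 2 * np.pi * nuc_r,
            "cellular_solidity": solidity,
            "median_dapi": noisy(means["dapi"]),
            "median_cd138": noisy(means["cd138"]),
            "median_bcma": noisy(means["bcma"]),
            "median_cd45": noisy(means["cd45"]),
            "mad_dapi": noisy(0.08 * means["dapi"]),
            "mad_cd138": noisy(0.08 * means["cd138"]),
            "mad_bcma": noisy(0.08 * means["bcma"]),
            "mad_cd45": noisy(0.08 * means["cd45"]),
            "bcma_membrane_score": noisy(means["bcma_memb"]),
            "bcma_perinuclear_score": noisy(means["bcma_peri"]),
        }
    )
    loc = np.where(
        np.char.find(labels.astype(str), "BCMA-Memb") >= 0,
        "membrane",
        np.where(np.char.find(labels.astype(str), "BCMA-Peri") >= 0, "perinuclear", "none"),
    )
    truth = pd.DataFrame(
        {
            "cell_id": events["cell_id"],
            "true_class": labels.astype(str),
            "bcma_localization": loc,
        }
    )
    return events, truth


def _event_columns() -> list[str]:
    return [
        "cell_id", "sample_id", "slide", "frame", "x", "y",
        "nuclear_area", "nuclear_eccentricity", "cellular_area",
        "cellular_eccentricity", "nuclear_perimeter", "cellular_solidity",
        "median_dapi", "median_cd138", "median_bcma", "median_cd45",
        "mad_dapi", "mad_cd138", "mad_bcma", "mad_cd45",
        "bcma_membrane_score", "bcma_perinuclear_score",
    ]


#: Feature columns used by detection and curation models.
FEATURE_COLUMNS = _event_columns()[6:]


# --------------------------------------------------------------------------
# Frame rendering


def generate_frame(
    spec: SampleSpec,
    frame_index: int = 0,
    seed: int | np.random.SeedSequence = 0,
    class_counts: Mapping[str, int] | None = None,
    frame_shape: tuple[int, int] = (1024, 1024),
    background_level: float = LOW_LEVEL,
    noise_sd: float = 8.0,
    poisson_noise: bool = False,
    max_place_attempts: int = 200,
) -> tuple[np.ndarray, list[CellTruth]]:
    """Render one multichannel field of view plus per-cell ground truth.

    The frame holds ``spec.n_background_cells`` background leukocytes (each
    flipped to debris with probability ``artifact_rate``) plus Poisson
    planted rare cells at per-frame incidence, unless ``class_counts`` pins
    exact per-class event counts (keys may also be ``"BACKGROUND"`` /
    ``"ARTIFACT"``).  Returns ``(image, truths)`` with ``image`` shaped
    ``(4, H, W)`` float32 in channel order DAPI, CD138, BCMA, CD45.

    Geometry: the nucleus is a filled ellipse; the cell is the same ellipse
    scaled outward; CD138/CD45 fill the cell mask; BCMA paints a membrane
    ring (a 3-px band just outside the cell boundary is included in the
    cell mask here, i.e. the outermost 3 px of the cell) or a perinuclear
    annulus (band 1-4 px outside the nuclear mask) according to the true
    localization.  Cells are placed without overlap by rejection sampling;
    exceeding capacity raises ``RuntimeError`` naming the placed count.
    """
    h, w = frame_shape
    if h <= 0 or w <= 0:
        raise ValueError("frame dimensions must be positive")
    rng = np.random.default_rng(seed)

    if class_counts is not None:
        labels: list[str] = []
        for cls, cnt in class_counts.items():
            if cls not in PHENOTYPE_CLASSES and cls not in ("BACKGROUND", "ARTIFACT"):
                raise ValueError(f"unknown class {cls!r}")
            labels.extend([cls] * int(cnt))
        labels_arr = np.array(labels, dtype=object)
    else:
        total_frames = spec.n_slides * spec.frames_per_slide
        per_frame = {
            cls: inc * spec.effective_volume_ml / total_frames
            for cls, inc in spec.class_incidence.items()
        }
        labels = ["BACKGROUND"] * spec.n_background_cells
        for cls in PHENOTYPE_CLASSES:
            lam = per_frame.get(cls, 0.0)
            if lam > 0:
                labels.extend([cls] * int(rng.poisson(lam)))
        labels_arr = np.array(labels, dtype=object)
        is_art = rng.random(len(labels_arr)) < spec.artifact_rate
        labels_arr[is_art] = "ARTIFACT"

    image = np.full((4, h, w), background_level, dtype=np.float64)
    truths: list[CellTruth] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)

    for i, lab in enumerate(labels_arr):
        mp = _morphology_params(str(lab))
        nuc_r = max(1.5, rng.normal(mp["nuclear_radius_mean"], 1.0))
        cell_r = nuc_r * max(1.05, rng.normal(mp["cell_ratio_mean"], 0.08))
        ecc = float(np.clip(rng.normal(mp["ecc_mean"], 0.08), 0.0, 0.9))
        margin = cell_r + 6
        for attempt in range(max_place_attempts):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if all(
                (r0 - r1) ** 2 + (c0 - c1) ** 2 > (margin + rad1 + 3) ** 2
                for r1, c1, rad1 in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place cell {i} of {len(labels_arr)}: "
                f"frame capacity exceeded after placing {len(placed)}"
            )
        placed.append((r0, c0, cell_r))

        levels = _channel_levels(str(lab))
        theta = rng.uniform(0, np.pi)
        # ellipse semi-axes with the requested eccentricity, same area as circle
        b_over_a = np.sqrt(1 - ecc**2)
        a_n = nuc_r / np.sqrt(b_over_a)
        b_n = nuc_r * np.sqrt(b_over_a)
        a_c, b_c = a_n * cell_r / nuc_r, b_n * cell_r / nuc_r

        nuc_mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_ellipse(r0, c0, a_n, b_n, shape=(h, w), rotation=theta)
        nuc_mask[rr, cc] = True
        cell_mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_ellipse(r0, c0, a_c, b_c, shape=(h, w), rotation=theta)
        cell_mask[rr, cc] = True
        cell_mask |= nuc_mask

        if lab == "ARTIFACT":
            image[1][cell_mask] = levels["cd138"]
            image[2][cell_mask] = levels["bcma"]
            image[0][cell_mask] = levels["dapi"]
            image[3][cell_mask] = levels["cd45"]
            bcma_loc = "none"
        else:
            image[0][nuc_mask] = levels["dapi"]
            if levels["cd138"] > LOW_LEVEL:
                image[1][cell_mask] = levels["cd138"]
            if levels["cd45"] > LOW_LEVEL:
                image[3][cell_mask] = levels["cd45"]
            name = str(lab)
            if "BCMA-Memb" in name:
                # 3-px band straddling the cell boundary (outside + inside)
                ring = ndi.binary_dilation(cell_mask, structure=disk(3)) & ~cell_mask
                ring |= cell_mask & ~ndi.binary_erosion(cell_mask, structure=disk(3))
                image[2][cell_mask] = BCMA_BLEED
                image[2][ring] = levels["bcma_memb"]
                bcma_loc = "membrane"
            elif "BCMA-Peri" in name:
                # annulus 1-4 px outside the nuclear boundary
                annulus = ndi.binary_dilation(nuc_mask, structure=disk(4)) & ~(
                    ndi.binary_dilation(nuc_mask, structure=disk(1))
                )
                image[2][cell_mask] = BCMA_BLEED
                image[2][annulus] = levels["bcma_peri"]
                bcma_loc = "perinuclear"
            else:
                bcma_loc = "none"

        truths.append(
            CellTruth(
                cell_id=f"{spec.sample_id}:f{frame_index}:{i}",
                true_class=str(lab),
                true_center=(c0, r0),
                true_nuclear_radius=float(nuc_r),
                true_cell_radius=float(cell_r),
                true_channel_levels={k: float(v) for k, v in levels.items()},
                bcma_localization=bcma_loc,
            )
        )

    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    if poisson_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(np.float64)
    return np.clip(image, 0, None).astype(np.float32), truths


def write_frame_tiff(path, image: np.ndarray) -> None:
    """Write a (4, H, W) frame as a multi-page TIFF with channel metadata."""
    import tifffile

    tifffile.imwrite(
        str(path),
        image,
        metadata={"axes": "CYX", "Channel": {"Name": ["DAPI", "CD138", "BCMA", "CD45"]}},
    )


# --------------------------------------------------------------------------
# Cohorts and curation sets


def _clinical_row(
    state: str, planted_key_count: float, rho: float, rng: np.random.Generator
) -> dict[str, float]:
    age_med = {"MGUS": 70, "SMM": 61, "NDMM": 63, "RRMM": 65}[state]
    mspike_med = {"MGUS": 0.4, "SMM": 1.3, "NDMM": 1.9, "RRMM": 0.45}[state]
    z_count = (planted_key_count - 2.0) / 1.5  # rough standardization
    z = rho * z_count + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal()
    return {
        "age": float(np.clip(round(rng.normal(age_med, 8)), 38, 88)),
        "m_spike": float(max(0.0, mspike_med * np.exp(0.5 * z))),
        "del13": int(rng.random() < 0.3),
        "gain_1q": int(rng.random() < 0.3),
    }


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], pd.DataFrame]:
    """Generate per-sample event tables, truths and a clinical covariate table.

    Returns ``(samples, clinical)`` where ``samples`` maps sample_id to
    ``(events, truth)`` and ``clinical`` holds one row per sample with
    disease state, age, an M-spike-like continuous marker whose coupling to
    the planted D | 138 | BCMA-Memb burden is set by
    ``covariate_correlation``, and binary cytogenetic flags.
    """
    root = np.random.SeedSequence(config.seed)
    samples: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    clin_rows = []
    idx = 0
    for state in DISEASE_STATES:
        n_state = config.state_counts.get(state, 0)
        for j in range(n_state):
            sid = f"{state}-{j:02d}"
            spec = SampleSpec(
                sample_id=sid,
                disease_state=state,
                n_background_cells=config.n_background_cells,
                class_incidence=dict(config.incidence_presets[state]),
                artifact_rate=config.artifact_rate,
            )
            child = root.spawn(1)[0]
            events, truth = generate_event_table(spec, child)
            samples[sid] = (events, truth)
            planted_key = int((truth["true_class"] == "D | 138 | BCMA-Memb").sum())
            rng = np.random.default_rng(root.spawn(1)[0])
            row = {"sample_id": sid, "disease_state": state}
            row.update(
                _clinical_row(state, planted_key, config.covariate_correlation, rng)
            )
            clin_rows.append(row)
            idx += 1
    clinical = pd.DataFrame(clin_rows)
    return samples, clinical


def generate_curation_set(
    n_events: int = 2000,
    artifact_fraction: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Labeled cell-vs-artifact training set for the curation model.

    A scaled-down stand-in for a manually curated training archive: a mix
    of background leukocytes and rare classes labeled ``"cell"`` plus
    debris labeled ``"artifact"``, with a ``label`` column appended.
    """
    if not 0 < artifact_fraction < 1:
        raise ValueError("artifact_fraction must be in (0, 1)")
    n_art = int(round(n_events * artifact_fraction))
    n_cells = n_events - n_art
    spec = SampleSpec(sample_id="curation", n_background_cells=n_cells)
    rng = np.random.default_rng(seed)
    # ~10% of the "cell" examples are rare classes, the rest leukocytes
    n_rare = n_cells // 10
    labels = np.array(
        ["BACKGROUND"] * (n_cells - n_rare)
        + ["D | 138 | BCMA-Memb"] * (n_rare - n_rare // 2)
        + ["D | 138"] * (n_rare // 2)
        + ["ARTIFACT"] * n_art,
        dtype=object,
    )
    events, truth = _features_from_labels(spec, labels, rng)
    events["label"] = np.where(truth["true_class"] == "ARTIFACT", "artifact", "cell")
    events["cell_id"] = [f"curation:{i}" for i in range(len(events))]
    return events
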