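"""Synthetic whole-slide data: tissue label rasters, cell point patterns,
simulated pathologist raters, an error-prone automated reader, and a
neoadjuvant-response cohort.

The generator emulates the data streams of a digital-pathology sTIL
(stromal tumor-infiltrating lymphocyte) reader study:

* a tissue map — an integer raster labelling background (0), cancer area (1)
  and cancer stroma (2) at a known physical scale (microns per pixel);
* a cell table — point detections of lymphoid and tumor cells in slide
  coordinates (μm, origin top-left, y increasing downward);
* visual raters — pathologists who estimate the stromal lymphocyte coverage
  percentage from a handful of fields, with bias, noise and coarse rounding;
* an automated reader — a stand-in for a deployed detection/segmentation
  model with imperfect lymphocyte recall, spurious detections, and a
  degraded stroma mask tuned to a target IoU;
* a response cohort — Miller-Payne grades linked to true sTIL through a
  latent-variable ordered-logit model, so that the binary responder flag
  (grade 4-5) follows an exact logistic law in the sTIL covariate.

Every operation is a pure function of its inputs and an integer seed.
Lymphoid cells are treated as spheres of radius 3 μm when converting counts
to an area-coverage percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, spatial, special

from .errors import InvalidConfigError, UndefinedScoreError

# ---------------------------------------------------------------------------
# Conventions and constants
# ---------------------------------------------------------------------------

#: Tissue label codes.
BACKGROUND, CANCER, STROMA = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, CANCER, STROMA})
LABEL_NAMES = {BACKGROUND: "background", CANCER: "cancer_area", STROMA: "cancer_stroma"}

#: Lymphoid cell radius in μm used for geometric coverage.
LYMPH_RADIUS_UM = 3.0

#: Cell class codes used in cell tables.
LYMPHOID, TUMOR = "lymphoid", "tumor"
CELL_CLASSES = (LYMPHOID, TUMOR)

#: Column schema of a cell table.
CELL_COLUMNS = ("slide_id", "x_um", "y_um", "cell_class")

UM2_PER_MM2 = 1e6


def empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slide_id": pd.Series(dtype=str),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "cell_class": pd.Series(dtype=str),
        }
    )


def validate_cell_table(cells: pd.DataFrame) -> None:
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise InvalidConfigError(f"cell table missing columns: {sorted(missing)}")
    bad = set(cells["cell_class"].unique()) - set(CELL_CLASSES)
    if bad:
        raise InvalidConfigError(f"unknown cell classes: {sorted(bad)}")
    if len(cells) and ((cells["x_um"] < 0).any() or (cells["y_um"] < 0).any()):
        raise InvalidConfigError("cell coordinates must be non-negative")


# ---------------------------------------------------------------------------
# Tissue map
# ---------------------------------------------------------------------------


@dataclass
class TissueMap:
    """Integer tissue-label raster with physical scale.

    ``labels`` is indexed (row, col) = (y, x); a point (x_um, y_um) maps to
    pixel (floor(y_um / mpp), floor(x_um / mpp)).
    """

    labels: np.ndarray
    mpp: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidConfigError("labels must be a 2-D raster")
        if self.mpp <= 0:
            raise InvalidConfigError("mpp must be positive")
        codes = set(np.unique(self.labels).tolist())
        if not codes <= VALID_LABELS:
            raise InvalidConfigError(f"labels contain illegal codes: {sorted(codes - VALID_LABELS)}")

    # -- geometry -----------------------------------------------------------

    @property
    def height_um(self) -> float:
        return self.labels.shape[0] * self.mpp

    @property
    def width_um(self) -> float:
        return self.labels.shape[1] * self.mpp

    @property
    def pixel_area_um2(self) -> float:
        return self.mpp * self.mpp

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def stroma_area_um2(self) -> float:
        """Stroma area: stroma pixel count × mpp², exactly the area used by scoring."""
        return float(np.count_nonzero(self.labels == STROMA)) * self.pixel_area_um2

    @property
    def cancer_area_um2(self) -> float:
        return float(np.count_nonzero(self.labels == CANCER)) * self.pixel_area_um2

    def pixel_of(self, x_um: np.ndarray, y_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) pixel indices of points, clipped to the raster."""
        rows = np.clip(np.floor(np.asarray(y_um) / self.mpp).astype(int), 0, self.labels.shape[0] - 1)
        cols = np.clip(np.floor(np.asarray(x_um) / self.mpp).astype(int), 0, self.labels.shape[1] - 1)
        return rows, cols

    def labels_at(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        rows, cols = self.pixel_of(x_um, y_um)
        return self.labels[rows, cols]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Gaussian-smoothed white noise, rescaled to unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(sigma_px, 1e-9))
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_tissue_map(
    width_um: float,
    height_um: float,
    mpp: float = 2.0,
    stroma_fraction: float = 0.35,
    cancer_fraction: float = 0.35,
    seed: int | np.random.Generator = 0,
    slide_id: str = "slide",
    correlation_length_um: float = 200.0,
) -> TissueMap:
    """Generate a spatially coherent tissue label raster.

    A smoothed Gaussian random field is rank-thresholded: the highest-valued
    ``cancer_fraction`` of pixels become cancer area and the next
    ``stroma_fraction`` become cancer stroma, so the realized fractions are
    exact to the pixel and the stroma forms a band around the tumor nests.
    """
    if width_um <= 0 or height_um <= 0:
        raise InvalidConfigError("slide dimensions must be positive")
    if mpp <= 0:
        raise InvalidConfigError("mpp must be positive")
    if stroma_fraction < 0 or cancer_fraction < 0 or stroma_fraction + cancer_fraction > 1:
        raise InvalidConfigError("tissue fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    shape = (max(int(round(height_um / mpp)), 1), max(int(round(width_um / mpp)), 1))
    f = _smooth_field(rng, shape, correlation_length_um / mpp)
    n = f.size
    n_cancer = int(round(cancer_fraction * n))
    n_stroma = int(round(stroma_fraction * n))
    order = np.argsort(f, axis=None)[::-1]  # descending field value
    labels = np.full(n, BACKGROUND, dtype=np.uint8)
    labels[order[:n_cancer]] = CANCER
    labels[order[n_cancer : n_cancer + n_stroma]] = STROMA
    return TissueMap(labels.reshape(shape), mpp=mpp, slide_id=slide_id)


# ---------------------------------------------------------------------------
# Cell point patterns
# ---------------------------------------------------------------------------


@dataclass
class IntensityConfig:
    """Intensity of the lymphoid / tumor point processes.

    base_density and tumor_density are cells per mm² of stroma and cancer
    area respectively. heterogeneity is the log-scale standard deviation of a
    smooth doubly stochastic intensity field (0 = homogeneous Poisson);
    field_correlation_length (μm) is its smoothing length.
    cancer_lymphoid_fraction places lymphoid cells in the cancer area at that
    fraction of base_density (default 0: strictly stromal lymphocytes).
    """

    base_density: float = 7000.0
    heterogeneity: float = 1.0
    field_correlation_length: float = 200.0
    tumor_density: float = 8000.0
    cancer_lymphoid_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.base_density < 0 or self.tumor_density < 0:
            raise InvalidConfigError("densities must be >= 0")
        if self.heterogeneity < 0:
            raise InvalidConfigError("heterogeneity must be >= 0")
        if not 0 <= self.cancer_lymphoid_fraction <= 1:
            raise InvalidConfigError("cancer_lymphoid_fraction must be in [0, 1]")


def _scatter_in_pixels(
    rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray, counts: np.ndarray, mpp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform point placement inside pixels with given per-pixel counts."""
    rep_rows = np.repeat(rows, counts)
    rep_cols = np.repeat(cols, counts)
    n = rep_rows.size
    x = (rep_cols + rng.random(n)) * mpp
    y = (rep_rows + rng.random(n)) * mpp
    return x, y


def _poisson_points_in_mask(
    rng: np.random.Generator,
    mask: np.ndarray,
    density_per_mm2: float,
    mpp: float,
    rel_intensity: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson sample restricted to a label mask.

    Per-pixel Poisson counts (pixel mean = density × pixel area × relative
    intensity) followed by uniform placement within each pixel — an exact
    realization of the inhomogeneous process at raster resolution.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or density_per_mm2 == 0:
        return np.empty(0), np.empty(0)
    lam = np.full(rows.size, density_per_mm2 * mpp * mpp / UM2_PER_MM2)
    if rel_intensity is not None:
        lam = lam * rel_intensity[rows, cols]
    counts = rng.poisson(lam)
    return _scatter_in_pixels(rng, rows, cols, counts, mpp)


def lymphoid_intensity_field(
    tmap: TissueMap, cfg: IntensityConfig, rng: np.random.Generator
) -> np.ndarray | None:
    """Relative (mean-one over stroma) log-Gaussian intensity field, or None
    when the process is homogeneous."""
    if cfg.heterogeneity == 0:
        return None
    g = _smooth_field(rng, tmap.labels.shape, cfg.field_correlation_length / tmap.mpp)
    f = np.exp(cfg.heterogeneity * g)
    stroma = tmap.mask(STROMA)
    norm = f[stroma].mean() if stroma.any() else f.mean()
    return f / norm


def generate_cells(tmap: TissueMap, cfg: IntensityConfig, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate lymphoid and tumor cell point patterns on a tissue map.

    Lymphoid cells follow an inhomogeneous Poisson process with a smooth
    random log-intensity field (the doubly stochastic mechanism behind
    spatially heterogeneous lymphocyte infiltration), restricted to cancer
    stroma; tumor cells are homogeneous Poisson in the cancer area.
    """
    rng = np.random.default_rng(seed)
    rel = lymphoid_intensity_field(tmap, cfg, rng)
    parts = []
    lx, ly = _poisson_points_in_mask(rng, tmap.mask(STROMA), cfg.base_density, tmap.mpp, rel)
    parts.append((lx, ly, LYMPHOID))
    if cfg.cancer_lymphoid_fraction > 0:
        cx, cy = _poisson_points_in_mask(
            rng, tmap.mask(CANCER), cfg.base_density * cfg.cancer_lymphoid_fraction, tmap.mpp, rel
        )
        parts.append((cx, cy, LYMPHOID))
    tx, ty = _poisson_points_in_mask(rng, tmap.mask(CANCER), cfg.tumor_density, tmap.mpp)
    parts.append((tx, ty, TUMOR))
    frames = [
        pd.DataFrame({"slide_id": tmap.slide_id, "x_um": x, "y_um": y, "cell_class": cls})
        for x, y, cls in parts
        if x.size
    ]
    if not frames:
        return empty_cell_table()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Geometric slide truth
# ---------------------------------------------------------------------------


@dataclass
class SlideTruth:
    """Ground-truth geometric sTIL of a slide: the percentage of stroma area
    covered by lymphoid cells modelled as disks of radius 3 μm."""

    slide_id: str
    true_stil: float
    stroma_area_um2: float
    lymphoid_in_stroma: int


def coverage_percent(lymphoid_count: float, stroma_area_um2: float) -> float:
    """100 · π r² · N / A with r = 3 μm, clamped to [0, 100]."""
    if stroma_area_um2 <= 0:
        raise UndefinedScoreError("stroma area is zero; coverage undefined")
    pct = 100.0 * np.pi * LYMPH_RADIUS_UM**2 * lymphoid_count / stroma_area_um2
    return float(np.clip(pct, 0.0, 100.0))


def count_lymphoid_in_stroma(tmap: TissueMap, cells: pd.DataFrame) -> int:
    lymph = cells[cells["cell_class"] == LYMPHOID]
    if lymph.empty:
        return 0
    on_stroma = tmap.labels_at(lymph["x_um"].to_numpy(), lymph["y_um"].to_numpy()) == STROMA
    return int(on_stroma.sum())


def true_stil(tmap: TissueMap, cells: pd.DataFrame) -> SlideTruth:
    """Geometric ground-truth sTIL score of a slide.

    Independent of tumor-cell rows and of lymphoid cells outside stroma.
    Raises UndefinedScoreError when the slide has no stroma.
    """
    area = tmap.stroma_area_um2
    if area <= 0:
        raise UndefinedScoreError(f"slide {tmap.slide_id!r} has no cancer stroma")
    n = count_lymphoid_in_stroma(tmap, cells)
    return SlideTruth(tmap.slide_id, coverage_percent(n, area), area, n)


# ---------------------------------------------------------------------------
# Simulated pathologist rater
# ---------------------------------------------------------------------------


@dataclass
class RaterProfile:
    """Generative model of one pathologist's visual sTIL estimation.

    The rater samples ``k_fields`` square visual fields (side ``field_size``
    μm) centred on stroma, estimates the local lymphocyte coverage in each
    with multiplicative lognormal noise (``noise_sd`` is the log-scale sigma),
    averages the fields, applies multiplicative then additive bias, rounds to
    ``rounding_grain`` percentage points and clamps to [0, 100].

    ``reliance_weight`` (w) and ``revision_prob`` (q) govern behaviour when a
    slide is revisited with automated assistance: with probability q the
    rater rescores, pulling a fraction w of the way toward the automated
    score.
    """

    rater_id: str = "A"
    k_fields: int = 8
    field_size: float = 300.0
    additive_bias: float = 0.0
    multiplicative_bias: float = 1.0
    noise_sd: float = 0.35
    rounding_grain: float = 5.0
    reliance_weight: float = 0.8
    revision_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.k_fields < 1:
            raise InvalidConfigError("k_fields must be >= 1")
        if self.rounding_grain < 1:
            raise InvalidConfigError("rounding_grain must be >= 1")
        if not (0 <= self.reliance_weight <= 1 and 0 <= self.revision_prob <= 1):
            raise InvalidConfigError("reliance_weight and revision_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


def round_to_grain(value: float, grain: float) -> float:
    return float(np.round(value / grain) * grain)


def simulate_rater(
    tmap: TissueMap,
    cells: pd.DataFrame,
    profile: RaterProfile,
    seed: int | np.random.Generator = 0,
) -> float:
    """Simulate one pathologist's visual sTIL percentage for a slide.

    With all error parameters zero and a field covering the whole slide this
    returns the geometric truth up to rounding.
    """
    rng = np.random.default_rng(seed)
    stroma = tmap.mask(STROMA)
    s_rows, s_cols = np.nonzero(stroma)
    if s_rows.size == 0:
        raise UndefinedScoreError(f"slide {tmap.slide_id!r} has no cancer stroma to score")

    lymph = cells[cells["cell_class"] == LYMPHOID]
    lx = lymph["x_um"].to_numpy()
    ly = lymph["y_um"].to_numpy()
    on_stroma = tmap.labels_at(lx, ly) == STROMA if len(lymph) else np.empty(0, bool)
    lx, ly = lx[on_stroma], ly[on_stroma]

    half = profile.field_size / 2.0
    whole_slide = profile.field_size >= max(tmap.width_um, tmap.height_um)
    pixel_area = tmap.pixel_area_um2
    # cumulative stroma-pixel count image for O(1) window area queries
    cum = np.cumsum(np.cumsum(stroma.astype(np.int64), axis=0), axis=1)
    cum = np.pad(cum, ((1, 0), (1, 0)))

    estimates = []
    for _ in range(profile.k_fields):
        if whole_slide:
            x0, y0 = 0.0, 0.0
            x1, y1 = tmap.width_um, tmap.height_um
        else:
            i = rng.integers(s_rows.size)
            cx = (s_cols[i] + 0.5) * tmap.mpp
            cy = (s_rows[i] + 0.5) * tmap.mpp
            x0 = min(max(cx - half, 0.0), max(tmap.width_um - profile.field_size, 0.0))
            y0 = min(max(cy - half, 0.0), max(tmap.height_um - profile.field_size, 0.0))
            x1 = min(x0 + profile.field_size, tmap.width_um)
            y1 = min(y0 + profile.field_size, tmap.height_um)
        r0, c0 = int(y0 / tmap.mpp), int(x0 / tmap.mpp)
        r1 = min(int(np.ceil(y1 / tmap.mpp)), stroma.shape[0])
        c1 = min(int(np.ceil(x1 / tmap.mpp)), stroma.shape[1])
        n_stroma_px = cum[r1, c1] - cum[r0, c1] - cum[r1, c0] + cum[r0, c0]
        if n_stroma_px == 0:
            continue
        in_win = (lx >= x0) & (lx < x1) & (ly >= y0) & (ly < y1)
        local = 100.0 * np.pi * LYMPH_RADIUS_UM**2 * int(in_win.sum()) / (n_stroma_px * pixel_area)
        if profile.noise_sd > 0:
            local *= float(np.exp(rng.normal(0.0, profile.noise_sd)))
        estimates.append(local)
    if not estimates:
        raise UndefinedScoreError("no scorable field contained stroma")
    score = float(np.mean(estimates))
    score = score * profile.multiplicative_bias + profile.additive_bias
    score = round_to_grain(score, profile.rounding_grain)
    return float(np.clip(score, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Simulated automated (DL-style) reader
# ---------------------------------------------------------------------------


@dataclass
class ReaderErrorProfile:
    """Error model of the automated reader.

    Defaults anchor the simulated reader to the deployed-model quality the
    study design assumes: lymphocyte detection F1 near 0.79 and stroma
    segmentation IoU near 0.666. The false-positive load is set so that,
    jointly with the recall loss and the counts lost to mask degradation,
    the automated sTIL score is approximately unbiased against the
    geometric truth — emulating a reader whose scoring constant was
    calibrated against pathologists.
    """

    lymphoid_recall: float = 0.90
    false_positive_rate: float = 1750.0  # spurious lymphoid detections per mm² stroma
    mask_iou_target: float = 0.666
    perturbation_scale: float = 120.0  # μm

    def __post_init__(self) -> None:
        if not 0 <= self.lymphoid_recall <= 1:
            raise InvalidConfigError("lymphoid_recall must be in [0, 1]")
        if self.false_positive_rate < 0:
            raise InvalidConfigError("false_positive_rate must be >= 0")
        if not 0 < self.mask_iou_target <= 1:
            raise InvalidConfigError("mask_iou_target must be in (0, 1]")
        if self.perturbation_scale <= 0:
            raise InvalidConfigError("perturbation_scale must be positive")


@dataclass
class DLReaderResult:
    detected_cells: pd.DataFrame
    degraded_map: TissueMap
    score: float
    realized_stroma_iou: float


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 when both empty)."""
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def _degrade_mask(
    mask: np.ndarray,
    iou_target: float,
    sigma_px: float,
    rng: np.random.Generator,
    tol: float = 0.005,
) -> tuple[np.ndarray, float]:
    """Area-preserving random morphological degradation of a binary mask.

    The mask indicator is smoothed, perturbed by a smooth noise field of
    amplitude ``a``, and re-thresholded at the quantile that preserves the
    pixel count; ``a`` is found by bisection so the realized IoU against the
    original mask hits ``iou_target``.
    """
    n_on = int(np.count_nonzero(mask))
    if n_on == 0 or iou_target >= 1.0:
        return mask.copy(), 1.0
    # base smoothing stays light so that thin stroma bands survive a = 0;
    # the perturbation length scale lives in the noise field
    base = ndimage.gaussian_filter(mask.astype(float), sigma=min(sigma_px, 2.0))
    q = 1.0 - n_on / mask.size

    best: np.ndarray | None = None
    best_iou = -np.inf
    # the thresholded-field IoU can jump in the noise amplitude; on a bad
    # draw of the noise field, retry with a fresh one
    for _attempt in range(3):
        noise = _smooth_field(rng, mask.shape, sigma_px)

        def realize(a: float) -> tuple[np.ndarray, float]:
            f = base + a * noise * base.std()
            new = f > np.quantile(f, q)
            return new, mask_iou(mask, new)

        new0, iou0 = realize(0.0)
        if iou0 <= iou_target:  # smoothing alone already at/below target
            if iou0 < iou_target - tol:
                warnings.warn(
                    f"mask IoU target {iou_target:.3f} unattainable at this perturbation "
                    f"scale; realized {iou0:.3f}",
                    stacklevel=3,
                )
            return new0, iou0
        lo, hi = 0.0, 1.0
        new_hi, iou_hi = realize(hi)
        while iou_hi > iou_target and hi < 64:
            hi *= 2.0
            new_hi, iou_hi = realize(hi)
        if iou_hi > iou_target:
            warnings.warn(
                f"mask IoU target {iou_target:.3f} unattainable at this perturbation "
                f"scale; realized {iou_hi:.3f}",
                stacklevel=3,
            )
            return new_hi, iou_hi
        cand, cand_iou = new_hi, iou_hi
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            new, iou = realize(mid)
            if abs(iou - iou_target) < abs(cand_iou - iou_target):
                cand, cand_iou = new, iou
            if abs(iou - iou_target) <= tol:
                break
            if iou > iou_target:
                lo = mid
            else:
                hi = mid
        if best is None or abs(cand_iou - iou_target) < abs(best_iou - iou_target):
            best, best_iou = cand, cand_iou
        if abs(best_iou - iou_target) <= 2 * tol:
            break
    return best, best_iou


def simulate_dl_reader(
    tmap: TissueMap,
    cells: pd.DataFrame,
    err: ReaderErrorProfile,
    seed: int | np.random.Generator = 0,
    scoring_config=None,
) -> DLReaderResult:
    """Simulate the automated reader on a slide.

    True lymphoid cells are kept with probability ``lymphoid_recall``; false
    positives are added uniformly over stroma at ``false_positive_rate`` per
    mm²; the stroma mask is randomly degraded toward ``mask_iou_target``; the
    sTIL score is then computed from the degraded outputs exactly as for real
    model output.
    """
    from .scoring import ScoringConfig, score_slide  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)
    lymph = cells[cells["cell_class"] == LYMPHOID]
    other = cells[cells["cell_class"] != LYMPHOID]
    keep = rng.random(len(lymph)) < err.lymphoid_recall
    detected = [other, lymph[keep]]
    if err.false_positive_rate > 0:
        fx, fy = _poisson_points_in_mask(rng, tmap.mask(STROMA), err.false_positive_rate, tmap.mpp)
        if fx.size:
            detected.append(
                pd.DataFrame({"slide_id": tmap.slide_id, "x_um": fx, "y_um": fy, "cell_class": LYMPHOID})
            )
    detected_cells = pd.concat([d for d in detected if len(d)], ignore_index=True) if any(
        len(d) for d in detected
    ) else empty_cell_table()

    stroma = tmap.mask(STROMA)
    new_stroma, realized_iou = _degrade_mask(
        stroma, err.mask_iou_target, err.perturbation_scale / tmap.mpp, rng
    )
    labels = tmap.labels.copy()
    labels[stroma & ~new_stroma] = CANCER  # lost stroma read as cancer area
    labels[new_stroma] = STROMA
    degraded = TissueMap(labels, mpp=tmap.mpp, slide_id=tmap.slide_id)

    cfg = scoring_config if scoring_config is not None else ScoringConfig()
    score = score_slide(detected_cells, degraded, cfg).score
    return DLReaderResult(detected_cells, degraded, score, realized_iou)


# ---------------------------------------------------------------------------
# Detection / segmentation quality metrics
# ---------------------------------------------------------------------------


@dataclass
class ClassDetectionStat:
    precision: float
    recall: float
    f1: float
    n_truth: int
    n_detected: int
    n_matched: int


def _greedy_match(truth_xy: np.ndarray, det_xy: np.ndarray, radius: float) -> int:
    """Number of one-to-one greedy nearest-pair matches within ``radius``."""
    if len(truth_xy) == 0 or len(det_xy) == 0:
        return 0
    tree_t = spatial.cKDTree(truth_xy)
    tree_d = spatial.cKDTree(det_xy)
    pairs = tree_t.sparse_distance_matrix(tree_d, radius, output_type="coo_matrix")
    if pairs.nnz == 0:
        return 0
    order = np.argsort(pairs.data, kind="stable")
    used_t = np.zeros(len(truth_xy), dtype=bool)
    used_d = np.zeros(len(det_xy), dtype=bool)
    n = 0
    for i, j in zip(pairs.row[order], pairs.col[order]):
        if not used_t[i] and not used_d[j]:
            used_t[i] = used_d[j] = True
            n += 1
    return n


def detection_metrics(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    match_radius_um: float = 6.0,
    truth_map: TissueMap | None = None,
    degraded_map: TissueMap | None = None,
) -> dict:
    """Point-detection F1 per cell class and mask IoU per tissue class.

    F1 uses greedy nearest-neighbour one-to-one matching within
    ``match_radius_um``. An empty truth matched against an empty detection
    set scores F1 = 1 by convention (nothing to find, nothing found).
    """
    out: dict = {"f1": {}, "iou": {}}
    for cls in CELL_CLASSES:
        t = truth[truth["cell_class"] == cls]
        d = detected[detected["cell_class"] == cls]
        n_t, n_d = len(t), len(d)
        if n_t == 0 and n_d == 0:
            out["f1"][cls] = ClassDetectionStat(1.0, 1.0, 1.0, 0, 0, 0)
            continue
        m = _greedy_match(
            t[["x_um", "y_um"]].to_numpy(), d[["x_um", "y_um"]].to_numpy(), match_radius_um
        )
        prec = m / n_d if n_d else 0.0
        rec = m / n_t if n_t else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        out["f1"][cls] = ClassDetectionStat(prec, rec, f1, n_t, n_d, m)
    if truth_map is not None and degraded_map is not None:
        for code in (CANCER, STROMA):
            out["iou"][LABEL_NAMES[code]] = mask_iou(truth_map.mask(code), degraded_map.mask(code))
    return out


# ---------------------------------------------------------------------------
# Response cohort
# ---------------------------------------------------------------------------

HER2 = "HER2_positive"
TNBC = "TNBC"


@dataclass
class CohortConfig:
    """Neoadjuvant-response cohort generator settings.

    The response model is a latent-variable ordered logit: latent = β0 +
    β_stil·(sTIL/10) + β_subtype·1[TNBC] + logistic noise, cut at
    ``grade_cutpoints`` into Miller-Payne grades 1-5. The responder flag
    (grade ≥ 4) therefore follows an exact binary-logistic law with slope
    β_stil per 10 sTIL percentage points.
    """

    n_total: int = 203
    n_her2: int = 148
    n_tnbc: int = 55
    beta0: float = 0.0
    beta_stil: float = 0.3
    beta_subtype: float = 0.2
    grade_cutpoints: tuple[float, float, float, float] = (-2.0, -1.0, 0.0, 0.85)

    def __post_init__(self) -> None:
        if self.n_her2 + self.n_tnbc != self.n_total:
            raise InvalidConfigError("n_her2 + n_tnbc must equal n_total")
        cuts = np.asarray(self.grade_cutpoints, dtype=float)
        if cuts.size != 4 or not np.all(np.diff(cuts) > 0):
            raise InvalidConfigError("grade_cutpoints must be 4 strictly increasing values")


def generate_cohort(
    cfg: CohortConfig,
    true_stil_values: Sequence[float],
    seed: int | np.random.Generator = 0,
    slide_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a response cohort from a library of true sTIL values.

    If the library size differs from ``cfg.n_total`` slides are sampled with
    replacement. Returns a DataFrame with columns slide_id, subtype,
    true_stil, mp_grade, responder.
    """
    rng = np.random.default_rng(seed)
    stil = np.asarray(true_stil_values, dtype=float)
    if stil.size == 0:
        raise InvalidConfigError("slide library is empty")
    if slide_ids is None:
        slide_ids = [f"slide_{i:04d}" for i in range(stil.size)]
    slide_ids = list(slide_ids)
    if stil.size != cfg.n_total:
        idx = rng.integers(stil.size, size=cfg.n_total)
        stil = stil[idx]
        slide_ids = [f"{slide_ids[i]}_r{k}" for k, i in enumerate(idx)]
    subtype = np.array([HER2] * cfg.n_her2 + [TNBC] * cfg.n_tnbc)
    subtype = subtype[rng.permutation(cfg.n_total)]
    eta = cfg.beta0 + cfg.beta_stil * stil / 10.0 + cfg.beta_subtype * (subtype == TNBC)
    latent = eta + rng.logistic(size=cfg.n_total)
    grade = 1 + np.searchsorted(np.asarray(cfg.grade_cutpoints), latent)
    return pd.DataFrame(
        {
            "slide_id": slide_ids,
            "subtype": subtype,
            "true_stil": stil,
            "mp_grade": grade.astype(int),
            "responder": grade >= 4,
        }
    )


def responder_probability(cfg: CohortConfig, stil: np.ndarray, is_tnbc: np.ndarray) -> np.ndarray:
    """Closed-form P(responder) implied by the latent-variable construction."""
    eta = cfg.beta0 + cfg.beta_stil * np.asarray(stil) / 10.0 + cfg.beta_subtype * np.asarray(is_tnbc)
    return special.expit(eta - cfg.grade_cutpoints[3])
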