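"""Dual-stain single-cell morphometrics (high-content image analysis).

Cells carrying both the fluorogenic turnover probe (SA) and the competing
F-actin stain (phalloidin, Ph) are segmented with nuclei as seeds, described
by 41 features — 9 shape, 6 intensity (3 per channel), 26 texture (13
Haralick statistics per channel) — and classified by canonical linear
discriminant analysis.  Group-mean equality is tested with Wilks' lambda
(Rao's approximate F), 50%-mass contour ellipses summarize the canonical
scatter, and a bootstrap forest ranks the discriminating features.

The 41-descriptor composition is a reconstruction (the original list is not
public): it matches the stated shape/intensity/texture categories and sums
to exactly 41.  Feature-set version tag: ``sa-ph-41-v1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import linalg, ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .texture import HARALICK_NAMES, haralick_features

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_SET_VERSION",
    "DualChannelCellImage",
    "SegmentationResult",
    "LDAModel",
    "ClassificationReport",
    "WilksResult",
    "ContourEllipse",
    "PredictorRanking",
    "segment_cells",
    "extract_features",
    "extract_population",
    "fit_lda",
    "transform",
    "classify",
    "cross_validated_accuracy",
    "wilks_test",
    "canonical_contour",
    "rank_predictors",
]

logger = logging.getLogger(__name__)

FEATURE_SET_VERSION = "sa-ph-41-v1"

SHAPE_FEATURES = (
    "area", "perimeter", "eccentricity", "solidity", "extent",
    "major_axis_length", "minor_axis_length", "form_factor", "compactness",
)
INTENSITY_FEATURES = (
    "sa_mean", "sa_integrated", "sa_std",
    "ph_mean", "ph_integrated", "ph_std",
)
TEXTURE_FEATURES = tuple(f"sa_{n}" for n in HARALICK_NAMES) + tuple(
    f"ph_{n}" for n in HARALICK_NAMES
)
FEATURE_NAMES = SHAPE_FEATURES + INTENSITY_FEATURES + TEXTURE_FEATURES
assert len(FEATURE_NAMES) == 41


@dataclass
class DualChannelCellImage:
    """Co-registered SA / phalloidin / nuclear channels of one field."""

    sa: np.ndarray
    ph: np.ndarray
    nuc: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.sa = np.asarray(self.sa, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.nuc = np.asarray(self.nuc, dtype=float)
        if not (self.sa.shape == self.ph.shape == self.nuc.shape):
            raise ValueError("channels must share dimensions")
        for name, ch in (("sa", self.sa), ("ph", self.ph), ("nuc", self.nuc)):
            if np.any(ch < 0):
                raise ValueError(f"negative intensities in {name} channel")


@dataclass
class SegmentationResult:
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    n_cells: int
    border_excluded: int

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]


def segment_cells(
    img: DualChannelCellImage,
    min_nucleus_area: int = 15,
    min_cell_area: int = 60,
    exclude_border: bool = True,
) -> SegmentationResult:
    """Nuclei-seeded cytoskeletal segmentation.

    Nuclei: Otsu threshold on the nuclear channel + connected components.
    Cytoplasm: Otsu threshold on the summed SA+Ph signal.  Cells: watershed
    on the inverted distance transform of the cytoplasm mask, seeded by the
    nuclei; touching cells with separate nuclei are thereby split.  Cells on
    the image border are excluded and counted.
    """
    empty = SegmentationResult(
        np.zeros(img.nuc.shape, int), np.zeros(img.nuc.shape, int), 0, 0
    )
    if np.ptp(img.nuc) == 0:
        return empty
    nuc_mask = img.nuc > threshold_otsu(img.nuc)
    nuc_mask = remove_small_objects(nuc_mask, max_size=min_nucleus_area - 1)
    nuclei, n_nuclei = ndimage.label(nuc_mask)
    if n_nuclei == 0:
        return empty

    actin = img.sa + img.ph
    if np.ptp(actin) == 0:
        return empty
    cyto_mask = actin > threshold_otsu(actin)
    cyto_mask |= nuc_mask  # every seed must lie inside the cell mask
    distance = ndimage.distance_transform_edt(cyto_mask)
    cells = watershed(-distance, markers=nuclei, mask=cyto_mask)

    border_excluded = 0
    if exclude_border:
        kept = clear_border(cells)
        border_excluded = len(np.unique(cells)) - len(np.unique(kept))
        cells = kept

    # drop fragments too small to be cells, and their orphaned nuclei
    for rid in np.unique(cells):
        if rid > 0 and np.count_nonzero(cells == rid) < min_cell_area:
            cells[cells == rid] = 0
    cells, _, _ = relabel_sequential(cells)
    nuclei = np.where(cells > 0, nuclei, 0)
    n_cells = int(cells.max())
    return SegmentationResult(nuclei, cells, n_cells, int(border_excluded))


def extract_features(
    img: DualChannelCellImage,
    seg: SegmentationResult,
    cell_id: int,
    gray_levels: int = 8,
) -> np.ndarray | None:
    """The 41-feature vector of one segmented cell, or None if degenerate.

    Haralick statistics are computed on the cell's bounding-box patch,
    min-max quantized to ``gray_levels`` within the cell mask, distance 1,
    averaged over the 4 standard directions.  Cells whose mask yields no
    co-occurrence pair (e.g. single-pixel regions) are dropped with a log
    message.
    """
    mask = seg.cell_labels == cell_id
    if not mask.any():
        raise ValueError(f"cell id {cell_id} not present in segmentation")
    props = regionprops(mask.astype(np.uint8))[0]

    perimeter = props.perimeter
    area = props.area
    if perimeter > 0:
        form_factor = 4.0 * np.pi * area / perimeter ** 2
        compactness = perimeter ** 2 / (4.0 * np.pi * area)
    else:  # point-like region: treated as the circular limit
        form_factor, compactness = 1.0, 1.0
    shape = np.array([
        area, perimeter, props.eccentricity, props.solidity, props.extent,
        props.axis_major_length, props.axis_minor_length,
        form_factor, compactness,
    ], dtype=float)

    intensity = []
    for ch in (img.sa, img.ph):
        vals = ch[mask]
        intensity += [vals.mean(), vals.sum(), vals.std(ddof=0)]
    intensity = np.asarray(intensity)

    rmin, cmin, rmax, cmax = props.bbox
    sub_mask = mask[rmin:rmax, cmin:cmax]
    texture = np.concatenate([
        haralick_features(ch[rmin:rmax, cmin:cmax], sub_mask, levels=gray_levels)
        for ch in (img.sa, img.ph)
    ])
    if np.any(~np.isfinite(texture)):
        logger.warning(
            "cell %d dropped: degenerate region, texture undefined", cell_id
        )
        return None
    return np.concatenate([shape, intensity, texture])


def extract_population(
    fields: list, gray_levels: int = 8
) -> pd.DataFrame:
    """Segment and featurize a list of ``(DualChannelCellImage, condition)``.

    Returns a tidy frame: cell_id, condition, then the 41 named features.
    """
    rows = []
    cell_counter = 0
    for img, condition in fields:
        seg = segment_cells(img)
        for cid in seg.cell_ids:
            vec = extract_features(img, seg, int(cid), gray_levels=gray_levels)
            if vec is None:
                continue
            rows.append([cell_counter, condition] + list(vec))
            cell_counter += 1
    return pd.DataFrame(rows, columns=["cell_id", "condition", *FEATURE_NAMES])


# ---------------------------------------------------------------------------
# canonical discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Canonical discriminant model.

    ``scalings`` (features x components) map standardized features to
    canonical scores whose pooled within-group covariance is the identity;
    ``group_means`` are the group centroids in canonical space.
    """

    scalings: np.ndarray
    eigenvalues: np.ndarray
    groups: np.ndarray
    group_means: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    pooled_cov: np.ndarray
    priors: np.ndarray
    regularized: bool = False
    feature_names: tuple = ()


@dataclass
class ClassificationReport:
    groups: np.ndarray
    confusion: np.ndarray            # true x predicted counts
    percent_correct: float
    per_group_percent: dict = dc_field(default_factory=dict)


@dataclass
class WilksResult:
    lambda_: float
    f_stat: float
    df1: float
    df2: float
    p_f: float


@dataclass
class ContourEllipse:
    group: str
    center: np.ndarray
    semi_axes: np.ndarray
    angle_rad: float
    coverage: float


@dataclass
class PredictorRanking:
    features: list
    importances: np.ndarray


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    groups = np.unique(y)
    n, p = X.shape
    grand = X.mean(axis=0)
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    means = []
    for g in groups:
        xg = X[y == g]
        mg = xg.mean(axis=0)
        means.append(mg)
        d = xg - mg
        s_w += d.T @ d
        db = (mg - grand)[:, None]
        s_b += len(xg) * (db @ db.T)
    return groups, np.asarray(means), s_w, s_b


def fit_lda(X, y, standardize: bool = True, feature_names=()) -> LDAModel:
    """Canonical LDA: eigenvectors of the S_W^-1 S_B generalized eigenproblem.

    Features are z-scored (training statistics) before computing scatter
    matrices so heterogeneous units (area vs texture) do not dominate.
    Components are ordered by decreasing eigenvalue and scaled so canonical
    scores have identity pooled within-group covariance.  A singular pooled
    scatter triggers a ridge-regularized fallback, flagged on the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups_all, counts = np.unique(y, return_counts=True)
    if len(groups_all) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 cells")

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Z = (X - mu) / sd

    groups, means, s_w, s_b = _scatter_matrices(Z, y)
    n, p = Z.shape
    dof_w = n - len(groups)

    regularized = False
    try:
        evals, evecs = linalg.eigh(s_b, s_w)
    except linalg.LinAlgError:
        regularized = True
        ridge = 1e-6 * np.trace(s_w) / p * np.eye(p)
        evals, evecs = linalg.eigh(s_b, s_w + ridge)
    order = np.argsort(evals)[::-1]
    m = min(len(groups) - 1, p)
    evals = np.clip(evals[order][:m], 0.0, None)
    vecs = evecs[:, order][:, :m]

    # eigh gives a' S_W a = 1; rescale for unit *pooled covariance* of scores
    vecs = vecs * np.sqrt(dof_w)
    # deterministic sign: largest-magnitude coefficient positive
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]

    return LDAModel(
        scalings=vecs,
        eigenvalues=evals,
        groups=groups,
        group_means=means @ vecs,
        feature_mean=mu,
        feature_scale=sd,
        pooled_cov=s_w / dof_w,
        priors=counts / n,
        regularized=regularized,
        feature_names=tuple(feature_names),
    )


def transform(model: LDAModel, X) -> np.ndarray:
    """Canonical scores of feature rows under a fitted model."""
    Z = (np.asarray(X, dtype=float) - model.feature_mean) / model.feature_scale
    return Z @ model.scalings


def classify(model: LDAModel, X, y) -> ClassificationReport:
    """Nearest-group-mean classification in canonical space (equal priors).

    Resubstitution when called with the training data, matching the
    percent-correct convention of fitting and scoring on the same cells.
    Ties go to the lowest group index.
    """
    y = np.asarray(y)
    unseen = set(np.unique(y)) - set(model.groups)
    if unseen:
        raise ValueError(f"labels not seen at fit time: {sorted(unseen)}")
    scores = transform(model, X)
    d2 = ((scores[:, None, :] - model.group_means[None, :, :]) ** 2).sum(axis=2)
    pred = model.groups[np.argmin(d2, axis=1)]  # argmin → lowest index on ties

    k = len(model.groups)
    idx = {g: i for i, g in enumerate(model.groups)}
    confusion = np.zeros((k, k), dtype=int)
    for yt, yp in zip(y, pred):
        confusion[idx[yt], idx[yp]] += 1
    correct = np.trace(confusion)
    per_group = {
        g: 100.0 * confusion[i, i] / confusion[i].sum()
        for i, g in enumerate(model.groups) if confusion[i].sum() > 0
    }
    return ClassificationReport(
        groups=model.groups,
        confusion=confusion,
        percent_correct=100.0 * correct / len(y),
        per_group_percent=per_group,
    )


def cross_validated_accuracy(X, y, n_splits: int = 5, seed: int = 0) -> float:
    """Stratified k-fold percent correct (the validation-split variant)."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        model = fit_lda(X[tr], y[tr])
        scores = transform(model, X[te])
        d2 = ((scores[:, None, :] - model.group_means[None, :, :]) ** 2).sum(axis=2)
        pred = model.groups[np.argmin(d2, axis=1)]
        correct += int((pred == y[te]).sum())
    return 100.0 * correct / len(y)


def wilks_test(X, y) -> WilksResult:
    """Wilks' lambda = det(S_W)/det(S_T) with Rao's approximate F.

    Tests equality of multivariate group means.  Requires n - groups >
    features; reduce the feature set first otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups, _, s_w, s_b = _scatter_matrices(X, y)
    n, p = X.shape
    g = len(groups)
    if n - g <= p:
        raise ValueError(
            f"n - groups = {n - g} must exceed the {p} features; "
            "reduce the feature set before testing"
        )
    s_t = s_w + s_b
    sign_t, logdet_t = np.linalg.slogdet(s_t)
    sign_w, logdet_w = np.linalg.slogdet(s_w)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise ValueError("singular total scatter matrix; reduce the feature set")
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise ValueError("singular within scatter matrix; reduce the feature set")
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)

    vh = g - 1
    w = n - 1 - (p + g) / 2.0
    denom = p ** 2 + vh ** 2 - 5
    t = np.sqrt((p ** 2 * vh ** 2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * vh
    df2 = w * t - (p * vh - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t == 0:
        f_stat, p_f = np.inf, 0.0
    else:
        f_stat = (1 - lam_t) / lam_t * df2 / df1
        p_f = float(stats.f.sf(f_stat, df1, df2))
    return WilksResult(lam, float(f_stat), float(df1), float(df2), p_f)


def canonical_contour(model: LDAModel, scores, y, group,
                      coverage: float = 0.5) -> ContourEllipse:
    """Covariance ellipse of a group's first two canonical scores.

    Centered on the group canonical mean with axes scaled to the chi-square
    quantile enclosing ``coverage`` probability mass under a bivariate
    normal fit — the 50%-of-cells contour convention by default.
    """
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    scores = np.asarray(scores, dtype=float)[:, :2]
    sel = np.asarray(y) == group
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 cells in group {group!r}")
    pts = scores[sel]
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0, None)[::-1]
    evecs = evecs[:, ::-1]
    r2 = stats.chi2.ppf(coverage, df=2)
    return ContourEllipse(
        group=group,
        center=center,
        semi_axes=np.sqrt(evals * r2),
        angle_rad=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        coverage=coverage,
    )


def rank_predictors(X, y, n_boot: int = 200, seed: int = 0,
                    feature_names=None) -> PredictorRanking:
    """Bootstrap-forest feature importance ranking.

    An ensemble of ``n_boot`` bootstrap-resampled decision trees; per-feature
    impurity reductions are summed per tree and averaged over the ensemble.
    Deterministic given the seed.  Constant features get importance 0.
    """
    from sklearn.ensemble import RandomForestClassifier

    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for a stable ranking")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 groups")
    forest = RandomForestClassifier(
        n_estimators=n_boot, bootstrap=True, random_state=seed, n_jobs=1
    ).fit(X, y)
    imp = forest.feature_importances_
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    order = np.argsort(-imp, kind="stable")
    return PredictorRanking(
        features=[names[i] for i in order], importances=imp[order]
    )
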