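"""Per-layer naive Bayes classifiers with discretization and calibration.

One binary classifier is trained per class (five layers plus ``no_enrichment``)
on curated genes. Features are the fractional expression profile over the
seven samples plus log10 total FPKM. Continuous features are discretized into
equal-frequency bins fit on training data only; conditional probabilities are
Laplace-smoothed. Raw posteriors are calibrated by isotonic regression on
pooled out-of-fold cross-validation predictions, lightly smoothed.

Enrichment calls use the raw posterior threshold of 0.5; calibrated
probabilities are reported alongside and drive the alternative "patterned"
criterion (maximum calibrated layer probability exceeding the calibrated
no-enrichment probability).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .expression import (
    CLASSES,
    LAYERS,
    NO_ENRICHMENT,
    CurationLabel,
    QuantRecord,
    fractional_profile,
    is_classifiable,
    is_expressed,
)

logger = logging.getLogger(__name__)

_CLIP = 1e-9


def feature_vector(rec: QuantRecord) -> np.ndarray:
    """Classifier features: fractional profile plus log10 total FPKM.

    Values are rounded to 12 decimals so that mathematically tied profiles
    (common in degenerate or noise-free data) discretize identically.
    """
    frac = fractional_profile(rec)
    return np.round(np.concatenate([frac, [math.log10(float(np.sum(rec.fpkm)))]]), 12)


@dataclass
class NBModel:
    """Binary naive Bayes model for one class.

    ``feature_bins[f]`` holds the interior bin edges for feature ``f`` (empty
    for a degenerate feature, giving a single bin). ``cond_prob[f][b, c]`` is
    the smoothed probability of bin ``b`` for class ``c`` (0 = negative,
    1 = positive) and sums to 1 over bins for each feature and class.
    """

    layer: str
    prior: float
    feature_bins: list[np.ndarray]
    cond_prob: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must be in (0, 1)")

    @property
    def n_features(self) -> int:
        return len(self.feature_bins)

    def bin_index(self, f: int, value: float) -> int:
        # searchsorted sends out-of-range values to the nearest edge bin
        return int(np.searchsorted(self.feature_bins[f], value, side="right"))


def _equal_frequency_edges(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin edges snapped to midpoints between distinct values,
    so tied observations never straddle an edge. Degenerate (constant)
    features get no edges, i.e. a single bin."""
    u = np.unique(values)
    if u.size <= 1:
        return np.empty(0)
    edges = []
    for q in np.quantile(values, np.arange(1, bins) / bins):
        idx = int(np.searchsorted(u, q, side="right"))
        if 0 < idx < u.size:
            edges.append((u[idx - 1] + u[idx]) / 2)
    return np.unique(edges)


def train(
    records: Sequence[QuantRecord],
    labels: Sequence[bool],
    layer: str,
    bins: int = 4,
    smoothing: float = 1.0,
) -> NBModel:
    """Fit the binary naive Bayes model for one class on curated records."""
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError(f"{layer}: need >= 2 positives and >= 2 negatives")
    X = np.vstack([feature_vector(r) for r in records])
    n_features = X.shape[1]
    feature_bins: list[np.ndarray] = []
    cond_prob: list[np.ndarray] = []
    for f in range(n_features):
        edges = _equal_frequency_edges(X[:, f], bins)
        n_bins = len(edges) + 1
        counts = np.zeros((n_bins, 2))
        idx = np.searchsorted(edges, X[:, f], side="right")
        for c, mask in enumerate((~y, y)):
            counts[:, c] = np.bincount(idx[mask], minlength=n_bins)
        probs = (counts + smoothing) / (counts.sum(axis=0) + smoothing * n_bins)
        feature_bins.append(edges)
        cond_prob.append(probs)
    prior = float(y.mean())
    return NBModel(layer=layer, prior=prior, feature_bins=feature_bins, cond_prob=cond_prob)


def posterior_from_features(model: NBModel, x: np.ndarray) -> float:
    """Naive Bayes posterior of the positive class for a raw feature vector."""
    x = np.asarray(x, dtype=float)
    if x.size != model.n_features:
        raise ValueError("feature dimensionality mismatch")
    log_odds = math.log(model.prior) - math.log(1.0 - model.prior)
    for f in range(model.n_features):
        b = model.bin_index(f, x[f])
        p = model.cond_prob[f][b]
        log_odds += math.log(p[1]) - math.log(p[0])
    post = 1.0 / (1.0 + math.exp(-log_odds))
    return float(min(max(post, _CLIP), 1.0 - _CLIP))


def predict_raw(model: NBModel, rec: QuantRecord) -> float:
    """Naive Bayes posterior probability of the positive class for one record."""
    return posterior_from_features(model, feature_vector(rec))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Out-of-fold performance summary for one class's classifier."""

    layer: str
    auc: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR)
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int | None = None


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties share rank)."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both classes")
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    return np.column_stack([fpr, tpr])


def cross_validate(
    records: Sequence[QuantRecord],
    curations: Mapping[str, CurationLabel],
    layer: str,
    folds: int = 10,
    seed: int = 0,
    bins: int = 4,
    smoothing: float = 1.0,
    threshold: float = 0.5,
) -> tuple[CVReport, np.ndarray]:
    """Stratified k-fold CV for one class; returns the report and pooled
    out-of-fold positive-class probabilities (aligned with ``records``).

    Contamination is the distribution, over the other curated classes, of the
    true classes of false-positive predictions; multi-layer curations split
    their weight equally across their layers.
    """
    y = np.array([curations[r.feature_id].is_positive_for(layer) for r in records])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"{layer}: cannot stratify {folds} folds with {n_pos} positives / {n_neg} negatives"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(records), np.nan)
    for train_idx, test_idx in skf.split(np.zeros(len(records)), y):
        model = train([records[i] for i in train_idx], y[train_idx], layer,
                      bins=bins, smoothing=smoothing)
        for i in test_idx:
            oof[i] = predict_raw(model, records[i])
    assert not np.any(np.isnan(oof))

    pred = oof > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0

    contamination: dict[str, float] = {}
    for i in np.flatnonzero(pred & ~y):
        cur = curations[records[i].feature_id]
        sources = [NO_ENRICHMENT] if cur.no_enrichment else sorted(cur.enriched_layers)
        sources = [s for s in sources if s != layer] or sources
        for s in sources:
            contamination[s] = contamination.get(s, 0.0) + 1.0 / len(sources)
    total = sum(contamination.values())
    if total:
        contamination = {k: v / total for k, v in contamination.items()}

    report = CVReport(
        layer=layer,
        auc=_rank_auc(oof, y),
        roc_points=_roc_points(oof, y),
        precision=precision,
        recall=recall,
        tp=tp, fp=fp, fn=fn, tn=tn,
        contamination=contamination,
        seed=seed,
    )
    return report, oof


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationMap:
    """Monotone map from raw to calibrated probability.

    Piecewise-linear interpolation between ordered control points; inputs
    outside the control range take the nearest endpoint value.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.x) < 0) or np.any(np.diff(self.y) < -1e-12):
            raise ValueError("calibration control points must be monotone")
        if self.x.size and (self.x.min() < 0 or self.x.max() > 1
                            or self.y.min() < 0 or self.y.max() > 1):
            raise ValueError("control points must lie in [0, 1]")

    def __call__(self, raw):
        return np.clip(np.interp(raw, self.x, self.y), 0.0, 1.0)


def calibrate(raw: Sequence[float], labels: Sequence[bool],
              smooth_window: int = 3, points_per_bin: int = 100) -> CalibrationMap:
    """Smoothed calibration curve: positive frequency as a function of raw
    probability, constrained to be monotone.

    Sorted predictions are pooled into equal-count reliability bins
    (~``points_per_bin`` each). Bin frequencies are shrunk toward a weighted
    cubic trend in proportion to their binomial noise (an empirical-Bayes
    step that keeps an already-calibrated classifier near the identity
    without flattening genuinely curved reliability), smoothed by a centred
    moving average of width ``smooth_window``, and monotonized. Degenerate
    all-one-class inputs yield a constant map at the label frequency.
    """
    raw = np.asarray(raw, dtype=float)
    y = np.asarray(labels, dtype=float)
    if raw.size < 20:
        raise ValueError("need >= 20 labeled predictions to calibrate")
    if y.min() == y.max():
        v = float(np.clip(y[0], _CLIP, 1.0 - _CLIP))
        return CalibrationMap(x=np.array([0.0, 1.0]), y=np.array([v, v]))
    order = np.argsort(raw, kind="stable")
    # bin the two sides of 0.5 separately: posteriors are often strongly
    # bimodal, and purely global equal-count bins starve the minority tail
    low = order[raw[order] < 0.5]
    high = order[raw[order] >= 0.5]
    splits = []
    for side in (low, high):
        if side.size == 0:
            continue
        k = max(min(4, side.size // 15), min(side.size // points_per_bin, 20), 1)
        splits.extend(np.array_split(side, k))
    bx = np.array([raw[s].mean() for s in splits])
    by = np.array([y[s].mean() for s in splits])
    bn = np.array([len(s) for s in splits], dtype=float)
    se2 = np.maximum(by * (1 - by), 0.05) / bn
    design = np.vander(bx, 4)
    w_root = np.sqrt(bn)
    beta, *_ = np.linalg.lstsq(design * w_root[:, None], by * w_root, rcond=None)
    trend = design @ beta
    tau2 = max(0.0, float(np.average((by - trend) ** 2 - se2, weights=bn)))
    shrink = tau2 / (tau2 + se2)
    cy = trend + shrink * (by - trend)
    if smooth_window > 1 and cy.size > smooth_window:
        pad = smooth_window // 2
        padded = np.concatenate([np.repeat(cy[0], pad), cy, np.repeat(cy[-1], pad)])
        cy = np.convolve(padded, np.ones(smooth_window) / smooth_window, mode="valid")
    cy = np.maximum.accumulate(np.clip(cy, 0.0, 1.0))
    return CalibrationMap(x=np.clip(bx, 0, 1), y=cy)


# ---------------------------------------------------------------------------
# Whole-table classification
# ---------------------------------------------------------------------------

@dataclass
class LayerPrediction:
    """Raw and calibrated class probabilities plus enrichment calls."""

    feature_id: str
    raw_prob: dict[str, float]
    cal_prob: dict[str, float]
    enriched_calls: frozenset[str]
    patterned: bool
    patterned_calibrated: bool  # max layer cal prob > no-enrichment cal prob


def classify_all(
    quant_table: Iterable[QuantRecord],
    models: Mapping[str, NBModel],
    calibration_maps: Mapping[str, CalibrationMap],
    expression_threshold: float = 0.1,
    call_threshold: float = 0.5,
) -> list[LayerPrediction]:
    """Score every expressed, classifiable feature with all six classifiers."""
    out: list[LayerPrediction] = []
    for rec in quant_table:
        if not is_expressed(rec, expression_threshold):
            logger.debug("%s excluded: not expressed", rec.feature_id)
            continue
        if not is_classifiable(rec):
            logger.debug("%s excluded: CI filter", rec.feature_id)
            continue
        raw = {cls: predict_raw(models[cls], rec) for cls in CLASSES}
        cal = {cls: float(calibration_maps[cls](raw[cls])) for cls in CLASSES}
        calls = frozenset(l for l in LAYERS if raw[l] > call_threshold)
        max_layer_cal = max(cal[l] for l in LAYERS)
        out.append(LayerPrediction(
            feature_id=rec.feature_id,
            raw_prob=raw,
            cal_prob=cal,
            enriched_calls=calls,
            patterned=bool(calls),
            patterned_calibrated=max_layer_cal > cal[NO_ENRICHMENT],
        ))
    return out


@dataclass
class FittedClassifiers:
    """All six fitted models with their CV reports and calibration maps."""

    models: dict[str, NBModel]
    calibration_maps: dict[str, CalibrationMap]
    cv_reports: dict[str, CVReport]
    seed: int


def fit_layer_models(
    curated_records: Sequence[QuantRecord],
    curations: Mapping[str, CurationLabel],
    seed: int = 0,
    folds: int = 10,
    bins: int = 4,
    smoothing: float = 1.0,
) -> FittedClassifiers:
    """Train, cross-validate and calibrate one classifier per class."""
    models: dict[str, NBModel] = {}
    maps: dict[str, CalibrationMap] = {}
    reports: dict[str, CVReport] = {}
    for cls in CLASSES:
        y = [curations[r.feature_id].is_positive_for(cls) for r in curated_records]
        models[cls] = train(curated_records, y, cls, bins=bins, smoothing=smoothing)
        reports[cls], oof = cross_validate(
            curated_records, curations, cls, folds=folds, seed=seed,
            bins=bins, smoothing=smoothing)
        maps[cls] = calibrate(oof, y)
    return FittedClassifiers(models=models, calibration_maps=maps,
                             cv_reports=reports, seed=seed)


# ---------------------------------------------------------------------------
# Derived counts
# ---------------------------------------------------------------------------

def expected_gene_count(predicted: int, precision: float, recall: float) -> int:
    """Expected truly-enriched count: round(predicted * precision / recall).

    Rounding is half away from zero; the arithmetic runs in decimal so that
    printed two-decimal precision/recall values give their exact quotients
    (e.g. 1001 * 0.42 / 0.52 is exactly 808.5, not a float one ulp below).
    """
    if recall == 0:
        raise ValueError("undefined expectation: recall = 0")
    if predicted < 0 or not (0.0 <= precision <= 1.0) or not (0.0 < recall <= 1.0):
        raise ValueError("invalid inputs")
    x = Decimal(predicted) * Decimal(repr(precision)) / Decimal(repr(recall))
    return int(x.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def relative_enrichment_span(pred: LayerPrediction, floor: float = 1e-9) -> float:
    """Ratio of the largest to smallest calibrated layer probability."""
    vals = [pred.cal_prob[l] for l in LAYERS]
    return max(vals) / max(min(vals), floor)
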