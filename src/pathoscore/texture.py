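"""First-order and gray-level-matrix texture features.

Implements a documented core radiomics set: first-order statistics of the
grayscale tile, Haralick features of the gray-level co-occurrence matrix
(GLCM), and gray-level run-length matrix (GLRLM) features.  Tiles are
discretized into ``Ng`` equal-width bins over the observed range
(fixed-bin-count scheme, so features are invariant to adding a constant to
all pixels).  Matrix features use offset distance 1 in the four standard
2-D directions and are averaged over directions.

Slide-level values are the arithmetic mean of the per-tile vectors over the
sampled tiles, and the cohort feature matrix is z-score standardized with
training-set parameters (sample standard deviation, zero-variance columns
dropped).

Conventions: population (1/N) moments inside texture definitions; entropy
and uniformity in log base 2; GLCM correlation of a constant tile is 1 by
convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from pathoscore.tiling import SlideImage, candidate_tiles, sample_tiles, to_grayscale

logger = logging.getLogger(__name__)

DEFAULT_NG = 32

GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
GLRLM_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

FIRST_ORDER_NAMES = [
    "fo_mean", "fo_variance", "fo_skewness", "fo_kurtosis", "fo_energy",
    "fo_entropy", "fo_minimum", "fo_maximum", "fo_median", "fo_p10",
    "fo_p90", "fo_iqr", "fo_robust_mad", "fo_uniformity",
]
GLCM_NAMES = [
    "glcm_contrast", "glcm_correlation", "glcm_joint_entropy",
    "glcm_joint_energy", "glcm_homogeneity", "glcm_dissimilarity",
    "glcm_cluster_shade", "glcm_cluster_prominence", "glcm_max_probability",
]
GLRLM_NAMES = [
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp",
    "glrlm_lglre", "glrlm_hglre",
]

#: Single source of feature names and their order.
FEATURE_REGISTRY = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES

REGISTRY_VERSION = "core-fo-glcm-glrlm-1"


def discretize(gray_tile: np.ndarray, ng: int = DEFAULT_NG) -> np.ndarray:
    """Quantize a 2-D gray tile into ``ng`` equal-width bins over [min, max].

    Returns an integer array of levels in 1..ng; a constant tile maps to
    level 1 everywhere.
    """
    x = np.asarray(gray_tile)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.shape, dtype=np.int32)
    levels = np.floor((x - lo) / (hi - lo) * ng).astype(np.int32) + 1
    np.clip(levels, 1, ng, out=levels)
    return levels


def first_order_features(gray_tile: np.ndarray, ng: int = DEFAULT_NG) -> dict:
    """First-order statistics of the gray values (histogram features on the
    ``ng``-level discretization)."""
    x = np.asarray(gray_tile, dtype=np.float32).ravel()
    n = x.size
    mean = float(x.mean(dtype=np.float64))
    xc = x - np.float32(mean)
    x2 = xc * xc
    var = float(x2.mean(dtype=np.float64))  # population
    if var > 0:
        m3 = float((x2 * xc).mean(dtype=np.float64))
        m4 = float((x2 * x2).mean(dtype=np.float64))
        skew = m3 / var**1.5
        kurt = m4 / var**2  # non-excess
    else:
        skew, kurt = 0.0, 0.0
    energy = n * (var + mean * mean)
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    robust_mad = (float(np.abs(inner - inner.mean(dtype=np.float64)).mean(dtype=np.float64))
                  if inner.size else 0.0)
    levels = discretize(gray_tile, ng)
    p = np.bincount(levels.ravel(), minlength=ng + 1)[1:] / n
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())
    return {
        "fo_mean": mean,
        "fo_variance": var,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": energy,
        "fo_entropy": entropy,
        "fo_minimum": float(x.min()),
        "fo_maximum": float(x.max()),
        "fo_median": float(median),
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(p75 - p25),
        "fo_robust_mad": robust_mad,
        "fo_uniformity": uniformity,
    }


def glcm_matrix(levels: np.ndarray, offset, ng: int | None = None,
                symmetric: bool = True) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix for one pixel offset.

    Counts ordered pairs (levels[r, c], levels[r+dr, c+dc]); in symmetric
    mode the transpose is added before normalization.  Entries sum to 1.
    """
    lv = np.asarray(levels, dtype=np.int64)
    if ng is None:
        ng = int(lv.max())
    dr, dc = offset
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.bincount(
        ((a - 1) * ng + (b - 1)).ravel(), minlength=ng * ng
    ).reshape(ng, ng).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("offset larger than tile: no co-occurring pairs")
    return counts / total


def _glcm_stats(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = (i * pi).sum()
    mu_j = (i * pj).sum()
    sig_i = np.sqrt(((i - mu_i) ** 2 * pi).sum())
    sig_j = np.sqrt(((i - mu_j) ** 2 * pj).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    if sig_i * sig_j > 0:
        corr = float((((ii - mu_i) * (jj - mu_j) * p).sum()) / (sig_i * sig_j))
    else:
        corr = 1.0
    nz = p[p > 0]
    return {
        "glcm_contrast": float((diff**2 * p).sum()),
        "glcm_correlation": corr,
        "glcm_joint_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_homogeneity": float((p / (1.0 + diff**2)).sum()),
        "glcm_dissimilarity": float((np.abs(diff) * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()),
        "glcm_cluster_prominence": float(((ii + jj - mu_i - mu_j) ** 4 * p).sum()),
        "glcm_max_probability": float(p.max()),
    }


def glcm_features(levels: np.ndarray, ng: int | None = None,
                  offsets=GLCM_OFFSETS, symmetric: bool = True) -> dict:
    """GLCM features averaged over the given offsets."""
    lv = np.asarray(levels, dtype=np.int64)
    if ng is None:
        ng = int(lv.max())
    per = [_glcm_stats(glcm_matrix(lv, off, ng, symmetric)) for off in offsets]
    return {k: float(np.mean([d[k] for d in per])) for k in GLCM_NAMES}


_LINE_ORDER_CACHE: dict = {}


def _line_order(shape, direction):
    """Flattening order that makes each maximal line along ``direction``
    contiguous, plus the line-boundary indicator between adjacent flat
    positions (both cached per shape)."""
    key = (shape, direction)
    if key in _LINE_ORDER_CACHE:
        return _LINE_ORDER_CACHE[key]
    h, w = shape
    i, j = np.indices(shape)
    dr, dc = direction
    if (dr, dc) == (0, 1):
        order, line_id = None, np.repeat(np.arange(h), w)
    elif (dr, dc) == (1, 0):
        order, line_id = None, np.repeat(np.arange(w), h)
    elif (dr, dc) == (1, 1):
        d = (j - i).ravel()
        order = np.lexsort((i.ravel(), d))
        line_id = d[order]
    elif (dr, dc) == (1, -1):
        d = (j + i).ravel()
        order = np.lexsort((i.ravel(), d))
        line_id = d[order]
    else:
        raise ValueError(f"unsupported direction {direction}")
    line_break = line_id[1:] != line_id[:-1]
    _LINE_ORDER_CACHE[key] = (order, line_break)
    return order, line_break


def _runs(levels: np.ndarray, direction):
    """(run_levels, run_lengths) of the maximal runs along one direction."""
    lv = np.asarray(levels)
    order, line_break = _line_order(lv.shape, direction)
    if direction == (0, 1):
        flat = lv.ravel()
    elif direction == (1, 0):
        flat = np.ascontiguousarray(lv.T).ravel()
    else:
        flat = lv.ravel()[order]
    breaks = np.flatnonzero((flat[1:] != flat[:-1]) | line_break)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [flat.size]))
    return flat[starts], ends - starts


def glrlm_matrix(levels: np.ndarray, direction, ng: int | None = None) -> np.ndarray:
    """Gray-level run-length count matrix R[i, j]: number of maximal runs
    of level i+1 with length j+1 along one direction."""
    lv = np.asarray(levels, dtype=np.int64)
    if ng is None:
        ng = int(lv.max())
    run_levels, run_lengths = _runs(lv, direction)
    h, w = lv.shape
    max_len = {(0, 1): w, (1, 0): h}.get(tuple(direction), min(h, w))
    mat = np.zeros((ng, max_len), dtype=np.float64)
    np.add.at(mat, (run_levels - 1, run_lengths - 1), 1.0)
    return mat


def _glrlm_stats_from_runs(run_levels, run_lengths, n_pixels: int) -> dict:
    nr = len(run_lengths)
    level_counts = np.bincount(run_levels)[1:].astype(np.float64)
    length_counts = np.bincount(run_lengths)[1:].astype(np.float64)
    i = np.arange(1, len(level_counts) + 1, dtype=np.float64)
    j = np.arange(1, len(length_counts) + 1, dtype=np.float64)
    return {
        "glrlm_sre": float((length_counts / j**2).sum() / nr),
        "glrlm_lre": float((length_counts * j**2).sum() / nr),
        "glrlm_gln": float((level_counts**2).sum() / nr),
        "glrlm_rln": float((length_counts**2).sum() / nr),
        "glrlm_rp": float(nr / n_pixels),
        "glrlm_lglre": float((level_counts / i**2).sum() / nr),
        "glrlm_hglre": float((level_counts * i**2).sum() / nr),
    }


def glrlm_features(levels: np.ndarray, ng: int | None = None,
                   directions=GLRLM_DIRECTIONS) -> dict:
    """GLRLM features averaged over the given directions."""
    lv = np.asarray(levels, dtype=np.int64)
    n_pixels = lv.size
    per = [_glrlm_stats_from_runs(*_runs(lv, d), n_pixels) for d in directions]
    return {k: float(np.mean([d[k] for d in per])) for k in GLRLM_NAMES}


def tile_features(tile_pixels: np.ndarray, ng: int = DEFAULT_NG) -> dict:
    """The full registry feature vector of one RGB (or grayscale) tile."""
    px = np.asarray(tile_pixels)
    gray = to_grayscale(px) if px.ndim == 3 else px.astype(np.float64)
    out = first_order_features(gray, ng)
    levels = discretize(gray, ng)
    out.update(glcm_features(levels, ng))
    out.update(glrlm_features(levels, ng))
    return out


def aggregate_slide(tile_vectors: list) -> dict:
    """Element-wise mean of per-tile feature vectors (identical registries)."""
    if not tile_vectors:
        raise ValueError("no tile feature vectors to aggregate")
    keys = list(tile_vectors[0])
    for v in tile_vectors[1:]:
        if list(v) != keys:
            raise ValueError("tile feature vectors use different registries")
    return {k: float(np.mean([v[k] for v in tile_vectors])) for k in keys}


def slide_features(slide: SlideImage, k: int = 10, seed: int = 0,
                   ng: int = DEFAULT_NG, max_white: float = 0.5) -> dict:
    """Tile a slide, sample ``k`` tiles, and return the mean feature vector."""
    tiles = candidate_tiles(slide, max_white=max_white)
    sample = sample_tiles(tiles, slide.patient_id, k=k, seed=seed)
    return aggregate_slide([tile_features(t.pixels, ng) for t in sample.tiles])


def feature_matrix(slides, k: int = 10, seed: int = 0, ng: int = DEFAULT_NG,
                   max_white: float = 0.5) -> pd.DataFrame:
    """Per-patient feature matrix (rows = patients, columns = registry).

    ``slides`` is an iterable of SlideImage; each slide gets a deterministic
    per-slide sampling seed derived from ``seed`` and its position.
    """
    rows, ids = [], []
    for i, slide in enumerate(slides):
        tile_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        rows.append(slide_features(slide, k=k, seed=tile_seed, ng=ng, max_white=max_white))
        ids.append(slide.patient_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Z-score standardization with training-set mean and sample SD.

    Zero-variance columns are dropped at fit time and recorded in
    ``dropped_``.  Accepts and returns pandas DataFrames.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        self.dropped_ = list(X.columns[~keep])
        if self.dropped_:
            logger.info("dropping %d zero-variance features: %s",
                        len(self.dropped_), self.dropped_)
        self.columns_ = list(X.columns[keep])
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        return (X[self.columns_] - self.mean_) / self.sd_

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        return X[self.columns_] * self.sd_ + self.mean_


def zscore_fit(training: pd.DataFrame) -> ZScoreScaler:
    """Fit standardization parameters on a training feature matrix."""
    if len(training) < 2:
        raise ValueError("need at least 2 training rows to estimate a SD")
    return ZScoreScaler().fit(training)


def zscore_apply(matrix: pd.DataFrame, params: ZScoreScaler) -> pd.DataFrame:
    """Apply training-set standardization to a (train or test) matrix."""
    return params.transform(matrix)
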