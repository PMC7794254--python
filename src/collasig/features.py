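"""The 146-feature collagen quantification of one SHG image.

The registry is fixed and ordered: 12 morphological features (from the
segmented mask and traced fiber network), 6 first-order histogram
features, 80 grey-level co-occurrence (GLCM) features (contrast,
correlation, energy, homogeneity at displacements 1-5 px and directions
0/45/90/135 degrees) and 48 Gabor features (mean and variance of the
response magnitude of a 4-scale x 6-orientation filter bank), for a
total of 146.

"Variation" is computed as variance throughout; degenerate moments
(skewness, kurtosis, GLCM correlation at zero spread) map to 0 so the
vector never contains NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel

from .image import SHGImage
from .network import FiberNetwork, extract_fiber_network
from .segmentation import segment_collagen

# ---------------------------------------------------------------------------
# Configuration and registry
# ---------------------------------------------------------------------------

GLCM_DISPLACEMENTS = (1, 2, 3, 4, 5)
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity")
GABOR_WAVELENGTHS_PX = (4, 8, 16, 32)
GABOR_ORIENTATIONS_DEG = (0, 30, 60, 90, 120, 150)

MORPHOLOGICAL_NAMES = (
    "collagen_area_ratio",
    "n_fibers",
    "length_mean",
    "length_var",
    "width_mean",
    "width_var",
    "straightness_mean",
    "straightness_var",
    "crosslink_count",
    "crosslink_density",
    "crosslink_spacing_mean",
    "orientation_index",
)
HISTOGRAM_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
)


def _glcm_names() -> tuple[str, ...]:
    return tuple(
        f"glcm_{stat}_d{d}_a{a}"
        for stat in GLCM_STATS
        for d in GLCM_DISPLACEMENTS
        for a in GLCM_ANGLES_DEG
    )


def _gabor_names() -> tuple[str, ...]:
    return tuple(
        f"gabor_w{w}_o{o}_{stat}"
        for w in GABOR_WAVELENGTHS_PX
        for o in GABOR_ORIENTATIONS_DEG
        for stat in ("mean", "variance")
    )


GLCM_NAMES = _glcm_names()
GABOR_NAMES = _gabor_names()
FEATURE_NAMES: tuple[str, ...] = (
    MORPHOLOGICAL_NAMES + HISTOGRAM_NAMES + GLCM_NAMES + GABOR_NAMES
)
FEATURE_GROUPS = {
    "morphological": MORPHOLOGICAL_NAMES,
    "histogram": HISTOGRAM_NAMES,
    "glcm": GLCM_NAMES,
    "gabor": GABOR_NAMES,
}
REGISTRY_VERSION = "collasig-146-v1"

assert len(FEATURE_NAMES) == 146, "feature registry must total 146"
assert len(set(FEATURE_NAMES)) == 146, "feature names must be unique"
assert tuple(len(v) for v in FEATURE_GROUPS.values()) == (12, 6, 80, 48)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the feature extractor."""

    n_hist_bins: int = 64
    n_gray_levels: int = 32
    masked_mode: bool = False  # restrict texture features to collagen pixels
    min_spur_px: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# Orientation index
# ---------------------------------------------------------------------------

def orientation_index(mask: np.ndarray) -> float:
    """Collagen alignment in [0, 1] from the Fourier power spectrum.

    The windowed power spectrum of the (mean-removed) mask is reduced to an
    angular energy distribution; the orientation index is the circular
    resultant length of the doubled angles, 1 for perfectly aligned fibers
    and 0 in the isotropic limit.  Frequencies are restricted to an annulus
    (DC disk removed, corners beyond the Nyquist disk excluded) so the
    angular support is isotropic.  An empty mask gives 0.
    """
    mask = np.asarray(mask, dtype=float)
    if mask.sum() == 0:
        return 0.0
    h, w = mask.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    f = np.fft.fftshift(np.fft.fft2((mask - mask.mean()) * win))
    power = np.abs(f) ** 2
    fy = np.arange(h) - h // 2
    fx = np.arange(w) - w // 2
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    radius = np.hypot(FY, FX)
    r_max = min(h, w) / 2.0
    # the excluded DC disk scales with image size: window leakage occupies
    # a fixed number of low-frequency bins where angular resolution is poor
    r_min = max(2.0, min(h, w) / 64.0)
    sel = (radius > r_min) & (radius <= r_max)
    p = power[sel]
    total = p.sum()
    if total == 0:
        return 0.0
    theta = np.arctan2(FY[sel], FX[sel])
    return float(np.abs(np.sum(p * np.exp(2j * theta))) / total)


# ---------------------------------------------------------------------------
# Morphological features
# ---------------------------------------------------------------------------

def morphological_features(
    network: FiberNetwork,
    mask: np.ndarray,
    image: SHGImage,
) -> pd.Series:
    """The 12 morphological features, in registry order.

    Cross-link density is cross-links per mm^2 of collagen (mask) area;
    cross-link spacing is the mean nearest-neighbour distance between
    cross-links in micrometres (0 with fewer than two cross-links).
    """
    mask = np.asarray(mask) > 0
    px_um = image.pixel_size_um
    vals = dict.fromkeys(MORPHOLOGICAL_NAMES, 0.0)
    if not mask.any():
        return pd.Series(vals, index=list(MORPHOLOGICAL_NAMES), dtype=float)

    vals["collagen_area_ratio"] = float(mask.mean())
    vals["orientation_index"] = orientation_index(mask)
    if network.n_fibers:
        lengths = np.array([f.length_um for f in network.fibers])
        widths = np.array([f.mean_width_um for f in network.fibers])
        straight = np.array([f.straightness for f in network.fibers])
        vals["n_fibers"] = float(network.n_fibers)
        vals["length_mean"] = float(lengths.mean())
        vals["length_var"] = float(lengths.var())
        vals["width_mean"] = float(widths.mean())
        vals["width_var"] = float(widths.var())
        vals["straightness_mean"] = float(straight.mean())
        vals["straightness_var"] = float(straight.var())
    n_cl = network.n_cross_links
    vals["crosslink_count"] = float(n_cl)
    collagen_area_mm2 = mask.sum() * (px_um**2) / 1e6
    if collagen_area_mm2 > 0:
        vals["crosslink_density"] = n_cl / collagen_area_mm2
    if n_cl >= 2:
        pts = np.array(network.cross_links)
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        vals["crosslink_spacing_mean"] = float(
            np.sqrt(d2.min(axis=1)).mean() * px_um
        )
    return pd.Series(vals, index=list(MORPHOLOGICAL_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

def histogram_features(
    image: SHGImage | np.ndarray, n_bins: int = 64
) -> pd.Series:
    """First-order statistics of the normalized intensity histogram.

    Mean/variance/skewness/excess-kurtosis use bin centers; energy is
    sum(p^2) and entropy is -sum(p log2 p) in bits.  A constant image has
    variance 0, energy 1, entropy 0 and (by convention) zero skewness and
    kurtosis.
    """
    vals = (
        image.intensities if isinstance(image, SHGImage) else
        np.asarray(image, dtype=float)
    ).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        p = np.zeros(n_bins)
        p[0] = 1.0
        centers = np.full(n_bins, lo)
    else:
        counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
        p = counts / counts.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
    mean = float(np.sum(p * centers))
    var = float(np.sum(p * (centers - mean) ** 2))
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.sum(p * ((centers - mean) / sd) ** 3))
        kurt = float(np.sum(p * ((centers - mean) / sd) ** 4) - 3.0)
    else:
        skew = kurt = 0.0
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return pd.Series(
        [mean, var, skew, kurt, energy, entropy],
        index=list(HISTOGRAM_NAMES),
        dtype=float,
    )


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization of an intensity grid to ``levels`` gray levels."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_matrix(
    image: SHGImage | np.ndarray,
    displacement: int,
    angle_deg: int,
    levels: int = 32,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix P_{delta,alpha}(i, j)."""
    arr = (
        image.intensities if isinstance(image, SHGImage) else
        np.asarray(image, dtype=float)
    )
    q = quantize(arr, levels)
    m = graycomatrix(
        q,
        distances=[displacement],
        angles=[np.deg2rad(angle_deg)],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    return m[:, :, 0, 0]


def glcm_stats(P: np.ndarray) -> dict[str, float]:
    """Contrast, correlation, energy and homogeneity of one GLCM."""
    levels = P.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float(np.sum(P * (i - j) ** 2))
    mu_i = float(np.sum(P * i))
    mu_j = float(np.sum(P * j))
    var_i = float(np.sum(P * (i - mu_i) ** 2))
    var_j = float(np.sum(P * (j - mu_j) ** 2))
    if var_i > 0 and var_j > 0:
        corr = float(
            np.sum(P * (i - mu_i) * (j - mu_j)) / np.sqrt(var_i * var_j)
        )
    else:
        corr = 0.0
    energy = float(np.sum(P**2))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    return {
        "contrast": contrast,
        "correlation": corr,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def glcm_features(
    image: SHGImage | np.ndarray, levels: int = 32
) -> pd.Series:
    """The 80 GLCM features: 4 statistics x 5 displacements x 4 directions,
    statistic-major order."""
    arr = (
        image.intensities if isinstance(image, SHGImage) else
        np.asarray(image, dtype=float)
    )
    q = quantize(arr, levels)
    m = graycomatrix(
        q,
        distances=list(GLCM_DISPLACEMENTS),
        angles=[np.deg2rad(a) for a in GLCM_ANGLES_DEG],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    stats_grid: dict[str, dict[tuple[int, int], float]] = {
        s: {} for s in GLCM_STATS
    }
    for di, d in enumerate(GLCM_DISPLACEMENTS):
        for ai, a in enumerate(GLCM_ANGLES_DEG):
            st = glcm_stats(m[:, :, di, ai])
            for s in GLCM_STATS:
                stats_grid[s][(d, a)] = st[s]
    values = [
        stats_grid[s][(d, a)]
        for s in GLCM_STATS
        for d in GLCM_DISPLACEMENTS
        for a in GLCM_ANGLES_DEG
    ]
    return pd.Series(values, index=list(GLCM_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Gabor features
# ---------------------------------------------------------------------------

def gabor_bank() -> dict[tuple[int, int], np.ndarray]:
    """The 4-scale x 6-orientation complex Gabor bank (1-octave bandwidth).

    Keys are (wavelength_px, orientation_deg); the orientation is the
    direction of the carrier wave vector, so a grating whose intensity
    varies along direction theta responds maximally to the theta filter.
    """
    bank = {}
    for w in GABOR_WAVELENGTHS_PX:
        for o in GABOR_ORIENTATIONS_DEG:
            bank[(w, o)] = gabor_kernel(
                frequency=1.0 / w, theta=np.deg2rad(o), bandwidth=1.0
            )
    return bank


def gabor_features(image: SHGImage | np.ndarray) -> pd.Series:
    """The 48 Gabor features: per filter, mean and variance of the complex
    response magnitude over the image; scale-major order."""
    arr = (
        image.intensities if isinstance(image, SHGImage) else
        np.asarray(image, dtype=float)
    )
    values = []
    for w in GABOR_WAVELENGTHS_PX:
        for o in GABOR_ORIENTATIONS_DEG:
            k = gabor_kernel(frequency=1.0 / w, theta=np.deg2rad(o),
                             bandwidth=1.0)
            resp = fftconvolve(arr, k, mode="same")
            mag = np.abs(resp)
            values.extend([float(mag.mean()), float(mag.var())])
    return pd.Series(values, index=list(GABOR_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Full vector and patient aggregation
# ---------------------------------------------------------------------------

def extract_all(
    image: SHGImage, config: FeatureConfig | None = None
) -> pd.Series:
    """The full ordered 146-feature vector of one SHG image.

    Morphological features always come from the GMM mask and traced
    network; histogram/GLCM/Gabor features are computed on the whole image
    by default, or on collagen pixels only (background zeroed, histogram on
    mask pixels) when ``config.masked_mode`` is set.
    """
    cfg = config or FeatureConfig()
    mask = segment_collagen(image, seed=cfg.seed)
    net = extract_fiber_network(mask, image, min_spur_px=cfg.min_spur_px)
    morph = morphological_features(net, mask, image)
    if cfg.masked_mode:
        tex_arr = image.intensities * mask
        hist_vals = image.intensities[mask > 0]
        hist = histogram_features(
            hist_vals if hist_vals.size else image.intensities,
            n_bins=cfg.n_hist_bins,
        )
    else:
        tex_arr = image.intensities
        hist = histogram_features(image, n_bins=cfg.n_hist_bins)
    glcm = glcm_features(tex_arr, levels=cfg.n_gray_levels)
    gabor = gabor_features(tex_arr)
    vec = pd.concat([morph, hist, glcm, gabor])
    vec.attrs["registry_version"] = REGISTRY_VERSION
    assert list(vec.index) == list(FEATURE_NAMES)
    return vec


def aggregate_patient(roi_vectors: list[pd.Series]) -> pd.Series:
    """Element-wise mean of per-ROI feature vectors for one patient."""
    if not roi_vectors:
        raise ValueError("need at least one ROI feature vector")
    for v in roi_vectors:
        if list(v.index) != list(FEATURE_NAMES):
            raise ValueError("ROI vector does not match the feature registry")
        ver = v.attrs.get("registry_version", REGISTRY_VERSION)
        if ver != REGISTRY_VERSION:
            raise ValueError(
                f"mixed registry versions: {ver} != {REGISTRY_VERSION}"
            )
    out = pd.concat(roi_vectors, axis=1).mean(axis=1)
    out.attrs["registry_version"] = REGISTRY_VERSION
    return out
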