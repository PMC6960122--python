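"""3D texture features from ROI-masked intensity volumes.

Implements the feature panel used for longitudinal (delta-radiomic) response
analysis: gray level co-occurrence matrix (GLCM) features, neighborhood gray
tone difference matrix (NGTDM) features, gray level run length matrix (GLRLM)
gray-level non-uniformity, first-order intensity statistics, and NESTD — the
voxel-wise normalized-entropy-minus-normalized-SD feature.

Conventions (all configurable via :class:`FeatureConfig`):

* fixed-bin-count quantization (default 32 levels) over the in-mask
  intensity range, which makes all quantized-matrix features invariant to
  affine intensity rescaling;
* GLCM/GLRLM accumulated over the 13 unique 3D directions at voxel distance 1
  and direction-averaged into a single matrix;
* NGTDM over the 26-neighborhood, neighborhood means restricted to in-mask
  voxels;
* kurtosis is the Pearson (non-excess) form: a normal sample gives ~3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeROI",
    "QuantizedROI",
    "FeatureConfig",
    "FEATURE_NAMES",
    "DIRECTIONS_3D",
    "quantize",
    "glcm_build",
    "glcm_features",
    "ngtdm_build",
    "ngtdm_features",
    "glrlm_build",
    "glrlm_gln",
    "first_order",
    "nestd",
    "extract_features",
    "extract_feature_table",
]

#: the 13 unique 3D offsets (one representative per +/- pair of the
#: 26-neighborhood); first nonzero component is positive.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

FEATURE_NAMES = (
    "complexity", "cluster_tendency", "coarseness", "information_measure",
    "contrast", "entropy", "inverse_variance", "gray_level_nonuniformity",
    "mean", "idn", "kurtosis", "skewness", "nestd",
)

_NGTDM_EPS = 1e-6


class InputError(ValueError):
    """Raised for malformed volumes, masks or degenerate ROIs."""


@dataclass
class VolumeROI:
    """One fraction's 3D intensity array with its ROI mask and voxel spacing."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise InputError("intensities must be a 3D array")
        if self.intensities.shape != self.mask.shape:
            raise InputError(
                f"mask shape {self.mask.shape} != image shape {self.intensities.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise InputError("voxel spacing must be positive")
        if not self.mask.any():
            raise InputError("ROI mask is empty")
        if not np.isfinite(self.intensities[self.mask]).all():
            raise InputError("non-finite intensities inside the ROI")

    @property
    def roi_values(self) -> np.ndarray:
        return self.intensities[self.mask]


@dataclass
class QuantizedROI:
    """ROI intensities discretized to integer levels 1..L (0 outside mask)."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray


@dataclass
class FeatureConfig:
    """Extraction parameters; defaults are the package-wide conventions."""

    n_levels: int = 32
    glcm_distance: int = 1
    nestd_radius: int = 1
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D

    def as_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "glcm_distance": self.glcm_distance,
            "nestd_radius": self.nestd_radius,
            "directions": [list(d) for d in self.directions],
            "kurtosis": "pearson",
            "information_measure": "IMC1",
            "idn_normalization": "abs(i-j)/L",
        }


def quantize(vol: VolumeROI, n_levels: int = 32) -> QuantizedROI:
    """Fixed-bin-count quantization of in-mask intensities to levels 1..L.

    Equal-width bins over the in-mask [min, max]; the maximum maps to level L.
    A constant ROI maps entirely to level 1.
    """
    if n_levels < 2:
        raise InputError("need at least 2 gray levels")
    vals = vol.roi_values
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(vol.mask.shape, dtype=np.int64)
    if hi == lo:
        levels[vol.mask] = 1
        edges = np.linspace(lo, lo + 1.0, n_levels + 1)
        return QuantizedROI(levels, vol.mask, n_levels, edges)
    width = (hi - lo) / n_levels
    lv = np.floor((vals - lo) / width).astype(np.int64) + 1
    np.clip(lv, 1, n_levels, out=lv)
    levels[vol.mask] = lv
    edges = np.linspace(lo, hi, n_levels + 1)
    return QuantizedROI(levels, vol.mask, n_levels, edges)


# ---------------------------------------------------------------------------
# GLCM

def _shift_pairs(arr: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """Index slices selecting voxel v and v+off with both inside the array."""
    src = []
    dst = []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    src, dst = tuple(src), tuple(dst)
    valid = mask[src] & mask[dst]
    return arr[src][valid], arr[dst][valid]


def glcm_build(
    qroi: QuantizedROI,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Direction-averaged, symmetric GLCM as an LxL probability matrix.

    For each direction, pairs (v, v + distance*offset) with both voxels in the
    mask are counted in both orders (symmetric accumulation); the
    direction-specific matrices are summed and the total normalized to 1.
    """
    if distance < 1:
        raise InputError("GLCM distance must be >= 1")
    L = qroi.n_levels
    counts = np.zeros((L, L), dtype=float)
    for d in directions:
        off = tuple(distance * o for o in d)
        a, b = _shift_pairs(qroi.levels, qroi.mask, off)
        if a.size == 0:
            continue
        np.add.at(counts, (a - 1, b - 1), 1.0)
        np.add.at(counts, (b - 1, a - 1), 1.0)
    total = counts.sum()
    if total == 0:
        raise InputError("no valid voxel pairs for GLCM")
    return counts / total


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """GLCM-derived features: entropy, cluster tendency, contrast, inverse
    variance, information measure of correlation 1, and IDN.

    Entropy uses log base 2 with the 0*log(0) = 0 convention. For a
    single-level (degenerate) matrix, contrast, inverse variance and IMC1
    are 0 by convention.
    """
    p = np.asarray(p, dtype=float)
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())

    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    cluster_tendency = float((((ii + jj - mu_i - mu_j) ** 2) * p).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    offdiag = ii != jj
    inverse_variance = float(
        (p[offdiag] / ((ii[offdiag] - jj[offdiag]) ** 2)).sum()
    )
    idn = float((p / (1.0 + np.abs(ii - jj) / L)).sum())

    # IMC1 = (HXY - HXY1) / max(HX, HY)
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxy = np.outer(px, py)
    m = nz & (pxy > 0)
    hxy1 = float(-(p[m] * np.log2(pxy[m])).sum())
    denom = max(hx, hy)
    information_measure = (entropy - hxy1) / denom if denom > 0 else 0.0

    return {
        "entropy": entropy,
        "cluster_tendency": cluster_tendency,
        "contrast": contrast,
        "inverse_variance": inverse_variance,
        "information_measure": information_measure,
        "idn": idn,
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_build(qroi: QuantizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """NGTDM components: per-level deviation sums s_i, counts n_i, N_valid.

    For every in-mask voxel with at least one in-mask 26-neighbor, the
    absolute difference between its level and the mean level of its in-mask
    neighbors is accumulated into s at its own level.
    """
    mask = qroi.mask
    lv = qroi.levels.astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_count = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    nb_sum = ndimage.convolve(np.where(mask, lv, 0.0), kernel, mode="constant")
    valid = mask & (nb_count > 0)
    if not valid.any():
        raise InputError("mask too small for any 26-neighborhood")
    dev = np.abs(lv[valid] - nb_sum[valid] / nb_count[valid])
    levels = qroi.levels[valid]
    L = qroi.n_levels
    s = np.zeros(L)
    n = np.zeros(L)
    np.add.at(s, levels - 1, dev)
    np.add.at(n, levels - 1, 1.0)
    return s, n, int(valid.sum())


def ngtdm_features(qroi: QuantizedROI) -> dict[str, float]:
    """Coarseness and complexity from the NGTDM.

    coarseness = 1 / (eps + sum_i p_i s_i), capped at 1/eps for a constant
    ROI; complexity = sum over occupied level pairs of
    |i-j| (p_i s_i + p_j s_j) / (N_valid (p_i + p_j)).
    """
    s, n, n_valid = ngtdm_build(qroi)
    p = n / n_valid
    coarseness = 1.0 / (_NGTDM_EPS + float((p * s).sum()))

    occ = np.nonzero(n)[0]
    lev = occ + 1.0
    pi = p[occ]
    si = s[occ]
    num = np.abs(lev[:, None] - lev[None, :]) * (
        (pi * si)[:, None] + (pi * si)[None, :]
    )
    den = n_valid * (pi[:, None] + pi[None, :])
    complexity = float((num / den).sum())
    return {"coarseness": coarseness, "complexity": complexity}


# ---------------------------------------------------------------------------
# GLRLM

def _runs_one_direction(
    qroi: QuantizedROI, d: tuple[int, int, int]
) -> np.ndarray:
    """Run counts r[level-1, length-1] for one direction.

    Every in-mask voxel belongs to exactly one maximal run (possibly of
    length 1) along the direction. Computed by dynamic programming over the
    leading axis of the direction.
    """
    lv = qroi.levels
    mask = qroi.mask
    shape = lv.shape
    # forward run length from each voxel
    fwd = np.where(mask, 1, 0).astype(np.int64)
    # cont[v]: v and v+d both in mask with the same level
    src = []
    dst = []
    for o, nn in zip(d, shape):
        if o >= 0:
            src.append(slice(0, nn - o))
            dst.append(slice(o, nn))
        else:
            src.append(slice(-o, nn))
            dst.append(slice(0, nn + o))
    src, dst = tuple(src), tuple(dst)
    cont = np.zeros(shape, dtype=bool)
    cont[src] = mask[src] & mask[dst] & (lv[src] == lv[dst])
    # iterate: fwd[v] = 1 + fwd[v+d] where cont; converges in <= max-run steps
    maxlen = int(max(shape))
    for _ in range(maxlen):
        nxt = np.zeros(shape, dtype=np.int64)
        nxt[src] = fwd[dst]
        new = np.where(cont, 1 + nxt, np.where(mask, 1, 0))
        if np.array_equal(new, fwd):
            break
        fwd = new
    # run starts: in-mask voxels whose predecessor along d is not same-run
    prev_cont = np.zeros(shape, dtype=bool)
    prev_cont[dst] = cont[src]
    starts = mask & ~prev_cont
    lengths = fwd[starts]
    levels = lv[starts]
    R = int(lengths.max()) if lengths.size else 1
    r = np.zeros((qroi.n_levels, R), dtype=float)
    np.add.at(r, (levels - 1, lengths - 1), 1.0)
    return r


def glrlm_build(
    qroi: QuantizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Direction-averaged run-length matrix (levels x max run length)."""
    mats = [_runs_one_direction(qroi, d) for d in directions]
    R = max(m.shape[1] for m in mats)
    out = np.zeros((qroi.n_levels, R), dtype=float)
    for m in mats:
        out[:, : m.shape[1]] += m
    return out / len(mats)


def glrlm_gln(
    qroi: QuantizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> float:
    """Gray level non-uniformity from the direction-averaged GLRLM:
    GLN = sum_i (sum_l r(i,l))^2 / sum_{i,l} r(i,l)."""
    r = glrlm_build(qroi, directions)
    total = r.sum()
    if total == 0:
        raise InputError("empty run-length matrix")
    return float((r.sum(axis=1) ** 2).sum() / total)


# ---------------------------------------------------------------------------
# first order

def first_order(vol: VolumeROI) -> dict[str, float]:
    """Mean, skewness and (Pearson) kurtosis of the raw in-mask intensities.

    Skewness/kurtosis are the biased moment estimators g1 and g2 + 3; for a
    zero-variance ROI they are undefined and returned as NaN.
    """
    x = vol.roi_values
    mu = float(x.mean())
    m2 = float(((x - mu) ** 2).mean())
    if m2 == 0 or x.size < 3:
        return {"mean": mu, "skewness": math.nan, "kurtosis": math.nan}
    m3 = float(((x - mu) ** 3).mean())
    m4 = float(((x - mu) ** 4).mean())
    return {
        "mean": mu,
        "skewness": m3 / m2 ** 1.5,
        "kurtosis": m4 / m2 ** 2,
    }


# ---------------------------------------------------------------------------
# NESTD

def nestd(
    vol: VolumeROI,
    n_levels: int = 32,
    radius: int = 1,
    return_map: bool = False,
):
    """NESTD: mean over the ROI of E_norm(v) - S_norm(v).

    For each in-mask voxel v, the (2r+1)^3 box neighborhood is intersected
    with the mask; E_norm is the Shannon entropy (base 2) of the quantized
    levels in the neighborhood divided by log2(L); S_norm is the population
    SD of the raw intensities in the neighborhood divided by the full ROI
    intensity range. A zero-range ROI gives NESTD = 0 everywhere.

    Returns the scalar feature, or ``(feature, map)`` with NaN outside the
    mask when ``return_map`` is set.
    """
    mask = vol.mask
    rng = float(vol.roi_values.max() - vol.roi_values.min())
    shape = mask.shape

    if rng == 0:
        nmap = np.where(mask, 0.0, np.nan)
        return (0.0, nmap) if return_map else 0.0

    qroi = quantize(vol, n_levels)

    offsets = [
        (dx, dy, dz)
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
        for dz in range(-radius, radius + 1)
    ]

    def slices(off):
        src, dst = [], []
        for o, nn in zip(off, shape):
            if o >= 0:
                src.append(slice(0, nn - o))
                dst.append(slice(o, nn))
            else:
                src.append(slice(-o, nn))
                dst.append(slice(0, nn + o))
        return tuple(src), tuple(dst)

    # exact per-voxel level histograms and intensity sums over the in-mask
    # box neighborhood (offset accumulation keeps counts integer-exact)
    counts = np.zeros(shape + (n_levels,), dtype=np.int32)
    n_nb = np.zeros(shape, dtype=np.int64)
    s_sum = np.zeros(shape)
    img = np.where(mask, vol.intensities, 0.0)
    for off in offsets:
        src, dst = slices(off)
        m = mask[src]
        n_nb[dst] += m
        s_sum[dst] += np.where(m, img[src], 0.0)
        lv = qroi.levels[src]
        for lev in range(1, n_levels + 1):
            counts[dst + (lev - 1,)] += m & (lv == lev)

    n_safe = np.maximum(n_nb, 1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / n_safe[..., None]
    ent = np.where(f > 0, -f * np.log2(np.where(f > 0, f, 1.0)), 0.0).sum(axis=-1)
    e_norm = ent / math.log2(n_levels)

    # two-pass population SD of the raw neighborhood intensities
    nb_mean = s_sum / n_safe
    ss = np.zeros(shape)
    for off in offsets:
        src, dst = slices(off)
        m = mask[src]
        ss[dst] += np.where(m, (img[src] - nb_mean[dst]) ** 2, 0.0)
    sd = np.sqrt(ss / n_safe)
    s_norm = sd / rng

    nmap = np.where(mask, e_norm - s_norm, np.nan)
    value = float(np.nanmean(nmap[mask]))
    return (value, nmap) if return_map else value


# ---------------------------------------------------------------------------
# panel extraction

def extract_features(
    vol: VolumeROI, config: FeatureConfig | None = None
) -> dict[str, float]:
    """The 13-feature response panel for one ROI-masked volume."""
    cfg = config or FeatureConfig()
    qroi = quantize(vol, cfg.n_levels)
    out: dict[str, float] = {}
    p = glcm_build(qroi, cfg.glcm_distance, cfg.directions)
    out.update(glcm_features(p))
    out.update(ngtdm_features(qroi))
    out["gray_level_nonuniformity"] = glrlm_gln(qroi, cfg.directions)
    out.update(first_order(vol))
    out["nestd"] = nestd(vol, cfg.n_levels, cfg.nestd_radius)
    return {k: out[k] for k in FEATURE_NAMES}


def extract_feature_table(
    volumes: dict[str, dict[int, VolumeROI]],
    config: FeatureConfig | None = None,
):
    """Long-format feature table from ``{patient_id: {fraction: VolumeROI}}``.

    Every patient must have a fraction-1 volume (the delta-transform
    baseline). Missing fractions stay missing; nothing is imputed.
    """
    import pandas as pd

    rows = []
    for pid, fracs in volumes.items():
        if 1 not in fracs:
            raise InputError(f"patient {pid!r} has no fraction-1 volume")
        for frac in sorted(fracs):
            feats = extract_features(fracs[frac], config)
            for name, val in feats.items():
                rows.append((pid, int(frac), name, val))
    return pd.DataFrame(rows, columns=["patient_id", "fraction", "feature", "value"])
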