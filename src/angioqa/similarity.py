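"""Cross-modality structural similarity on complex wavelet sub-bands.

The index compares two angiograms (e.g. an MRA maximum-intensity projection
against a catheter-angiography frame) by decomposing both with a complex,
oriented, multi-scale wavelet transform and scoring, per sub-band,

    CW-SSI(c_x, c_y) = (2 |sum_i c_x,i conj(c_y,i)| + K)
                       / (sum_i |c_x,i|^2 + sum_i |c_y,i|^2 + K),

where c_x,i and c_y,i are coefficients of the same sub-band at the same
location, N is the number of coefficients in the band, and K > 0 stabilizes
the ratio at low signal energy. The index is insensitive to small relative
translations and rotations: a small shift turns into a near-constant phase
shift of the coefficients, which the modulus of the cross-sum absorbs. The
equivalent factored form (a magnitude term times a phase-consistency term)
is implemented independently as a cross-check.

The transform here is a complex steerable pyramid built in the frequency
domain: raised-cosine radial octave windows and cos^(Q-1) angular windows
covering a single half-plane per orientation, forming an exactly invertible
tight frame (analysis masks are also the synthesis masks, and the squared
masks partition unity). It is the canonical near-shift-invariant choice of
complex oriented transform; oriented sub-bands shrink dyadically with scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from .volume import Image2D

__all__ = [
    "SimilarityConfig",
    "SubbandSet",
    "SimilarityResult",
    "otsu_threshold",
    "cwt_forward",
    "cwt_inverse",
    "cwssi_band",
    "cwssi_band_factored",
    "cwssi",
    "compare_modality",
]


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(image: Image2D | np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing the between-class variance.

    The intensity range is split into ``n_bins`` equal bins; every split
    point is scanned and the split maximizing w0*w1*(mu0-mu1)^2 is returned
    (ties broken toward the lower threshold). The returned value is the bin
    edge; binarize as ``data > threshold``.
    """
    data = np.asarray(image.data if isinstance(image, Image2D) else image, dtype=float).ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("Otsu threshold is undefined for a constant image")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    # exact integer arithmetic on bin indices (affine to intensity, so the
    # argmax is unchanged): ties across empty-valley plateaus then resolve
    # deterministically to the lowest threshold instead of by float noise
    c = [int(v) for v in counts]
    total, total_s = sum(c), sum(i * v for i, v in enumerate(c))
    w0 = s0 = 0
    best_t, best_num, best_den = 0, -1, 1
    for t in range(n_bins - 1):
        w0 += c[t]
        s0 += t * c[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (total_s - s0) * w0) ** 2  # w0*w1*(mu0-mu1)^2 = num/den
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: first maximizer wins
            best_t, best_num, best_den = t, num, den
    return float(edges[best_t + 1])


# ---------------------------------------------------------------------------
# complex steerable pyramid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityConfig:
    """Transform and index configuration.

    ``K="auto"`` sets the stabilizer to ``k_fraction`` (default 1%) of the
    mean sub-band energy, so K matters only where signal energy vanishes; an
    explicit float is used as given. Default aggregation is the windowed
    mean (7x7 sliding windows, each window's score weighted by its local
    signal energy): within a small window a rigid shift produces a
    near-constant coefficient phase ramp that the windowed cross-term
    modulus absorbs, and energy weighting keeps empty background windows —
    whose score is set entirely by K — from diluting or inflating the index.
    The unweighted global per-band variant remains available.

    ``min_scale`` (default 2) drops the finest octave from the aggregate:
    the index's translation insensitivity holds only for shifts small
    relative to the wavelet filter size, which a multi-pixel shift is not
    for the ~2-px wavelets of scale 1. Set ``min_scale=1`` to score every
    scale.
    """

    K: float | str = "auto"
    n_levels: int = 4
    n_orientations: int = 6
    aggregation: str = "windowed_mean"  # or "global_per_band_mean"
    window_px: int = 7
    binarize: str = "otsu_masks"  # or "grayscale"
    k_fraction: float = 0.01  # auto-K as a fraction of mean band energy
    min_scale: int = 2  # finest scale entering the aggregate (see docstring)

    def __post_init__(self) -> None:
        if isinstance(self.K, (int, float)) and self.K <= 0:
            raise ValueError("K must be > 0")
        if self.k_fraction <= 0:
            raise ValueError("k_fraction must be > 0")
        if self.n_levels < 1 or self.n_orientations < 1:
            raise ValueError("n_levels and n_orientations must be >= 1")
        if not 1 <= self.min_scale <= self.n_levels:
            raise ValueError("min_scale must be in 1..n_levels")
        if self.aggregation not in ("global_per_band_mean", "windowed_mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.binarize not in ("otsu_masks", "grayscale"):
            raise ValueError(f"unknown binarize mode {self.binarize!r}")


@dataclass
class SubbandSet:
    """Complex oriented sub-bands by (scale, orientation), plus the real
    highpass and lowpass residuals needed for exact reconstruction."""

    bands: dict  # (scale, orientation) -> complex array, scale 1 = finest
    highpass: np.ndarray
    lowpass: np.ndarray
    source_shape: tuple[int, int]
    padded_shape: tuple[int, int]
    transform_config: tuple[int, int, str]  # (n_levels, n_orientations, family)


def _hermitian_partner(arr: np.ndarray) -> np.ndarray:
    """Value at the Hermitian-conjugate frequency bin of every bin."""
    return np.roll(np.flip(arr), shift=(1, 1), axis=(0, 1))


@lru_cache(maxsize=8)
def _pyramid_masks(shape: tuple[int, int], n_levels: int, n_orients: int):
    """FFT-shifted analysis/synthesis masks whose squares partition unity.

    Returns (highpass, [[band masks per scale]], lowpass, [decimation per scale]).
    """
    P, Q = shape
    fy = (np.arange(P) - P // 2) * (2 * np.pi / P)
    fx = (np.arange(Q) - Q // 2) * (2 * np.pi / Q)
    wy, wx = np.meshgrid(fy, fx, indexing="ij")
    r = np.hypot(wx, wy)
    theta = np.arctan2(wy, wx)

    def rise(radius_hi: float) -> np.ndarray:
        """0 below radius_hi/2, raised-cosine ramp, 1 at and above radius_hi."""
        out = np.ones_like(r)
        with np.errstate(divide="ignore"):
            ramp = np.cos(0.5 * np.pi * np.log2(np.maximum(r, 1e-300) / radius_hi))
        band = (r > radius_hi / 2) & (r < radius_hi)
        out[band] = ramp[band]
        out[r <= radius_hi / 2] = 0.0
        return out

    # single-lobe angular powers, normalized so that for every frequency bin
    # sum_k [A_k^2(bin) + A_k^2(partner bin)] = 1 exactly (partner computed on
    # the discrete grid, which keeps reconstruction exact on Nyquist lines)
    lobes = []
    for k in range(n_orients):
        th = np.mod(theta - np.pi * k / n_orients + np.pi, 2 * np.pi) - np.pi
        a = np.where(np.abs(th) < np.pi / 2, np.cos(th) ** (n_orients - 1), 0.0)
        lobes.append(a)
    s = np.zeros_like(r)
    for a in lobes:
        s += a**2 + _hermitian_partner(a**2)
    # the only zero-coverage bins are self-conjugate Nyquist bins (r >= pi),
    # where every oriented radial window is zero and the highpass residual
    # carries the content alone; guard the division there
    s[s == 0.0] = 1.0
    lobes = [a / np.sqrt(s) for a in lobes]

    U = [rise(np.pi / 2**k) for k in range(n_levels + 1)]
    L = [np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0)) for u in U]
    highpass = U[0]
    bands = []
    lprod = L[0]
    for sidx in range(1, n_levels + 1):
        radial = lprod * U[sidx]
        bands.append([np.sqrt(2.0) * a * radial for a in lobes])
        lprod = lprod * L[sidx]
    lowpass = lprod
    decim = [2 ** (sidx - 1) for sidx in range(1, n_levels + 1)]
    return highpass, bands, lowpass, decim


def _crop(spec: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return spec
    P, Q = spec.shape
    return spec[P // 2 - P // (2 * f) : P // 2 + P // (2 * f), Q // 2 - Q // (2 * f) : Q // 2 + Q // (2 * f)]


def _uncrop(spec: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    P, Q = shape
    p, q = spec.shape
    out = np.zeros(shape, dtype=complex)
    out[P // 2 - p // 2 : P // 2 + p // 2, Q // 2 - q // 2 : Q // 2 + q // 2] = spec
    return out


def cwt_forward(image: Image2D | np.ndarray, config: SimilarityConfig = SimilarityConfig()) -> SubbandSet:
    """Decompose an image into complex oriented sub-bands.

    The image is zero-padded to a multiple of 2^n_levels; sub-band grids at
    scale s are decimated by 2^(s-1) (alias-free: each band's frequency
    support fits its decimated Nyquist box). A 1-px input translation
    changes coefficient magnitudes only mildly at scales >= 2 — the
    near-shift-invariance the similarity index relies on.
    """
    data = np.asarray(image.data if isinstance(image, Image2D) else image, dtype=float)
    n, q = config.n_levels, config.n_orientations
    if min(data.shape) < 2**n:
        raise ValueError(f"image of shape {data.shape} is too small for {n} pyramid levels")
    block = 2**n
    pad = [(0, (-s) % block) for s in data.shape]
    padded = np.pad(data, pad) if any(p for _, p in pad) else data
    highpass_m, band_m, lowpass_m, decim = _pyramid_masks(padded.shape, n, q)
    X = fftshift(fft2(padded))
    bands = {}
    for sidx in range(1, n + 1):
        f = decim[sidx - 1]
        for k in range(q):
            sub = _crop(X * band_m[sidx - 1][k], f) / f
            bands[(sidx, k)] = ifft2(ifftshift(sub))
    f_low = decim[-1]
    low = ifft2(ifftshift(_crop(X * lowpass_m, f_low) / f_low)).real
    high = ifft2(ifftshift(X * highpass_m)).real
    return SubbandSet(
        bands=bands,
        highpass=high,
        lowpass=low,
        source_shape=data.shape,
        padded_shape=padded.shape,
        transform_config=(n, q, "complex_steerable_pyramid"),
    )


def cwt_inverse(subbands: SubbandSet) -> np.ndarray:
    """Exact synthesis: apply the same masks and sum; crop away the padding."""
    n, q, _ = subbands.transform_config
    highpass_m, band_m, lowpass_m, decim = _pyramid_masks(subbands.padded_shape, n, q)
    Xhat = fftshift(fft2(subbands.highpass)) * highpass_m
    for sidx in range(1, n + 1):
        f = decim[sidx - 1]
        for k in range(q):
            sub = fftshift(fft2(subbands.bands[(sidx, k)])) * f
            Xhat = Xhat + _uncrop(sub, subbands.padded_shape) * band_m[sidx - 1][k]
    f_low = decim[-1]
    Xhat = Xhat + _uncrop(fftshift(fft2(subbands.lowpass)) * f_low, subbands.padded_shape) * lowpass_m
    recon = ifft2(ifftshift(Xhat)).real
    sx, sy = subbands.source_shape
    return recon[:sx, :sy]


# ---------------------------------------------------------------------------
# the similarity index
# ---------------------------------------------------------------------------

@dataclass
class SimilarityResult:
    cwssi: float
    per_band: dict  # (scale, orientation) -> float
    config: SimilarityConfig
    preprocessing_log: str = ""


def _resolve_k(config: SimilarityConfig, cx: np.ndarray, cy: np.ndarray) -> float:
    if config.K == "auto":
        mean_energy = 0.5 * float(np.sum(cx * np.conj(cx)).real + np.sum(cy * np.conj(cy)).real)
        return max(config.k_fraction * mean_energy, 1e-12)
    return float(config.K)


def cwssi_band(cx: np.ndarray, cy: np.ndarray, K: float) -> float:
    """One sub-band's similarity, direct form:
    (2 |sum c_x c_y*| + K) / (sum |c_x|^2 + sum |c_y|^2 + K).

    Energies are accumulated as ``c * conj(c)`` so that ``cy = cx`` yields
    exactly 1.0 in floating point, not merely approximately.
    """
    if cx.shape != cy.shape:
        raise ValueError(f"sub-band shapes differ: {cx.shape} vs {cy.shape}")
    if K <= 0:
        raise ValueError("K must be > 0")
    # all three sums go through the same complex product-and-sum path, so
    # cy = cx gives numerator == denominator bitwise and the score is 1.0 exact
    cross = complex(np.sum(cx * np.conj(cy)))
    ex = complex(np.sum(cx * np.conj(cx))).real
    ey = complex(np.sum(cy * np.conj(cy))).real
    return float((2.0 * abs(cross) + K) / (ex + ey + K))


def cwssi_band_factored(cx: np.ndarray, cy: np.ndarray, K: float) -> float:
    """The factored form: a coefficient-magnitude term times a
    phase-consistency term. Algebraically identical to :func:`cwssi_band`
    (sum |c_x c_y*| = sum |c_x| |c_y|); computed independently so the two
    routes cross-validate each other."""
    if cx.shape != cy.shape:
        raise ValueError(f"sub-band shapes differ: {cx.shape} vs {cy.shape}")
    if K <= 0:
        raise ValueError("K must be > 0")
    mags = float(np.sum(np.abs(cx) * np.abs(cy)))
    energy = float(np.sum(np.abs(cx) ** 2) + np.sum(np.abs(cy) ** 2))
    cross_abs = abs(complex(np.sum(cx * np.conj(cy))))
    magnitude_term = (2.0 * mags + K) / (energy + K)
    phase_term = (2.0 * cross_abs + K) / (2.0 * float(np.sum(np.abs(cx * np.conj(cy)))) + K)
    return float(magnitude_term * phase_term)


def _windowed_band(cx: np.ndarray, cy: np.ndarray, K: float, window: int) -> float:
    """Energy-weighted mean of sliding-window scores over one sub-band."""
    from scipy.ndimage import uniform_filter

    def uf(a: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(a):
            return uniform_filter(a.real, window) + 1j * uniform_filter(a.imag, window)
        return uniform_filter(a, window)

    n = window * window
    k_local = K * n / cx.size  # rescale the stabilizer to the window size
    cross = uf(cx * np.conj(cy)) * n
    # same product path as the cross-term so identical inputs score exactly 1
    energy = (uf((cx * np.conj(cx)).real) + uf((cy * np.conj(cy)).real)) * n
    scores = (2.0 * np.abs(cross) + k_local) / (energy + k_local)
    h = window // 2
    sl = (slice(h, scores.shape[0] - h or None), slice(h, scores.shape[1] - h or None))
    sc, w = scores[sl], energy[sl]
    if sc.size == 0:
        sc, w = scores, energy
    total_w = float(w.sum())
    return float((sc * w).sum() / total_w) if total_w > 0 else float(sc.mean())


def cwssi(
    image_x: Image2D | np.ndarray,
    image_y: Image2D | np.ndarray,
    config: SimilarityConfig = SimilarityConfig(),
) -> SimilarityResult:
    """Similarity of two images on a common grid.

    Each oriented sub-band is scored (default: mean over 7x7 sliding
    windows; globally per band if configured) and the result is the
    unweighted mean over all oriented sub-bands — the residual lowpass and
    highpass are excluded."""
    sx = cwt_forward(image_x, config)
    sy = cwt_forward(image_y, config)
    per_band = {}
    for key in sx.bands:
        if key[0] < config.min_scale:
            continue
        cx, cy = sx.bands[key], sy.bands[key]
        K = _resolve_k(config, cx, cy)
        if config.aggregation == "windowed_mean":
            per_band[key] = _windowed_band(cx, cy, K, config.window_px)
        else:
            per_band[key] = cwssi_band(cx, cy, K)
    value = float(np.mean(list(per_band.values())))
    return SimilarityResult(cwssi=value, per_band=per_band, config=config)


def _normalize_percentile(data: np.ndarray, name: str, log: list) -> np.ndarray:
    lo, hi = np.percentile(data, [1.0, 99.0])
    if hi <= lo:
        lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError(f"{name} image is constant; cannot normalize or threshold it")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    log.append(f"{name}: clipped to 1st-99th percentile [{lo:.6g}, {hi:.6g}], rescaled to [0, 1]")
    return out


def compare_modality(
    mra_mip: Image2D,
    dsa_image: Image2D,
    config: SimilarityConfig = SimilarityConfig(),
) -> SimilarityResult:
    """Full cross-modality pipeline: percentile intensity normalization,
    common-grid resampling (bilinear, larger image onto the smaller grid),
    Otsu binarization of both images (default), then the wavelet similarity
    index. Every preprocessing step is recorded in the result log.
    """
    from skimage.transform import resize

    log: list[str] = []
    x = _normalize_percentile(np.asarray(mra_mip.data, dtype=float), "mra", log)
    y = _normalize_percentile(np.asarray(dsa_image.data, dtype=float), "dsa", log)
    if x.size != y.size or x.shape != y.shape:
        target = x.shape if x.size <= y.size else y.shape
        if x.shape != target:
            x = resize(x, target, order=1, anti_aliasing=False, preserve_range=True)
            log.append(f"mra: bilinear resample to {target}")
        if y.shape != target:
            y = resize(y, target, order=1, anti_aliasing=False, preserve_range=True)
            log.append(f"dsa: bilinear resample to {target}")
    if config.binarize == "otsu_masks":
        for name, arr in (("mra", x), ("dsa", y)):
            if float(arr.min()) == float(arr.max()):
                raise ValueError(f"{name} image is constant; Otsu segmentation is undefined")
        tx, ty = otsu_threshold(x), otsu_threshold(y)
        x = (x > tx).astype(float)
        y = (y > ty).astype(float)
        log.append(f"otsu binarization: thresholds mra={tx:.6g}, dsa={ty:.6g}")
    else:
        log.append("grayscale mode: no binarization")
    result = cwssi(x, y, config)
    result.preprocessing_log = "\n".join(log)
    return result
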