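"""SSIM-family similarity metrics for reconstructed optical-property images.

Four full-reference metrics over 8-bit grayscale pairs (reference X = the
homogeneous reconstruction, test Y = the reconstruction under assessment):

* ``mssim``      — mean SSIM: sliding 9×9 Gaussian window (σ = 1.5, unit
  sum), per-window product of luminance l, contrast c and structure s with
  unit exponents, averaged over all fully-interior windows.
* ``ms_ssim``    — multiscale SSIM: c and s pooled at K = 5 dyadic scales
  (2×2 mean filter + decimation between scales), luminance at the coarsest
  scale only, combined with the standard exponent weights
  β = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), βk = γk = αk.
* ``missim_s``   — mean improved SSIM with sharpness: the structure term is
  replaced by a split-standard-deviation comparison s̃ (separate σ over the
  below-mean and at-or-above-mean pixels of each window) and a sharpness
  comparison h built from the mean-removed window; per-window score
  l·c·s̃·h, averaged.
* ``ms_issim_s`` — multiscale ISSIM-S (the novel metric): the MS-SSIM
  pooled c/s/l terms multiplied by the across-scale *mean* of the pooled
  sharpness term h̄k.

All scores are 1 exactly for identical images and symmetric in (X, Y).

Two printed-form ambiguities are resolved by bounded, identity-normalized
readings (see docs/methods.md); the literal variants remain available via
``SSIMConfig.sharpness_literal`` and ``SSIMConfig.ms_prefactor = "sum"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SSIMConfig",
    "WindowStats",
    "SimilarityMap",
    "gaussian_window",
    "window_stats",
    "ssim_components",
    "issim_components",
    "mssim",
    "downsample2",
    "ms_ssim",
    "missim_s",
    "ms_issim_s",
    "compute_metric",
    "METRIC_NAMES",
    "similarity_grid_map",
    "render_similarity_map",
]

MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
METRIC_NAMES = ("mssim", "ms_ssim", "missim_s", "ms_issim_s")


@dataclass(frozen=True)
class SSIMConfig:
    """Constants and window settings shared by all four metrics."""

    k1: float = 0.01
    k2: float = 0.03
    L: int = 255
    window_size: int = 9
    window_sigma: float = 1.5
    scale_weights: tuple = MS_SSIM_WEIGHTS
    n_scales: int = 5
    sharpness_literal: bool = False
    ms_prefactor: str = "mean"          # "mean" (default) or "sum"

    def __post_init__(self):
        if not (0 < self.k1 < 1 and 0 < self.k2 < 1):
            raise ValueError("K1 and K2 must be small positive constants")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if len(self.scale_weights) < self.n_scales:
            raise ValueError("need one scale weight per scale")
        if self.ms_prefactor not in ("mean", "sum"):
            raise ValueError("ms_prefactor must be 'mean' or 'sum'")

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def gaussian_window(size: int = 9, sigma: float = 1.5) -> np.ndarray:
    """Isotropic Gaussian weights at pixel centres, normalized to unit sum."""
    if size < 3 or size % 2 == 0:
        raise ValueError("window size must be odd and >= 3")
    half = size // 2
    i = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(i, i)
    w = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


@dataclass
class WindowStats:
    """Weighted first/second moments of one window pair.

    The split standard deviations σ− / σ+ are taken over the pixels strictly
    below (resp. at or above) the window's weighted mean, with the Gaussian
    weights renormalized within each subset; deviations are measured about
    the full-window mean.  λ is the weighted RMS of the mean-removed window
    (the scalar magnitude of the normalized digital Laplacian x − μx).
    """

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    sigma_xy: float
    sigma_x_minus: float
    sigma_x_plus: float
    sigma_y_minus: float
    sigma_y_plus: float
    lambda_x: float
    lambda_y: float


def _split_sigma(window, mu, weights):
    dev2 = (window - mu) ** 2
    below = window < mu
    out = []
    for mask in (below, ~below):
        wm = weights * mask
        tot = wm.sum()
        out.append(np.sqrt((wm * dev2).sum() / tot) if tot > 0 else 0.0)
    return out


def window_stats(x_window: np.ndarray, y_window: np.ndarray,
                 weights: np.ndarray) -> WindowStats:
    """Weighted moments of a single window pair (reference implementation).

    The sliding-window metrics use an equivalent vectorized path; agreement
    between the two is asserted in the test suite.
    """
    x = np.asarray(x_window, dtype=float)
    y = np.asarray(y_window, dtype=float)
    if x.shape != y.shape or x.shape != weights.shape:
        raise ValueError("windows and weights must share one shape")
    mu_x = float((weights * x).sum())
    mu_y = float((weights * y).sum())
    dx = x - mu_x
    dy = y - mu_y
    var_x = float((weights * dx * dx).sum())
    var_y = float((weights * dy * dy).sum())
    cov = float((weights * dx * dy).sum())
    sxm, sxp = _split_sigma(x, mu_x, weights)
    sym, syp = _split_sigma(y, mu_y, weights)
    return WindowStats(
        mu_x=mu_x, mu_y=mu_y,
        sigma_x=float(np.sqrt(var_x)), sigma_y=float(np.sqrt(var_y)),
        sigma_xy=cov,
        sigma_x_minus=float(sxm), sigma_x_plus=float(sxp),
        sigma_y_minus=float(sym), sigma_y_plus=float(syp),
        lambda_x=float(np.sqrt(var_x)), lambda_y=float(np.sqrt(var_y)))


def ssim_components(stats: WindowStats, config: SSIMConfig
                    ) -> tuple[float, float, float]:
    """Luminance, contrast and structure comparison terms of one window."""
    c1, c2, c3 = config.c1, config.c2, config.c3
    l = (2 * stats.mu_x * stats.mu_y + c1) / (
        stats.mu_x ** 2 + stats.mu_y ** 2 + c1)
    c = (2 * stats.sigma_x * stats.sigma_y + c2) / (
        stats.sigma_x ** 2 + stats.sigma_y ** 2 + c2)
    s = (stats.sigma_xy + c3) / (stats.sigma_x * stats.sigma_y + c3)
    return l, c, s


def issim_components(stats: WindowStats, config: SSIMConfig
                     ) -> tuple[float, float]:
    """Split-σ structure s̃ and sharpness comparison h of one window."""
    c2 = config.c2
    s_tilde = ((2 * stats.sigma_x_minus * stats.sigma_y_minus + c2)
               * (2 * stats.sigma_x_plus * stats.sigma_y_plus + c2)) / (
        (stats.sigma_x_minus ** 2 + stats.sigma_y_minus ** 2 + c2)
        * (stats.sigma_x_plus ** 2 + stats.sigma_y_plus ** 2 + c2))
    lx, ly = stats.lambda_x, stats.lambda_y
    if config.sharpness_literal:
        h = (2 * lx * ly + c2) / (lx ** 2 * ly ** 2 + c2)
    else:
        h = (2 * lx * ly + c2) / (lx ** 2 + ly ** 2 + c2)
    return s_tilde, h


@dataclass
class SimilarityMap:
    """Per-window score map plus its arithmetic-mean scalar score."""

    map: np.ndarray

    @property
    def score(self) -> float:
        return float(self.map.mean())


# ---------------------------------------------------------------------------
# Vectorized sliding-window statistics

def _as_array(image) -> np.ndarray:
    pixels = getattr(image, "pixels", image)
    return np.asarray(pixels, dtype=float)


def _stats_maps(x: np.ndarray, y: np.ndarray, cfg: SSIMConfig,
                split: bool) -> dict:
    s = cfg.window_size
    if x.shape != y.shape:
        raise ValueError("images must have identical shapes")
    if min(x.shape) < s:
        raise ValueError(
            f"image side {min(x.shape)} smaller than the {s}×{s} window")
    w = gaussian_window(s, cfg.window_sigma)
    wx = sliding_window_view(x, (s, s))
    wy = sliding_window_view(y, (s, s))
    mu_x = np.einsum("ijkl,kl->ij", wx, w)
    mu_y = np.einsum("ijkl,kl->ij", wy, w)
    dx = wx - mu_x[..., None, None]
    dy = wy - mu_y[..., None, None]
    var_x = np.einsum("ijkl,ijkl,kl->ij", dx, dx, w)
    var_y = np.einsum("ijkl,ijkl,kl->ij", dy, dy, w)
    cov = np.einsum("ijkl,ijkl,kl->ij", dx, dy, w)
    out = {
        "mu_x": mu_x, "mu_y": mu_y,
        "sigma_x": np.sqrt(np.maximum(var_x, 0.0)),
        "sigma_y": np.sqrt(np.maximum(var_y, 0.0)),
        "sigma_xy": cov,
    }
    if split:
        for tag, win, dev in (("x", wx, dx), ("y", wy, dy)):
            below = dev < 0
            for sub, mask in (("minus", below), ("plus", ~below)):
                wm = w[None, None] * mask
                tot = wm.sum(axis=(-1, -2))
                num = np.einsum("ijkl,ijkl,ijkl->ij", wm, dev, dev)
                var = np.divide(num, tot, out=np.zeros_like(num),
                                where=tot > 0)
                out[f"sigma_{tag}_{sub}"] = np.sqrt(np.maximum(var, 0.0))
    return out


def _component_maps(x, y, cfg: SSIMConfig, split: bool) -> dict:
    st = _stats_maps(x, y, cfg, split)
    c1, c2, c3 = cfg.c1, cfg.c2, cfg.c3
    maps = {
        "l": (2 * st["mu_x"] * st["mu_y"] + c1)
             / (st["mu_x"] ** 2 + st["mu_y"] ** 2 + c1),
        "c": (2 * st["sigma_x"] * st["sigma_y"] + c2)
             / (st["sigma_x"] ** 2 + st["sigma_y"] ** 2 + c2),
        "s": (st["sigma_xy"] + c3)
             / (st["sigma_x"] * st["sigma_y"] + c3),
    }
    if split:
        maps["s_tilde"] = (
            (2 * st["sigma_x_minus"] * st["sigma_y_minus"] + c2)
            * (2 * st["sigma_x_plus"] * st["sigma_y_plus"] + c2)) / (
            (st["sigma_x_minus"] ** 2 + st["sigma_y_minus"] ** 2 + c2)
            * (st["sigma_x_plus"] ** 2 + st["sigma_y_plus"] ** 2 + c2))
        lx, ly = st["sigma_x"], st["sigma_y"]   # λ = weighted RMS = σ
        if cfg.sharpness_literal:
            maps["h"] = (2 * lx * ly + c2) / (lx ** 2 * ly ** 2 + c2)
        else:
            maps["h"] = (2 * lx * ly + c2) / (lx ** 2 + ly ** 2 + c2)
    return maps


# ---------------------------------------------------------------------------
# The four metrics

def mssim(x, y, config: SSIMConfig | None = None) -> SimilarityMap:
    """Mean SSIM over all fully-interior sliding windows (stride 1)."""
    cfg = config or SSIMConfig()
    m = _component_maps(_as_array(x), _as_array(y), cfg, split=False)
    return SimilarityMap(m["l"] * m["c"] * m["s"])


def missim_s(x, y, config: SSIMConfig | None = None) -> SimilarityMap:
    """Mean improved-SSIM-with-sharpness (per-window l·c·s̃·h)."""
    cfg = config or SSIMConfig()
    m = _component_maps(_as_array(x), _as_array(y), cfg, split=True)
    return SimilarityMap(m["l"] * m["c"] * m["s_tilde"] * m["h"])


def downsample2(image) -> np.ndarray:
    """2×2 mean low-pass filter followed by dyadic decimation."""
    a = _as_array(image)
    h, w = a.shape
    if h % 2 or w % 2:
        raise ValueError(f"image sides must be even to downsample, got {a.shape}")
    return a.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def _check_multiscale_size(side: int, cfg: SSIMConfig) -> None:
    needed = cfg.window_size * 2 ** (cfg.n_scales - 1)
    coarsest = side // 2 ** (cfg.n_scales - 1)
    if side % 2 ** (cfg.n_scales - 1) or coarsest < cfg.window_size:
        raise ValueError(
            f"image side {side} too small for {cfg.n_scales} scales with a "
            f"{cfg.window_size}px window; need a multiple of "
            f"{2 ** (cfg.n_scales - 1)} of at least {needed}")


def _multiscale_terms(x, y, cfg: SSIMConfig, split: bool):
    """Pooled per-scale terms: lists of c̄k, s̄k, (h̄k) and the coarsest l̄K."""
    x = _as_array(x)
    y = _as_array(y)
    _check_multiscale_size(min(x.shape), cfg)
    cbars, sbars, hbars = [], [], []
    lbar = None
    for k in range(cfg.n_scales):
        m = _component_maps(x, y, cfg, split=split)
        cbars.append(float(m["c"].mean()))
        sbars.append(float(m["s"].mean()))
        if split:
            hbars.append(float(m["h"].mean()))
        if k == cfg.n_scales - 1:
            lbar = float(m["l"].mean())
        else:
            x = downsample2(x)
            y = downsample2(y)
    return cbars, sbars, hbars, lbar


def ms_ssim(x, y, config: SSIMConfig | None = None) -> float:
    """Multiscale SSIM scalar score (K = 5 dyadic scales)."""
    cfg = config or SSIMConfig()
    cbars, sbars, _, lbar = _multiscale_terms(x, y, cfg, split=False)
    w = cfg.scale_weights
    score = lbar ** w[cfg.n_scales - 1]
    for k in range(cfg.n_scales):
        score *= cbars[k] ** w[k] * sbars[k] ** w[k]
    return float(score)


def ms_issim_s(x, y, config: SSIMConfig | None = None) -> float:
    """Multiscale improved SSIM with sharpness (the novel metric).

    The MS-SSIM pooled c/s/l combination is multiplied by the mean over
    scales of the pooled sharpness term h̄k.
    """
    cfg = config or SSIMConfig()
    cbars, sbars, hbars, lbar = _multiscale_terms(x, y, cfg, split=True)
    w = cfg.scale_weights
    score = lbar ** w[cfg.n_scales - 1]
    for k in range(cfg.n_scales):
        score *= cbars[k] ** w[k] * sbars[k] ** w[k]
    h_sum = float(np.sum(hbars))
    prefactor = h_sum / cfg.n_scales if cfg.ms_prefactor == "mean" else h_sum
    return float(prefactor * score)


def compute_metric(metric_id: str, x, y,
                   config: SSIMConfig | None = None) -> float:
    """Scalar score for any of the four metrics by name."""
    if metric_id == "mssim":
        return mssim(x, y, config).score
    if metric_id == "ms_ssim":
        return ms_ssim(x, y, config)
    if metric_id == "missim_s":
        return missim_s(x, y, config).score
    if metric_id == "ms_issim_s":
        return ms_issim_s(x, y, config)
    raise ValueError(f"unknown metric {metric_id!r}; expected one of "
                     f"{METRIC_NAMES}")


def similarity_grid_map(reference, batch, metric_id: str,
                        grid_shape: tuple[int, int] | None = None,
                        config: SSIMConfig | None = None) -> np.ndarray:
    """Scores of a batch against one reference, arranged as a grid.

    ``grid_shape`` (rows, cols) reshapes the flat batch, e.g. the study's
    (contrast levels × radii); defaults to one row.
    """
    scores = np.array([compute_metric(metric_id, reference, img, config)
                       for img in batch])
    if grid_shape is not None:
        scores = scores.reshape(grid_shape)
    else:
        scores = scores.reshape(1, -1)
    return scores


def render_similarity_map(score_grid: np.ndarray, path,
                          row_labels=None, col_labels=None,
                          title: str = "") -> None:
    """Render a score grid bright-high / dark-low and save to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(score_grid, cmap="gray", vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="similarity score")
    if col_labels is not None:
        ax.set_xticks(range(len(col_labels)), [str(c) for c in col_labels])
    if row_labels is not None:
        ax.set_yticks(range(len(row_labels)), [str(r) for r in row_labels])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
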