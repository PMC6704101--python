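"""Neck/skin segmentation with a weighted Gaussian mixture model.

Per-pixel chroma features of the temporal median frame are clustered with
an expectation-maximization fit in which every sample carries a
nonnegative weight; a centered spatial prior weights pixels near the frame
center more heavily, reflecting an acquisition protocol that frames the
neck centrally.  The skin component is the mixture component whose mean
chroma is nearest a configurable skin-tone reference; its posterior map is
thresholded and cleaned up morphologically into a single static mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal
from skimage import measure as _measure
from skimage import morphology as _morph
from skimage.color import rgb2yiq

from .video_io import FrameSequence

__all__ = [
    "GmmModel",
    "RoiMask",
    "SegmentationConfig",
    "SegmentationFailedError",
    "fit_weighted_gmm",
    "segment_neck",
    "postprocess_mask",
]

#: chroma (I, Q of YIQ) of a mid-tone skin color, the component selector default
DEFAULT_SKIN_CHROMA = (0.18, 0.05)


class SegmentationFailedError(RuntimeError):
    """Raised when no usable skin region can be found.

    Callers may fall back to a full-frame mask or supply a mask explicitly
    via ``SegmentationConfig.user_mask``.
    """


@dataclass
class GmmModel:
    """A fitted Gaussian mixture: weights, means, covariances."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    covariances: np.ndarray  # (K, D, D)
    log_likelihood: float
    ll_trace: list  # weighted log-likelihood per EM iteration
    n_iter: int
    feature_space: str = "chroma"

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        log_r = _log_component_densities(X, self.weights, self.means, self.covariances)
        log_norm = _logsumexp(log_r, axis=1, keepdims=True)
        return np.exp(log_r - log_norm)


@dataclass
class RoiMask:
    """Binary region-of-interest mask for one video."""

    mask: np.ndarray  # (H, W) bool

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class SegmentationConfig:
    n_components: int = 3  # skin / background / shadow
    p_min: float = 0.5  # posterior threshold for skin membership
    min_coverage: float = 0.01
    skin_reference_chroma: tuple[float, float] = DEFAULT_SKIN_CHROMA
    # components whose mean chroma lies within this distance of the
    # reference all count as skin (shadowed/vessel skin keeps its hue at
    # lower saturation, so it clusters separately but stays nearby)
    skin_chroma_max_distance: float = 0.12
    spatial_prior_sigma_frac: float = 0.35  # of min(H, W)
    closing_radius_at_1920: float = 5.0  # px, scaled with frame width
    seed: int = 0
    max_iter: int = 200
    tol: float = 1e-6
    user_mask: np.ndarray | None = None


def _logsumexp(a, axis=None, keepdims=False):
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True)) + amax
    return out if keepdims else np.squeeze(out, axis=axis)


def _log_component_densities(X, weights, means, covs):
    """log(pi_k) + log N(x | mu_k, Sigma_k), shape (N, K)."""
    n, _ = X.shape
    k = len(weights)
    out = np.empty((n, k))
    for j in range(k):
        out[:, j] = np.log(max(weights[j], 1e-300)) + multivariate_normal.logpdf(
            X, mean=means[j], cov=covs[j], allow_singular=False
        )
    return out


def _kmeans_like_init(X, w, k, rng, lloyd_iters: int = 10):
    """Weighted k-means++ seeding refined by a few Lloyd iterations."""
    n = len(X)
    probs = w / w.sum()
    idx = [rng.choice(n, p=probs)]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((X - X[i]) ** 2, axis=1) for i in idx], axis=0
        )
        p = d2 * w
        if p.sum() <= 0:
            p = np.ones(n)
        idx.append(rng.choice(n, p=p / p.sum()))
    means = X[np.array(idx)].copy()
    for _ in range(lloyd_iters):
        d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for j in range(k):
            sel = assign == j
            if w[sel].sum() > 0:
                means[j] = np.average(X[sel], axis=0, weights=w[sel])
    return means


def fit_weighted_gmm(
    features: np.ndarray,
    sample_weights: np.ndarray | None = None,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    cov_floor: float = 1e-6,
    means_init: np.ndarray | None = None,
    n_init: int = 3,
) -> GmmModel:
    """Fit a Gaussian mixture by weighted EM.

    In the E-step, responsibilities are the usual posteriors
    ``r_nk \\propto pi_k N(x_n | mu_k, Sigma_k)``; in the M-step each
    sample contributes ``w_n * r_nk`` instead of ``r_nk``, so uniform
    weights reduce exactly to standard EM.  Iterations stop when the
    weighted log-likelihood ``sum_n w_n log p(x_n)`` improves by less than
    ``tol`` (or at ``max_iter``).  Covariance eigenvalues are floored at
    ``cov_floor`` to guard against component collapse.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be an (N, D) array")
    n, d = X.shape
    if n < n_components:
        raise ValueError(f"need at least {n_components} samples, got {n}")
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
        if w.shape != (n,) or (w < 0).any():
            raise ValueError("sample_weights must be N nonnegative values")
        if not w.sum() > 0:
            raise ValueError("sample_weights must not be all zero")

    rng = np.random.default_rng(seed)
    k = n_components
    if means_init is not None:
        starts = [np.asarray(means_init, dtype=np.float64)]
    else:
        # seeded restarts guard against a bad k-means++ draw; the run with
        # the best final weighted log-likelihood wins
        starts = [_kmeans_like_init(X, w, k, rng) for _ in range(max(1, n_init))]
    best = None
    for start in starts:
        model = _run_em(X, w, start, max_iter, tol, cov_floor)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    return best


def _run_em(X, w, means_init, max_iter, tol, cov_floor) -> GmmModel:
    n, d = X.shape
    k = len(means_init)
    means = means_init.copy()
    gvar = np.atleast_2d(np.cov(X.T, aweights=w + 1e-12))
    covs = np.stack([gvar + cov_floor * np.eye(d) for _ in range(k)])
    weights = np.full(k, 1.0 / k)

    ll_prev = -np.inf
    ll_trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        log_r = _log_component_densities(X, weights, means, covs)
        log_norm = _logsumexp(log_r, axis=1, keepdims=True)
        ll = float(np.sum(w * log_norm[:, 0]))
        ll_trace.append(ll)
        resp = np.exp(log_r - log_norm)

        wr = resp * w[:, None]  # weighted responsibilities
        nk = wr.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / nk.sum()
        means = (wr.T @ X) / nk[:, None]
        for j in range(k):
            diff = X - means[j]
            cov = (wr[:, j][:, None] * diff).T @ diff / nk[j]
            covs[j] = _floor_covariance(cov, cov_floor)

        if ll - ll_prev < tol and it > 1:
            break
        ll_prev = ll

    return GmmModel(
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=ll_trace[-1],
        ll_trace=ll_trace,
        n_iter=it,
    )


def _floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    """Floor eigenvalues to keep the covariance positive definite."""
    cov = (cov + cov.T) / 2
    vals, vecs = np.linalg.eigh(cov)
    if (vals < floor).any():
        vals = np.maximum(vals, floor)
        cov = (vecs * vals) @ vecs.T
    return cov


def _spatial_prior(shape: tuple[int, int], sigma_frac: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = sigma_frac * min(h, w)
    return np.exp(-(((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2) / (2 * sigma**2)))


def postprocess_mask(mask: np.ndarray, closing_radius: int) -> np.ndarray:
    """Morphological closing, then keep the largest connected component.

    Idempotent: applying it to its own output returns the same mask.
    Component-size ties break toward the component whose top-left-most
    pixel has the lowest (row, column).
    """
    if closing_radius > 0:
        mask = _morph.closing(mask, _morph.disk(closing_radius)).astype(bool)
    labels = _measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    best = None
    best_key = None
    for region in _measure.regionprops(labels):
        anchor = min(map(tuple, region.coords))
        key = (-region.area, anchor)
        if best_key is None or key < best_key:
            best_key, best = key, region.label
    return labels == best


def segment_neck(seq: FrameSequence, config: SegmentationConfig | None = None) -> RoiMask:
    """Derive one static skin mask per video.

    Pipeline: chroma features of the temporal median frame; weighted EM
    with a centered spatial prior; pick the component nearest the skin
    reference chroma; threshold its posterior at ``p_min``; close and keep
    the largest connected component.
    """
    config = config or SegmentationConfig()
    if config.user_mask is not None:
        mask = np.asarray(config.user_mask, dtype=bool)
        if mask.shape != seq.frame_shape:
            raise ValueError("user mask shape does not match the frames")
        return RoiMask(mask=mask)
    if seq.colorspace != "RGB":
        raise ValueError("segmentation expects an RGB sequence")

    median_frame = np.median(seq.frames, axis=0)
    chroma = rgb2yiq(median_frame)[..., 1:]  # (H, W, 2)
    h, w = seq.frame_shape
    X = chroma.reshape(-1, 2)
    if X.std(axis=0).max() < 1e-6:
        raise SegmentationFailedError(
            "uniform frames: no separable chroma component; supply a mask "
            "via SegmentationConfig.user_mask or use a full-frame mask"
        )

    prior = _spatial_prior((h, w), config.spatial_prior_sigma_frac).ravel()
    model = fit_weighted_gmm(
        X,
        sample_weights=prior,
        n_components=config.n_components,
        seed=config.seed,
        max_iter=config.max_iter,
        tol=config.tol,
    )
    ref = np.asarray(config.skin_reference_chroma)
    dist = np.linalg.norm(model.means - ref, axis=1)
    skin_ks = np.flatnonzero(dist <= config.skin_chroma_max_distance)
    if skin_ks.size == 0:
        skin_ks = np.array([int(np.argmin(dist))])
    posterior = model.responsibilities(X)[:, skin_ks].sum(axis=1).reshape(h, w)
    raw = posterior >= config.p_min

    radius = max(1, int(round(config.closing_radius_at_1920 * w / 1920.0)))
    mask = postprocess_mask(raw, radius)
    roi = RoiMask(mask=mask)
    if roi.coverage < config.min_coverage:
        raise SegmentationFailedError(
            f"segmented region covers {roi.coverage:.2%} of the frame "
            f"(< {config.min_coverage:.0%}); fall back to a full-frame mask "
            "or supply SegmentationConfig.user_mask"
        )
    return roi
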