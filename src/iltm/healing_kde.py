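"""Token healing, stochastic reconstruction stacks and KDE anomaly maps.

Given a trained quantizer and prior, an image is scored in four steps:

1. *Resample mask* — tokens whose autoregressive likelihood p(s_i) falls
   strictly below the resampling threshold t are flagged as suspicious.
2. *Healing* — each flagged position is redrawn from the prior's
   next-token distribution, left to right, conditioning on original tokens
   at unflagged positions and on already-healed tokens at earlier flagged
   positions.  Repeating this n_resamples times gives plausible "normal"
   versions of the token sequence.
3. *Reconstruction stack* — every healed sequence is decoded n_decodes
   times with dropout, yielding n_resamples * n_decodes stochastic
   reconstructions of what the image would look like without anomalies.
4. *KDE scoring* — at each pixel a Gaussian kernel density estimate with
   Silverman bandwidth h = (4 sigma^5 / 3n)^(1/5) + eps is fit to the
   stack intensities, and the log density at the original intensity is the
   anomaly score L: low L means the observed intensity is implausible
   under the healed reconstructions.  Pixels with density below a
   threshold (L < log(threshold)) are segmented as anomalous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import transformer as tr
from . import vqvae as vq
from ._nn import softmax

__all__ = [
    "ScoreParams",
    "ResampleMask",
    "ReconstructionStack",
    "AnomalyMap",
    "compute_resample_mask",
    "heal_sequence",
    "build_reconstruction_stack",
    "silverman_bandwidth",
    "kde_log_score",
    "anomaly_map",
    "segment",
    "score_image",
    "score_images",
]

_GAUSS_NORM = 1.0 / np.sqrt(2.0 * np.pi)


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the healing + KDE scoring stage.

    t : token resampling threshold on p(s_i).
    eps : bandwidth regularizer (0.05 on the normalized [0,1] intensity
        scale; 12.75 is the matching choice for 0-255-scale data).
    n_resamples / n_decodes : healed sequences per image and stochastic
        decodes per healed sequence (stack size is their product).
    density_threshold : KDE density value below which a pixel is
        segmented as anomalous (applied as L < log(density_threshold)).
    literal_sum : if True, drop the 1/n normalization inside the log
        (a constant shift of log n for fixed stack size).
    """

    t: float = 0.005
    eps: float = 0.05
    n_resamples: int = 60
    n_decodes: int = 5
    density_threshold: float = 0.005
    literal_sum: bool = False


DESK_PROFILE = ScoreParams(n_resamples=6, n_decodes=2)


@dataclass(frozen=True)
class ResampleMask:
    """Positions with p(s_i) strictly below the resampling threshold t."""

    flags: np.ndarray  # (l,) bool
    t: float


@dataclass(frozen=True)
class ReconstructionStack:
    """n stochastic "healed" reconstructions of one image."""

    images: np.ndarray  # (n, H, W)
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class AnomalyMap:
    """Per-pixel KDE log-likelihood score; lower means more anomalous."""

    L: np.ndarray          # (H, W)
    bandwidth: np.ndarray  # (H, W)
    params: ScoreParams


def compute_resample_mask(likelihoods, t: float) -> ResampleMask:
    """Flag position i iff p_i < t.  Accepts TokenLikelihoods or an array."""
    if not 0.0 < t < 1.0:
        raise ValueError("t must lie in (0, 1)")
    p = likelihoods.p if isinstance(likelihoods, tr.TokenLikelihoods) else \
        np.asarray(likelihoods, dtype=float)
    return ResampleMask(flags=p < t, t=t)


def heal_sequence(model: tr.TransformerModel, s: tr.TokenSequence,
                  resample_mask: ResampleMask, n_resamples: int,
                  seed=None) -> list[tr.TokenSequence]:
    """Draw n_resamples healed versions of ``s``.

    Unflagged positions are kept verbatim; flagged positions are redrawn
    left-to-right from the prior's next-token distribution, with earlier
    healed draws already in the conditioning context (so a healed blob
    onset steers later flagged positions toward coherent normal
    continuations).  All n_resamples sequences are advanced in one batched
    forward pass per flagged position.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    flags = np.flatnonzero(resample_mask.flags)
    healed = np.tile(s.s, (n_resamples, 1))
    cfg = model.config
    for pos in flags:
        ids = np.empty((n_resamples, pos + 1), dtype=np.int64)
        ids[:, 0] = cfg.bos
        ids[:, 1:] = healed[:, :pos]
        key_masked = np.zeros_like(ids, dtype=bool)
        logits, _ = tr._forward(model.params, cfg, ids, key_masked)
        dist = softmax(logits[:, -1], axis=-1)
        u = rng.random(n_resamples)
        cum = np.cumsum(dist, axis=-1)
        healed[:, pos] = np.minimum((u[:, None] < cum).argmax(axis=-1),
                                    cfg.vocab - 1)
    return [tr.TokenSequence(s=row, shape=s.shape) for row in healed]


def build_reconstruction_stack(vqvae_model: vq.VqvaeModel,
                               healed: Sequence[tr.TokenSequence],
                               n_decodes: int, seed=None, *,
                               stochastic: bool = True) -> ReconstructionStack:
    """Decode every healed sequence n_decodes times (with dropout if
    stochastic) into a stack of n_resamples * n_decodes reconstructions."""
    if n_decodes < 1:
        raise ValueError("n_decodes must be >= 1")
    codebook = vqvae_model.codebook
    grids = np.stack([vq.embed(codebook, tr.derasterize(h)) for h in healed])
    tiled = np.repeat(grids, n_decodes, axis=0)
    # one batched decode; each batch element draws independent dropout masks
    images = vq.decode(vqvae_model, tiled, stochastic=stochastic,
                       seed=_seedseq(seed))
    return ReconstructionStack(
        images=images,
        provenance={"n_resamples": len(healed), "n_decodes": n_decodes,
                    "seed": seed, "stochastic": stochastic})


def silverman_bandwidth(values: np.ndarray, eps: float = 0.0) -> float:
    """Silverman rule-of-thumb bandwidth (4 sigma^5 / 3n)^(1/5) + eps.

    sigma is the sample standard deviation (ddof=1; defined as 0 for a
    single value), so eps keeps the bandwidth positive for degenerate
    (constant) samples.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    n = values.size
    # an exactly-constant sample has sigma 0 by definition; bypassing the
    # numerical std avoids a ~1e-16 residual so that h == eps exactly
    if n == 1 or np.ptp(values) == 0.0:
        sigma = 0.0
    else:
        sigma = float(values.std(ddof=1))
    return float((4.0 * sigma**5 / (3.0 * n)) ** 0.2 + eps)


def kde_log_score(values: np.ndarray, x0: float, h: float, *,
                  literal_sum: bool = False) -> float:
    """Gaussian-KDE log density of x0 given samples ``values``.

    L = log( (1/(n h)) * sum_i K((x0 - x_i)/h) ) with the standard normal
    kernel K; ``literal_sum`` drops the 1/n factor.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    u = (x0 - values) / h
    kern = _GAUSS_NORM * np.exp(-0.5 * u * u)
    denom = h if literal_sum else values.size * h
    return float(np.log(np.maximum(kern.sum() / denom, 1e-300)))


def anomaly_map(stack: ReconstructionStack, original: np.ndarray,
                eps: float = 0.05, *, literal_sum: bool = False,
                params: ScoreParams | None = None) -> AnomalyMap:
    """Vectorized per-pixel Silverman bandwidth + KDE log score.

    Pixelwise identical to looping the two scalar operations.
    """
    imgs = stack.images
    if imgs.shape[1:] != original.shape:
        raise ValueError("stack and original image shapes differ")
    n = imgs.shape[0]
    if n > 1:
        sigma = imgs.std(axis=0, ddof=1)
        sigma[np.ptp(imgs, axis=0) == 0.0] = 0.0
    else:
        sigma = np.zeros_like(original)
    h = (4.0 * sigma**5 / (3.0 * n)) ** 0.2 + eps
    u = (original[None] - imgs) / h[None]
    kern = _GAUSS_NORM * np.exp(-0.5 * u * u)
    denom = h if literal_sum else n * h
    L = np.log(np.maximum(kern.sum(axis=0) / denom, 1e-300))
    p = params if params is not None else ScoreParams(eps=eps,
                                                     literal_sum=literal_sum)
    return AnomalyMap(L=L, bandwidth=h, params=p)


def segment(amap: AnomalyMap, score_threshold: float | None = None, *,
            log_scale: bool = False) -> np.ndarray:
    """Binary segmentation: pixel flagged iff L < log(score_threshold).

    ``log_scale=True`` interprets the threshold as already being on the
    log-density scale.
    """
    thr = amap.params.density_threshold if score_threshold is None \
        else score_threshold
    log_thr = thr if log_scale else np.log(thr)
    return amap.L < log_thr


def score_image(vqvae_model: vq.VqvaeModel, prior: tr.TransformerModel,
                image: np.ndarray, params: ScoreParams = ScoreParams(),
                seed=None, *,
                context_mask: np.ndarray | None = None) -> AnomalyMap:
    """Full healing + KDE scoring of one image.

    ``context_mask`` (length h*w) marks tokens already suspected anomalous
    (e.g. the previous training-loop iteration's mask).  When given, a
    token is flagged for resampling if it is improbable under EITHER
    conditioning view: the plain context, or the context with the
    suspected tokens excluded.  The second view exposes anomalous
    continuations whose visible anomalous context would otherwise make
    them look likely; the first is immune to the prior having learned to
    expect anomalies right after masked positions.  Healing itself always
    conditions on the healed prefix, so flagged positions earlier in
    raster order steer later ones.
    """
    ss = _seedseq(seed)
    grid = vq.tokens_for(vqvae_model, image)
    seq = tr.rasterize(grid)
    p = tr.token_likelihoods_batch(prior, seq.s[None])[0]
    flags = p < params.t
    if context_mask is not None and np.any(context_mask):
        cm = np.asarray(context_mask, bool)
        p_ctx = tr.token_likelihoods_batch(prior, seq.s[None], cm[None])[0]
        flags = flags | (p_ctx < params.t)
    return _score_with_flags(vqvae_model, prior, image, seq, flags, params, ss)


def _score_with_flags(vqvae_model, prior, image, seq, flags, params, ss):
    s_heal, s_dec = ss.spawn(2)
    rmask = ResampleMask(flags=flags, t=params.t)
    healed = heal_sequence(prior, seq, rmask, params.n_resamples, s_heal)
    stack = build_reconstruction_stack(vqvae_model, healed, params.n_decodes,
                                       s_dec)
    return anomaly_map(stack, image, params.eps,
                       literal_sum=params.literal_sum, params=params)


def score_images(vqvae_model: vq.VqvaeModel, prior: tr.TransformerModel,
                 images: np.ndarray, params: ScoreParams = ScoreParams(),
                 seed=None, *, context_masks=None) -> list[AnomalyMap]:
    """Score a batch of images with per-image seeds spawned from ``seed``.

    Equivalent to calling :func:`score_image` per image, but the token
    likelihood passes that decide the resample flags are batched across
    the whole image set.
    """
    ss = _seedseq(seed)
    children = ss.spawn(len(images))
    grids = vq.tokens_for(vqvae_model, np.asarray(images))
    S = grids.reshape(len(images), -1)
    latent_shape = grids.shape[1:]
    p = tr.token_likelihoods_batch(prior, S)
    flags = p < params.t
    if context_masks is not None:
        cm = np.asarray(context_masks, dtype=bool)
        if cm.any():
            p_ctx = tr.token_likelihoods_batch(prior, S, cm)
            flags = flags | (p_ctx < params.t)
    maps = []
    for img, srow, frow, child in zip(images, S, flags, children):
        seq = tr.TokenSequence(s=srow, shape=latent_shape)
        maps.append(_score_with_flags(vqvae_model, prior, img, seq, frow,
                                      params, child))
    return maps
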