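"""Iterative latent token masking: the self-supervised training loop.

The quantizer is trained once on the (possibly contaminated) training set
and frozen.  The prior is then trained repeatedly:

* iteration 0 trains with all-zero masks (plain maximum likelihood);
* each iteration scores every training image with the current prior
  (healing + KDE anomaly map at the iteration's resampling threshold),
  thresholds the map into a segmentation, max-pools it down to the latent
  grid to obtain per-sample token masks, and retrains the prior from
  scratch with those tokens excluded from attention context and loss;
* the resampling threshold decays geometrically,
  t_m = t0 * (1 - decay)**m;
* the loop stops when the total masked-token count changes by at most 1%
  between consecutive iterations, or at max_iterations.

Under contamination, suspected anomalous tokens are progressively removed
from training, so the prior converges toward the model that would have
been fit on inlier data alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import Adam
from . import healing_kde as hk
from . import transformer as tr
from . import vqvae as vq

__all__ = [
    "LoopConfig",
    "IterationState",
    "ILTMResult",
    "downsample_segmentation",
    "threshold_schedule",
    "convergence_check",
    "run_iltm",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoopConfig:
    """Loop-level parameters.

    t0 : initial resampling threshold.
    decay : per-iteration fractional reduction of the threshold
        (0.125 by default; 0 gives the constant-threshold ablation).
    max_iterations : hard cap on training iterations.
    score : healing/KDE parameters used to score the training set.
    pool : 'max' flags a token if ANY pixel in its cell is flagged;
        'majority' requires more than half.
    convergence_tol : relative change in masked-token count that counts
        as converged.
    fine_tune : warm-start each iteration from the previous parameters
        instead of retraining from scratch; ``fine_tune_epochs`` (default:
        the transformer config's epochs) controls the warm-start budget.
    augment : train the prior on the 8 dihedral transforms of each token
        grid (flips/rotations in latent space).  Off by default; useful on
        small training sets where the prior otherwise overfits and flags
        held-out normal tokens.
    mask_context_scoring : when scoring the training set at iteration m,
        condition token likelihoods on the context minus the previous
        iteration's masked tokens — the same regime the prior was trained
        in.
    """

    t0: float = 0.005
    decay: float = 0.125
    max_iterations: int = 10
    score: hk.ScoreParams = field(default_factory=hk.ScoreParams)
    pool: str = "max"
    convergence_tol: float = 0.01
    fine_tune: bool = False
    fine_tune_epochs: int | None = None
    keep_models: bool = False
    augment: bool = False
    mask_context_scoring: bool = True


@dataclass
class IterationState:
    """Bookkeeping for one loop iteration (0-based)."""

    m: int
    t_m: float
    masks: np.ndarray          # (N, l) bool token masks produced BY this iteration
    c_m: int                   # total masked-token count (sum of mask entries)
    converged: bool
    loss_log: list = field(default_factory=list)
    model: tr.TransformerModel | None = None

    def __post_init__(self):
        if self.c_m != int(self.masks.sum()):
            raise ValueError("c_m must equal the sum of mask entries")


@dataclass
class ILTMResult:
    vqvae: vq.VqvaeModel
    transformer: tr.TransformerModel
    states: list[IterationState]
    converged: bool


def downsample_segmentation(pixel_mask: np.ndarray,
                            latent_shape: tuple[int, int], *,
                            pool: str = "max") -> np.ndarray:
    """Pool a pixel segmentation down to the latent grid, row-major.

    'max' pooling flags a token if any pixel of its receptive cell is
    flagged (under-masking an anomaly is costlier than over-masking a
    normal token); 'majority' requires > half the cell.
    Returns the rasterized (length h*w) token mask.
    """
    H, W = pixel_mask.shape
    h, w = latent_shape
    if H % h or W % w:
        raise ValueError(f"pixel mask {pixel_mask.shape} not divisible by "
                         f"latent shape {latent_shape}")
    cells = pixel_mask.reshape(h, H // h, w, W // w)
    if pool == "max":
        tok = cells.any(axis=(1, 3))
    elif pool == "majority":
        tok = cells.mean(axis=(1, 3)) > 0.5
    else:
        raise ValueError(f"unknown pool {pool!r}")
    return tok.reshape(-1)


def threshold_schedule(t0: float, decay: float, m: int) -> float:
    """t_m = t0 * (1 - decay)**m (decay=0 gives the constant schedule)."""
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    if not 0.0 <= decay < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    return t0 * (1.0 - decay) ** m


def convergence_check(c_m: int, c_prev: int, tol: float = 0.01) -> bool:
    """True iff the masked-token count changed by at most tol (relative).

    With c_prev = 0 only c_m = 0 counts as converged.
    """
    if c_prev < 0:
        raise ValueError("counts must be non-negative")
    if c_prev == 0:
        return c_m == 0
    return abs(c_m - c_prev) <= tol * c_prev


def _dihedral(grid: np.ndarray, k: int) -> np.ndarray:
    """k-th of the 8 symmetries of the square (rotations + mirrored)."""
    g = np.rot90(grid, k % 4)
    return np.flip(g, axis=1) if k >= 4 else g


def augment_dihedral(S: np.ndarray, M: np.ndarray,
                     latent_shape: tuple[int, int]):
    """All 8 dihedral transforms of every token grid (and its mask)."""
    h, w = latent_shape
    G = S.reshape(-1, h, w)
    Gm = M.reshape(-1, h, w)
    seqs, masks = [], []
    for k in range(8):
        seqs.append(np.stack([_dihedral(g, k) for g in G]).reshape(len(G), -1))
        masks.append(np.stack([_dihedral(g, k) for g in Gm]).reshape(len(G), -1))
    return np.concatenate(seqs), np.concatenate(masks)


def _score_training_set(vmodel, prior, images, params, seed,
                        context_masks=None, pool="max"):
    """Anomaly maps -> segmentations -> token masks for every image."""
    f = vmodel.config.factor
    latent_shape = (images.shape[1] // f, images.shape[2] // f)
    maps = hk.score_images(vmodel, prior, images, params, seed,
                           context_masks=context_masks)
    masks = np.stack([
        downsample_segmentation(hk.segment(m), latent_shape, pool=pool)
        for m in maps])
    return masks, maps


def run_iltm(dataset, vqvae_config: vq.VqvaeConfig = vq.VqvaeConfig(),
             transformer_config: tr.TransformerConfig = tr.TransformerConfig(),
             loop_config: LoopConfig = LoopConfig(),
             seed: int = 0) -> ILTMResult:
    """Run the full iterative procedure on a training dataset.

    Returns the frozen quantizer, the final prior, and one IterationState
    per executed iteration.  If the 1%-change stopping rule is not met by
    ``max_iterations`` the result carries ``converged=False`` (with a
    warning, not an exception).
    """
    images = dataset if isinstance(dataset, np.ndarray) else dataset.images
    ss = np.random.SeedSequence(seed)
    s_vq, s_tr, s_score = ss.spawn(3)
    # one derived seed reused across iterations (common random numbers):
    # retraining is from scratch with identical initialization and shuffle
    # order, and scoring redraws identical healing/decode randomness, so
    # differences between iterations are attributable to the masks alone
    tr_seed = int(s_tr.generate_state(1)[0])
    score_seed = int(s_score.generate_state(1)[0])
    tr_seeds = [tr_seed] * loop_config.max_iterations
    score_seeds = [score_seed] * loop_config.max_iterations

    vmodel = vq.train_vqvae(images, vqvae_config, s_vq)
    f = vmodel.config.factor
    latent_shape = (images.shape[1] // f, images.shape[2] // f)
    S = np.stack([vq.tokens_for(vmodel, img).reshape(-1) for img in images])

    masks = np.zeros_like(S, dtype=bool)   # iteration 0: no masking
    states: list[IterationState] = []
    prior = None
    c_prev: int | None = None
    converged = False
    for m in range(loop_config.max_iterations):
        t_m = threshold_schedule(loop_config.t0, loop_config.decay, m)
        if loop_config.augment:
            S_tr, M_tr = augment_dihedral(S, masks, latent_shape)
        else:
            S_tr, M_tr = S, masks
        if loop_config.fine_tune and prior is not None:
            prior = _fine_tune(prior, S_tr, M_tr, transformer_config,
                               tr_seeds[m],
                               epochs=loop_config.fine_tune_epochs)
        else:
            prior = tr.train_transformer(S_tr, M_tr, transformer_config,
                                         tr_seeds[m])
        params_m = replace(loop_config.score, t=t_m)
        ctx = masks if (loop_config.mask_context_scoring and masks.any()) \
            else None
        new_masks, _ = _score_training_set(vmodel, prior, images, params_m,
                                           score_seeds[m], context_masks=ctx,
                                           pool=loop_config.pool)
        c_m = int(new_masks.sum())
        converged = (c_prev is not None
                     and convergence_check(c_m, c_prev,
                                           loop_config.convergence_tol))
        log.info("iteration m=%d t_m=%.6g c_m=%d converged=%s",
                 m, t_m, c_m, converged)
        states.append(IterationState(
            m=m, t_m=t_m, masks=new_masks, c_m=c_m, converged=converged,
            loss_log=list(prior.loss_log),
            model=prior if loop_config.keep_models else None))
        if converged:
            break
        c_prev = c_m
        masks = new_masks
    if not converged:
        warnings.warn("ILTM loop reached max_iterations without meeting the "
                      "masked-token convergence rule", RuntimeWarning)
    return ILTMResult(vqvae=vmodel, transformer=prior, states=states,
                      converged=converged)


def _fine_tune(prior, S, masks, config, seed, epochs=None):
    """Continue training the existing prior (warm start)."""
    epochs = config.epochs if epochs is None else epochs
    model = tr.TransformerModel(params={k: v.copy()
                                        for k, v in prior.params.items()},
                                config=config,
                                loss_log=list(prior.loss_log))
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=config.lr)
    n = len(S)
    for _ in range(epochs):
        order = rng.permutation(n)
        total, weight = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            if (~masks[sel]).sum() == 0:
                continue
            loss, grads = tr.masked_cross_entropy(
                model.params, config, S[sel], masks[sel], with_grads=True)
            opt.step(grads)
            total += loss * len(sel)
            weight += len(sel)
        model.loss_log.append(total / max(weight, 1))
    return model
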