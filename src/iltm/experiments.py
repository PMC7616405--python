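"""Desk-scale experiment profiles and the contamination-robustness study.

The profiles below define the package's reference desk-scale conditions:
200 training images (32x32, 8x8 latent grid), held-out evaluation set of
50 images, three training iterations, and a reduced healing budget of
6 resamples x 2 stochastic decodes per image.  They are sized so a full
run takes a couple of minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation as ev
from . import healing_kde as hk
from . import loop as lp
from . import synthetic as syn
from . import transformer as tr
from . import vqvae as vq

__all__ = [
    "DeskProfile",
    "DESK",
    "contamination_run",
    "contamination_study",
]


@dataclass(frozen=True)
class DeskProfile:
    """Bundle of desk-scale configurations for the full pipeline."""

    n_train: int = 200
    n_test: int = 50
    image_size: tuple[int, int] = (32, 32)
    vqvae: vq.VqvaeConfig = field(default_factory=lambda: vq.VqvaeConfig(
        hidden=48, n_z=8, K=64, epochs=40, lr=2e-3, revive_dead_codes=True))
    transformer: tr.TransformerConfig = field(
        default_factory=lambda: tr.TransformerConfig(
            vocab=64, context=65, d_model=64, n_heads=4, n_layers=2,
            d_ff=128, epochs=16, lr=3e-3, batch_size=64))
    loop: lp.LoopConfig = field(default_factory=lambda: lp.LoopConfig(
        max_iterations=3, score=hk.DESK_PROFILE, keep_models=True,
        augment=True, fine_tune=True, fine_tune_epochs=8))


DESK = DeskProfile()


def contamination_run(contamination: float, seed: int,
                      profile: DeskProfile = DESK) -> dict:
    """One full ILTM run plus held-out evaluation at a contamination ratio.

    Returns per-iteration masked-token counts, thresholds, recall and
    precision of the token masks against ground-truth anomalous latent
    cells, the masked-token fraction, and held-out pixel AUROC of the
    iteration-0 (no masking) and final priors.
    """
    train = syn.build_dataset(profile.n_train, contamination, seed,
                              profile.image_size)
    test = syn.build_dataset(profile.n_test, 0.5, seed + 500_000,
                             profile.image_size)

    res = lp.run_iltm(train, profile.vqvae, profile.transformer,
                      profile.loop, seed)
    f = res.vqvae.config.factor
    latent_shape = (profile.image_size[0] // f, profile.image_size[1] // f)
    gt_latent = np.stack([
        lp.downsample_segmentation(s.anomaly_mask, latent_shape)
        for s in train])

    iters = []
    for st in res.states:
        tp = int((st.masks & gt_latent).sum())
        iters.append({
            "m": st.m,
            "t_m": st.t_m,
            "c_m": st.c_m,
            "masked_fraction": float(st.masks.mean()),
            "recall": tp / max(int(gt_latent.sum()), 1),
            "precision": tp / max(int(st.masks.sum()), 1),
        })

    def heldout_auroc(prior):
        maps = hk.score_images(res.vqvae, prior, test.images,
                               profile.loop.score, seed + 900_000)
        return ev.pixel_auroc(ev.maps_to_scores(maps), test.masks)

    return {
        "contamination": contamination,
        "seed": seed,
        "converged": res.converged,
        "iterations": iters,
        "auroc_iter0": heldout_auroc(res.states[0].model),
        "auroc_final": heldout_auroc(res.transformer),
        "n_train": profile.n_train,
        "n_test": profile.n_test,
    }


def contamination_study(seeds, contamination: float = 0.5,
                        profile: DeskProfile = DESK) -> dict:
    """Aggregate contamination runs over several seeds.

    Reports per-iteration mean token-mask recall and the mean held-out
    AUROC of the iteration-0 and final priors.
    """
    runs = [contamination_run(contamination, s, profile) for s in seeds]
    n_iters = min(len(r["iterations"]) for r in runs)
    mean_recall = [float(np.mean([r["iterations"][m]["recall"] for r in runs]))
                   for m in range(n_iters)]
    return {
        "contamination": contamination,
        "seeds": list(seeds),
        "runs": runs,
        "mean_recall_per_iteration": mean_recall,
        "mean_auroc_iter0": float(np.mean([r["auroc_iter0"] for r in runs])),
        "mean_auroc_final": float(np.mean([r["auroc_final"] for r in runs])),
    }
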