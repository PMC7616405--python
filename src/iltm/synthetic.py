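"""Seeded synthetic datasets of textured normal images with localized anomalies.

Emulates the statistical setting of anomaly-segmentation benchmarks in which
a training set of homogeneous textured images is contaminated, at a known
ratio, with images carrying localized blob anomalies of shifted intensity
(hot or cold lesions on a smooth background).  Every sample carries an exact
ground-truth mask, so the whole detection pipeline is testable at desk scale
without any external download.

Normal images are band-limited noise: white Gaussian noise convolved with a
Gaussian kernel and min-max rescaled to [0, 1].  Anomalies are additive
elliptical blobs with soft (linear-ramp) edges; the ground-truth mask is the
support where the additive term exceeds half its peak amplitude.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "SyntheticSample",
    "AnomalySpec",
    "ContaminatedDataset",
    "generate_normal",
    "inject_anomaly",
    "build_dataset",
    "build_splits",
    "save_dataset",
    "load_dataset",
]

MIN_SIZE = 16


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SyntheticSample:
    """One image with its ground-truth anomaly mask.

    Invariants: image and mask share a shape, intensities lie in [0, 1],
    and the mask is non-empty iff the sample is anomalous.
    """

    image: np.ndarray
    anomaly_mask: np.ndarray
    is_anomalous: bool

    def __post_init__(self):
        if self.image.shape != self.anomaly_mask.shape:
            raise ValueError("image and anomaly_mask shapes differ")
        if self.image.min() < 0.0 or self.image.max() > 1.0:
            raise ValueError("image intensities must lie in [0, 1]")
        if bool(self.anomaly_mask.any()) != bool(self.is_anomalous):
            raise ValueError("anomaly_mask must be non-empty iff is_anomalous")


@dataclass(frozen=True)
class AnomalySpec:
    """Parameters of the injected blob anomalies.

    n_blobs : inclusive range of blob count per anomalous image.
    radius : range of blob radius in pixels (mask support radius).
    shift : range of the additive intensity shift magnitude.
    sign : 'auto' picks the direction with head-room (darken bright areas,
        brighten dark ones); 'positive'/'negative' force it.
    edge_width : half-width in pixels of the linear soft edge.
    min_contrast : minimum |mean(inside) - mean(just outside)| enforced by
        rescaling the additive field once if needed.
    axis_ratio : range of per-axis scale factors (elliptical blobs).
    allow_empty : if True, a request for zero blobs is a no-op instead of
        an error.
    """

    n_blobs: tuple[int, int] = (1, 3)
    radius: tuple[float, float] = (2.0, 5.0)
    shift: tuple[float, float] = (0.3, 0.6)
    sign: str = "auto"
    edge_width: float = 1.5
    min_contrast: float = 0.15
    axis_ratio: tuple[float, float] = (0.75, 1.33)
    allow_empty: bool = False


@dataclass(frozen=True)
class ContaminatedDataset:
    """An ordered collection of samples at a known contamination ratio."""

    samples: tuple[SyntheticSample, ...]
    contamination: float
    seed: int

    def __post_init__(self):
        n_anom = sum(s.is_anomalous for s in self.samples)
        if n_anom != round(self.contamination * len(self.samples)):
            raise ValueError("anomalous count does not match contamination")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i) -> SyntheticSample:
        return self.samples[i]

    @property
    def images(self) -> np.ndarray:
        """All images stacked into an (N, H, W) array."""
        return np.stack([s.image for s in self.samples])

    @property
    def masks(self) -> np.ndarray:
        """All ground-truth masks stacked into an (N, H, W) bool array."""
        return np.stack([s.anomaly_mask for s in self.samples])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.is_anomalous for s in self.samples])


def generate_normal(seed, size: tuple[int, int] = (32, 32), *,
                    filter_sigma: float = 4.0) -> SyntheticSample:
    """Generate one normal (anomaly-free) textured image.

    Low-pass-filtered white noise, min-max rescaled to [0, 1].
    """
    h, w = size
    if h < MIN_SIZE or w < MIN_SIZE:
        raise ValueError(f"size must be at least {MIN_SIZE}x{MIN_SIZE}, got {size}")
    rng = _rng(seed)
    noise = rng.standard_normal((h, w))
    tex = ndimage.gaussian_filter(noise, sigma=filter_sigma, mode="wrap")
    lo, hi = tex.min(), tex.max()
    if hi - lo < 1e-12:  # degenerate flat field; cannot happen in practice
        tex = np.zeros_like(tex)
    else:
        tex = (tex - lo) / (hi - lo)
    return SyntheticSample(image=tex,
                           anomaly_mask=np.zeros((h, w), dtype=bool),
                           is_anomalous=False)


def _blob_field(shape, center, radius, axes, angle, edge_width) -> np.ndarray:
    """Soft elliptical bump with unit peak: 1 inside, linear ramp across the
    edge, exactly 0.5 at the nominal radius, 0 outside radius+edge_width."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = (c * dx + s * dy) / axes[1]
    v = (-s * dx + c * dy) / axes[0]
    # scaled distance: equals `radius` on the ellipse boundary and approximates
    # pixel distance near it, so edge_width stays in pixel units
    d = radius * np.sqrt(u * u + v * v)
    e = max(edge_width, 1e-9)
    return np.clip((radius + e - d) / (2.0 * e), 0.0, 1.0)


def inject_anomaly(sample: SyntheticSample, seed,
                   params: AnomalySpec = AnomalySpec()) -> SyntheticSample:
    """Blend one or more soft-edged blobs into a normal sample.

    The ground-truth mask marks pixels where some blob's additive field
    exceeds half its peak — i.e. the rasterized ellipse of the nominal
    radius.  The mean intensity change inside the mask is at least
    ``params.min_contrast``.
    """
    if sample.is_anomalous:
        raise ValueError("inject_anomaly expects a normal sample")
    rng = _rng(seed)
    h, w = sample.image.shape

    n_blobs = int(rng.integers(params.n_blobs[0], params.n_blobs[1] + 1))
    if n_blobs == 0:
        if params.allow_empty:
            return sample
        raise ValueError("zero blobs requested (set allow_empty to permit)")

    # one shift direction per image (lesions are consistently hot or cold);
    # 'auto' brightens dark images and darkens bright ones for head-room
    if params.sign == "auto":
        sign = -1.0 if sample.image.mean() > 0.5 else 1.0
    else:
        sign = {"positive": 1.0, "negative": -1.0}[params.sign]

    delta = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_blobs):
        radius = float(rng.uniform(*params.radius))
        axes = rng.uniform(*params.axis_ratio, size=2) * radius
        if 2 * axes.max() > min(h, w):
            raise ValueError("blob larger than image")
        pad = axes.max()
        center = (rng.uniform(pad, h - 1 - pad), rng.uniform(pad, w - 1 - pad))
        angle = rng.uniform(0, np.pi)
        amp = float(rng.uniform(*params.shift))
        field_ = _blob_field((h, w), center, radius, axes, angle,
                             params.edge_width)
        delta = np.maximum(delta, amp * field_)
        mask |= field_ > 0.5   # nominal-radius ellipse support

    # enforce the configured contrast between the blob interior and the
    # surrounding unmodified texture (ring beyond the soft edge)
    support = delta > 1e-12
    ring = ndimage.binary_dilation(support, iterations=3) & ~support
    if not ring.any():
        ring = ~support
    for _ in range(4):
        out = np.clip(sample.image + sign * delta, 0.0, 1.0)
        contrast = abs(out[mask].mean() - out[ring].mean())
        if contrast >= params.min_contrast:
            break
        delta = delta * (params.min_contrast / max(contrast, 0.02)) * 1.3

    return SyntheticSample(image=out, anomaly_mask=mask, is_anomalous=True)


def build_dataset(n: int, contamination: float, seed: int,
                  size: tuple[int, int] = (32, 32),
                  params: AnomalySpec = AnomalySpec(), *,
                  filter_sigma: float = 4.0,
                  shuffle: bool = True) -> ContaminatedDataset:
    """Build a dataset with exactly round(contamination*n) anomalous samples.

    Fully determined by ``seed``: per-sample generators are spawned from a
    single SeedSequence, and the sample order is shuffled by the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must lie in [0, 1]")
    n_anom = round(contamination * n)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    samples = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        s = generate_normal(rng, size, filter_sigma=filter_sigma)
        if i < n_anom:
            s = inject_anomaly(s, rng, params)
        samples.append(s)
    if shuffle:
        order = np.random.default_rng(children[n]).permutation(n)
        samples = [samples[i] for i in order]
    return ContaminatedDataset(samples=tuple(samples),
                               contamination=contamination, seed=seed)


def build_splits(n_per_split: dict[str, int], contamination: float, seed: int,
                 size: tuple[int, int] = (32, 32),
                 params: AnomalySpec = AnomalySpec(), *,
                 test_contamination: float | None = None,
                 filter_sigma: float = 4.0) -> dict[str, ContaminatedDataset]:
    """Independent train/val/test splits generated from per-split seed offsets.

    Ground-truth masks of non-training splits are intended for evaluation
    only, mirroring the unlabeled-training assumption.
    """
    out = {}
    for k, (name, n) in enumerate(n_per_split.items()):
        frac = contamination
        if name != "train" and test_contamination is not None:
            frac = test_contamination
        split_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0]
            % (2**31)
        )
        out[name] = build_dataset(n, frac, split_seed, size, params,
                                  filter_sigma=filter_sigma)
    return out


def save_dataset(dataset: ContaminatedDataset, outdir, *, fmt: str = "png",
                 split: str = "train") -> Path:
    """Write images and masks to disk plus a CSV manifest; returns its path.

    ``fmt='png'`` stores 8-bit quantized intensities; ``fmt='tiff'`` stores
    float32 losslessly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    rows = []
    for i, s in enumerate(dataset):
        if fmt == "png":
            img_path = outdir / f"img_{i:05d}.png"
            iio.imwrite(img_path, np.round(s.image * 255).astype(np.uint8))
        elif fmt == "tiff":
            img_path = outdir / f"img_{i:05d}.tiff"
            tifffile.imwrite(img_path, s.image.astype(np.float32))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        mask_path = ""
        if s.is_anomalous:
            mask_path = outdir / f"mask_{i:05d}.png"
            iio.imwrite(mask_path, (s.anomaly_mask * 255).astype(np.uint8))
            mask_path = mask_path.name
        rows.append([img_path.name, mask_path, int(s.is_anomalous), split])
    with open(manifest, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["path", "mask_path", "is_anomalous", "split"])
        wr.writerows(rows)
    return manifest


def load_dataset(manifest, *, contamination: float | None = None,
                 seed: int = 0) -> ContaminatedDataset:
    """Load a dataset written by :func:`save_dataset`."""
    manifest = Path(manifest)
    root = manifest.parent
    samples = []
    with open(manifest) as f:
        for row in csv.DictReader(f):
            img = iio.imread(root / row["path"])
            if img.dtype == np.uint8:
                img = img.astype(float) / 255.0
            img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
            is_anom = bool(int(row["is_anomalous"]))
            if row["mask_path"]:
                mask = iio.imread(root / row["mask_path"]) > 127
            else:
                mask = np.zeros(img.shape, dtype=bool)
            samples.append(SyntheticSample(img, mask, is_anom))
    if contamination is None:
        contamination = sum(s.is_anomalous for s in samples) / len(samples)
    return ContaminatedDataset(tuple(samples), contamination, seed)
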