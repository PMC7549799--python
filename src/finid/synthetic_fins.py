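"""Synthetic dorsal-fin image generator with ground truth.

Real blue-whale dorsal fins fall into three shape families — falcate
(sickle-shaped, concave trailing edge), hooked (tip curled over the trailing
edge) and triangular (straight edges) — each photographed from the right or
left flank, the mirror image.  This module renders labeled images of those
six classes so every pipeline stage can be exercised and scored against
known geometry without a photographic database.

Shape model.  The outline is two cubic Bezier curves (leading and trailing
edge) over a straight base.  One parameter, ``tip_curl`` in [0, 1], moves
the family continuously from straight-edged triangles (curl near 0) through
backward-swept concave falcate blades (mid curl) to overhanging drooping
hooks (high curl); each class constrains the parameter to its band.  All
fins carry a constant backward rake — as real dorsal fins do — so that even
a low-curl triangular fin is chiral and its mirror image is a genuinely
different shape.  Base width is drawn from a class-banded range (falcate
fins are long-based, hooked fins narrow-based).  A one-sided band at the
fin base represents the whale's back receding toward the peduncle, the way
photo-identification ROIs actually frame a fin.

Appearance.  Fins are three-dimensional bodies, not flat cut-outs: the
silhouette is shaded with a linear distance-to-edge dome (darkest at the
waterline-shadowed outline, brightest along the medial ridge), composited
over a bright background — flat, or a low-frequency sinusoid mixture
emulating sea-surface shading — and zero-mean Gaussian pixel noise is
added.  Left-flank classes are the exact horizontal mirror of the
right-flank render.  Everything is a deterministic function of the spec,
including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .classifier import CLASS_LABELS
from .imaging import ContourMask, GrayImage

#: tip_curl bands per shape family.
CURL_BANDS = {
    "triangular": (0.0, 0.15),
    "falcate": (0.35, 0.6),
    "hooked": (0.75, 1.0),
}

#: base width (fraction of fin height) bands per shape family.
BASE_WIDTH_BANDS = {
    "falcate": (0.58, 0.68),
    "hooked": (0.42, 0.52),
    "triangular": (0.50, 0.60),
}

FIN_VALUE = 0.15  # darkest fin luminance (outline shadow)
SHADING_AMPLITUDE = 0.45  # medial-ridge brightening of the shading dome
BACKGROUND_VALUE = 0.75  # bright sea luminance
FIN_SIZE_FRACTION = 0.55  # unit fin height as a fraction of the canvas side


def _family(label: str) -> str:
    return label.split("_", 1)[1]


def _is_left(label: str) -> bool:
    return label.startswith("left_")


def mirror_label(label: str) -> str:
    """The same shape family seen from the other flank."""
    side, fam = label.split("_", 1)
    return ("left_" if side == "right" else "right_") + fam


@dataclass(frozen=True)
class FinSpec:
    """Parameters fully determining one synthetic fin image."""

    label: str
    height_px: int = 160
    width_px: int = 160
    tip_curl: float | None = None  # None -> band midpoint for the class
    base_width_frac: float = 0.55
    rotation_deg: float = 0.0
    scale: float = 1.0
    noise_sigma: float = 0.02
    background: str = "flat"  # flat | sea_texture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label: {self.label!r}")
        band = CURL_BANDS[_family(self.label)]
        if self.tip_curl is None:
            object.__setattr__(self, "tip_curl", 0.5 * (band[0] + band[1]))
        if not (band[0] <= self.tip_curl <= band[1]):
            raise ValueError(
                f"tip_curl {self.tip_curl} outside the {_family(self.label)} "
                f"band {band}"
            )
        if not (0 < self.base_width_frac < 1):
            raise ValueError("base_width_frac must lie in (0, 1)")
        if not (-15.0 <= self.rotation_deg <= 15.0):
            raise ValueError("rotation_deg must lie in [-15, 15]")
        if not (0.5 <= self.scale <= 2.0):
            raise ValueError("scale must lie in [0.5, 2]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.background not in ("flat", "sea_texture"):
            raise ValueError(f"unknown background: {self.background!r}")


@dataclass(frozen=True)
class FinSample:
    image: GrayImage
    contour_truth: ContourMask
    label: str
    spec: FinSpec


def _bezier(p0, p1, p2, p3, n: int = 120) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def _fin_polygon(curl: float, bw: float) -> np.ndarray:
    """Right-flank fin outline as (n, 2) (x, y), y up, unit height, base at y=0.

    The tip rakes backward by (0.38 + curl) * base_width and droops once the
    curl passes into the hooked band; the trailing edge gains concavity
    linearly with curl (straight for triangular, sickle for falcate, deep
    for hooked); the leading edge bulges slightly convex.
    """
    droop = 0.35 * max(0.0, (curl - 0.55) / 0.45) ** 1.5
    tip = np.array([(0.38 + 1.0 * curl) * bw, 1.0 - droop])
    base_front = np.array([-bw / 2.0, 0.0])
    base_rear = np.array([bw / 2.0, 0.0])
    lead_c1 = base_front + (tip - base_front) / 3.0 + np.array([(0.08 + 0.22 * curl) * bw, 0])
    lead_c2 = base_front + 2 * (tip - base_front) / 3.0 + np.array([(0.12 + 0.3 * curl) * bw, 0])
    d = 0.55 * curl * bw
    trail_c1 = tip + (base_rear - tip) / 3.0 + np.array([d, 0.0])
    trail_c2 = tip + 2 * (base_rear - tip) / 3.0 + np.array([0.6 * d, 0.0])
    leading = _bezier(base_front, lead_c1, lead_c2, tip)
    trailing = _bezier(tip, trail_c1, trail_c2, base_rear)
    return np.vstack([leading, trailing[1:]])


def _back_polygon(bw: float) -> np.ndarray:
    """The whale's back at the fin base: blunt ahead, receding toward the tail."""
    return np.array(
        [
            [-bw / 2.0 - 0.12, 0.02],
            [bw / 2.0 + 0.55, -0.08],
            [bw / 2.0 + 0.55, -0.14],
            [-bw / 2.0 - 0.12, -0.08],
        ]
    )


def _render_mask(spec: FinSpec) -> np.ndarray:
    """Rasterize the (right-flank) fin + back silhouette after rotation/scaling."""
    H, W = spec.height_px, spec.width_px
    size = FIN_SIZE_FRACTION * min(H, W) * spec.scale
    theta = np.deg2rad(spec.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    fin = _fin_polygon(float(spec.tip_curl), spec.base_width_frac) * size
    centroid = fin.mean(axis=0)

    def rasterize(pts: np.ndarray) -> np.ndarray:
        p = (pts - centroid) @ rot.T
        cols = p[:, 0] + (W - 1) / 2.0
        rows = (H - 1) / 2.0 - p[:, 1]  # y up -> raster rows down
        rr, cc = _sk_polygon(rows, cols, shape=(H, W))
        m = np.zeros((H, W), dtype=bool)
        m[rr, cc] = True
        return m

    return rasterize(fin) | rasterize(_back_polygon(spec.base_width_frac) * size)


def _background(spec: FinSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.height_px, spec.width_px
    if spec.background == "flat":
        return np.full((H, W), BACKGROUND_VALUE)
    # sea texture: a few low-frequency sinusoids with random phase/frequency
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    bg = np.full((H, W), BACKGROUND_VALUE)
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.02, 0.05)
        bg += amp * np.sin(2 * np.pi * (fx * xx / W + fy * yy / H) + phase)
    return bg


def generate_fin(spec: FinSpec) -> FinSample:
    """Render one labeled fin sample; bitwise deterministic in the spec.

    The ground-truth contour is the outline of the noise-free silhouette
    (fin plus back ridge), one pixel wide.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _render_mask(spec)
    bg = _background(spec, rng)
    dome = ndimage.distance_transform_edt(mask)
    dome = dome / max(dome.max(), 1.0)
    img = np.where(mask, FIN_VALUE + SHADING_AMPLITUDE * dome, bg)
    contour = mask & ~ndimage.binary_erosion(mask, np.ones((3, 3), dtype=bool))
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if _is_left(spec.label):
        img = np.fliplr(img)
        contour = np.fliplr(contour)
    img = np.clip(img, 0.0, 1.0)
    return FinSample(
        image=GrayImage(img),
        contour_truth=ContourMask(contour.copy()),
        label=spec.label,
        spec=spec,
    )


def sample_spec(
    label: str,
    seed: int,
    noise_sigma: float = 0.02,
    jitter: bool = True,
    height_px: int = 160,
    width_px: int = 160,
    background: str = "flat",
) -> FinSpec:
    """Draw one FinSpec, jittering shape and pose within class bounds.

    Jitter draws tip_curl and base width uniformly from their class bands,
    rotation from [-15, 15] degrees, and scale from [0.8, 1.25].
    """
    rng = np.random.default_rng(seed)
    curl_band = CURL_BANDS[_family(label)]
    bw_band = BASE_WIDTH_BANDS[_family(label)]
    if jitter:
        tip_curl = float(rng.uniform(*curl_band))
        base_width = float(rng.uniform(*bw_band))
        rotation = float(rng.uniform(-15.0, 15.0))
        scale = float(rng.uniform(0.8, 1.25))
    else:
        tip_curl = None
        base_width = 0.5 * (bw_band[0] + bw_band[1])
        rotation, scale = 0.0, 1.0
    return FinSpec(
        label=label,
        height_px=height_px,
        width_px=width_px,
        tip_curl=tip_curl,
        base_width_frac=base_width,
        rotation_deg=rotation,
        scale=scale,
        noise_sigma=noise_sigma,
        background=background,
        seed=seed,
    )


def generate_dataset(
    n_per_class: int = 20,
    base_seed: int = 0,
    noise_sigma: float = 0.02,
    jitter: bool = True,
    height_px: int = 160,
    width_px: int = 160,
    background: str = "flat",
) -> list[FinSample]:
    """6 * n_per_class labeled samples; per-sample seed = base_seed*10000 + index."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    samples = []
    index = 0
    for label in CLASS_LABELS:
        for _ in range(n_per_class):
            seed = base_seed * 10000 + index
            spec = sample_spec(
                label, seed, noise_sigma, jitter, height_px, width_px, background
            )
            samples.append(generate_fin(spec))
            index += 1
    return samples


def stratified_split(
    samples: list[FinSample], train_frac: float = 0.5, seed: int = 0
) -> tuple[list[FinSample], list[FinSample]]:
    """Per-class shuffle-and-split; class train/test counts differ by <= 1."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in CLASS_LABELS:
        group = [s for s in samples if s.label == label]
        order = rng.permutation(len(group))
        n_train = int(round(len(group) * train_frac))
        for i, idx in enumerate(order):
            (train if i < n_train else test).append(group[idx])
    return train, test


def mirrored_sample(sample: FinSample) -> FinSample:
    """Horizontally flip a sample and its ground truth, swapping the flank label."""
    return FinSample(
        image=GrayImage(np.fliplr(sample.image.pixels).copy()),
        contour_truth=ContourMask(np.fliplr(sample.contour_truth.mask).copy()),
        label=mirror_label(sample.label),
        spec=replace(sample.spec, label=mirror_label(sample.spec.label)),
    )
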