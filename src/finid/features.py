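"""Interest-point detection, localization, orientation and description.

Keypoints are local extrema of the (reduced) DoG stack: a sample survives
only if the scale-pruning mask retained it and it is strictly larger or
strictly smaller than all 26 neighbors in its 3x3x3 scale-space
neighborhood.  Surviving candidates are refined to sub-pixel/sub-scale
position by fitting a 3-D quadratic to the DoG values (z_hat = -H^-1 grad D)
and rejected when the refined contrast is low.  Each keypoint receives one
or more dominant gradient orientations from a magnitude-weighted histogram,
and each oriented keypoint a 128-vector descriptor: gradient magnitudes in a
rotated 16x16 sampling window accumulated into 4x4 spatial cells x 8
orientation bins with trilinear interpolation, Gaussian-weighted, normalized,
clamped at 0.2 and renormalized for illumination robustness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import RunConfig, DEFAULT_CONFIG
from .imaging import ContourMask, GrayImage
from .scale_space import (
    DoGStack,
    ReducedDoG,
    build_scale_stack,
    dog_differences,
    dog_threshold,
    reduce_scales,
)

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Keypoint:
    """A scale-space interest point; coordinates are sub-pixel after refinement.

    ``level`` indexes the DoG layer the point was detected on; ``offset`` is
    the quadratic-fit correction (x, y, scale) and ``contrast`` the absolute
    interpolated DoG value used for low-contrast rejection.
    """

    x: float
    y: float
    level: int
    sigma: float
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast: float = 0.0
    orientations: tuple[float, ...] = ()

    def with_orientation(self, angle: float) -> "Keypoint":
        return dataclasses.replace(self, orientations=(float(angle) % TWO_PI,))


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient magnitude and orientation of one Gaussian level.

    Central differences without the 1/2 factor (M = 2 on a unit ramp),
    replicate padding at borders; orientation is atan2(dy, dx) in (-pi, pi],
    zero where both differences vanish.
    """

    magnitude: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.orientation.shape:
            raise ValueError("magnitude/orientation shape mismatch")


@dataclass(frozen=True)
class Descriptor:
    """128-element gradient-histogram vector (4x4 cells x 8 bins), L2 norm 1."""

    values: np.ndarray
    keypoint: Keypoint
    sigma_g: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (128,):
            raise ValueError(f"descriptor must have length 128, got {v.shape}")
        object.__setattr__(self, "values", v)


def detect_extrema(reduced: ReducedDoG, edge_exclusion: int = 4) -> list[Keypoint]:
    """Strict 26-neighbor extrema of retained DoG samples on interior levels.

    Candidates within ``edge_exclusion`` pixels of the raster border (always
    at least 1, for neighborhood validity) are excluded.  Returned in
    deterministic (level, y, x) order.
    """
    D = reduced.diffs
    if reduced.n < 3:
        raise ValueError("extremum detection needs at least 3 DoG levels")
    fp = np.ones((3, 3, 3), dtype=bool)
    fp[1, 1, 1] = False
    nb_max = ndimage.maximum_filter(D, footprint=fp, mode="constant", cval=-np.inf)
    nb_min = ndimage.minimum_filter(D, footprint=fp, mode="constant", cval=np.inf)
    cand = ((D > nb_max) | (D < nb_min)) & reduced.retained
    cand[0] = cand[-1] = False
    margin = max(1, int(edge_exclusion))
    keep = np.zeros_like(cand)
    if D.shape[1] > 2 * margin and D.shape[2] > 2 * margin:
        keep[:, margin:-margin, margin:-margin] = True
    cand &= keep
    out = []
    for m, y, x in zip(*np.nonzero(cand)):
        out.append(
            Keypoint(
                x=float(x),
                y=float(y),
                level=int(m),
                sigma=float(reduced.sigmas[m]),
                contrast=float(abs(D[m, y, x])),
            )
        )
    return out


def _scale_space_derivatives(D: np.ndarray, m: int, y: int, x: int):
    """Finite-difference gradient and Hessian of the DoG stack at a sample.

    Component order is (x, y, scale).  First derivatives use half central
    differences; the Hessian uses the standard second-difference stencils.
    """
    g = np.array(
        [
            (D[m, y, x + 1] - D[m, y, x - 1]) / 2.0,
            (D[m, y + 1, x] - D[m, y - 1, x]) / 2.0,
            (D[m + 1, y, x] - D[m - 1, y, x]) / 2.0,
        ]
    )
    dxx = D[m, y, x + 1] - 2.0 * D[m, y, x] + D[m, y, x - 1]
    dyy = D[m, y + 1, x] - 2.0 * D[m, y, x] + D[m, y - 1, x]
    dss = D[m + 1, y, x] - 2.0 * D[m, y, x] + D[m - 1, y, x]
    dxy = (
        D[m, y + 1, x + 1] - D[m, y + 1, x - 1] - D[m, y - 1, x + 1] + D[m, y - 1, x - 1]
    ) / 4.0
    dxs = (
        D[m + 1, y, x + 1] - D[m + 1, y, x - 1] - D[m - 1, y, x + 1] + D[m - 1, y, x - 1]
    ) / 4.0
    dys = (
        D[m + 1, y + 1, x] - D[m + 1, y - 1, x] - D[m - 1, y + 1, x] + D[m - 1, y - 1, x]
    ) / 4.0
    H = np.array([[dxx, dxy, dxs], [dxy, dyy, dys], [dxs, dys, dss]])
    return g, H


def localize_keypoint(
    dog: DoGStack,
    candidate: Keypoint,
    contrast_threshold: float = 0.03,
    max_iter: int = 5,
    edge_response_threshold: float = 0.0,
) -> Keypoint | None:
    """Refine a candidate to sub-pixel position by quadratic interpolation.

    Solves z_hat = -H^-1 grad(D) in (x, y, scale); when any offset component
    exceeds 0.5 the candidate moves to the neighboring sample and the fit
    repeats, up to ``max_iter`` times.  A pseudo-inverse handles rank-deficient
    Hessians (flat directions get zero offset); genuinely inconsistent systems
    are rejected.  Rejections (returned as None): no convergence, out of
    bounds, refined contrast |D(z_hat)| below ``contrast_threshold``, or —
    when ``edge_response_threshold`` r > 0 — an edge-like spatial Hessian with
    trace^2/det above (r+1)^2/r.
    """
    D = dog.diffs
    n, H_img, W_img = D.shape
    m, y, x = candidate.level, int(round(candidate.y)), int(round(candidate.x))
    for _ in range(max_iter):
        if not (1 <= m <= n - 2 and 1 <= y <= H_img - 2 and 1 <= x <= W_img - 2):
            return None
        g, H = _scale_space_derivatives(D, m, y, x)
        z = -np.linalg.pinv(H, rcond=1e-10) @ g
        if np.linalg.norm(H @ z + g) > 1e-6 * max(1.0, np.linalg.norm(g)):
            return None  # inconsistent (degenerate but non-flat) system
        if np.all(np.abs(z) <= 0.5):
            value = D[m, y, x] + 0.5 * float(g @ z)
            if abs(value) < contrast_threshold:
                return None
            if edge_response_threshold > 0:
                r = edge_response_threshold
                tr = H[0, 0] + H[1, 1]
                det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
                if det <= 0 or tr * tr / det >= (r + 1.0) ** 2 / r:
                    return None
            new_x, new_y = x + z[0], y + z[1]
            if not (0 <= new_x < W_img and 0 <= new_y < H_img):
                return None
            sigma = float(dog.sigmas[m] * dog.k ** z[2])
            return dataclasses.replace(
                candidate,
                x=float(new_x),
                y=float(new_y),
                level=m,
                sigma=sigma,
                offset=(float(z[0]), float(z[1]), float(z[2])),
                contrast=abs(value),
            )
        x += int(round(np.clip(z[0], -1, 1))) if abs(z[0]) > 0.5 else 0
        y += int(round(np.clip(z[1], -1, 1))) if abs(z[1]) > 0.5 else 0
        m += int(round(np.clip(z[2], -1, 1))) if abs(z[2]) > 0.5 else 0
    return None


def gradient_field(level: np.ndarray) -> GradientField:
    """Central-difference gradients of one Gaussian level (no 1/2 factor)."""
    level = np.asarray(level, dtype=np.float64)
    if level.ndim != 2 or min(level.shape) < 3:
        raise ValueError("gradient field needs a raster of at least 3x3")
    padded = np.pad(level, 1, mode="edge")
    dx = padded[1:-1, 2:] - padded[1:-1, :-2]
    dy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.sqrt(dx * dx + dy * dy)
    orientation = np.arctan2(dy, dx)
    return GradientField(magnitude=magnitude, orientation=orientation)


def assign_orientations(
    kp: Keypoint,
    fld: GradientField,
    n_bins: int = 36,
    window_sigma_factor: float = 1.5,
    peak_mode: str = "peak80",
) -> list[Keypoint]:
    """Dominant gradient directions from a weighted orientation histogram.

    Gradient angles in a radius ceil(3*sigma_w) window (sigma_w =
    window_sigma_factor * kp.sigma) are histogrammed into ``n_bins`` bins over
    [0, 2pi), weighted by magnitude times a Gaussian in distance from the
    keypoint.  ``peak80``: every bin reaching 80% of the histogram maximum
    spawns one oriented copy of the keypoint at its bin center.
    ``literal_mean``: bins whose mass reaches 0.8 times the plain window mean
    of the angle values spawn copies (a dimensionally odd rule, kept as an
    alternative reading of the 80% criterion).  A window with no gradient
    signal drops the keypoint (empty list).
    """
    H, W = fld.magnitude.shape
    sigma_w = window_sigma_factor * kp.sigma
    radius = int(np.ceil(3.0 * sigma_w))
    cx, cy = int(round(kp.x)), int(round(kp.y))
    if cx + radius < 0 or cx - radius >= W or cy + radius < 0 or cy - radius >= H:
        return []
    x0, x1 = max(0, cx - radius), min(W, cx + radius + 1)
    y0, y1 = max(0, cy - radius), min(H, cy + radius + 1)
    mag = fld.magnitude[y0:y1, x0:x1]
    ang = np.mod(fld.orientation[y0:y1, x0:x1], TWO_PI)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    w = np.exp(-((xx - kp.x) ** 2 + (yy - kp.y) ** 2) / (2.0 * sigma_w**2))
    weights = mag * w
    bins = np.minimum((ang / TWO_PI * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(bins.ravel(), weights=weights.ravel(), minlength=n_bins)
    if hist.max() <= 0:
        return []
    if peak_mode == "peak80":
        thr = 0.8 * hist.max()
    elif peak_mode == "literal_mean":
        thr = 0.8 * float(ang[mag > 0].mean()) if (mag > 0).any() else np.inf
    else:
        raise ValueError(f"unknown peak mode: {peak_mode!r}")
    centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
    selected = np.nonzero(hist >= thr)[0]
    if selected.size == 0:
        return []
    return [kp.with_orientation(centers[b]) for b in selected]


def _bilinear(raster: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sampling; positions outside the raster contribute zero."""
    H, W = raster.shape
    valid = (xs >= 0) & (xs <= W - 1) & (ys >= 0) & (ys <= H - 1)
    xs_c = np.clip(xs, 0, W - 1.000001)
    ys_c = np.clip(ys, 0, H - 1.000001)
    x0 = np.floor(xs_c).astype(int)
    y0 = np.floor(ys_c).astype(int)
    fx, fy = xs_c - x0, ys_c - y0
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    val = (
        raster[y0, x0] * (1 - fx) * (1 - fy)
        + raster[y0, x1] * fx * (1 - fy)
        + raster[y1, x0] * (1 - fx) * fy
        + raster[y1, x1] * fx * fy
    )
    return np.where(valid, val, 0.0)


def compute_descriptor(
    kp: Keypoint,
    fld: GradientField,
    sigma_g_mode: str = "half_window",
) -> Descriptor | None:
    """128-vector gradient histogram around an oriented keypoint.

    A 16x16 sample grid with spacing equal to kp.sigma is rotated into the
    keypoint frame; gradient magnitudes (bilinearly interpolated) are
    accumulated into 4x4 spatial cells x 8 orientation bins with trilinear
    interpolation, after subtracting the keypoint orientation from each
    gradient angle.  Samples are weighted by a Gaussian of sigma_G = half the
    window width (``half_window``, default) or half the keypoint scale
    (``half_scale``).  The vector is L2-normalized, clamped at 0.2 and
    renormalized; a window with no gradient signal is rejected (None).
    """
    if len(kp.orientations) != 1:
        raise ValueError("compute_descriptor expects exactly one orientation")
    theta = kp.orientations[0]
    n_cells, n_ori, n_samples = 4, 8, 16
    spacing = max(kp.sigma, 1e-6)
    window_width = n_samples * spacing
    if sigma_g_mode == "half_window":
        sigma_g = 0.5 * window_width
    elif sigma_g_mode == "half_scale":
        sigma_g = 0.5 * kp.sigma
    else:
        raise ValueError(f"unknown sigma_g mode: {sigma_g_mode!r}")

    # descriptor-frame sample offsets, in units of pixels
    grid = (np.arange(n_samples) - (n_samples - 1) / 2.0) * spacing
    u, v = np.meshgrid(grid, grid)  # u: along orientation, v: perpendicular
    u, v = u.ravel(), v.ravel()
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    xs = kp.x + u * cos_t - v * sin_t
    ys = kp.y + u * sin_t + v * cos_t

    dx = _bilinear(fld.magnitude * np.cos(fld.orientation), ys, xs)
    dy = _bilinear(fld.magnitude * np.sin(fld.orientation), ys, xs)
    mag = np.sqrt(dx * dx + dy * dy)
    rel_ang = np.mod(np.arctan2(dy, dx) - theta, TWO_PI)
    weight = np.exp(-(u * u + v * v) / (2.0 * sigma_g**2))
    contrib = mag * weight

    cell_width = window_width / n_cells
    rbin = v / cell_width + (n_cells - 1) / 2.0
    cbin = u / cell_width + (n_cells - 1) / 2.0
    obin = rel_ang / (TWO_PI / n_ori)

    hist = np.zeros((n_cells, n_cells, n_ori))
    r0 = np.floor(rbin).astype(int)
    c0 = np.floor(cbin).astype(int)
    o0 = np.floor(obin).astype(int)
    fr, fc, fo = rbin - r0, cbin - c0, obin - o0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        rr = r0 + dr
        ok_r = (rr >= 0) & (rr < n_cells)
        for dc, wc in ((0, 1 - fc), (1, fc)):
            cc = c0 + dc
            ok_c = (cc >= 0) & (cc < n_cells)
            for do, wo in ((0, 1 - fo), (1, fo)):
                oo = (o0 + do) % n_ori
                ok = ok_r & ok_c
                np.add.at(
                    hist,
                    (rr[ok], cc[ok], oo[ok]),
                    (contrib * wr * wc * wo)[ok],
                )
    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm <= 0:
        return None
    vec = np.minimum(vec / norm, 0.2)
    vec /= np.linalg.norm(vec)
    return Descriptor(values=vec, keypoint=kp, sigma_g=sigma_g)


def extract_features(
    image: GrayImage,
    config: RunConfig = DEFAULT_CONFIG,
    contour: ContourMask | None = None,
) -> list[Descriptor]:
    """Full pipeline: scale stack -> DoG -> threshold -> reduce -> extrema ->
    localize -> orient -> describe.

    Deterministic: descriptors are ordered by (level, y, x, orientation).
    When a contour mask is supplied (segmentation enabled), gradient
    magnitudes outside the mask are zeroed before orientation and descriptor
    computation, focusing features on the fin edge.
    """
    ss, fc = config.scale_space, config.features
    stack = build_scale_stack(image, ss.sigma0, ss.k, ss.n_levels)
    dog = dog_differences(stack)
    thr = dog_threshold(dog, pooling=ss.pooling)
    reduced = reduce_scales(dog, thr, mode=ss.reduce_mode)
    candidates = detect_extrema(reduced, edge_exclusion=fc.edge_exclusion)

    fields: dict[int, GradientField] = {}

    def field_for(level: int) -> GradientField:
        if level not in fields:
            fld = gradient_field(stack.levels[level])
            if contour is not None:
                keep = contour.mask.astype(np.float64)
                fld = GradientField(
                    magnitude=fld.magnitude * keep, orientation=fld.orientation
                )
            fields[level] = fld
        return fields[level]

    descriptors = []
    for cand in candidates:
        kp = localize_keypoint(
            dog,
            cand,
            contrast_threshold=fc.contrast_threshold,
            max_iter=fc.max_iter,
            edge_response_threshold=fc.edge_response_threshold,
        )
        if kp is None:
            continue
        # gradients from the Gaussian level nearest the refined scale
        lvl = int(np.clip(round(np.log(kp.sigma / stack.sigma0) / np.log(stack.k)),
                          0, len(stack.levels) - 1))
        fld = field_for(lvl)
        for oriented in assign_orientations(
            kp, fld, fc.n_bins, fc.window_sigma_factor, fc.peak_mode
        ):
            desc = compute_descriptor(oriented, fld, fc.sigma_g_mode)
            if desc is not None:
                descriptors.append(desc)
    descriptors.sort(
        key=lambda d: (d.keypoint.level, d.keypoint.y, d.keypoint.x,
                       d.keypoint.orientations[0])
    )
    return descriptors


DESCRIPTOR_FORMAT_VERSION = 1


def save_descriptors(
    descriptors: list[Descriptor], path: str | Path, config_hash: str = ""
) -> None:
    """Write descriptors as versioned JSON with extraction provenance."""
    payload = {
        "version": DESCRIPTOR_FORMAT_VERSION,
        "config_hash": config_hash,
        "descriptors": [
            {
                "x": d.keypoint.x,
                "y": d.keypoint.y,
                "level": d.keypoint.level,
                "sigma": d.keypoint.sigma,
                "orientation": d.keypoint.orientations[0],
                "values": d.values.tolist(),
            }
            for d in descriptors
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_descriptors(path: str | Path) -> tuple[list[Descriptor], str]:
    """Load a descriptor JSON file; returns (descriptors, config_hash)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != DESCRIPTOR_FORMAT_VERSION:
        raise ValueError(f"unsupported descriptor version: {payload.get('version')}")
    out = []
    for rec in payload["descriptors"]:
        kp = Keypoint(
            x=rec["x"], y=rec["y"], level=rec["level"], sigma=rec["sigma"],
            orientations=(rec["orientation"],),
        )
        out.append(Descriptor(values=np.asarray(rec["values"]), keypoint=kp,
                              sigma_g=0.0))
    return out, payload.get("config_hash", "")
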