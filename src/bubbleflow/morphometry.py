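"""Microbubble counting and sizing in brightfield micrographs, and
conversion of per-FOV counts to suspension concentration.

Detection pipeline: flatten the background (large-scale Gaussian),
invert so the dark bubble rims become positive "darkness", smooth at the
expected bubble radius so each ring collapses into a single centred
blob, seed candidates at local maxima above a robust noise threshold,
refine each centre by the darkness centroid, and size each object by the
minimum of its angularly averaged radial intensity profile with
parabolic sub-step interpolation.  The profile minimum sits exactly at
the rim radius for a radially symmetric rim, so the diameter estimate is
subpixel and unbiased.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .containers import BubbleDetections, ChamberGeometry, SizeDistribution
from .errors import InvalidConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "BubbleDetector",
    "detect_bubbles",
    "size_distribution",
    "estimate_concentration",
    "match_detections",
]


class BubbleDetector(BaseEstimator):
    """Detect and size dark-rimmed microbubbles in a grayscale micrograph.

    Parameters
    ----------
    pixel_scale : float
        Micrometres per pixel.
    min_diameter, max_diameter : float
        Acceptance band in micrometres; objects sized outside it are
        discarded.
    background_sigma : float
        Gaussian scale (pixels) of the background-flattening filter.
    threshold_k : float
        Seed threshold in robust (MAD-based) noise standard deviations of
        the smoothed darkness response.
    hough : bool
        Cross-check mode: size objects by a circular Hough transform
        instead of the radial-profile fit.
    """

    def __init__(self, pixel_scale: float, min_diameter: float = 0.5,
                 max_diameter: float = 8.0, background_sigma: float = 50.0,
                 threshold_k: float = 6.0, hough: bool = False):
        self.pixel_scale = pixel_scale
        self.min_diameter = min_diameter
        self.max_diameter = max_diameter
        self.background_sigma = background_sigma
        self.threshold_k = threshold_k
        self.hough = hough

    # -- internals ---------------------------------------------------------
    def _radial_profile_diameter(self, darkness: np.ndarray, center: tuple[float, float],
                                 r_max: float) -> float | None:
        """Rim radius from the angularly averaged darkness profile (px)."""
        from scipy.ndimage import map_coordinates

        radii = np.arange(0.5, r_max, 0.25)
        angles = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
        rr = center[0] + radii[:, None] * np.sin(angles)[None, :]
        cc = center[1] + radii[:, None] * np.cos(angles)[None, :]
        prof = map_coordinates(darkness, [rr.ravel(), cc.ravel()], order=1,
                               mode="nearest").reshape(radii.size, angles.size)
        profile = prof.mean(axis=1)
        i = int(np.argmax(profile))  # darkness peaks at the rim
        if profile[i] <= 0:
            return None
        if 0 < i < radii.size - 1:
            y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        return float(radii[i] + shift * 0.25)

    def _hough_diameter(self, darkness: np.ndarray, center: tuple[float, float],
                        r_max: float) -> float | None:
        from skimage.transform import hough_circle

        r0 = int(max(2, round(self.min_diameter / 2 / self.pixel_scale)))
        r1 = int(max(r0 + 1, round(r_max)))
        half = r1 + 2
        r_c, c_c = int(round(center[0])), int(round(center[1]))
        win = darkness[max(0, r_c - half): r_c + half + 1,
                       max(0, c_c - half): c_c + half + 1]
        radii = np.arange(r0, r1 + 1)
        acc = hough_circle(win > 0.5 * win.max(), radii)
        best = np.unravel_index(np.argmax(acc), acc.shape)
        return float(radii[best[0]])

    # -- main entry --------------------------------------------------------
    def detect(self, image: np.ndarray, fov_id: str = "") -> BubbleDetections:
        """Run the detector on one field of view."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise InvalidInputError("micrograph must be a 2-D grayscale image")

        # background flattening and inversion: bubbles are darker than bg
        background = ndimage.gaussian_filter(image, self.background_sigma)
        darkness = np.clip(background - image, 0.0, None)
        smooth = ndimage.gaussian_filter(darkness, 1.0)

        # robust noise threshold: the rims are a tiny area fraction, so
        # median/MAD of the smoothed darkness estimate the background
        med = float(np.median(smooth))
        mad = float(np.median(np.abs(smooth - med)))
        thr = med + self.threshold_k * 1.4826 * max(mad, 1e-12)

        binary = ndimage.binary_fill_holes(smooth > thr)
        min_r_px = 0.5 * self.min_diameter / self.pixel_scale
        min_area = max(4, int(np.pi * min_r_px**2 * 0.25))
        labels, _ = ndimage.label(binary)

        from skimage.measure import regionprops

        centers: list[tuple[float, float]] = []
        diameters: list[float] = []
        for region in regionprops(labels):
            if region.area < min_area:
                continue
            for mask, bbox in self._split_region(region, min_r_px):
                res = self._measure(darkness, mask, bbox)
                if res is None:
                    continue
                center, radius_px = res
                diameter_um = 2.0 * radius_px * self.pixel_scale
                if not self.min_diameter <= diameter_um <= self.max_diameter:
                    continue
                centers.append(center)
                diameters.append(diameter_um)

        return BubbleDetections(
            centers=np.array(centers, dtype=float).reshape(-1, 2),
            diameters=np.array(diameters, dtype=float),
            fov_id=fov_id,
            image_shape=image.shape,
        )

    def _split_region(self, region, min_r_px: float):
        """Yield (mask, bbox) per object; watershed-split merged rims.

        A single filled rim is convex, so a low solidity flags touching
        bubbles; these are split on the distance transform.  Residual
        failures stay single objects (logged upstream by their size).
        """
        bbox = region.bbox
        mask = region.image
        if region.solidity >= 0.9:
            yield mask, bbox
            return
        from skimage.feature import peak_local_max
        from skimage.segmentation import watershed

        dist = ndimage.distance_transform_edt(mask)
        peaks = peak_local_max(dist, min_distance=max(2, int(min_r_px)),
                               labels=mask)
        if len(peaks) < 2:
            logger.info("unsplittable merged region of %d px kept as one",
                        region.area)
            yield mask, bbox
            return
        markers = np.zeros(mask.shape, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = watershed(-dist, markers, mask=mask)
        for lab in range(1, len(peaks) + 1):
            yield ws == lab, bbox

    def _measure(self, darkness: np.ndarray, mask: np.ndarray,
                 bbox) -> tuple[tuple[float, float], float] | None:
        """Darkness-weighted centroid and rim radius of one object."""
        r0, c0 = bbox[0], bbox[1]
        yy, xx = np.nonzero(mask)
        win = darkness[yy + r0, xx + c0]
        total = win.sum()
        if total <= 0:
            return None
        center = (float(((yy + r0) * win).sum() / total),
                  float(((xx + c0) * win).sum() / total))
        half_extent = 0.5 * max(mask.shape)
        r_max = half_extent + 3.0
        if self.hough:
            radius = self._hough_diameter(darkness, center, r_max)
        else:
            radius = self._radial_profile_diameter(darkness, center, r_max)
        if radius is None:
            return None
        return center, radius


def detect_bubbles(image: np.ndarray, pixel_scale: float,
                   min_diameter: float = 0.5, max_diameter: float = 8.0,
                   **kwargs) -> BubbleDetections:
    """Functional wrapper around :class:`BubbleDetector`."""
    if not pixel_scale > 0:
        raise InvalidConfigurationError("pixel_scale must be > 0")
    return BubbleDetector(pixel_scale, min_diameter, max_diameter,
                          **kwargs).detect(image)


def size_distribution(detections: list[BubbleDetections] | BubbleDetections,
                      bin_width: float = 0.25,
                      max_size: float = 10.0) -> SizeDistribution:
    """Pool detections across FOVs into size statistics and a histogram.

    The pooled mean and SD are computed over all detected diameters, so
    the result is invariant to the ordering of the FOVs.
    """
    if isinstance(detections, BubbleDetections):
        detections = [detections]
    diam = np.concatenate([d.diameters for d in detections]) if detections else np.array([])
    if diam.size == 0:
        raise InvalidInputError("no detections to summarise")
    edges = np.arange(0.0, max_size + bin_width / 2, bin_width)
    counts, _ = np.histogram(diam, bins=edges)
    # objects beyond the last edge are appended to the final bin so the
    # histogram always accounts for every detection
    counts[-1] += int(np.sum(diam >= edges[-1]))
    return SizeDistribution(
        n=int(diam.size),
        mean_diameter=float(diam.mean()),
        sd_diameter=float(diam.std(ddof=0)),
        bin_edges=edges,
        counts=counts,
    )


def estimate_concentration(counts_per_fov: list[int] | np.ndarray,
                           geometry: ChamberGeometry) -> float:
    """Suspension concentration in MB/ml from per-FOV counts.

    ``mean(count) / (fov_area * depth)`` converts the per-field count to
    a number density in the counting chamber (1 mm^3 = 1e-3 ml), then the
    dilution factor maps it back to the undiluted suspension.
    """
    counts = np.asarray(counts_per_fov, dtype=float)
    if counts.size == 0:
        raise InvalidInputError("need at least one FOV count")
    if counts.size < 10:
        logger.warning("concentration estimated from fewer than 10 FOVs")
    volume_ml = geometry.fov_area_mm2 * geometry.chamber_depth_mm * 1e-3
    return float(counts.mean() / volume_ml * geometry.dilution_factor)


def match_detections(detected: BubbleDetections, truth: BubbleDetections,
                     max_dist_px: float = 3.0) -> tuple[int, int, int, np.ndarray]:
    """Greedy one-to-one matching of detections against ground truth.

    Returns ``(n_matched, n_false_pos, n_missed, diameter_errors_um)``
    where errors are signed (detected - true) over matched pairs.
    Intended for validation against the synthetic generator's truth.
    """
    if detected.n == 0:
        return 0, 0, truth.n, np.array([])
    if truth.n == 0:
        return 0, detected.n, 0, np.array([])
    d2 = np.linalg.norm(
        detected.centers[:, None, :] - truth.centers[None, :, :], axis=2
    )
    pairs = []
    used_d: set[int] = set()
    used_t: set[int] = set()
    order = np.argsort(d2, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, d2.shape)
        if d2[i, j] > max_dist_px:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(int(i))
        used_t.add(int(j))
        pairs.append((int(i), int(j)))
    errors = np.array([
        detected.diameters[i] - truth.diameters[j] for i, j in pairs
    ])
    return len(pairs), detected.n - len(pairs), truth.n - len(pairs), errors
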