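"""Seeded synthetic-data generators for every stage of the pipeline.

Three families of inputs are emulated, each with exact ground truth
returned alongside:

* bolus **time-intensity curves** following a gamma-variate, optionally
  augmented with a bound-microbubble retention pool (targeted agents);
* paired **sub-aperture CEUS frame stacks** — a high-amplitude low-rank
  tissue-clutter background shared by both apertures, a common
  flow-speckle signal on a vessel mask modulated by the bolus envelope,
  and aperture-independent electronic noise;
* brightfield **micrographs** of microbubble suspensions rendered as
  dark-rimmed disks at subpixel positions.

All randomness flows through one ``numpy.random.Generator`` per call,
seeded from the config, so equal configs produce bitwise-equal outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .containers import BubbleDetections, FrameStack, TimeIntensityCurve
from .errors import InvalidConfigurationError
from .kinetics import gamma_variate

logger = logging.getLogger(__name__)

__all__ = [
    "BolusParams",
    "RetentionParams",
    "SceneConfig",
    "MicrographConfig",
    "gamma_variate_curve",
    "generate_tic",
    "generate_retention_tic",
    "generate_ceus_scene",
    "make_vessel_mask",
    "generate_micrograph",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class BolusParams:
    """Ground-truth parameters of a gamma-variate bolus transit.

    The noiseless curve is ``I(t) = A (t-t0)^alpha exp(-(t-t0)/beta)`` for
    ``t > t0`` and zero before arrival.  ``noise_sd`` is the additive
    Gaussian noise standard deviation expressed as a fraction of the peak
    intensity.
    """

    A: float = 1.0
    alpha: float = 2.0
    beta: float = 5.0
    t0: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.alpha > 0 and self.beta > 0):
            raise InvalidConfigurationError("A, alpha, beta must be > 0")
        if self.t0 < 0:
            raise InvalidConfigurationError("t0 must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigurationError("noise_sd must be >= 0")

    @property
    def time_to_peak(self) -> float:
        """Time of the noiseless maximum, measured from injection."""
        return self.t0 + self.alpha * self.beta

    @property
    def peak_intensity(self) -> float:
        ab = self.alpha * self.beta
        return self.A * ab**self.alpha * np.exp(-self.alpha)


@dataclass
class RetentionParams:
    """Bound-pool model for targeted microbubbles adhering to endothelium.

    A fraction ``bound_fraction`` of the peak signal accumulates during
    wash-in (linear ramp) and then decays exponentially with time constant
    ``decay_tau`` — a minimal two-compartment extension that lengthens the
    half-area transit time relative to the free bolus.
    """

    bound_fraction: float = 0.2
    decay_tau: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.bound_fraction <= 1:
            raise InvalidConfigurationError("bound_fraction must be in [0, 1]")
        if not self.decay_tau > 0:
            raise InvalidConfigurationError("decay_tau must be > 0")


@dataclass
class SceneConfig:
    """Geometry, amplitudes and kinetics of a paired sub-aperture acquisition.

    Defaults emulate a 2 Hz, 180 s bolus acquisition on a 64x64 grid with
    a 40 dB clutter-to-flow amplitude ratio (100:1).
    """

    grid_shape: tuple[int, int] = (64, 64)
    frame_rate: float = 2.0
    duration: float = 180.0
    vessel_mask: np.ndarray | None = None  # default: make_vessel_mask(seed)
    clutter_amplitude: float = 100.0
    clutter_rank: int = 2
    flow_amplitude: float = 1.0
    flow_decorrelation: float = 0.6
    noise_sd: float = 0.075
    bolus: BolusParams = field(default_factory=lambda: BolusParams(t0=10.0))
    retention: RetentionParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frame_rate > 0 and self.duration > 0):
            raise InvalidConfigurationError("frame_rate and duration must be > 0")
        if self.n_frames < 2:
            raise InvalidConfigurationError("scene needs at least 2 frames")
        if self.clutter_rank < 1:
            raise InvalidConfigurationError("clutter_rank must be >= 1")
        if self.clutter_rank >= self.n_frames:
            raise InvalidConfigurationError("clutter_rank must be < frame count")
        if not 0 < self.flow_decorrelation < 1:
            raise InvalidConfigurationError("flow_decorrelation must be in (0, 1)")
        if self.noise_sd < 0 or self.clutter_amplitude < 0 or self.flow_amplitude < 0:
            raise InvalidConfigurationError("amplitudes must be >= 0")
        if self.vessel_mask is not None:
            self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
            if self.vessel_mask.shape != tuple(self.grid_shape):
                raise InvalidConfigurationError(
                    f"vessel_mask shape {self.vessel_mask.shape} != grid {self.grid_shape}"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


@dataclass
class MicrographConfig:
    """Rendering parameters for a synthetic haemocytometer field of view.

    Bubbles are drawn as dark Gaussian rings of radius ``diameter/2`` on a
    bright background, matching their brightfield appearance.  Defaults
    mimic a 40x objective (0.16 um/pixel) field.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_scale: float = 0.16  # um per pixel
    n_bubbles: int = 40
    diameter_mean: float = 2.0  # um
    diameter_sd: float = 0.4  # um
    ring_contrast: float = 0.35  # fractional intensity drop at the rim
    rim_width: float = 0.3  # um, Gaussian sigma of the rim profile
    background_level: float = 1000.0
    background_noise_sd: float = 20.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bubbles < 0:
            raise InvalidConfigurationError("n_bubbles must be >= 0")
        if not (self.pixel_scale > 0 and self.diameter_mean > 0):
            raise InvalidConfigurationError("pixel_scale and diameter_mean must be > 0")
        if self.diameter_sd < 0 or self.background_noise_sd < 0:
            raise InvalidConfigurationError("standard deviations must be >= 0")
        if not 0 < self.ring_contrast < 1:
            raise InvalidConfigurationError("ring_contrast must be in (0, 1)")


# ---------------------------------------------------------------------------
# time-intensity curves
# ---------------------------------------------------------------------------

# canonical model implementation lives in kinetics; re-exported here since
# the generator is its inverse (sample the model, add noise)
gamma_variate_curve = gamma_variate


def _time_grid(frame_rate: float, duration: float) -> np.ndarray:
    if not (frame_rate > 0 and duration > 0):
        raise InvalidConfigurationError("frame_rate and duration must be > 0")
    n = int(round(frame_rate * duration))
    if n < 2:
        raise InvalidConfigurationError("duration too short for the frame rate")
    return np.arange(n) / frame_rate


def generate_tic(params: BolusParams, frame_rate: float = 2.0,
                 duration: float = 180.0) -> tuple[TimeIntensityCurve, np.ndarray]:
    """Sample a noisy bolus TIC plus its noiseless ground truth.

    Returns
    -------
    tic : TimeIntensityCurve
        Noisy samples at ``t_k = k / frame_rate``, clipped at zero.
    truth : ndarray
        The noiseless model curve on the same grid.
    """
    if duration <= params.t0:
        raise InvalidConfigurationError("duration must exceed the arrival time t0")
    t = _time_grid(frame_rate, duration)
    truth = gamma_variate_curve(t, params.A, params.alpha, params.beta, params.t0)
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd * params.peak_intensity, size=t.shape)
    noisy = np.clip(truth + noise, 0.0, None)
    return TimeIntensityCurve(t, noisy), truth


def _retention_truth(t: np.ndarray, params: BolusParams,
                     retention: RetentionParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless (total, free, bound) components of a targeted-agent TIC."""
    free = (1.0 - retention.bound_fraction) * gamma_variate_curve(
        t, params.A, params.alpha, params.beta, params.t0
    )
    tau = np.clip(t - params.t0, 0.0, None)
    wash_in = params.alpha * params.beta  # time from arrival to peak
    ramp = np.clip(tau / wash_in, 0.0, 1.0)
    decay = np.exp(-np.clip(tau - wash_in, 0.0, None) / retention.decay_tau)
    bound = retention.bound_fraction * params.peak_intensity * ramp * decay
    return free + bound, free, bound


def generate_retention_tic(
    params: BolusParams,
    retention: RetentionParams,
    frame_rate: float = 2.0,
    duration: float = 180.0,
) -> tuple[TimeIntensityCurve, dict[str, np.ndarray]]:
    """Sample a targeted-microbubble TIC: free bolus plus bound pool.

    The returned components dict holds the noiseless ``total``, ``free``
    and ``bound`` curves.  The composite always has a half-area transit
    time at least as long as the pure bolus with the same parameters.
    """
    if duration <= params.t0:
        raise InvalidConfigurationError("duration must exceed the arrival time t0")
    t = _time_grid(frame_rate, duration)
    total, free, bound = _retention_truth(t, params, retention)
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd * params.peak_intensity, size=t.shape)
    noisy = np.clip(total + noise, 0.0, None)
    components = {"total": total, "free": free, "bound": bound}
    return TimeIntensityCurve(t, noisy), components


# ---------------------------------------------------------------------------
# paired sub-aperture CEUS scenes
# ---------------------------------------------------------------------------

def make_vessel_mask(shape: tuple[int, int] = (64, 64), n_vessels: int = 4,
                     width: int = 2, seed: int = 0) -> np.ndarray:
    """Draw a reproducible binary mask of a few meandering vessels."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        r = float(rng.uniform(0.15, 0.85) * rows)
        c = float(rng.uniform(0.05, 0.2) * cols)
        drift = rng.uniform(-0.4, 0.4)
        while 0 <= int(r) < rows and c < cols:
            rr = int(round(r))
            cc = int(round(c))
            mask[max(0, rr - width // 2): rr + (width + 1) // 2,
                 max(0, cc - width // 2): cc + (width + 1) // 2] = True
            drift += rng.normal(0.0, 0.15)
            drift = float(np.clip(drift, -0.8, 0.8))
            r += drift
            c += 1.0
    return mask


def _smooth_complex_field(rng: np.random.Generator, shape: tuple[int, int],
                          corr_px: float = 6.0) -> np.ndarray:
    """Spatially-smooth unit-RMS complex field (tissue texture)."""
    from scipy.ndimage import gaussian_filter

    raw = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    sm = gaussian_filter(raw.real, corr_px) + 1j * gaussian_filter(raw.imag, corr_px)
    rms = np.sqrt(np.mean(np.abs(sm) ** 2))
    return sm / rms


def generate_ceus_scene(
    config: SceneConfig,
) -> tuple[FrameStack, FrameStack, dict]:
    """Simulate the two sub-aperture stacks of a CEUS bolus acquisition.

    Both stacks share (i) a tissue-clutter background built as a sum of
    ``clutter_rank`` outer products of smooth spatial patterns with slowly
    varying temporal envelopes — exactly low-rank by construction — and
    (ii) the flow signal: per-vessel-pixel AR(1) complex speckle scaled by
    the peak-normalised bolus (or retention) envelope times
    ``flow_amplitude``.  The stacks differ only in independent complex
    Gaussian noise of standard deviation ``noise_sd`` per real component.

    Returns ``(stack_a, stack_b, ground_truth)`` where ``ground_truth``
    holds the vessel mask, the envelope and the noiseless true TIC.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    t = np.arange(n) / config.frame_rate
    rows, cols = config.grid_shape

    mask = config.vessel_mask
    if mask is None:
        mask = make_vessel_mask(config.grid_shape, seed=config.seed)

    # --- bolus envelope (amplitude scale, peak-normalised)
    if config.retention is None:
        true_tic = gamma_variate_curve(
            t, config.bolus.A, config.bolus.alpha, config.bolus.beta, config.bolus.t0
        )
    else:
        true_tic, _, _ = _retention_truth(t, config.bolus, config.retention)
    peak = true_tic.max()
    envelope = true_tic / peak if peak > 0 else true_tic

    # --- low-rank tissue clutter, identical in both apertures
    clutter = np.zeros((n, rows, cols), dtype=complex)
    per_component = config.clutter_amplitude / np.sqrt(config.clutter_rank)
    for k in range(config.clutter_rank):
        pattern = _smooth_complex_field(rng, (rows, cols)) * per_component
        freq = rng.uniform(0.03, 0.25)  # Hz: respiration-scale motion
        phase = rng.uniform(0.0, 2 * np.pi)
        env = 1.0 + 0.05 * np.sin(2 * np.pi * freq * t + phase)
        clutter += env[:, None, None] * pattern[None, :, :]

    # --- AR(1) flow speckle on vessel pixels, shared by both apertures
    flow = np.zeros((n, rows, cols), dtype=complex)
    n_vessel = int(mask.sum())
    if n_vessel and config.flow_amplitude > 0:
        rho = config.flow_decorrelation
        innov_scale = np.sqrt((1.0 - rho**2) / 2.0)
        state = (rng.normal(size=n_vessel) + 1j * rng.normal(size=n_vessel)) / np.sqrt(2.0)
        speckle = np.empty((n, n_vessel), dtype=complex)
        for k in range(n):
            speckle[k] = state
            innov = rng.normal(size=n_vessel) + 1j * rng.normal(size=n_vessel)
            state = rho * state + innov_scale * innov
        flow[:, mask] = speckle * (config.flow_amplitude * envelope)[:, None]

    shared = clutter + flow

    def _noisy_copy() -> np.ndarray:
        if config.noise_sd == 0:
            return shared.copy()
        noise = config.noise_sd * (
            rng.normal(size=shared.shape) + 1j * rng.normal(size=shared.shape)
        ) / np.sqrt(2.0)
        return shared + noise

    stack_a = FrameStack(_noisy_copy(), config.frame_rate)
    stack_b = FrameStack(_noisy_copy(), config.frame_rate)
    ground_truth = {
        "vessel_mask": mask,
        "true_tic": true_tic,
        "envelope": envelope,
        "times": t,
    }
    return stack_a, stack_b, ground_truth


# ---------------------------------------------------------------------------
# microbubble micrographs
# ---------------------------------------------------------------------------

def generate_micrograph(
    config: MicrographConfig,
) -> tuple[np.ndarray, BubbleDetections]:
    """Render a brightfield FOV of dark-rimmed microbubbles.

    Bubbles are Gaussian rings (sigma ``rim_width``) centred at subpixel
    positions; the truth table lists centres in pixels and diameters in
    micrometres.  When ``allow_overlap`` is false, centres are rejection
    sampled so rings never touch.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    image = np.full((rows, cols), config.background_level, dtype=float)

    diameters = np.abs(rng.normal(config.diameter_mean, config.diameter_sd,
                                  size=config.n_bubbles))
    diameters = np.clip(diameters, 0.2 * config.diameter_mean, None)
    radii_px = diameters / 2.0 / config.pixel_scale
    rim_px = config.rim_width / config.pixel_scale
    if np.any(diameters / config.pixel_scale < 2.0):
        logger.warning("some bubbles smaller than 2 pixels at this pixel scale")

    centers: list[tuple[float, float]] = []
    margin = radii_px + 4 * rim_px
    for i in range(config.n_bubbles):
        for _attempt in range(10_000):
            r = rng.uniform(margin[i], rows - 1 - margin[i])
            c = rng.uniform(margin[i], cols - 1 - margin[i])
            if config.allow_overlap:
                break
            ok = True
            for j, (rj, cj) in enumerate(centers):
                min_sep = 1.5 * (diameters[i] + diameters[j]) / 2.0 / config.pixel_scale
                if np.hypot(r - rj, c - cj) < min_sep:
                    ok = False
                    break
            if ok:
                break
        else:
            raise InvalidConfigurationError(
                "could not place non-overlapping bubbles; reduce n_bubbles"
            )
        centers.append((r, c))

    for (r, c), rad in zip(centers, radii_px):
        half = int(np.ceil(rad + 4 * rim_px)) + 1
        r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
        c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows), min(c1, cols)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        rho = np.hypot(yy - r, xx - c)
        ring = np.exp(-((rho - rad) ** 2) / (2.0 * rim_px**2))
        image[r0:r1, c0:c1] -= config.ring_contrast * config.background_level * ring

    image += rng.normal(0.0, config.background_noise_sd, size=image.shape)

    truth = BubbleDetections(
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        diameters=diameters,
        fov_id=f"synthetic-{config.seed}",
        image_shape=(rows, cols),
    )
    return image, truth
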