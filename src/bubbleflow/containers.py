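"""Core in-memory containers for ultrasound frame stacks, time-intensity
curves, Doppler images, fits and morphometry results.

All containers are plain dataclasses that validate their invariants at
construction time.  Arrays are kept as handed in (no silent copies) except
where a dtype conversion is required for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "FrameStack",
    "TimeIntensityCurve",
    "DopplerImage",
    "GammaVariateFit",
    "PerfusionParameters",
    "BubbleDetections",
    "SizeDistribution",
    "ChamberGeometry",
]


@dataclass
class FrameStack:
    """A time-ordered sequence of 2-D ultrasound frames.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_rows, n_cols)
        Real intensities or complex beamformed amplitudes.
    frame_rate : float
        Acquisition frame rate in Hz.
    pixel_size : float, optional
        Pixel pitch in micrometres (isotropic), if known.
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"frame stack must be 3-D (frame, row, col); got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 2:
            raise InvalidInputError("frame stack needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("frame stack contains non-finite values")
        if not self.frame_rate > 0:
            raise InvalidInputError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (t=0 at the first frame)."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    def with_data(self, data: np.ndarray) -> "FrameStack":
        """Return a new stack with the same metadata but different samples."""
        return FrameStack(data, self.frame_rate, self.pixel_size)


@dataclass
class TimeIntensityCurve:
    """ROI-mean contrast intensity as a function of time after injection."""

    times: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.ndim != 1:
            raise InvalidInputError("TIC times and intensities must be 1-D")
        if self.times.shape != self.intensities.shape:
            raise InvalidInputError("TIC times and intensities differ in length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("TIC times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise InvalidInputError("TIC times must start at t >= 0")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def peak(self) -> float:
        return float(np.max(self.intensities))


@dataclass
class DopplerImage:
    """A 2-D microvascular map: power Doppler or sub-aperture correlation."""

    data: np.ndarray
    kind: str  # "power-doppler" | "asap-correlation"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise InvalidInputError("Doppler image must be 2-D")
        if self.kind not in ("power-doppler", "asap-correlation"):
            raise InvalidInputError(f"unknown Doppler image kind: {self.kind!r}")
        if self.kind == "power-doppler" and np.any(self.data.real < 0):
            raise InvalidInputError("power Doppler map must be non-negative")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class GammaVariateFit:
    """Result of a gamma-variate bolus fit ``I(t) = A (t-t0)^alpha exp(-(t-t0)/beta)``.

    ``baseline`` is the pre-arrival offset subtracted before fitting; the
    fitted curve is on the baseline-subtracted scale.
    """

    A: float
    alpha: float
    beta: float
    t0: float
    rss: float
    converged: bool
    n_iter: int = 0
    baseline: float = 0.0
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.A > 0 and self.alpha > 0 and self.beta > 0 and self.t0 >= 0):
                raise InvalidInputError(
                    "converged fit requires A>0, alpha>0, beta>0, t0>=0"
                )
        if self.rss < 0:
            raise InvalidInputError("rss must be non-negative")


@dataclass
class PerfusionParameters:
    """The six bolus-kinetics readouts derived from a fitted TIC.

    ``mtt`` is the half-area transit time of the measured curve,
    relative to bolus arrival; ``mtt_model`` is the closed-form half-area
    time of the fitted gamma-variate.  ``time_of_arrival`` and
    ``time_to_peak`` are measured from injection (t = 0).
    ``wash_out_rate`` is reported as a non-negative magnitude.
    """

    auc: float
    wash_in_rate: float
    wash_out_rate: float
    mtt: float
    time_of_arrival: float
    time_to_peak: float
    peak_enhancement: float
    peak_enhancement_raw: float = float("nan")
    mtt_model: float = float("nan")  # closed-form transit time of the fit

    def __post_init__(self) -> None:
        if not self.auc > 0:
            raise InvalidInputError("auc must be positive")
        if not self.peak_enhancement > 0:
            raise InvalidInputError("peak_enhancement must be positive")
        if self.time_of_arrival > self.time_to_peak + 1e-9:
            raise InvalidInputError("time_of_arrival cannot exceed time_to_peak")

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "wash_in_rate": self.wash_in_rate,
            "wash_out_rate": self.wash_out_rate,
            "mtt": self.mtt,
            "time_of_arrival": self.time_of_arrival,
            "time_to_peak": self.time_to_peak,
            "peak_enhancement": self.peak_enhancement,
        }

    # canonical ordering used by cohort tables and Bonferroni families
    PARAM_NAMES = (
        "auc",
        "wash_in_rate",
        "wash_out_rate",
        "mtt",
        "time_of_arrival",
        "time_to_peak",
        "peak_enhancement",
    )


@dataclass
class BubbleDetections:
    """Per-object microbubble centroids (pixels) and diameters (micrometres)."""

    centers: np.ndarray  # (n, 2) subpixel (row, col)
    diameters: np.ndarray  # (n,) um
    fov_id: str = ""
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.diameters = np.asarray(self.diameters, dtype=float).reshape(-1)
        if self.centers.shape[0] != self.diameters.shape[0]:
            raise InvalidInputError("centers and diameters differ in length")
        if self.diameters.size and not np.all(self.diameters > 0):
            raise InvalidInputError("diameters must be positive")
        if self.image_shape is not None and self.centers.size:
            rows, cols = self.image_shape
            inside = (
                (self.centers[:, 0] >= 0)
                & (self.centers[:, 0] <= rows - 1)
                & (self.centers[:, 1] >= 0)
                & (self.centers[:, 1] <= cols - 1)
            )
            if not np.all(inside):
                raise InvalidInputError("detection centers fall outside the image")

    @property
    def n(self) -> int:
        return self.diameters.size


@dataclass
class SizeDistribution:
    """Pooled microbubble size statistics across fields of view."""

    n: int
    mean_diameter: float
    sd_diameter: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.sd_diameter < 0:
            raise InvalidInputError("sd must be non-negative")
        if int(np.sum(self.counts)) != self.n:
            raise InvalidInputError("histogram counts do not sum to n")


@dataclass
class ChamberGeometry:
    """Counting-chamber geometry used to convert per-FOV counts to MB/ml."""

    fov_area_mm2: float
    chamber_depth_mm: float = 0.1  # improved-Neubauer haemocytometer depth
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        from .errors import InvalidConfigurationError

        if not (
            self.fov_area_mm2 > 0 and self.chamber_depth_mm > 0 and self.dilution_factor > 0
        ):
            raise InvalidConfigurationError("all chamber geometry fields must be > 0")
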