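"""SVD spatiotemporal clutter rejection and acoustic sub-aperture
processing (ASAP) of paired Doppler frame stacks.

Tissue echoes are high-amplitude and slowly varying, so they concentrate
in the leading singular components of the Casorati matrix (pixels x
frames); blood/microbubble speckle decorrelates quickly and spreads over
the rest of the spectrum.  Truncating the leading components rejects the
clutter.  ASAP then multiplies the clutter-filtered Doppler signals of
two receive sub-apertures and averages across frames: flow signal is
common to both apertures and survives, while electronic noise is
independent between them and averages out as ``1/sqrt(n_frames)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import DopplerImage, FrameStack
from .errors import InvalidConfigurationError, InvalidInputError

__all__ = [
    "casorati",
    "stack_from_casorati",
    "SVDClutterFilter",
    "svd_clutter_filter",
    "power_doppler",
    "asap_correlation",
    "contrast_ratio",
]


def casorati(stack: FrameStack) -> np.ndarray:
    """Casorati matrix of a stack: column ``k`` is frame ``k`` flattened
    row-major, giving a (pixels x frames) matrix."""
    return stack.data.reshape(stack.n_frames, -1).T


def stack_from_casorati(matrix: np.ndarray, template: FrameStack) -> FrameStack:
    """Inverse of :func:`casorati`; metadata copied from ``template``."""
    data = matrix.T.reshape(template.data.shape)
    return template.with_data(data)


class SVDClutterFilter(TransformerMixin, BaseEstimator):
    """Remove tissue clutter by truncating singular components of the
    Casorati matrix.

    Parameters
    ----------
    low_cutoff : int, default 2
        Number of leading (high-energy, tissue) components removed in
        ``"rank"`` mode.
    high_cutoff : int, default 0
        Number of trailing (noise) components removed additionally.
    mode : {"rank", "energy"}, default "rank"
        ``"rank"`` removes exactly ``low_cutoff`` leading components;
        ``"energy"`` removes the smallest leading set holding at least
        ``energy_threshold`` of the total singular energy (sum of squared
        singular values).
    energy_threshold : float, default 0.95

    Attributes
    ----------
    singular_values_ : ndarray
        Full singular spectrum of the last stack decomposed.
    low_cutoff_ : int
        The effective number of leading components removed.

    Notes
    -----
    The filter is adaptive: the decomposition belongs to the acquisition
    being filtered, so :meth:`transform` decomposes its own input.
    :meth:`fit` exposes the spectrum of a stack for inspection and
    threshold selection.
    """

    def __init__(self, low_cutoff: int = 2, high_cutoff: int = 0,
                 mode: str = "rank", energy_threshold: float = 0.95):
        self.low_cutoff = low_cutoff
        self.high_cutoff = high_cutoff
        self.mode = mode
        self.energy_threshold = energy_threshold

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_stack(X) -> FrameStack:
        if isinstance(X, FrameStack):
            return X
        X = np.asarray(X)
        if X.ndim != 3:
            raise InvalidInputError("expected a FrameStack or a 3-D array")
        return FrameStack(X, frame_rate=1.0)

    def _validate(self, n_frames: int) -> None:
        if self.low_cutoff < 0 or self.high_cutoff < 0:
            raise InvalidConfigurationError("cutoffs must be non-negative")
        if self.mode not in ("rank", "energy"):
            raise InvalidConfigurationError(f"unknown mode {self.mode!r}")
        if not 0 < self.energy_threshold <= 1:
            raise InvalidConfigurationError("energy_threshold must be in (0, 1]")
        if self.low_cutoff + self.high_cutoff >= n_frames:
            raise InvalidConfigurationError(
                f"cutoffs ({self.low_cutoff}+{self.high_cutoff}) must total "
                f"fewer than the {n_frames} frames"
            )

    def _decompose(self, stack: FrameStack):
        self._validate(stack.n_frames)
        M = casorati(stack)
        U, s, Vh = np.linalg.svd(M, full_matrices=False)
        if self.mode == "energy":
            energy = np.cumsum(s**2) / np.sum(s**2)
            low = int(np.searchsorted(energy, self.energy_threshold) + 1)
            low = min(low, stack.n_frames - 1 - self.high_cutoff)
        else:
            low = self.low_cutoff
        return U, s, Vh, low

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y=None):
        """Decompose a stack and record its singular spectrum."""
        stack = self._as_stack(X)
        _, s, _, low = self._decompose(stack)
        self.singular_values_ = s
        self.low_cutoff_ = low
        self.n_frames_ = stack.n_frames
        return self

    def transform(self, X) -> FrameStack:
        """Return the clutter-filtered stack (same shape and metadata)."""
        stack = self._as_stack(X)
        U, s, Vh, low = self._decompose(stack)
        self.singular_values_ = s
        self.low_cutoff_ = low
        self.n_frames_ = stack.n_frames
        keep = np.ones_like(s)
        keep[:low] = 0.0
        if self.high_cutoff:
            keep[len(s) - self.high_cutoff:] = 0.0
        filtered = (U * (s * keep)) @ Vh
        out = stack_from_casorati(filtered, stack)
        if isinstance(X, FrameStack):
            return out
        return out.data


def svd_clutter_filter(stack: FrameStack, low_cutoff: int = 2,
                       high_cutoff: int = 0, mode: str = "rank",
                       energy_threshold: float = 0.95) -> FrameStack:
    """Functional wrapper around :class:`SVDClutterFilter`."""
    return SVDClutterFilter(
        low_cutoff=low_cutoff, high_cutoff=high_cutoff, mode=mode,
        energy_threshold=energy_threshold,
    ).transform(stack)


def power_doppler(stack: FrameStack) -> DopplerImage:
    """Per-pixel mean squared magnitude across frames."""
    data = np.mean(np.abs(stack.data) ** 2, axis=0)
    return DopplerImage(data, kind="power-doppler")


def asap_correlation(stack_a: FrameStack, stack_b: FrameStack,
                     normalized: bool = True) -> DopplerImage:
    """Cross-correlate two sub-aperture stacks: per pixel, the mean over
    frames of ``a * conj(b)`` (``a * b`` for real data).

    With ``normalized=True`` the product is divided by the product of the
    per-pixel RMS amplitudes of each stack, bounding the magnitude by 1
    (exactly 1 where the two signals are identical and nonzero).
    Noise-dominated pixels may be negative or complex; values are
    reported as-is.
    """
    if stack_a.data.shape != stack_b.data.shape:
        raise InvalidInputError("sub-aperture stacks differ in shape")
    if stack_a.frame_rate != stack_b.frame_rate:
        raise InvalidInputError("sub-aperture stacks differ in frame rate")
    a, b = stack_a.data, stack_b.data
    prod = np.mean(a * np.conj(b), axis=0)
    if normalized:
        rms_a = np.sqrt(np.mean(np.abs(a) ** 2, axis=0))
        rms_b = np.sqrt(np.mean(np.abs(b) ** 2, axis=0))
        denom = rms_a * rms_b
        with np.errstate(invalid="ignore", divide="ignore"):
            prod = np.where(denom > 0, prod / np.where(denom > 0, denom, 1.0), 0.0)
    if not (stack_a.is_complex or stack_b.is_complex):
        prod = prod.real
    return DopplerImage(prod, kind="asap-correlation")


def contrast_ratio(image: DopplerImage | np.ndarray, mask: np.ndarray,
                   db: bool = False) -> float:
    """Vessel-to-background contrast: mean magnitude inside ``mask`` over
    mean magnitude outside.  ``db=True`` returns ``10 log10`` of the ratio."""
    data = image.magnitude if isinstance(image, DopplerImage) else np.abs(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise InvalidInputError("mask shape does not match image")
    if not mask.any() or mask.all():
        raise InvalidInputError("mask must split the image into two regions")
    ratio = float(data[mask].mean() / data[~mask].mean())
    return float(10.0 * np.log10(ratio)) if db else ratio
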