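"""Core in-memory containers for time-domain and frequency-domain MRS data.

Conventions
-----------
* A FID (free-induction decay) is stored as a complex array of shape
  ``(n_channels, n_points)``; single-channel data keep the leading axis.
* The chemical-shift axis is anchored at the carrier: a component with
  time-domain frequency ``f`` Hz appears at
  ``reference_ppm + f / transmitter_freq_mhz`` ppm.  Larger ppm values are
  more downfield (further from TMS on the left of a displayed spectrum).
* Spectra are displayed with the ppm axis monotone *decreasing* left to
  right, the universal NMR display convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["FidSeries", "Spectrum"]


@dataclass
class FidSeries:
    """Complex time-domain signal(s) plus acquisition metadata.

    Parameters
    ----------
    samples : complex ndarray, shape (n_channels, n_points)
        Raw complex FID per receive channel.
    dwell_time : float
        Sampling interval in seconds (> 0).
    transmitter_freq : float
        Transmitter (carrier) frequency in MHz.
    reference_shift : float
        Chemical shift in ppm of the carrier (zero time-domain frequency).
    meta : dict
        Free-form acquisition metadata.  The pipeline uses the keys
        ``TS`` (saturation delay, ms), ``experiment``
        (``selective | broadband | m0 | water_ref``), ``TR``, ``TE``, ``NEX``.
    """

    samples: np.ndarray
    dwell_time: float
    transmitter_freq: float
    reference_shift: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=complex))
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must have shape (n_channels, n_points)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_points(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def spectral_width(self) -> float:
        """Sampling bandwidth in Hz."""
        return 1.0 / self.dwell_time

    def ppm_of_freq(self, freq_hz: np.ndarray | float) -> np.ndarray | float:
        return self.reference_shift + np.asarray(freq_hz) / self.transmitter_freq

    def freq_of_ppm(self, ppm: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(ppm) - self.reference_shift) * self.transmitter_freq

    def with_samples(self, samples: np.ndarray) -> "FidSeries":
        """Copy of this series with new sample data, metadata preserved."""
        return replace(self, samples=np.atleast_2d(np.asarray(samples, dtype=complex)))

    def copy(self) -> "FidSeries":
        return self.with_samples(self.samples.copy())


@dataclass
class Spectrum:
    """A single-channel complex spectrum on an explicit ppm axis.

    ``ppm_axis`` is monotone decreasing (display convention); ``values``
    is aligned with it.  ``provenance`` records the processing steps that
    produced the spectrum.
    """

    values: np.ndarray
    ppm_axis: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.values.shape != self.ppm_axis.shape:
            raise ValueError("values and ppm_axis must have identical shape")
        if self.ppm_axis.size > 1 and not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm_axis must be monotone decreasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def window(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Boolean mask selecting lo_ppm <= axis <= hi_ppm."""
        lo, hi = sorted((lo_ppm, hi_ppm))
        return (self.ppm_axis >= lo) & (self.ppm_axis <= hi)
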