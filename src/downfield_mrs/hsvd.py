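"""Hankel-SVD time-domain spectral fitting and fixed-basis amplitude regression.

The no-saturation (equilibrium) scan is decomposed into damped complex
exponentials by Hankel singular value decomposition (HSVD, 60 components by
default).  Within a narrow chemical-shift window around each target
resonance the single largest component is assigned to that resonance; all
other components constitute the baseline and can be subtracted in the time
domain.  The assigned components — with frequency and damping *frozen* —
form a basis onto which every saturation-recovery scan is projected by
complex linear least squares, yielding one real amplitude per resonance per
scan after phasing against the equilibrium scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hankel, lstsq, svd

from .fid import FidSeries

__all__ = [
    "HsvdComponent",
    "PeakBasis",
    "PeakAmplitudeSeries",
    "DEFAULT_WINDOWS",
    "hsvd_decompose",
    "reconstruct",
    "assign_components",
    "subtract_baseline",
    "regress_amplitudes",
    "extract_series",
    "build_basis",
]

#: Assignment windows: nominal shift +/- 0.08 ppm around each resonance.
DEFAULT_WINDOWS = {
    "TRP": (10.02, 10.18),
    "NAD_H2": (9.22, 9.38),
    "NAD_H6": (9.02, 9.18),
    "NAD_H4": (8.82, 8.98),
}


@dataclass(frozen=True)
class HsvdComponent:
    """One damped complex exponential: a * exp((i*2*pi*f - d) t).

    ``frequency`` in Hz relative to the carrier; ``damping`` in 1/s
    (positive = decaying; FWHM = damping/pi); ``amplitude`` complex.
    """

    frequency: float
    damping: float
    amplitude: complex

    @property
    def linewidth_fwhm(self) -> float:
        return self.damping / np.pi

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp((1j * 2 * np.pi * self.frequency - self.damping) * t)


@dataclass
class PeakBasis:
    """Per-resonance component sets with frozen frequency and damping.

    ``components`` maps resonance label to its assigned HSVD component(s);
    a resonance that could not be assigned is *missing* from the mapping
    (mirrors in-vivo subjects whose peaks failed to fit).  ``baseline``
    holds every unassigned component.  ``far_baseline`` restricts the
    baseline to components outside every assignment window: those are the
    ones safe to use as free regression columns, since leftover components
    *inside* a peak window are near-collinear with the assigned peak and
    destabilize its amplitude.
    """

    components: dict[str, list[HsvdComponent]]
    baseline: list[HsvdComponent] = field(default_factory=list)
    windows: dict[str, tuple[float, float]] | None = None
    reference_shift: float | None = None
    transmitter_freq: float | None = None
    fwhm_bounds: tuple[float, float] = (8.0, 120.0)

    @property
    def labels(self) -> list[str]:
        return list(self.components)

    def _window_of(self, component: HsvdComponent) -> str | None:
        if not self.windows or self.reference_shift is None:
            return None
        ppm = self.reference_shift + component.frequency / self.transmitter_freq
        for label, (lo, hi) in self.windows.items():
            if lo <= ppm <= hi:
                return label
        return None

    #: ppm band of the upfield baseline complex (adenosine/NAA/amide tails)
    #: whose components are carried as free nuisance columns in regression.
    baseline_band: tuple[float, float] = (7.9, 8.85)

    @property
    def far_baseline(self) -> list[HsvdComponent]:
        """Baseline components outside every window, within the baseline band.

        Only the region of the partially excited upfield complex carries
        real signal that recovers between scans; components elsewhere are
        noise poles, and giving each of them a free column would only leak
        noise into the peak amplitudes.
        """
        out = []
        for c in self.baseline:
            if self._window_of(c) is not None:
                continue
            if self.windows and self.reference_shift is not None:
                ppm = self.reference_shift + c.frequency / self.transmitter_freq
                if not self.baseline_band[0] <= ppm <= self.baseline_band[1]:
                    continue
            out.append(c)
        return out

    def window_attached(self, label: str) -> list[HsvdComponent]:
        """Unassigned components falling inside the window of ``label``.

        Under the single-component assignment rule a doublet's second line
        (or, on noisy data, a split-off part of the peak) lands in the
        baseline while sitting inside the peak window; for amplitude
        readout those components belong to the resonance and their
        amplitudes are summed with the primary component's.  Components
        with implausible linewidths (outside ``fwhm_bounds``) are excluded
        — they are baseline tails or noise, not peak structure.
        """
        lo_w, hi_w = self.fwhm_bounds
        return [c for c in self.baseline
                if self._window_of(c) == label
                and lo_w <= c.linewidth_fwhm <= hi_w]

    def shape_amplitude(self, label: str) -> complex:
        """t = 0 amplitude of the composite lineshape of ``label``."""
        comps = list(self.components[label]) + self.window_attached(label)
        return complex(sum(c.amplitude for c in comps))

    def design_matrix(self, t: np.ndarray, include_baseline: bool = False
                      ) -> tuple[np.ndarray, list[str]]:
        """One composite lineshape column per resonance, plus free baseline.

        Each resonance column is the sum of its assigned component and any
        window-attached components, weighted by their (equilibrium-scan)
        complex amplitudes and normalized to unit t = 0 amplitude — a
        single free scale per resonance keeps the regression well
        conditioned, makes the doublet's two lines co-scale exactly, and is
        what 'fitting with a fixed basis of frequencies and linewidths'
        means operationally.  With ``include_baseline`` the free columns of
        the far baseline are appended after the peak columns.
        """
        cols, names = [], []
        for label, comps in self.components.items():
            members = list(comps) + self.window_attached(label)
            shape = np.zeros(t.size, dtype=complex)
            for c in members:
                shape += c.amplitude * np.exp(
                    (1j * 2 * np.pi * c.frequency - c.damping) * t)
            total = self.shape_amplitude(label)
            if total == 0:
                continue
            cols.append(shape / total)
            names.append(label)
        if include_baseline:
            for j, c in enumerate(self.far_baseline):
                cols.append(np.exp((1j * 2 * np.pi * c.frequency - c.damping) * t))
                names.append(f"baseline[{j}]")
        if not cols:
            raise ValueError("empty basis")
        return np.stack(cols, axis=1), names


@dataclass
class PeakAmplitudeSeries:
    """Per-resonance amplitude versus saturation delay for one experiment."""

    resonance: str
    experiment: str
    ts_ms: np.ndarray
    amplitudes: np.ndarray
    r_squared: np.ndarray

    def __post_init__(self) -> None:
        self.ts_ms = np.asarray(self.ts_ms, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)


def hsvd_decompose(fid: FidSeries, n_components: int = 60) -> list[HsvdComponent]:
    """Decompose a 1-channel FID into damped complex exponentials.

    Classic HSVD: build a (near-)square Hankel matrix from the FID, truncate
    its SVD to ``n_components`` to estimate the signal subspace, solve the
    shift-invariance least-squares eigenproblem for the signal poles
    ``z_k = exp((i 2 pi f_k - d_k) dt)``, keep decaying poles (d > 0), and
    estimate complex amplitudes by linear least squares against the FID.

    Components are returned sorted by frequency.  An all-zero FID returns
    an empty list.
    """
    if fid.n_channels != 1:
        raise ValueError("hsvd_decompose expects a single (combined) channel")
    x = fid.samples[0]
    n = x.size
    if n < 2 * n_components:
        raise ValueError("need n_points >= 2 * n_components")
    if not np.any(x):
        return []

    rows = n // 2
    h = hankel(x[:rows], x[rows - 1:])
    u, s, _vh = svd(h, full_matrices=False)
    # Never model below the numerical rank: on clean data the requested
    # model order can exceed the true number of lines, and poles estimated
    # from null-space directions are spurious.
    rank = int(np.sum(s > s[0] * 1e-10))
    k = min(n_components, rank)
    uk = u[:, :k]
    # Shift invariance of the signal subspace: Uk_bottom ~= Uk_top @ Z
    z_mat, *_ = lstsq(uk[:-1], uk[1:], lapack_driver="gelsd")
    poles = np.linalg.eigvals(z_mat)

    dt = fid.dwell_time
    with np.errstate(divide="ignore"):
        dampings = -np.log(np.abs(poles)) / dt
    freqs = np.angle(poles) / (2 * np.pi * dt)
    keep = np.isfinite(dampings) & (dampings > 0)
    freqs, dampings = freqs[keep], dampings[keep]
    if freqs.size == 0:
        return []

    t = fid.times
    design = np.exp((1j * 2 * np.pi * freqs[None, :] - dampings[None, :]) * t[:, None])
    amps, *_ = lstsq(design, x, lapack_driver="gelsd")

    comps = [
        HsvdComponent(float(f), float(d), complex(a))
        for f, d, a in zip(freqs, dampings, amps)
    ]
    comps.sort(key=lambda c: c.frequency)
    return comps


def reconstruct(components: list[HsvdComponent], t: np.ndarray) -> np.ndarray:
    """Sum of component signals on time grid ``t`` (seconds)."""
    out = np.zeros(t.size, dtype=complex)
    for c in components:
        out += c.evaluate(t)
    return out


def reconstruction_rsquared(fid: FidSeries, components: list[HsvdComponent]
                            ) -> float:
    """Fit quality of a full decomposition: R^2 of the component sum.

    This is the quantity a 'total fit' overlay of the decomposed
    no-saturation spectrum displays: how much of the scan's variability
    the complete spectral model (peaks and baseline together) captures.
    """
    if fid.n_channels != 1:
        raise ValueError("expects a single channel")
    x = fid.samples[0]
    resid = x - reconstruct(components, fid.times)
    ss_tot = float(np.sum(np.abs(x - x.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum(np.abs(resid) ** 2)) / ss_tot


def assign_components(
    components: list[HsvdComponent],
    windows: dict[str, tuple[float, float]],
    reference_shift: float,
    transmitter_freq: float,
    fwhm_bounds: tuple[float, float] = (8.0, 120.0),
) -> PeakBasis:
    """Assign one component per resonance window; everything else is baseline.

    Within each (disjoint) ppm window the *plausible* component of largest
    amplitude magnitude wins; any runner-up inside the window joins the
    baseline.  Plausible means a linewidth inside ``fwhm_bounds`` (Hz):
    the target resonances are 28-54 Hz wide (plus line broadening), so
    much broader components are tails of the upfield baseline complex and
    much narrower ones are noise spikes — neither may represent a peak.
    An empty window leaves that resonance missing from the basis rather
    than raising — poor-quality peaks are dropped per subject, not fatal.
    """
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (_, a), (_, b) in zip(spans, spans[1:]):
        if a[1] > b[0]:
            raise ValueError("assignment windows must be disjoint")

    ppm = np.array([reference_shift + c.frequency / transmitter_freq
                    for c in components])
    lo_w, hi_w = fwhm_bounds
    assigned: dict[str, list[HsvdComponent]] = {}
    taken: set[int] = set()
    for label, (lo, hi) in windows.items():
        inside = [i for i in range(len(components))
                  if lo <= ppm[i] <= hi
                  and lo_w <= components[i].linewidth_fwhm <= hi_w]
        if not inside:
            continue
        best = max(inside, key=lambda i: abs(components[i].amplitude))
        assigned[label] = [components[best]]
        taken.add(best)
    baseline = [c for i, c in enumerate(components) if i not in taken]
    return PeakBasis(
        components=assigned, baseline=baseline, windows=dict(windows),
        reference_shift=reference_shift, transmitter_freq=transmitter_freq,
        fwhm_bounds=fwhm_bounds,
    )


def subtract_baseline(fid: FidSeries, baseline: list[HsvdComponent]) -> FidSeries:
    """Subtract the reconstructed baseline sum from a 1-channel FID (time domain)."""
    if fid.n_channels != 1:
        raise ValueError("subtract_baseline expects a single channel")
    if not baseline:
        return fid.copy()
    out = fid.with_samples(fid.samples[0] - reconstruct(baseline, fid.times))
    out.meta = {**fid.meta, "baseline_removed": len(baseline)}
    return out


def regress_amplitudes(
    fid: FidSeries,
    basis: PeakBasis,
    include_baseline: bool = True,
) -> tuple[dict[str, complex], float]:
    """Fixed-basis complex linear regression of one scan.

    Frequencies and dampings are frozen; one complex scale per resonance
    lineshape is free (see :meth:`PeakBasis.design_matrix`), and the
    returned value per resonance is the fitted t = 0 amplitude of its
    composite shape.  ``include_baseline`` adds the far-baseline
    components (outside every assignment window) as free nuisance columns,
    so that partially recovered baseline signal is modeled per scan
    instead of biasing the peaks.  The returned R-squared is computed on
    the complex residual against the scan's own variability.
    """
    if fid.n_channels != 1:
        raise ValueError("regress_amplitudes expects a single channel")
    x = fid.samples[0]
    peak_design, _ = basis.design_matrix(fid.times, include_baseline=False)
    if np.linalg.matrix_rank(peak_design) < peak_design.shape[1]:
        raise ValueError("rank-deficient basis")
    design, names = basis.design_matrix(fid.times, include_baseline=include_baseline)
    coef, *_ = lstsq(design, x, lapack_driver="gelsd")
    resid = x - design @ coef
    ss_res = float(np.sum(np.abs(resid) ** 2))
    ss_tot = float(np.sum(np.abs(x - x.mean()) ** 2))
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    amplitudes: dict[str, complex] = {}
    for name, a in zip(names, coef):
        if name.startswith("baseline["):
            continue
        label = name.split("[")[0]
        amplitudes[label] = amplitudes.get(label, 0j) + complex(a)
    return amplitudes, rsq


def build_basis(
    m0_fid: FidSeries,
    windows: dict[str, tuple[float, float]] | None = None,
    n_components: int = 60,
) -> PeakBasis:
    """HSVD-decompose the equilibrium scan and assign the target resonances."""
    if windows is None:
        windows = DEFAULT_WINDOWS
    comps = hsvd_decompose(m0_fid, n_components=n_components)
    return assign_components(
        comps, windows, m0_fid.reference_shift, m0_fid.transmitter_freq
    )


def extract_series(
    scans: dict[str, dict[float, FidSeries]],
    m0_fid: FidSeries,
    basis: PeakBasis,
    ts_m0: float = 10000.0,
    include_baseline: bool = True,
) -> dict[tuple[str, str], PeakAmplitudeSeries]:
    """Amplitude-versus-TS series per resonance per experiment.

    ``scans`` maps experiment name ("selective"/"broadband") to
    ``{TS_ms: combined 1-channel FidSeries}``.  Every scan — including the
    equilibrium scan — is regressed onto the frozen peak basis with the
    far-baseline components as free nuisance columns (the baseline complex
    recovers at its own rate, so its amplitude must be re-estimated per
    scan rather than subtracted at equilibrium strength).  Amplitudes are
    phased by the equilibrium-scan amplitude of the same resonance: the
    reported value is ``Re(a * conj(a_m0) / |a_m0|)``, so the equilibrium
    point is positive real and appended to *both* experiments at
    TS = ``ts_m0``.
    """
    if m0_fid is None:
        raise ValueError("equilibrium (m0) scan is required")
    m0_amps, m0_rsq = regress_amplitudes(m0_fid, basis, include_baseline)

    series: dict[tuple[str, str], PeakAmplitudeSeries] = {}
    for experiment, by_ts in scans.items():
        ts_sorted = sorted(by_ts)
        fits = [regress_amplitudes(by_ts[ts], basis, include_baseline)
                for ts in ts_sorted]
        for label in basis.labels:
            ref = m0_amps[label]
            ref_mag = abs(ref)
            if ref_mag == 0:
                continue
            phase = np.conj(ref) / ref_mag
            amps = [float(np.real(a[label] * phase)) for a, _ in fits]
            rsqs = [r for _, r in fits]
            series[(label, experiment)] = PeakAmplitudeSeries(
                resonance=label,
                experiment=experiment,
                ts_ms=np.array(ts_sorted + [ts_m0]),
                amplitudes=np.array(amps + [ref_mag]),
                r_squared=np.array(rsqs + [m0_rsq]),
            )
    return series
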