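"""Saturation-recovery relaxation models for exchanging downfield resonances.

Two models are fitted to peak-amplitude-versus-saturation-delay data:

**Model 1 (apparent T1).**  Each saturation-recovery experiment (selective or
broadband) is fitted independently with the three-parameter exponential

    S(TS) = M0 * (1 - k * exp(-TS / T1_app))

where ``k`` in [0, 1] is the saturation efficiency and ``T1_app`` the
*apparent* longitudinal relaxation time, which implicitly folds in
magnetization exchange with water.

**Model 2 (two-spin exchange).**  Both experiments are fitted simultaneously
with the coupled Solomon/Bloch equations for metabolite (A) and water (B)
longitudinal magnetization:

    dMz_A/dt = -(Mz_A - M0_A)/T1_A - sigma_AB (Mz_A - M0_A) + sigma_BA (Mz_B - M0_B)
    dMz_B/dt = -(Mz_B - M0_B)/T1_B - sigma_BA (Mz_B - M0_B) + sigma_AB (Mz_A - M0_A)

with detailed balance  sigma_BA = sigma_AB * M0_A / M0_B.  Initial
conditions: selective saturation nulls only the metabolite,
``Mz_A(0) = M0_A (1 - k_sel), Mz_B(0) = M0_B``; broadband saturation nulls
both pools with efficiency ``k_broad``.  The water T1 and the
water:metabolite equilibrium-magnetization ratio are fixed; free parameters
are the exchange-corrected ``T1_A``, the exchange rate ``sigma_AB``, and the
amplitude scale ``M0_A``.  The objective (summed squared residuals over both
experiments) is minimized globally by basin-hopping over a bounded local
least-squares solver.

Units: times in ms at the API surface, rates in Hz; internally seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.integrate import solve_ivp

__all__ = [
    "WATER_T1_MS",
    "WATER_METABOLITE_M0_RATIO",
    "TwoSpinParams",
    "model1_signal",
    "two_spin_rhs",
    "two_spin_solve",
    "ApparentT1Model",
    "ApparentT1Results",
    "TwoSpinExchangeModel",
    "TwoSpinExchangeResults",
    "fit_model1",
    "fit_model2",
    "apparent_t1_ratio",
]

#: Assumed longitudinal relaxation time of brain water at 7 T (ms).
WATER_T1_MS = 1800.0

#: Water : metabolite equilibrium magnetization ratio M0_B / M0_A,
#: (2 protons x 55 M water) / 0.3 mM metabolite.
WATER_METABOLITE_M0_RATIO = (2.0 * 55.0) / 0.3e-3


def model1_signal(
    ts_ms: np.ndarray | float, m0: float, k: float, t1_ms: float
) -> np.ndarray | float:
    """Three-parameter saturation-recovery signal M0*(1 - k*exp(-TS/T1))."""
    if t1_ms <= 0:
        raise ValueError("t1_ms must be positive")
    return m0 * (1.0 - k * np.exp(-np.asarray(ts_ms, dtype=float) / t1_ms))


@dataclass(frozen=True)
class TwoSpinParams:
    """Parameters of the two-pool exchange system (A = metabolite, B = water)."""

    t1_a_ms: float
    sigma_ab_hz: float
    m0_a: float = 1.0
    t1_b_ms: float = WATER_T1_MS
    m0_b_over_m0_a: float = WATER_METABOLITE_M0_RATIO
    k_sel: float = 0.85
    k_broad: float = 0.85

    def __post_init__(self) -> None:
        if self.t1_a_ms <= 0 or self.t1_b_ms <= 0:
            raise ValueError("T1 values must be positive")
        if self.sigma_ab_hz < 0:
            raise ValueError("sigma_AB must be non-negative")
        for k in (self.k_sel, self.k_broad):
            if not 0.0 <= k <= 1.0:
                raise ValueError("saturation efficiencies must lie in [0, 1]")

    @property
    def sigma_ba_hz(self) -> float:
        """Reverse rate from detailed balance: sigma_AB * M0_A / M0_B."""
        return self.sigma_ab_hz / self.m0_b_over_m0_a

    @property
    def m0_b(self) -> float:
        return self.m0_a * self.m0_b_over_m0_a

    def rate_matrix(self) -> np.ndarray:
        """System matrix (1/s) for the deviation vector (Mz_A - M0_A, Mz_B - M0_B)."""
        r1a = 1000.0 / self.t1_a_ms
        r1b = 1000.0 / self.t1_b_ms
        s_ab = self.sigma_ab_hz
        s_ba = self.sigma_ba_hz
        return np.array([[-(r1a + s_ab), s_ba], [s_ab, -(r1b + s_ba)]])

    def balanced_rate_matrix(self) -> np.ndarray:
        """System matrix for the fractional deviations (u_A/M0_A, u_B/M0_B).

        The similarity transform by diag(M0_A, M0_B) maps the huge
        water:metabolite scale disparity out of the state vector, leaving
        off-diagonal entries (sigma_AB, sigma_BA): numerically benign.
        """
        r1a = 1000.0 / self.t1_a_ms
        r1b = 1000.0 / self.t1_b_ms
        s_ab = self.sigma_ab_hz
        s_ba = self.sigma_ba_hz
        return np.array([[-(r1a + s_ab), s_ab], [s_ba, -(r1b + s_ba)]])

    def initial_fractional_deviation(self, experiment: str) -> np.ndarray:
        """(u_A/M0_A, u_B/M0_B) immediately after the saturation pulse."""
        if experiment == "selective":
            return np.array([-self.k_sel, 0.0])
        if experiment == "broadband":
            return np.array([-self.k_broad, -self.k_broad])
        raise ValueError(f"unknown experiment {experiment!r}")

    def initial_state(self, experiment: str) -> np.ndarray:
        """(Mz_A, Mz_B) immediately after the saturation pulse."""
        if experiment == "selective":
            return np.array([self.m0_a * (1.0 - self.k_sel), self.m0_b])
        if experiment == "broadband":
            return np.array(
                [self.m0_a * (1.0 - self.k_broad), self.m0_b * (1.0 - self.k_broad)]
            )
        raise ValueError(f"unknown experiment {experiment!r}")


def two_spin_rhs(state: np.ndarray, params: TwoSpinParams) -> np.ndarray:
    """Time derivative (1/s) of (Mz_A, Mz_B) under the coupled Solomon equations."""
    mz_a, mz_b = state
    da = mz_a - params.m0_a
    db = mz_b - params.m0_b
    r1a = 1000.0 / params.t1_a_ms
    r1b = 1000.0 / params.t1_b_ms
    d_a = -r1a * da - params.sigma_ab_hz * da + params.sigma_ba_hz * db
    d_b = -r1b * db - params.sigma_ba_hz * db + params.sigma_ab_hz * da
    return np.array([d_a, d_b])


def _solve_closed_form(
    params: TwoSpinParams, w0: np.ndarray, t_s: np.ndarray
) -> np.ndarray:
    """Fractional-deviation trajectory w(t) = expm(A t) w0, explicit 2x2 form.

    The balanced system matrix has real eigenvalues (non-negative
    off-diagonal entries).  The larger-magnitude root comes from the
    quadratic formula and the smaller from det/lambda1 (numerically stable
    product rule).  A (near-)defective matrix — eigenvalue gap vanishing —
    falls back to ``scipy.linalg.expm``.
    """
    a = params.balanced_rate_matrix()
    a11, a12 = a[0]
    a21, a22 = a[1]
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    disc_sq = (a11 - a22) ** 2 + 4.0 * a12 * a21
    if disc_sq <= max(1e-28, 1e-14 * tr * tr):
        return np.stack([linalg.expm(a * t) @ w0 for t in t_s], axis=1)
    disc = np.sqrt(disc_sq)
    lam1 = (tr - disc) / 2.0 if tr < 0 else (tr + disc) / 2.0
    lam2 = det / lam1 if lam1 != 0 else (tr + disc) / 2.0
    # Eigenvectors from whichever row representation is better conditioned.
    if abs(a12) >= abs(a21):
        v1 = np.array([a12, lam1 - a11])
        v2 = np.array([a12, lam2 - a11])
    else:
        v1 = np.array([lam1 - a22, a21])
        v2 = np.array([lam2 - a22, a21])
    det_v = v1[0] * v2[1] - v2[0] * v1[1]
    if det_v == 0:
        return np.stack([linalg.expm(a * t) @ w0 for t in t_s], axis=1)
    c1 = (w0[0] * v2[1] - v2[0] * w0[1]) / det_v
    c2 = (v1[0] * w0[1] - w0[0] * v1[1]) / det_v
    e1 = np.exp(lam1 * t_s)
    e2 = np.exp(lam2 * t_s)
    return np.outer(c1 * v1, e1).reshape(2, -1) + np.outer(c2 * v2, e2).reshape(2, -1)


def two_spin_solve(
    params: TwoSpinParams,
    experiment: str,
    ts_ms: np.ndarray,
    method: str = "closed_form",
    return_water: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Metabolite longitudinal magnetization Mz_A at each saturation delay.

    Parameters
    ----------
    experiment : {"selective", "broadband"}
        Selects the post-saturation initial condition.
    ts_ms : array
        Saturation delays in ms, all >= 0.
    method : {"closed_form", "numeric"}
        Closed form evaluates the matrix exponential of the 2x2 linear
        system through its eigendecomposition; numeric integrates the ODEs
        with ``solve_ivp`` at tight tolerances.  Both solve the same
        equations; numeric exists as an independent cross-check.
    return_water : bool
        Also return Mz_B.
    """
    ts_ms = np.asarray(ts_ms, dtype=float)
    if np.any(ts_ms < 0):
        raise ValueError("saturation delays must be non-negative")
    t_s = ts_ms / 1000.0
    w0 = params.initial_fractional_deviation(experiment)

    if method == "closed_form":
        w = _solve_closed_form(params, w0, t_s)
    elif method == "numeric":
        t_unique, inverse = np.unique(t_s, return_inverse=True)
        t_end = max(t_unique[-1], 1e-9)
        a = params.balanced_rate_matrix()
        sol = solve_ivp(
            lambda _t, y: a @ y,
            (0.0, t_end),
            w0,
            t_eval=t_unique,
            method="DOP853",
            rtol=1e-13,
            atol=1e-15,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        w = sol.y[:, inverse]
    else:
        raise ValueError(f"unknown method {method!r}")

    mz_a = params.m0_a * (1.0 + np.real(w[0]))
    if return_water:
        return mz_a, params.m0_b * (1.0 + np.real(w[1]))
    return mz_a


# ---------------------------------------------------------------------------
# Model 1: apparent T1
# ---------------------------------------------------------------------------


@dataclass
class ApparentT1Results:
    """Fitted three-parameter saturation-recovery model."""

    m0: float
    k: float
    t1_ms: float
    rsquared: float
    experiment: str | None = None
    success: bool = True
    bse: np.ndarray | None = None  # (m0, k, t1) standard errors
    nobs: int = 0
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.m0, self.k, self.t1_ms])

    def predict(self, ts_ms: np.ndarray) -> np.ndarray:
        return model1_signal(ts_ms, self.m0, self.k, self.t1_ms)

    def summary(self) -> str:
        lines = [
            "Apparent-T1 saturation-recovery fit",
            "===================================",
            f"experiment:   {self.experiment or '-'}",
            f"n obs:        {self.nobs}",
            f"M0:           {self.m0:.6g}",
            f"k (sat eff):  {self.k:.4f}",
            f"T1 apparent:  {self.t1_ms:.1f} ms",
            f"R-squared:    {self.rsquared:.4f}",
            f"converged:    {self.success}",
        ]
        return "\n".join(lines)


class ApparentT1Model:
    """Three-parameter exponential model of one saturation-recovery curve.

    Parameters
    ----------
    ts_ms, amplitudes : arrays
        Saturation delays (ms) and peak amplitudes, including the
        equilibrium scan conventionally assigned TS = 10 s.
    experiment : str, optional
        Tag carried into the results ("selective" or "broadband").
    """

    def __init__(
        self,
        ts_ms: np.ndarray,
        amplitudes: np.ndarray,
        experiment: str | None = None,
    ) -> None:
        self.ts_ms = np.asarray(ts_ms, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        if self.ts_ms.shape != self.amplitudes.shape or self.ts_ms.ndim != 1:
            raise ValueError("ts_ms and amplitudes must be 1-D arrays of equal length")
        if self.ts_ms.size < 4:
            raise ValueError("need at least 4 points (including the equilibrium scan)")
        self.experiment = experiment

    def fit(self) -> ApparentT1Results:
        ts, y = self.ts_ms, self.amplitudes
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        m0_guess = float(y[np.argmax(ts)])
        if m0_guess <= 0:
            m0_guess = float(max(np.max(np.abs(y)), 1e-12))
        span = float(np.ptp(y))
        if ss_tot == 0 or span < 1e-12 * max(abs(m0_guess), 1e-30):
            # Constant series: no recovery information, T1 unidentifiable.
            return ApparentT1Results(
                m0=float(y.mean()), k=0.0, t1_ms=float("nan"), rsquared=1.0,
                experiment=self.experiment, success=False, nobs=ts.size,
                message="constant series; T1 unidentifiable",
            )

        k_guess = float(np.clip(1.0 - y.min() / m0_guess, 1e-3, 1.0))
        bounds = ([0.0, 0.0, 1e-2], [np.inf, 1.0, 1e5])

        def residuals(x: np.ndarray) -> np.ndarray:
            return model1_signal(ts, *x) - y

        best = None
        for t1_start in (50.0, 200.0, 800.0, 3000.0):
            x0 = np.array([m0_guess, k_guess, t1_start])
            sol = optimize.least_squares(residuals, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol

        ss_res = float(2 * best.cost)
        rsq = 1.0 - ss_res / ss_tot
        bse = _jacobian_bse(best.jac, ss_res, ts.size)
        return ApparentT1Results(
            m0=float(best.x[0]), k=float(best.x[1]), t1_ms=float(best.x[2]),
            rsquared=rsq, experiment=self.experiment, success=bool(best.success),
            bse=bse, nobs=ts.size, message=best.message,
        )


def _jacobian_bse(jac: np.ndarray, ss_res: float, nobs: int) -> np.ndarray | None:
    """Asymptotic standard errors from the least-squares Jacobian."""
    p = jac.shape[1]
    if nobs <= p:
        return None
    try:
        cov = np.linalg.inv(jac.T @ jac) * ss_res / (nobs - p)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return None


def fit_model1(
    ts_ms: np.ndarray, amplitudes: np.ndarray, experiment: str | None = None
) -> ApparentT1Results:
    """Functional wrapper around :class:`ApparentT1Model`."""
    return ApparentT1Model(ts_ms, amplitudes, experiment=experiment).fit()


def apparent_t1_ratio(
    broadband: ApparentT1Results, selective: ApparentT1Results
) -> float:
    """Ratio of broadband to selective apparent T1; NaN if either fit failed."""
    if not (broadband.success and selective.success):
        return float("nan")
    if not (np.isfinite(broadband.t1_ms) and np.isfinite(selective.t1_ms)):
        return float("nan")
    return broadband.t1_ms / selective.t1_ms


# ---------------------------------------------------------------------------
# Model 2: simultaneous two-spin exchange fit
# ---------------------------------------------------------------------------


@dataclass
class TwoSpinExchangeResults:
    """Simultaneous two-experiment fit of the two-spin exchange model."""

    t1_a_ms: float
    sigma_ab_hz: float
    m0_a: float
    rsquared: float
    objective_value: float
    params_full: TwoSpinParams | None = None
    success: bool = True
    boundary_pinned: bool = False
    n_iterations: int = 0
    seed: int | None = None
    bse: np.ndarray | None = None  # (t1_a_ms, sigma_ab_hz, m0_a)
    nobs: int = 0
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.t1_a_ms, self.sigma_ab_hz, self.m0_a])

    def predict(self, ts_ms: np.ndarray, experiment: str) -> np.ndarray:
        return two_spin_solve(self.params_full, experiment, ts_ms)

    def summary(self) -> str:
        se = self.bse if self.bse is not None else (np.nan, np.nan, np.nan)
        lines = [
            "Two-spin exchange fit (selective + broadband)",
            "=============================================",
            f"n obs:                {self.nobs}",
            f"T1_A (corrected):     {self.t1_a_ms:.1f} ms  (se {se[0]:.3g})",
            f"sigma_AB:             {self.sigma_ab_hz:.2f} Hz  (se {se[1]:.3g})",
            f"M0_A:                 {self.m0_a:.6g}",
            f"joint R-squared:      {self.rsquared:.4f}",
            f"objective (SSR):      {self.objective_value:.6g}",
            f"basin-hopping iters:  {self.n_iterations} (seed {self.seed})",
            f"converged:            {self.success}  boundary-pinned: {self.boundary_pinned}",
        ]
        return "\n".join(lines)


class TwoSpinExchangeModel:
    """Two-pool Solomon-equation model fitted to both saturation experiments.

    The saturation efficiencies are *not* free: they are fixed to the values
    estimated by the apparent-T1 fits of the respective experiments.  The
    water T1 and the water:metabolite equilibrium-magnetization ratio are
    fixed assumptions.  Free parameters: T1_A (exchange-corrected), sigma_AB
    and the amplitude scale M0_A.

    Parameters
    ----------
    sel_ts_ms, sel_amplitudes : arrays
        Selective-saturation recovery curve (including the TS = 10 s point).
    broad_ts_ms, broad_amplitudes : arrays
        Broadband-saturation recovery curve (including the TS = 10 s point).
    k_sel, k_broad : float
        Saturation efficiencies from the Model-1 fits.
    t1_b_ms, m0_b_over_m0_a : float
        Fixed water T1 and equilibrium-magnetization ratio.
    bounds : dict, optional
        Override parameter bounds; defaults
        ``t1_a_ms (50, 10000), sigma_ab_hz (0, 100)``.
    """

    _default_bounds = {"t1_a_ms": (50.0, 10000.0), "sigma_ab_hz": (0.0, 100.0)}

    def __init__(
        self,
        sel_ts_ms: np.ndarray,
        sel_amplitudes: np.ndarray,
        broad_ts_ms: np.ndarray,
        broad_amplitudes: np.ndarray,
        k_sel: float,
        k_broad: float,
        t1_b_ms: float = WATER_T1_MS,
        m0_b_over_m0_a: float = WATER_METABOLITE_M0_RATIO,
        bounds: dict | None = None,
    ) -> None:
        self.sel_ts = np.asarray(sel_ts_ms, dtype=float)
        self.sel_y = np.asarray(sel_amplitudes, dtype=float)
        self.broad_ts = np.asarray(broad_ts_ms, dtype=float)
        self.broad_y = np.asarray(broad_amplitudes, dtype=float)
        for ts, y in ((self.sel_ts, self.sel_y), (self.broad_ts, self.broad_y)):
            if ts.shape != y.shape or ts.ndim != 1 or ts.size < 3:
                raise ValueError("each experiment needs >= 3 (TS, amplitude) points")
        self.k_sel = float(k_sel)
        self.k_broad = float(k_broad)
        self.t1_b_ms = float(t1_b_ms)
        self.m0_b_over_m0_a = float(m0_b_over_m0_a)
        b = dict(self._default_bounds)
        if bounds:
            b.update(bounds)
        self.bounds = b

    def _params(self, t1_a_ms: float, sigma_hz: float, m0_a: float) -> TwoSpinParams:
        return TwoSpinParams(
            t1_a_ms=t1_a_ms, sigma_ab_hz=sigma_hz, m0_a=m0_a,
            t1_b_ms=self.t1_b_ms, m0_b_over_m0_a=self.m0_b_over_m0_a,
            k_sel=self.k_sel, k_broad=self.k_broad,
        )

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        p = self._params(*x)
        res_sel = two_spin_solve(p, "selective", self.sel_ts) - self.sel_y
        res_broad = two_spin_solve(p, "broadband", self.broad_ts) - self.broad_y
        return np.concatenate([res_sel, res_broad])

    def fit(self, seed: int | None = 0, niter: int = 15, stepsize: float = 0.6
            ) -> TwoSpinExchangeResults:
        """Basin-hopping global minimization of the joint sum of squares.

        Deterministic for a given ``seed``.  ``niter`` basin-hopping
        iterations over an L-BFGS-B local solver in a normalized parameter
        space, followed by a bounded least-squares polish.
        """
        (t1_lo, t1_hi) = self.bounds["t1_a_ms"]
        (sg_lo, sg_hi) = self.bounds["sigma_ab_hz"]
        amp_scale = max(float(np.max(np.abs(np.concatenate([self.sel_y, self.broad_y])))),
                        1e-12)
        m0_lo, m0_hi = 1e-6 * amp_scale, 10.0 * amp_scale
        # Normalized space: x_n = (T1A/1000 ms, sigma/10 Hz, M0A/amp_scale)
        scales = np.array([1000.0, 10.0, amp_scale])
        lo = np.array([t1_lo, sg_lo, m0_lo]) / scales
        hi = np.array([t1_hi, sg_hi, m0_hi]) / scales

        def fun(xn: np.ndarray) -> float:
            r = self._residuals(np.clip(xn, lo, hi) * scales)
            return float(r @ r)

        x0 = np.array([800.0, 5.0, amp_scale]) / scales
        rng_seed = None if seed is None else int(seed) % (2**31)
        bh = optimize.basinhopping(
            fun, x0,
            minimizer_kwargs={"method": "L-BFGS-B", "bounds": list(zip(lo, hi))},
            niter=niter, stepsize=stepsize, seed=rng_seed,
        )
        x_best = np.clip(bh.x, lo, hi) * scales

        polish = optimize.least_squares(
            self._residuals, x_best,
            bounds=([t1_lo, sg_lo, m0_lo], [t1_hi, sg_hi, m0_hi]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        x = polish.x
        ssr = float(2 * polish.cost)
        y_all = np.concatenate([self.sel_y, self.broad_y])
        ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
        rsq = 1.0 - ssr / ss_tot if ss_tot > 0 else float("nan")
        tol = 1e-8
        pinned = bool(
            x[0] < t1_lo * (1 + tol) or x[0] > t1_hi * (1 - tol)
            or x[1] > sg_hi * (1 - tol)
        )
        bse = _jacobian_bse(polish.jac, ssr, y_all.size)
        return TwoSpinExchangeResults(
            t1_a_ms=float(x[0]), sigma_ab_hz=float(x[1]), m0_a=float(x[2]),
            rsquared=rsq, objective_value=ssr,
            params_full=self._params(*x),
            success=bool(polish.success) and not pinned,
            boundary_pinned=pinned, n_iterations=niter, seed=seed,
            bse=bse, nobs=y_all.size, message=str(bh.message),
        )


def fit_model2(
    sel_ts_ms: np.ndarray,
    sel_amplitudes: np.ndarray,
    broad_ts_ms: np.ndarray,
    broad_amplitudes: np.ndarray,
    k_sel: float,
    k_broad: float,
    t1_b_ms: float = WATER_T1_MS,
    m0_b_over_m0_a: float = WATER_METABOLITE_M0_RATIO,
    seed: int | None = 0,
    niter: int = 15,
) -> TwoSpinExchangeResults:
    """Functional wrapper around :class:`TwoSpinExchangeModel`."""
    model = TwoSpinExchangeModel(
        sel_ts_ms, sel_amplitudes, broad_ts_ms, broad_amplitudes,
        k_sel=k_sel, k_broad=k_broad,
        t1_b_ms=t1_b_ms, m0_b_over_m0_a=m0_b_over_m0_a,
    )
    return model.fit(seed=seed, niter=niter)
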