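"""Translational and rotational diffusion analysis of BD trajectories.

Translational diffusion is interval-dependent: D_trans(δt) =
MSD(δt)/(6 δt).  Under transient anomalous subdiffusion, MSD ∝ δt^α
with an anomality exponent α(δt) that dips below one at intermediate
intervals and returns to one at long times.  α is obtained by numerical
log-differentiation of D_trans on a geometric interval schedule,
evaluated at the logarithmic midpoints δt_mid = sqrt(δt_k δt_{k+1}),
fitted to an empirical double-exponential form, and integrated to an
asymptotic long-time coefficient D^L_trans.

Rotational diffusion comes from the body-axis autocorrelation function
θ(δt) = <e(0)·e(δt)> (averaged over the three body axes); a free
isotropic rotor decays as exp(−2 D0_rot δt).  A transiently anomalous
rotor is fitted with θ(δt) = exp(−δt/τ_rot) exp(−a (1 − e^{−δt/τ_rel})),
giving the long-time coefficient D^L_rot = 1/(2 τ_rot) and short-time
coefficient D^S_rot = (1/2)(1/τ_rot + a/τ_rel) (the δt→0 slope).

The relative viscosities η_rel^T = D0_trans/D^L_trans (translations are
measured experimentally over µs–s) and η_rel^R = D0_rot/D^S_rot
(rotations over ns) are the quantities compared with in-cell and
in-vitro measurements, along with a closed-form literature estimate
built on the concentration dependence of the macroscopic viscosity of
concentrated protein (HSA) solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .trajio import Trajectory

__all__ = [
    "DiffusionSeries", "AlphaFit", "RotFit", "ViscosityRatios",
    "LiteratureViscosityParams",
    "default_interval_schedule", "msd", "dtrans_vs_interval",
    "log_midpoints", "anomality_exponent", "fit_alpha_model",
    "alpha_model", "extrapolate_long_time_dtrans",
    "rotational_acf", "rotational_model", "fit_rotational_model",
    "viscosity_ratios", "literature_hsa_viscosity",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class DiffusionSeries:
    """Interval-dependent translational diffusion of one molecule type."""

    molecule_type: str
    dt_values: np.ndarray  # ps, strictly increasing
    d_trans: np.ndarray  # Å²/ps
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        self.dt_values = np.asarray(self.dt_values, float)
        self.d_trans = np.asarray(self.d_trans, float)
        if not np.all(np.diff(self.dt_values) > 0):
            raise ValueError("dt schedule must be strictly increasing")


@dataclass
class AlphaFit:
    """Fitted anomality-exponent model parameters."""

    alpha0: float
    a: float
    b: float
    tau_short: float  # ps
    tau_long: float  # ps
    residual: float

    def __post_init__(self):
        if not (self.tau_long > self.tau_short > 0):
            raise ValueError("need tau_long > tau_short > 0")

    def __call__(self, dt):
        return alpha_model(dt, self.alpha0, self.a, self.b,
                           self.tau_short, self.tau_long)


@dataclass
class RotFit:
    """Fitted rotational-relaxation model; θ0 is fixed at 1."""

    a: float
    tau_rot: float  # ps
    tau_rel: float  # ps
    residual: float
    theta0: float = 1.0

    def __post_init__(self):
        if not (self.tau_rot > 0 and self.tau_rel > 0):
            raise ValueError("correlation times must be > 0")

    def __call__(self, dt):
        return rotational_model(dt, self.a, self.tau_rot, self.tau_rel)

    @property
    def d_rot_long(self) -> float:
        """Long-time rotational diffusion coefficient, rad²/ps."""
        return 1.0 / (2.0 * self.tau_rot)

    @property
    def d_rot_short(self) -> float:
        """Short-time (δt→0 slope) rotational coefficient, rad²/ps."""
        return 0.5 * (1.0 / self.tau_rot + self.a / self.tau_rel)


@dataclass
class ViscosityRatios:
    """Relative viscosities seen by translation and rotation."""

    eta_T: float  # D0_trans / D^L_trans
    eta_R: float  # D0_rot / D^S_rot

    def __post_init__(self):
        if self.eta_T <= 0 or self.eta_R <= 0:
            raise ValueError("relative viscosities must be > 0")

    @property
    def ratio(self) -> float:
        return self.eta_T / self.eta_R


@dataclass
class LiteratureViscosityParams:
    """η_m/η_0 = exp(A c/(1−B c)) with power-law transl./rot. scalings."""

    A: float = 2.7e-3  # ml/mg (HSA)
    B: float = 1.3e-3  # ml/mg (HSA)
    c: float = 275.0  # mg/ml
    exponent_T: float = 1.28
    exponent_R: float = 0.44

    def __post_init__(self):
        if 1.0 - self.B * self.c <= 0:
            raise ValueError("need 1 - B c > 0")


# --------------------------------------------------------------------------
# translational analysis
# --------------------------------------------------------------------------

def default_interval_schedule(span: float) -> np.ndarray:
    """The 100, 200, 300, 600, 1000, 2000, ... ps interval ladder, up to
    (half of) the trajectory span."""
    base = np.array([1.0, 2.0, 3.0, 6.0])
    out = []
    decade = 100.0
    while True:
        for b in base:
            v = b * decade
            if v > span / 2:
                return np.array(out)
            out.append(v)
        decade *= 10


def msd(trajectory: Trajectory, molecule_type: str, dt: float) -> float:
    """Mean-squared displacement (Å²) of a type at interval dt (ps),
    averaged over all molecules of the type and all time origins."""
    spacing = trajectory.frame_spacing
    k = dt / spacing
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"dt={dt} ps is not a multiple of the frame "
                         f"spacing {spacing} ps")
    k = int(round(k))
    if k < 1 or k >= trajectory.n_frames:
        raise ValueError(f"dt={dt} ps outside the trajectory span")
    idx = trajectory.molecules_of_type(molecule_type)
    pos = trajectory.positions[:, idx, :]
    disp = pos[k:] - pos[:-k]
    return float(np.mean(np.sum(disp ** 2, axis=-1)))


def dtrans_vs_interval(trajectories, molecule_type: str,
                       schedule=None) -> DiffusionSeries:
    """D_trans(δt) = MSD(δt)/(6 δt) on an interval schedule.

    ``trajectories`` may be one trajectory or a list of replicates; with
    two or more, the replicate standard deviation is attached per point.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    span = min(t.times[-1] - t.times[0] for t in trajectories)
    if schedule is None:
        schedule = default_interval_schedule(span)
    schedule = np.asarray(schedule, float)
    if len(schedule) == 0 or schedule[-1] > span:
        raise ValueError("schedule exceeds trajectory span")
    per_rep = np.array([[msd(t, molecule_type, dt) / (6.0 * dt)
                         for dt in schedule] for t in trajectories])
    d = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if len(trajectories) >= 2 else None
    return DiffusionSeries(molecule_type=molecule_type, dt_values=schedule,
                           d_trans=d, replicate_sd=sd)


def log_midpoints(schedule) -> np.ndarray:
    """Logarithmic midpoints sqrt(δt_k δt_{k+1}), rounded to whole ps
    for reporting (100, 200 → 141; 300, 600 → 424)."""
    s = np.asarray(schedule, float)
    if len(s) < 2:
        raise ValueError("need at least 2 schedule points")
    return np.round(np.sqrt(s[:-1] * s[1:]))


def anomality_exponent(series: DiffusionSeries):
    """α at the logarithmic midpoints by numerical log-differentiation.

    α_k = 1 + [ln D(δt_{k+1}) − ln D(δt_k)]/[ln δt_{k+1} − ln δt_k].
    Returns (dt_mid, alpha, alpha_sd) with alpha_sd None when the series
    has no replicate scatter attached.
    """
    d = series.d_trans
    if np.any(d <= 0):
        raise ValueError("non-positive D_trans in series")
    dts = series.dt_values
    alpha = 1.0 + np.diff(np.log(d)) / np.diff(np.log(dts))
    sd = None
    if series.replicate_sd is not None:
        # propagate relative errors through the log-difference quotient
        rel = series.replicate_sd / d
        sd = np.sqrt(rel[:-1] ** 2 + rel[1:] ** 2) / np.diff(np.log(dts))
    return log_midpoints(dts), alpha, sd


def alpha_model(dt, alpha0, a, b, tau_short, tau_long):
    """Empirical transient-anomality form: a sets the initial dip, b the
    slow component, the taus the onset and recovery timescales."""
    dt = np.asarray(dt, float)
    es = np.exp(-dt / tau_short)
    el = np.exp(-dt / tau_long)
    return alpha0 - a * es - b * (el - es)


def fit_alpha_model(dt_mid, alpha, alpha_sd=None,
                    max_percent_error: float = 25.0) -> AlphaFit:
    """Nonlinear least-squares fit of the anomality-exponent model.

    Points are used from the shortest δt_mid up to (excluding) the first
    whose replicate percent error exceeds ``max_percent_error``, matching
    the truncation rule used when replicate scatter grows at long
    intervals.  Needs >= 5 surviving points.
    """
    dt_mid = np.asarray(dt_mid, float)
    alpha = np.asarray(alpha, float)
    n = len(dt_mid)
    if alpha_sd is not None:
        pct = 100.0 * np.abs(np.asarray(alpha_sd) / alpha)
        bad = np.where(pct > max_percent_error)[0]
        if len(bad):
            n = bad[0]
    dt_mid, alpha = dt_mid[:n], alpha[:n]
    if len(dt_mid) < 5:
        raise ValueError("need >= 5 points after truncation to fit")
    t0 = float(np.exp(np.mean(np.log(dt_mid))))

    # parametrize tau_long = tau_short * (1 + g), g > 0, so the ordering
    # invariant holds by construction
    def _model(dt, alpha0, a, b, tau_short, g):
        return alpha_model(dt, alpha0, a, b, tau_short, tau_short * (1 + g))

    lo = (0.5, 0.0, 0.0, 1e-3, 1e-6)
    hi = (1.5, 2.0, 2.0, 1e9, 1e9)
    # the short-time amplitude is effectively a−b, so the objective has
    # shallow local minima: multi-start over the timescale decades
    amp0 = max(1e-3, 1.0 - alpha.min())
    best = None
    span = dt_mid[-1] / dt_mid[0]
    for ts0 in np.geomspace(dt_mid[0] / 3.0, dt_mid[-1], 5):
        for g0 in (3.0, 30.0, 300.0):
            p0 = (1.0, amp0, amp0 / 2.0, ts0, g0)
            try:
                popt, _ = curve_fit(_model, dt_mid, alpha, p0=p0,
                                    bounds=(lo, hi), maxfev=20000)
            except RuntimeError:
                continue
            r = float(np.sqrt(np.mean((_model(dt_mid, *popt) - alpha) ** 2)))
            if best is None or r < best[0]:
                best = (r, popt)
    if best is None:
        raise RuntimeError("alpha-model fit did not converge")
    resid, (a0, a, b, ts, g) = best
    return AlphaFit(alpha0=a0, a=a, b=b, tau_short=ts,
                    tau_long=ts * (1 + g), residual=resid)


def extrapolate_long_time_dtrans(series: DiffusionSeries, fit: AlphaFit,
                                 start_dt: float = 100.0,
                                 tol: float = 1e-4,
                                 cap: float = 1e9) -> float:
    """Asymptotic long-time D_trans from the fitted α(δt).

    ln D(δt) = ln D(start) + ∫ (α(u) − 1) d ln u, integrated from the
    starting interval until the increment in ln D falls below ``tol``
    (capped at ``cap`` ps).  Raises if α does not return to 1.
    """
    from scipy.integrate import quad
    i0 = np.where(np.isclose(series.dt_values, start_dt))[0]
    if len(i0) == 0:
        raise ValueError(f"series has no D value at δt = {start_dt} ps")
    ln_d = float(np.log(series.d_trans[i0[0]]))

    def integrand(ln_u):
        return fit(np.exp(ln_u)) - 1.0

    upper = start_dt * 10.0
    total = 0.0
    prev_edge = start_dt
    while upper <= cap:
        inc, _ = quad(integrand, np.log(prev_edge), np.log(upper), limit=200)
        total += inc
        if abs(inc) < tol:
            return float(np.exp(ln_d + total))
        prev_edge = upper
        upper *= 10.0
    # final check at the cap: alpha must have relaxed back to ~1
    if abs(fit(cap) - 1.0) > 1e-3:
        raise RuntimeError("α(δt) does not return to 1; extrapolation "
                           "diverges")
    return float(np.exp(ln_d + total))


# --------------------------------------------------------------------------
# rotational analysis
# --------------------------------------------------------------------------

def rotational_acf(trajectory: Trajectory, molecule_type: str,
                   max_lag: float | None = None):
    """Axis autocorrelation θ(δt) = <e(0)·e(δt)>, averaged over the three
    body axes, molecules of the type, and all time origins.

    Returns (dt_values, theta).  θ(0) = 1 identically.
    """
    idx = trajectory.molecules_of_type(molecule_type)
    rot = trajectory.rotations[:, idx, :, :]  # (T, m, 3, 3)
    spacing = trajectory.frame_spacing
    T = trajectory.n_frames
    kmax = T - 1
    if max_lag is not None:
        kmax = min(kmax, int(round(max_lag / spacing)))
    dts = spacing * np.arange(0, kmax + 1)
    theta = np.empty(kmax + 1)
    theta[0] = 1.0
    for k in range(1, kmax + 1):
        # mean over axes of e_a(0)·e_a(dt) = trace(R0^T Rk)/3
        tr = np.einsum("tmij,tmij->tm", rot[:-k], rot[k:])
        theta[k] = float(np.mean(tr) / 3.0)
    return dts, theta


def rotational_model(dt, a, tau_rot, tau_rel):
    """θ(δt) = exp(−δt/τ_rot) · exp(−a (1 − e^{−δt/τ_rel}))."""
    dt = np.asarray(dt, float)
    return np.exp(-dt / tau_rot) * np.exp(-a * (1.0 - np.exp(-dt / tau_rel)))


def fit_rotational_model(dt_values, theta) -> RotFit:
    """Fit the transient-anomalous rotational relaxation model.

    Uniform weighting over the supplied δt range.  A pure exponential is
    recovered with a ≈ 0 (then D^S_rot = D^L_rot).
    """
    dt_values = np.asarray(dt_values, float)
    theta = np.asarray(theta, float)
    if not np.isclose(theta[0], 1.0, atol=1e-6):
        raise ValueError("θ(0) must be 1")
    pos = theta > 0
    tail = np.interp(0.36787944117, theta[pos][::-1], dt_values[pos][::-1],
                     left=dt_values[pos][-1])
    p0 = (0.1, max(tail, dt_values[1]), max(dt_values[1], tail / 100.0))
    try:
        popt, _ = curve_fit(rotational_model, dt_values, theta, p0=p0,
                            bounds=((0.0, 1e-6, 1e-6), (50.0, 1e12, 1e12)),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"rotational fit did not converge: {exc}")
    resid = float(np.sqrt(np.mean(
        (rotational_model(dt_values, *popt) - theta) ** 2)))
    return RotFit(a=popt[0], tau_rot=popt[1], tau_rel=popt[2], residual=resid)


# --------------------------------------------------------------------------
# viscosity ratios
# --------------------------------------------------------------------------

def viscosity_ratios(d0_trans: float, dl_trans: float,
                     d0_rot: float, ds_rot: float) -> ViscosityRatios:
    """Relative viscosities from the long-time translational and
    short-time rotational coefficients (the timescales experiments see)."""
    if min(d0_trans, dl_trans, d0_rot, ds_rot) <= 0:
        raise ValueError("all diffusion coefficients must be > 0")
    return ViscosityRatios(eta_T=d0_trans / dl_trans, eta_R=d0_rot / ds_rot)


def literature_hsa_viscosity(params: LiteratureViscosityParams | None = None
                             ) -> dict:
    """Closed-form literature estimate of η_rel^T, η_rel^R and their ratio.

    η_m/η_0 = exp(A c/(1−B c)); the translational and rotational relative
    viscosities are that quantity raised to the experimentally fitted
    exponents (1.28 and 0.44 for apomyoglobin in HSA).
    """
    p = params or LiteratureViscosityParams()
    eta_m_rel = float(np.exp(p.A * p.c / (1.0 - p.B * p.c)))
    eta_t = eta_m_rel ** p.exponent_T
    eta_r = eta_m_rel ** p.exponent_R
    return {"eta_m_rel": eta_m_rel, "eta_T": eta_t, "eta_R": eta_r,
            "ratio": eta_t / eta_r}
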