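"""Curve fitting for the membrane-association and aggregation assays.

Each public function fits one readout to its standard model:

* Stern-Volmer quenching: I0/I = 1 + K_sv * [Q].
* Two-state denaturant unfolding with linear baselines:
  y = [(yn + mn*x) + (yd + md*x) * e] / (1 + e),  e = exp(-(dG0 - m*x)/0.5826).
* Calcein leakage: %release = 100 * (I_F - I_B) / (I_T - I_B), and a
  single-exponential growth rate for the leakage time course.
* FCS autocorrelation (1 or 2 diffusing components sharing N and the
  structure parameter S), with Stokes-Einstein conversion of diffusion
  times to hydrodynamic radii.
* Hill-form lipid-binding isotherms (Ka = 1/L_half at the fitted h).
* ThT aggregation kinetics: Boltzmann sigmoid with a "not detectable"
  classification for flat traces.
* GUV deformation: peak-to-peak intensity of phase-contrast line profiles
  fit to a sigmoidal decay with rate lambda.
* Amide-I FTIR deconvolution: second-derivative peak picking followed by a
  Gaussian mixture fit and band-assigned secondary-structure fractions.

All fits use deterministic initial guesses derived from data quantiles, so
repeated runs are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

logger = logging.getLogger(__name__)

K_BOLTZMANN = 1.380649e-23  # J/K
RT_UNFOLD = 0.5826  # kcal mol^-1, fixed denominator of the two-state fit

# amide-I band windows (cm^-1) for secondary-structure assignment
BAND_WINDOWS = {
    "beta": (1627.0, 1641.0),
    "disorder": (1641.0, 1648.0),
    "helix": (1648.0, 1660.0),
    "turns_loops": (1660.0, 1680.0),
}


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SternVolmerResult:
    K_sv: float  # M^-1
    intercept: float  # diagnostic; the model fixes it at 1
    residual_norm: float
    stderr: float | None = None


@dataclass
class UnfoldingFitResult:
    dG0: float  # kcal/mol
    m: float  # kcal mol^-1 M^-1
    yn: float
    mn: float
    yd: float
    md: float
    residual_norm: float = 0.0
    RT_const: float = RT_UNFOLD

    @property
    def Cm(self) -> float:
        return self.dG0 / abs(self.m)


@dataclass
class LeakageResult:
    percent_release: np.ndarray
    rate: float  # s^-1
    flat: bool = False


@dataclass
class FcsComponent:
    fraction: float
    tau_D: float  # s


@dataclass
class FcsFitResult:
    N: float
    components: list[FcsComponent]
    S: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    residual_norm: float = 0.0

    def diffusion_coefficients(self, omega: float) -> list[float]:
        """D = omega^2 / (4 tau_D) per component, m^2/s."""
        return [omega**2 / (4.0 * c.tau_D) for c in self.components]

    def hydrodynamic_radii(self, omega: float, T: float, eta: float) -> list[float]:
        return [
            hydrodynamic_radius(c.tau_D, omega, T, eta) for c in self.components
        ]


@dataclass
class BindingFitResult:
    Ka: float  # M^-1
    hill: float
    bound_fraction: np.ndarray
    saturated: bool = True
    residual_norm: float = 0.0


@dataclass
class KineticsFitResult:
    t50: float | None  # midpoint (h for ThT, s for GUV)
    lag: float | None
    growth_rate: float | None  # 1/tau of the sigmoid
    plateau: float | None
    baseline: float | None
    detectable: bool = True
    lambda_rate: float | None = None  # GUV deformation rate, s^-1
    residual_norm: float = 0.0

    @property
    def label(self) -> str:
        return f"{self.t50:.1f}" if self.detectable else "Not detectable"


@dataclass
class FtirDeconvolution:
    peak_positions: list[float]  # cm^-1, second-derivative minima
    gaussians: list[tuple[float, float, float]]  # (center, width, area)
    fractions: dict[str, float]  # percent beta / helix / disorder_turns_loops


# ---------------------------------------------------------------------------
# Eq. 1: Stern-Volmer


def stern_volmer_fit(Q, I0_over_I) -> SternVolmerResult:
    """Least-squares line through (Q, I0/I); K_sv is the slope (M^-1)."""
    Q = np.asarray(Q, dtype=float)
    y = np.asarray(I0_over_I, dtype=float)
    if Q.size < 3:
        raise ValueError("Stern-Volmer fit needs at least 3 points")
    fit = linregress(Q, y)
    resid = y - (fit.intercept + fit.slope * Q)
    return SternVolmerResult(
        K_sv=float(fit.slope),
        intercept=float(fit.intercept),
        residual_norm=float(np.linalg.norm(resid)),
        stderr=float(fit.stderr) if fit.stderr is not None else None,
    )


def quench_ratio(K_sv: float, K_svm: float) -> tuple[float, float]:
    """K_sv/K_svm in free vs membrane-bound conditions.

    Returns ``(raw, rounded-to-2-dp)``; the rounded value mirrors how the
    ratio is tabulated."""
    if K_svm <= 0:
        raise ValueError("K_svm must be positive")
    raw = K_sv / K_svm
    return raw, round(raw, 2)


# ---------------------------------------------------------------------------
# Eq. 2: two-state denaturant unfolding


def _two_state(x, dG0, m, yn, mn, yd, md):
    e = np.exp(-(dG0 - m * x) / RT_UNFOLD)
    return ((yn + mn * x) + (yd + md * x) * e) / (1.0 + e)


def two_state_unfolding_fit(x, y) -> UnfoldingFitResult:
    """Nonlinear two-state fit of a denaturant melt.

    dG0 (kcal/mol) and m (kcal mol^-1 M^-1) are both positive for a
    cooperative unfolder; the transition midpoint is Cm = dG0/m."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 8:
        raise ValueError("two-state fit needs at least 8 points")
    if np.ptp(y) <= 0 or np.allclose(y, y[0]):
        raise ValueError("no transition in data (flat signal)")

    # deterministic initialization from quantiles
    y_lo, y_hi = float(np.median(y[x <= np.quantile(x, 0.2)])), float(
        np.median(y[x >= np.quantile(x, 0.8)])
    )
    # midpoint guess: x where y crosses the mean of the two baselines
    mid_level = 0.5 * (y_lo + y_hi)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    crossings = np.nonzero(np.diff(np.sign(ys - mid_level)))[0]
    Cm0 = float(xs[crossings[0]]) if crossings.size else float(np.median(x))
    m0 = 2.0
    model = lmfit.Model(_two_state)
    params = model.make_params(
        dG0=dict(value=m0 * max(Cm0, 0.1), min=1e-3),
        m=dict(value=m0, min=1e-3),
        yn=dict(value=y_lo),
        mn=dict(value=0.0),
        yd=dict(value=y_hi),
        md=dict(value=0.0),
    )
    res = model.fit(y, params, x=x)
    if not res.success:
        raise RuntimeError(f"two-state fit did not converge: {res.message}")
    v = res.best_values
    return UnfoldingFitResult(
        dG0=v["dG0"], m=v["m"], yn=v["yn"], mn=v["mn"], yd=v["yd"], md=v["md"],
        residual_norm=float(np.linalg.norm(res.residual)),
    )


# ---------------------------------------------------------------------------
# Eq. 3: calcein release and leakage kinetics


def calcein_release(I_B, I_F, I_T) -> float:
    """Percent calcein release 100*(I_F - I_B)/(I_T - I_B)."""
    if I_T <= I_B:
        raise ValueError("total-release intensity I_T must exceed background I_B")
    return 100.0 * (I_F - I_B) / (I_T - I_B)


def leakage_rate(t, F, flat_rtol: float = 1e-3) -> LeakageResult:
    """Single-exponential growth rate of a leakage time course.

    Fits F(t) = F0 + A*(1 - exp(-k*t)); returns rate k (s^-1).  A trace whose
    span is below ``flat_rtol`` of its mean is reported flat with rate 0."""
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    span = float(np.ptp(F))
    scale = max(abs(float(np.mean(F))), 1e-12)
    if span <= flat_rtol * scale:
        logger.warning("flat leakage trace; rate set to 0")
        return LeakageResult(percent_release=np.zeros_like(F), rate=0.0, flat=True)

    def model(t, F0, A, k):
        return F0 + A * (1.0 - np.exp(-k * t))

    half = F[0] + 0.5 * span
    above = np.nonzero(F >= half)[0]
    t_half = float(t[above[0]]) if above.size else float(np.median(t))
    k0 = math.log(2.0) / max(t_half, np.diff(t).min())
    m = lmfit.Model(model)
    params = m.make_params(
        F0=dict(value=float(F[0])),
        A=dict(value=span, min=0),
        k=dict(value=k0, min=1e-12),
    )
    res = m.fit(F, params, t=t)
    v = res.best_values
    pct = 100.0 * (F - v["F0"]) / max(v["A"], 1e-12)
    return LeakageResult(percent_release=pct, rate=float(v["k"]))


# ---------------------------------------------------------------------------
# Eqs. 4-6: FCS


def fcs_model(tau, N, fractions, tau_Ds, S):
    """Multi-component 3-D diffusion autocorrelation sharing one N and S.

    G(tau) = 1 + (1/N) * sum_i f_i * (1 + tau/tau_Di)^-1
                              * (1 + tau/(S^2 tau_Di))^-1/2
    """
    tau = np.asarray(tau, dtype=float)
    g = np.zeros_like(tau)
    for f, tD in zip(fractions, tau_Ds):
        g = g + f / ((1.0 + tau / tD) * np.sqrt(1.0 + tau / (S**2 * tD)))
    return 1.0 + g / N


def fcs_fit(tau, G, n_components: int = 1, S_fixed: float | None = None) -> FcsFitResult:
    """Fit an FCS autocorrelation curve with 1 or 2 diffusing components."""
    tau = np.asarray(tau, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau values must be positive")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    amp0 = max(float(G[np.argmin(tau)]) - 1.0, 1e-6)
    N0 = 1.0 / amp0
    # tau where G - 1 falls to half its zero-lag amplitude
    dec = G - 1.0
    half_idx = np.nonzero(dec <= 0.5 * amp0)[0]
    tD0 = float(tau[half_idx[0]]) if half_idx.size else float(np.median(tau))

    params = lmfit.Parameters()
    params.add("N", value=N0, min=1e-6)
    if S_fixed is not None:
        params.add("S", value=float(S_fixed), vary=False)
    else:
        params.add("S", value=5.0, min=1.0, max=100.0)
    if n_components == 1:
        params.add("tau_D1", value=tD0, min=tau.min() / 100, max=tau.max() * 100)

        def resid(p):
            return fcs_model(tau, p["N"], [1.0], [p["tau_D1"]], p["S"]) - G

    else:
        params.add("f1", value=0.5, min=0.0, max=1.0)
        params.add("tau_D1", value=tD0 / 5, min=tau.min() / 100, max=tau.max() * 100)
        params.add("tau_D2", value=tD0 * 5, min=tau.min() / 100, max=tau.max() * 100)

        def resid(p):
            return (
                fcs_model(
                    tau,
                    p["N"],
                    [p["f1"], 1.0 - p["f1"]],
                    [p["tau_D1"], p["tau_D2"]],
                    p["S"],
                )
                - G
            )

    out = lmfit.minimize(resid, params, method="leastsq")
    v = out.params
    if n_components == 1:
        comps = [FcsComponent(fraction=1.0, tau_D=float(v["tau_D1"]))]
    else:
        comps = [
            FcsComponent(fraction=float(v["f1"]), tau_D=float(v["tau_D1"])),
            FcsComponent(fraction=1.0 - float(v["f1"]), tau_D=float(v["tau_D2"])),
        ]
        comps.sort(key=lambda c: c.tau_D)
        ratio = comps[1].tau_D / comps[0].tau_D
        if ratio < 3.0:
            warnings.warn(
                f"diffusion times separated by only {ratio:.2f}x; "
                "component fractions are poorly identifiable",
                stacklevel=2,
            )
    residuals = np.asarray(out.residual)
    return FcsFitResult(
        N=float(v["N"]),
        components=comps,
        S=float(v["S"]),
        residuals=residuals,
        residual_norm=float(np.linalg.norm(residuals)),
    )


def hydrodynamic_radius(tau_D: float, omega: float, T: float, eta: float) -> float:
    """Stokes-Einstein radius (A) from a diffusion time.

    D = omega^2/(4 tau_D) with omega the observation-volume radius (m), then
    r_H = kT/(6 pi eta D)."""
    if min(tau_D, omega, T, eta) <= 0:
        raise ValueError("all arguments must be positive")
    D = omega**2 / (4.0 * tau_D)
    r_m = K_BOLTZMANN * T / (6.0 * math.pi * eta * D)
    return r_m * 1e10


def diffusion_time(r_H_angstrom: float, omega: float, T: float, eta: float) -> float:
    """Inverse of :func:`hydrodynamic_radius`: tau_D (s) for a given radius."""
    D = K_BOLTZMANN * T / (6.0 * math.pi * eta * r_H_angstrom * 1e-10)
    return omega**2 / (4.0 * D)


# ---------------------------------------------------------------------------
# lipid binding isotherm


def binding_isotherm_fit(lipid, bound_percent) -> BindingFitResult:
    """Hill-form fit of membrane-bound percentage vs lipid concentration.

    bound = 100 * (Ka*L)^h / (1 + (Ka*L)^h); Ka is 1/L_half at the fitted h.
    """
    L = np.asarray(lipid, dtype=float)
    b = np.asarray(bound_percent, dtype=float)
    if L.size < 5:
        raise ValueError("binding fit needs at least 5 points")
    if np.all(b <= 0):
        raise ValueError("bound fraction is zero everywhere; nothing to fit")

    def model(L, Ka, h):
        z = np.power(np.maximum(Ka * L, 0.0), h)
        return 100.0 * z / (1.0 + z)

    half_idx = np.nonzero(b >= 50.0)[0]
    L_half0 = float(L[half_idx[0]]) if half_idx.size else float(np.median(L[L > 0]))
    m = lmfit.Model(model)
    params = m.make_params(
        Ka=dict(value=1.0 / L_half0, min=1e-3),
        h=dict(value=1.0, min=0.5, max=4.0),
    )
    res = m.fit(b, params, L=L)
    saturated = bool(b.max() >= 80.0)
    if not saturated:
        warnings.warn(
            "binding data do not reach saturation; Ka is poorly constrained",
            stacklevel=2,
        )
    v = res.best_values
    return BindingFitResult(
        Ka=float(v["Ka"]),
        hill=float(v["h"]),
        bound_fraction=model(L, v["Ka"], v["h"]) / 100.0,
        saturated=saturated,
        residual_norm=float(np.linalg.norm(res.residual)),
    )


# ---------------------------------------------------------------------------
# ThT aggregation kinetics


def _boltzmann(t, F0, Finf, t50, tau):
    z = np.clip((t50 - t) / tau, -500.0, 500.0)
    return F0 + (Finf - F0) / (1.0 + np.exp(z))


def tht_kinetics_fit(
    t, F, noise_sigma_factor: float = 3.0
) -> KineticsFitResult:
    """Boltzmann sigmoid fit of a ThT trace; lag = t50 - 2*tau.

    Traces whose fitted amplitude is below ``noise_sigma_factor`` times the
    standard deviation of the first 10% of points are classified as
    "Not detectable" (no aggregation), mirroring how flat traces are
    tabulated."""
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    if t.size < 10:
        raise ValueError("ThT fit needs at least 10 points")
    n_head = max(3, t.size // 10)
    noise = float(np.std(F[:n_head]))
    amp = float(np.ptp(F))
    if amp <= noise_sigma_factor * max(noise, 1e-12) or amp == 0.0:
        return KineticsFitResult(
            t50=None, lag=None, growth_rate=None, plateau=None,
            baseline=float(np.mean(F)), detectable=False,
        )

    half = F.min() + 0.5 * amp
    above = np.nonzero(F >= half)[0]
    t50_0 = float(t[above[0]]) if above.size else float(np.median(t))
    tau0 = max(float(np.ptp(t)) / 20.0, 1e-6)
    m = lmfit.Model(_boltzmann)
    params = m.make_params(
        F0=dict(value=float(np.median(F[:n_head]))),
        Finf=dict(value=float(np.median(F[-n_head:]))),
        t50=dict(value=t50_0, min=float(t.min()), max=float(t.max()) * 2),
        tau=dict(value=tau0, min=1e-9),
    )
    res = m.fit(F, params, t=t)
    v = res.best_values
    fitted_amp = abs(v["Finf"] - v["F0"])
    if fitted_amp <= noise_sigma_factor * max(noise, 1e-12):
        return KineticsFitResult(
            t50=None, lag=None, growth_rate=None, plateau=None,
            baseline=float(np.mean(F)), detectable=False,
        )
    return KineticsFitResult(
        t50=float(v["t50"]),
        lag=float(v["t50"] - 2.0 * v["tau"]),
        growth_rate=float(1.0 / v["tau"]),
        plateau=float(v["Finf"]),
        baseline=float(v["F0"]),
        detectable=True,
        residual_norm=float(np.linalg.norm(res.residual)),
    )


# ---------------------------------------------------------------------------
# GUV deformation


def peak_to_peak(profile) -> float:
    """I_ptp of one line profile: halo maximum minus interior minimum."""
    p = np.asarray(profile, dtype=float)
    return float(p.max() - p.min())


def guv_deformation(
    t, profile_stack, min_lines: int = 1, flat_rtol: float = 1e-3
) -> KineticsFitResult:
    """Deformation rate lambda (s^-1) from phase-contrast line profiles.

    ``profile_stack`` maps each time point to >= ``min_lines`` line-intensity
    arrays crossing the vesicle rim; I_ptp(t) is the max-minus-min of each
    profile averaged over lines, and lambda comes from a sigmoidal-decay fit
    of I_ptp(t).  Time points whose profiles have no halo structure (zero
    peak-to-peak span) are dropped with a log message."""
    t = np.asarray(t, dtype=float)
    iptp, kept_t = [], []
    for ti, profiles in zip(t, profile_stack):
        vals = [peak_to_peak(p) for p in profiles]
        if len(vals) < min_lines:
            logger.warning("time %.3g s: fewer than %d line profiles; dropped", ti, min_lines)
            continue
        iptp.append(float(np.mean(vals)))
        kept_t.append(ti)
    iptp = np.asarray(iptp)
    kept_t = np.asarray(kept_t)
    if iptp.size < 4:
        raise ValueError("too few usable time points for a deformation fit")

    span = float(np.ptp(iptp))
    scale = max(abs(float(np.mean(iptp))), 1e-12)
    if span <= flat_rtol * scale:
        return KineticsFitResult(
            t50=None, lag=None, growth_rate=None,
            plateau=float(iptp[-1]), baseline=float(iptp[0]),
            detectable=False, lambda_rate=0.0,
        )

    def decay(t, I0, Iinf, t50, lam):
        return Iinf + (I0 - Iinf) / (1.0 + np.exp(lam * (t - t50)))

    half = iptp.min() + 0.5 * span
    below = np.nonzero(iptp <= half)[0]
    t50_0 = float(kept_t[below[0]]) if below.size else float(np.median(kept_t))
    m = lmfit.Model(decay)
    params = m.make_params(
        I0=dict(value=float(iptp[0])),
        Iinf=dict(value=float(iptp[-1])),
        t50=dict(value=t50_0),
        lam=dict(value=4.0 / max(float(np.ptp(kept_t)), 1e-9), min=1e-12),
    )
    res = m.fit(iptp, params, t=kept_t)
    v = res.best_values
    return KineticsFitResult(
        t50=float(v["t50"]),
        lag=None,
        growth_rate=None,
        plateau=float(v["Iinf"]),
        baseline=float(v["I0"]),
        detectable=True,
        lambda_rate=float(v["lam"]),
        residual_norm=float(np.linalg.norm(res.residual)),
    )


# ---------------------------------------------------------------------------
# FTIR amide-I deconvolution


def _band_of(center: float) -> str | None:
    for band, (lo, hi) in BAND_WINDOWS.items():
        if lo <= center < hi:
            return band
    return None


def ftir_deconvolve(
    wavenumber,
    absorbance,
    center_bound: float = 4.0,
    smooth_window: int = 13,
    min_depth_fraction: float = 0.05,
    peak_window: tuple[float, float] = (1615.0, 1690.0),
) -> FtirDeconvolution:
    """Amide-I (1600-1700 cm^-1) secondary-structure deconvolution.

    Peak positions are the minima of the smoothed second derivative of the
    spectrum; a Gaussian mixture with centers bounded to +/- ``center_bound``
    cm^-1 of those positions is then fit to the raw spectrum, and band areas
    are pooled into beta sheet (1633-1638 region), alpha helix (1649-1656),
    and disorder + turns/loops (1644 and 1665-1672) percentages.
    """
    w = np.asarray(wavenumber, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    order = np.argsort(w)
    w, a = w[order], a[order]
    sel = (w >= 1600.0) & (w <= 1700.0)
    if w[sel].size < 15 or w.min() > 1605 or w.max() < 1695:
        raise ValueError("spectrum must cover the amide-I region 1600-1700 cm^-1")
    w, a = w[sel], a[sel]

    win = min(smooth_window if smooth_window % 2 else smooth_window + 1, len(w) - 1)
    if win < 5:
        raise ValueError("too few spectral points")
    d2 = savgol_filter(a, window_length=win, polyorder=3, deriv=2)
    # second-derivative minima = absorbance band centers; a depth filter
    # rejects shallow noise minima and the edges of the fitted window are
    # excluded where the derivative is unreliable
    interior = np.arange(1, len(w) - 1)
    is_min = (d2[interior] < d2[interior - 1]) & (d2[interior] <= d2[interior + 1])
    depth = -d2[interior]
    deep = depth >= min_depth_fraction * depth.max()
    in_window = (w[interior] >= peak_window[0]) & (w[interior] <= peak_window[1])
    centers0 = w[interior[is_min & deep & in_window & (d2[interior] < 0)]]
    if centers0.size == 0:
        raise ValueError("no second-derivative minima found in the amide-I region")

    model = None
    params = lmfit.Parameters()
    span = float(np.ptp(w))
    for k, c0 in enumerate(centers0):
        g = lmfit.models.GaussianModel(prefix=f"g{k}_")
        model = g if model is None else model + g
        params.add(f"g{k}_center", value=float(c0), min=c0 - center_bound, max=c0 + center_bound)
        params.add(f"g{k}_sigma", value=4.0, min=1.0, max=span / 2)
        params.add(f"g{k}_amplitude", value=float(max(a.max(), 1e-9) * 8.0 / len(centers0)), min=0.0)
    res = model.fit(a, params, x=w)

    gaussians, areas = [], {}
    for k in range(len(centers0)):
        c = float(res.params[f"g{k}_center"])
        s = float(res.params[f"g{k}_sigma"])
        area = float(res.params[f"g{k}_amplitude"])  # lmfit amplitude == area
        gaussians.append((c, s, area))
        band = _band_of(c)
        if band is None:
            logger.warning("Gaussian at %.1f cm^-1 outside known bands; pooled as other", c)
            band = "turns_loops"
        areas[band] = areas.get(band, 0.0) + area

    total = sum(areas.values())
    if total <= 0:
        raise ValueError("deconvolution produced zero total band area")
    frac = {b: 100.0 * v / total for b, v in areas.items()}
    fractions = {
        "beta": frac.get("beta", 0.0),
        "helix": frac.get("helix", 0.0),
        "disorder_turns_loops": frac.get("disorder", 0.0) + frac.get("turns_loops", 0.0),
    }
    return FtirDeconvolution(
        peak_positions=[float(c) for c in centers0],
        gaussians=gaussians,
        fractions=fractions,
    )
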