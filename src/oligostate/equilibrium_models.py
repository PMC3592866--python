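"""Equilibrium thermodynamic models of a homodimer.

Two fits:

* a two-state thermal unfolding transition N2 <-> 2U (folded dimer to two
  unfolded monomers) with van't Hoff temperature dependence and linear
  native/unfolded baselines, fitted to a melt curve; and
* a single-species sedimentation-equilibrium model, c(r) = baseline +
  c_ref · exp[ M (1 − v̄ρ) ω² (r² − r_ref²) / (2RT) ], fitted globally over
  rotor speeds with one shared molar mass.

Conventions: the melting temperature Tm is the temperature where the
unfolded fraction fU equals 1/2 at the stated total monomer concentration
Ct, equivalent to K(Tm) = Ct for the N2 <-> 2U mass-action law
K = [U]²/[N2] = 2 Ct fU²/(1 − fU). Dimer melts are concentration
dependent; Ct is part of the model, not a nuisance. ΔCp is fixed at zero
(pure van't Hoff) unless supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "R_GAS",
    "TwoStateDimerFit",
    "SedimentationProfile",
    "SedimentationFit",
    "MeltCurve",
    "dimer_unfolded_fraction",
    "monomer_unfolded_fraction",
    "melt_signal",
    "fit_two_state_dimer_melt",
    "sedimentation_profile",
    "fit_sedimentation",
]

R_GAS = 8.31446261815324  # J mol^-1 K^-1


@dataclass
class MeltCurve:
    """A thermal denaturation trace: signal vs temperature (K)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")

    @classmethod
    def from_csv(cls, path) -> "MeltCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["temp_K"].to_numpy(), df["signal"].to_numpy())


def dimer_unfolded_fraction(
    temperature: float | np.ndarray,
    delta_h: float,
    t_m: float,
    total_monomer_conc: float,
    reference_conc: Optional[float] = None,
) -> float | np.ndarray:
    """Unfolded fraction fU(T) of the N2 <-> 2U transition.

    ``delta_h`` in J/mol, ``t_m`` in K, ``total_monomer_conc`` (Ct) in M.
    Solves 2 Ct fU² / (1 − fU) = K(T) with van't Hoff
    K(T) = K(Tm) · exp[−(ΔH/R)(1/T − 1/Tm)] and K(Tm) = reference_conc
    (default Ct, which anchors fU(Tm) = 1/2 at that concentration), taking
    the unique root of the quadratic in (0, 1):
    fU = (−K + sqrt(K² + 8 K Ct)) / (4 Ct). Passing ``reference_conc``
    different from Ct evaluates the same transition (Tm stated at the
    reference concentration) at another total concentration, exposing the
    concentration dependence characteristic of dimer melts.
    """
    T = np.asarray(temperature, dtype=float)
    if t_m <= 0 or total_monomer_conc <= 0:
        raise ValueError("t_m and total_monomer_conc must be positive")
    ct = total_monomer_conc
    k_tm = reference_conc if reference_conc is not None else ct
    # K/Ct kept as the working variable for numerical range safety
    ln_k_over_ct = np.log(k_tm / ct) - (delta_h / R_GAS) * (1.0 / T - 1.0 / t_m)
    k_over_ct = np.exp(np.clip(ln_k_over_ct, -700, 700))
    fu = (-k_over_ct + np.sqrt(k_over_ct**2 + 8.0 * k_over_ct)) / 4.0
    fu = np.clip(fu, 0.0, 1.0)
    return float(fu) if np.isscalar(temperature) else fu


def monomer_unfolded_fraction(
    temperature: float | np.ndarray, delta_h: float, t_m: float
) -> float | np.ndarray:
    """Unfolded fraction of a monomolecular two-state transition N <-> U
    (concentration independent); provided for comparison with the
    dimer-coupled default."""
    T = np.asarray(temperature, dtype=float)
    k = np.exp(np.clip(-(delta_h / R_GAS) * (1.0 / T - 1.0 / t_m), -700, 700))
    fu = k / (1.0 + k)
    return float(fu) if np.isscalar(temperature) else fu


def melt_signal(
    temperature: np.ndarray,
    delta_h: float,
    t_m: float,
    native_intercept: float,
    native_slope: float,
    unfolded_intercept: float,
    unfolded_slope: float,
    total_monomer_conc: float,
    coupling: str = "dimer",
) -> np.ndarray:
    """Observed melt signal: baseline-weighted two-state transition."""
    T = np.asarray(temperature, dtype=float)
    if coupling == "dimer":
        fu = dimer_unfolded_fraction(T, delta_h, t_m, total_monomer_conc)
    elif coupling == "monomer":
        fu = monomer_unfolded_fraction(T, delta_h, t_m)
    else:
        raise ValueError("coupling must be 'dimer' or 'monomer'")
    native = native_intercept + native_slope * T
    unfolded = unfolded_intercept + unfolded_slope * T
    return (1.0 - fu) * native + fu * unfolded


@dataclass
class TwoStateDimerFit:
    delta_h: float  # J/mol
    t_m: float  # K
    native_baseline: tuple[float, float]  # intercept, slope
    unfolded_baseline: tuple[float, float]
    total_monomer_conc: float  # M
    covariance: np.ndarray  # order: delta_h, t_m, aN, bN, aU, bU
    coupling: str = "dimer"

    @property
    def delta_h_kj(self) -> float:
        return self.delta_h / 1e3

    @property
    def t_m_sd(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


def _melt_initial_guess(T: np.ndarray, y: np.ndarray) -> tuple[float, float, tuple, tuple]:
    n = len(T)
    # a single global line explaining the data means no transition
    a_all, b_all = _line(T, y)
    resid = y - (a_all + b_all * T)
    if np.sqrt(np.mean(resid**2)) < 0.02 * max(float(np.ptp(y)), 1e-30):
        raise ValueError("no unfolding transition detected; fit baselines only")
    k = max(2, n // 10)
    aN, bN = _line(T[:k], y[:k])
    aU, bU = _line(T[-k:], y[-k:])
    # transition midpoint from the smoothed derivative of the normalised signal
    base_n = aN + bN * T
    base_u = aU + bU * T
    denom = base_u - base_n
    denom = np.where(np.abs(denom) < 1e-12 * max(1.0, np.abs(denom).max()), np.nan, denom)
    frac = (y - base_n) / denom
    frac = np.clip(np.nan_to_num(frac, nan=0.5), -0.2, 1.2)
    w = max(3, n // 20)
    kernel = np.ones(w) / w
    smooth = np.convolve(frac, kernel, mode="same")
    dfrac = np.gradient(smooth, T)
    if dfrac.max() <= 1e-6:
        raise ValueError("no unfolding transition detected; fit baselines only")
    i_mid = int(np.argmax(dfrac))
    t_m0 = float(T[i_mid])
    # van't Hoff width rule: dfU/dT at Tm ~ ΔH/(6RTm²) for the dimer model
    dh0 = float(np.clip(6.0 * R_GAS * t_m0**2 * dfrac[i_mid], 5e4, 3e6))
    return t_m0, dh0, (aN, bN), (aU, bU)


def _line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def fit_two_state_dimer_melt(
    curve: MeltCurve,
    total_monomer_conc: float,
    coupling: str = "dimer",
) -> TwoStateDimerFit:
    """Non-linear least-squares fit of a two-state melt with linear
    baselines. Initialisation: baselines from the terminal 10% of points,
    Tm from the maximum of the smoothed derivative, ΔH from its height."""
    T, y = curve.temperature, curve.signal
    if len(T) < 20:
        raise ValueError("need at least 20 temperature points")
    t_m0, dh0, (aN, bN), (aU, bU) = _melt_initial_guess(T, y)

    def fmodel(Tx, dh, tm, a_n, b_n, a_u, b_u):
        return melt_signal(Tx, dh, tm, a_n, b_n, a_u, b_u, total_monomer_conc, coupling)

    p0 = [dh0, t_m0, aN, bN, aU, bU]
    popt, pcov = curve_fit(
        fmodel,
        T,
        y,
        p0=p0,
        bounds=(
            [1e3, T.min(), -np.inf, -np.inf, -np.inf, -np.inf],
            [1e7, T.max(), np.inf, np.inf, np.inf, np.inf],
        ),
        maxfev=20000,
    )
    return TwoStateDimerFit(
        delta_h=float(popt[0]),
        t_m=float(popt[1]),
        native_baseline=(float(popt[2]), float(popt[3])),
        unfolded_baseline=(float(popt[4]), float(popt[5])),
        total_monomer_conc=total_monomer_conc,
        covariance=pcov,
        coupling=coupling,
    )


# ---------------------------------------------------------------------------
# Sedimentation equilibrium
# ---------------------------------------------------------------------------

@dataclass
class SedimentationProfile:
    """One radial concentration profile at one rotor speed."""

    radius: np.ndarray  # cm
    concentration: np.ndarray  # AU
    rotor_speed: float  # rad/s
    reference_radius: Optional[float] = None  # cm; defaults to first radius

    def __post_init__(self) -> None:
        self.radius = np.asarray(self.radius, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.radius.shape != self.concentration.shape:
            raise ValueError("radius and concentration must have equal length")
        if self.reference_radius is None:
            self.reference_radius = float(self.radius[0])


def reduced_buoyant_mass(
    molar_mass: float, vbar: float, density: float, rotor_speed: float, temperature: float
) -> float:
    """σ = M (1 − v̄ρ) ω² / (R T) in cm⁻² when radius is in cm.

    ``molar_mass`` g/mol, ``vbar`` mL/g, ``density`` g/mL, ``rotor_speed``
    rad/s, ``temperature`` K. R is expressed in erg/(mol·K) so that σ r²
    is dimensionless with r in cm.
    """
    buoyancy = 1.0 - vbar * density
    if not 0.0 < buoyancy < 1.0:
        raise ValueError("need 0 < 1 - vbar*density < 1 (positive buoyancy)")
    r_cgs = R_GAS * 1e7  # erg / (mol K)
    return molar_mass * buoyancy * rotor_speed**2 / (r_cgs * temperature)


def sedimentation_profile(
    radius: np.ndarray,
    molar_mass: float,
    vbar: float,
    density: float,
    rotor_speed: float,
    temperature: float,
    reference_radius: float,
    reference_conc: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Single-species equilibrium profile c(r) = baseline + c_ref ·
    exp[σ (r² − r_ref²)/2]."""
    r = np.asarray(radius, dtype=float)
    sigma = reduced_buoyant_mass(molar_mass, vbar, density, rotor_speed, temperature)
    return baseline + reference_conc * np.exp(sigma * (r**2 - reference_radius**2) / 2.0)


@dataclass
class SedimentationFit:
    molar_mass: float  # Da
    molar_mass_sd: float
    reference_concs: list[float]
    baselines: list[float]
    vbar: float
    density: float
    temperature: float
    rotor_speeds: list[float]
    covariance: np.ndarray


def fit_sedimentation(
    profiles: Sequence[SedimentationProfile],
    vbar: float,
    density: float,
    temperature: float,
) -> SedimentationFit:
    """Global single-species fit: one shared molar mass, per-profile
    reference concentration (log-parameterised for positivity) and
    baseline. Initialised from a linearised ln(c − baseline) vs r²/2 fit.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles:
        if len(p.radius) < 20:
            raise ValueError("each profile needs at least 20 radial points")

    # linearised initial guess from the first profile
    p0 = profiles[0]
    base0 = float(p0.concentration.min()) - 1e-3 * float(np.ptp(p0.concentration))
    c = p0.concentration - base0
    if np.any(np.diff(c) < 0):
        warnings.warn("non-monotone profile after baseline subtraction")
    c = np.clip(c, 1e-12, None)
    slope, intercept = np.polyfit(p0.radius**2 / 2.0, np.log(c), 1)
    buoyancy = 1.0 - vbar * density
    m0 = float(slope * (R_GAS * 1e7) * temperature / (buoyancy * p0.rotor_speed**2))
    m0 = float(np.clip(m0, 500.0, 1e7))

    n = len(profiles)

    def unpack(theta):
        m = theta[0]
        lncs = theta[1 : 1 + n]
        bases = theta[1 + n :]
        return m, np.exp(lncs), bases

    def residuals(theta):
        m, crefs, bases = unpack(theta)
        out = []
        for p, cr, b in zip(profiles, crefs, bases):
            model = sedimentation_profile(
                p.radius, m, vbar, density, p.rotor_speed, temperature,
                p.reference_radius, cr, b,
            )
            out.append(model - p.concentration)
        return np.concatenate(out)

    theta0 = np.concatenate(
        [
            [m0],
            [
                np.log(
                    max(
                        float(
                            np.interp(p.reference_radius, p.radius, p.concentration)
                        )
                        - base0,
                        1e-9,
                    )
                )
                for p in profiles
            ],
            [base0] * n,
        ]
    )
    sol = least_squares(residuals, theta0, method="lm", max_nfev=20000)
    m, crefs, bases = unpack(sol.x)
    if m <= 0:
        raise ValueError("fitted molar mass is non-positive")
    # covariance from the Jacobian at the solution
    dof = max(sum(len(p.radius) for p in profiles) - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        m_sd = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        cov = np.full((len(sol.x), len(sol.x)), np.nan)
        m_sd = float("nan")
    return SedimentationFit(
        molar_mass=float(m),
        molar_mass_sd=m_sd,
        reference_concs=[float(c) for c in crefs],
        baselines=[float(b) for b in bases],
        vbar=vbar,
        density=density,
        temperature=temperature,
        rotor_speeds=[p.rotor_speed for p in profiles],
        covariance=cov,
    )
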