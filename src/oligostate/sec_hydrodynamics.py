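"""Analytical size-exclusion chromatography (SEC) hydrodynamics.

Calibrates analytical SEC columns from standards of known molecular weight
(and optionally Stokes radius), converts elution volumes into partition
coefficients, apparent molecular weights (AMW), apparent Stokes radii and
apparent aggregation numbers (AAN), classifies oligomeric state, and
estimates the dimer fraction of unresolved two-state mixtures.

The calibration model is the classical pair of linear plots

    Mr^(1/3)  vs  x,   and   Rs  vs  x,   with   x = sqrt(-log10 Kav),

where Kav = (Ve - Vo) / (Vt - Vo) is the partition coefficient of a peak
eluting at Ve on a column of void volume Vo and total volume Vt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ColumnGeometry",
    "CalibrationStandard",
    "ColumnCalibration",
    "SpeciesSpec",
    "HydrodynamicResult",
    "Chromatogram",
    "OligomerState",
    "compute_kav",
    "fit_calibration",
    "estimate_amw",
    "estimate_rs",
    "predict_rs_folded",
    "predict_rs_unfolded",
    "compute_aan",
    "classify_oligomer",
    "estimate_dimer_fraction",
    "mixture_dimer_fraction",
    "detect_peaks",
    "analyze_sample",
]

# Default AAN bands for the oligomeric-state call. Chosen so that common
# printed AAN values (1.2 monomer; 1.5/1.7/2.1 mixtures; 2.4-2.8 dimers;
# 4.8 disulphide-linked tetramer) land in the intended class.
DEFAULT_AAN_BANDS = (1.35, 2.25, 3.6)


class OligomerState(str, Enum):
    MONOMER = "monomer"
    MONOMER_DIMER = "monomer/dimer mixture"
    DIMER = "dimer"
    HIGHER_ORDER = "higher-order"


@dataclass(frozen=True)
class ColumnGeometry:
    """Analytical column geometry.

    ``void_volume`` may be ``None`` when unknown; :func:`fit_calibration`
    then treats it as a bounded fit parameter.
    """

    total_volume: float  # Vt, mL
    void_volume: Optional[float] = None  # Vo, mL
    name: str = ""

    def __post_init__(self) -> None:
        if not self.total_volume > 0:
            raise ValueError("total_volume must be positive")
        if self.void_volume is not None and not (0 < self.void_volume < self.total_volume):
            raise ValueError(
                f"void_volume must lie in (0, Vt={self.total_volume}), got {self.void_volume}"
            )


@dataclass(frozen=True)
class CalibrationStandard:
    """A calibration standard: molar mass, elution volume, optional Rs."""

    molar_mass: float  # Da
    elution_volume: float  # mL
    stokes_radius: Optional[float] = None  # Angstrom
    name: str = ""

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError("molar_mass must be positive")


@dataclass(frozen=True)
class SpeciesSpec:
    """End-member description of a two-state (monomer/dimer) species."""

    name: str
    monomer_mass: float  # Da
    rs_monomer: float  # Angstrom
    rs_dimer: float  # Angstrom

    def __post_init__(self) -> None:
        if not self.monomer_mass > 0:
            raise ValueError("monomer_mass must be positive")
        if not self.rs_dimer > self.rs_monomer:
            raise ValueError("rs_dimer must exceed rs_monomer")


@dataclass
class Chromatogram:
    """An A280 elution trace on a volume grid."""

    volume: np.ndarray  # mL
    absorbance: np.ndarray  # AU

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.volume.shape != self.absorbance.shape:
            raise ValueError("volume and absorbance must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"volume_ml": self.volume, "a280": self.absorbance})

    @classmethod
    def from_csv(cls, path) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df["volume_ml"].to_numpy(), df["a280"].to_numpy())


@dataclass
class LinearMap:
    """A fitted line y = slope * x + intercept on transformed SEC axes."""

    slope: float
    intercept: float
    residual_ss: float
    x_domain: tuple[float, float]

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(x) + self.intercept

    def in_domain(self, x: float) -> bool:
        lo, hi = self.x_domain
        return lo <= x <= hi


@dataclass
class ColumnCalibration:
    """Fitted calibration of one column: the Mr^(1/3) and/or Rs lines."""

    geometry: ColumnGeometry
    mw_line: Optional[LinearMap] = None
    rs_line: Optional[LinearMap] = None
    standards: list[CalibrationStandard] = field(default_factory=list)


def compute_kav(ve: float, geometry: ColumnGeometry, clamp: bool = False) -> float:
    """Partition coefficient Kav = (Ve - Vo) / (Vt - Vo).

    With ``clamp=True``, values marginally outside [0, 1] (apex-interpolation
    jitter) are clamped with a warning instead of raising.
    """
    vo, vt = geometry.void_volume, geometry.total_volume
    if vo is None:
        raise ValueError("geometry.void_volume is unset; calibrate or supply Vo")
    kav = (ve - vo) / (vt - vo)
    if not 0.0 <= kav <= 1.0:
        if clamp and -0.05 <= kav <= 1.05:
            warnings.warn(f"Kav {kav:.4f} clamped into [0, 1] for Ve={ve}")
            return float(np.clip(kav, 0.0, 1.0))
        bound = f"void volume Vo={vo}" if kav < 0 else f"total volume Vt={vt}"
        raise ValueError(f"elution volume {ve} mL outside column range ({bound})")
    return float(kav)


def _xval(ve: float | np.ndarray, vo: float, vt: float) -> np.ndarray:
    kav = (np.asarray(ve, dtype=float) - vo) / (vt - vo)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(-np.log10(kav))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) < 1e-12:
        raise ValueError("singular calibration fit: all standards share one x value")
    slope, intercept = np.polyfit(x, y, 1)
    ss = float(np.sum((slope * x + intercept - y) ** 2))
    return float(slope), float(intercept), ss


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    geometry: ColumnGeometry,
    vo_bounds: tuple[float, float] = (0.3, 0.6),
    vo_grid_points: int = 2001,
) -> ColumnCalibration:
    """Fit the Mr^(1/3)-vs-x and Rs-vs-x calibration lines.

    If ``geometry.void_volume`` is ``None``, Vo is fitted by a 1-D grid scan
    over ``vo_bounds`` (as fractions of Vt, further restricted below the
    smallest standard Ve) minimising the summed squared residuals of all
    available lines, with an ordinary least-squares line fitted at each
    candidate Vo.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("at least 2 standards required")
    vt = geometry.total_volume
    ves = np.array([s.elution_volume for s in standards])
    if geometry.void_volume is not None:
        vo_candidates = np.array([geometry.void_volume])
    else:
        lo = vo_bounds[0] * vt
        hi = min(vo_bounds[1] * vt, float(ves.min()) - 1e-3 * vt)
        if hi <= lo:
            hi = float(ves.min()) - 1e-3 * vt
            lo = min(lo, hi - 0.05 * vt)
        vo_candidates = np.linspace(lo, hi, vo_grid_points)

    mr13 = np.array([s.molar_mass ** (1.0 / 3.0) for s in standards])
    rs_mask = np.array([s.stokes_radius is not None for s in standards])
    rs = np.array([s.stokes_radius if m else np.nan for s, m in zip(standards, rs_mask)])

    best = None
    for vo in vo_candidates:
        x = _xval(ves, vo, vt)
        if not np.all(np.isfinite(x)):
            continue
        ss_total = 0.0
        mw_fit = _ols(x, mr13)
        ss_total += mw_fit[2] / max(np.var(mr13), 1e-30)
        rs_fit = None
        if rs_mask.sum() >= 2:
            rs_fit = _ols(x[rs_mask], rs[rs_mask])
            ss_total += rs_fit[2] / max(np.var(rs[rs_mask]), 1e-30)
        if best is None or ss_total < best[0]:
            best = (ss_total, vo, x, mw_fit, rs_fit)

    if best is None:
        raise ValueError("no valid void volume in the scanned range")
    _, vo, x, mw_fit, rs_fit = best
    domain = (float(x.min()), float(x.max()))
    geom = ColumnGeometry(total_volume=vt, void_volume=float(vo), name=geometry.name)
    cal = ColumnCalibration(geometry=geom, standards=standards)
    cal.mw_line = LinearMap(mw_fit[0], mw_fit[1], mw_fit[2], domain)
    if rs_fit is not None:
        xr = x[rs_mask]
        cal.rs_line = LinearMap(rs_fit[0], rs_fit[1], rs_fit[2], (float(xr.min()), float(xr.max())))
    return cal


def _calibrated_x(cal: ColumnCalibration, ve: float) -> float:
    kav = compute_kav(ve, cal.geometry, clamp=True)
    kav = min(max(kav, 1e-12), 1.0 - 1e-12)
    return float(np.sqrt(-np.log10(kav)))


def estimate_amw(cal: ColumnCalibration, ve: float) -> float:
    """Apparent molecular weight (Da) from the cube-root calibration line."""
    if cal.mw_line is None:
        raise ValueError("calibration has no molecular-weight line")
    x = _calibrated_x(cal, ve)
    if not cal.mw_line.in_domain(x):
        warnings.warn(f"Ve={ve} mL extrapolates beyond the calibration domain")
    mr13 = float(cal.mw_line(x))
    if mr13 <= 0:
        raise ValueError(f"calibration predicts non-positive Mr^(1/3) at Ve={ve}")
    return mr13**3


def estimate_rs(cal: ColumnCalibration, ve: float) -> float:
    """Apparent Stokes radius (Angstrom) from the Rs calibration line."""
    if cal.rs_line is None:
        raise ValueError("calibration has no Stokes-radius line")
    x = _calibrated_x(cal, ve)
    if not cal.rs_line.in_domain(x):
        warnings.warn(f"Ve={ve} mL extrapolates beyond the Rs calibration domain")
    rs = float(cal.rs_line(x))
    if rs <= 0:
        raise ValueError(f"calibration predicts non-positive Rs at Ve={ve}")
    return rs


def predict_rs_folded(mr: float) -> float:
    """Stokes radius (Angstrom) expected for a globular folded protein of
    mass ``mr`` (Da): log10(Rs) = -0.204 + 0.357 log10(Mr)."""
    if not mr > 0:
        raise ValueError("Mr must be positive")
    return float(10 ** (-0.204 + 0.357 * np.log10(mr)))


def predict_rs_unfolded(mr: float) -> float:
    """Stokes radius (Angstrom) expected for an unfolded chain of mass
    ``mr`` (Da): log10(Rs) = -0.551 + 0.493 log10(Mr)."""
    if not mr > 0:
        raise ValueError("Mr must be positive")
    return float(10 ** (-0.551 + 0.493 * np.log10(mr)))


def compute_aan(amw: float, monomer_mass: float) -> float:
    """Apparent aggregation number AMW / monomer mass (full precision;
    round to one decimal for display)."""
    if amw <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    return amw / monomer_mass


def classify_oligomer(
    aan: float, bands: tuple[float, float, float] = DEFAULT_AAN_BANDS
) -> OligomerState:
    """Map an apparent aggregation number to an oligomeric-state call."""
    if not aan > 0:
        raise ValueError("AAN must be positive")
    b1, b2, b3 = bands
    if aan < b1:
        return OligomerState.MONOMER
    if aan < b2:
        return OligomerState.MONOMER_DIMER
    if aan < b3:
        return OligomerState.DIMER
    return OligomerState.HIGHER_ORDER


def estimate_dimer_fraction(rs_obs: float, species: SpeciesSpec) -> float:
    """Dimer fraction of an unresolved mixture from its apparent Stokes
    radius via linear mixing: (Rs_obs - Rs_mono) / (Rs_dim - Rs_mono)."""
    frac = (rs_obs - species.rs_monomer) / (species.rs_dimer - species.rs_monomer)
    if not 0.0 <= frac <= 1.0:
        warnings.warn(
            f"dimer fraction {frac:.3f} outside [0, 1]; clipped "
            f"(Rs_obs={rs_obs} vs end-members {species.rs_monomer}/{species.rs_dimer})"
        )
        frac = float(np.clip(frac, 0.0, 1.0))
    return float(frac)


def mixture_dimer_fraction(
    ve_obs: float,
    ve_dimer: float,
    ve_monomer: float,
    geometry: ColumnGeometry,
    species: SpeciesSpec,
) -> float:
    """Dimer fraction of an unresolved two-state mixture from its apex
    elution volume.

    The single merged apex of a similarly-populated folded-dimer/unfolded-
    monomer mixture is assumed to move linearly between the pure end-member
    peaks. The apparent Rs at the observed apex is interpolated between the
    end-member radii on the calibration abscissa x = sqrt(-log10 Kav), and
    the linear-mixing formula of :func:`estimate_dimer_fraction` is applied.
    """
    x_obs = _xval(ve_obs, geometry.void_volume, geometry.total_volume)
    x_dim = _xval(ve_dimer, geometry.void_volume, geometry.total_volume)
    x_mono = _xval(ve_monomer, geometry.void_volume, geometry.total_volume)
    rs_obs = species.rs_monomer + (species.rs_dimer - species.rs_monomer) * (
        (x_obs - x_mono) / (x_dim - x_mono)
    )
    return estimate_dimer_fraction(float(rs_obs), species)


def detect_peaks(
    chrom: Chromatogram, rel_height: float = 0.05, min_separation: int = 3
) -> list[tuple[float, float]]:
    """Locate elution peaks as local maxima above ``rel_height`` of the
    baseline-subtracted trace maximum, with 3-point parabolic apex
    refinement. Returns (Ve, height) pairs sorted by volume."""
    v, y = chrom.volume, chrom.absorbance
    if v.size < 5:
        raise ValueError("need at least 5 grid points")
    y0 = y - np.median(y)
    threshold = rel_height * float(y0.max())
    idx, _ = find_peaks(y0, height=threshold, distance=min_separation)
    if idx.size == 0:
        warnings.warn("no peak above threshold")
        return []
    out = []
    for i in idx:
        if 0 < i < v.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.0 if abs(denom) < 1e-300 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step = v[i + 1] - v[i] if delta >= 0 else v[i] - v[i - 1]
            apex_v = v[i] + delta * step
            apex_h = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
        else:
            apex_v, apex_h = v[i], y[i]
        out.append((float(apex_v), float(apex_h)))
    return sorted(out)


@dataclass
class HydrodynamicResult:
    """Per-peak hydrodynamic interpretation (one Table-style row)."""

    elution_volume: float
    kav: float
    apparent_mw: float
    apparent_rs: Optional[float]
    aan: float
    oligomer_call: OligomerState
    dimer_fraction: Optional[float] = None

    def to_row(self) -> dict:
        return {
            "ve_ml": round(self.elution_volume, 2),
            "kav": round(self.kav, 3),
            "amw_kda": round(self.apparent_mw / 1e3, 0),
            "rs_angstrom": None if self.apparent_rs is None else round(self.apparent_rs),
            "aan": round(self.aan, 1),
            "state": self.oligomer_call.value,
            "dimer_fraction": None
            if self.dimer_fraction is None
            else round(self.dimer_fraction, 2),
        }


def analyze_sample(
    cal: ColumnCalibration,
    ve: float,
    monomer_mass: float,
    species: Optional[SpeciesSpec] = None,
    bands: tuple[float, float, float] = DEFAULT_AAN_BANDS,
) -> HydrodynamicResult:
    """Full hydrodynamic interpretation of one elution peak."""
    kav = compute_kav(ve, cal.geometry, clamp=True)
    amw = estimate_amw(cal, ve)
    rs = estimate_rs(cal, ve) if cal.rs_line is not None else None
    aan = compute_aan(amw, monomer_mass)
    call = classify_oligomer(aan, bands)
    frac = None
    if species is not None and rs is not None and call is OligomerState.MONOMER_DIMER:
        frac = estimate_dimer_fraction(rs, species)
    return HydrodynamicResult(ve, kav, amw, rs, aan, call, frac)
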