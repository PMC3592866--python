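"""Synthetic-data generators with known ground truth for every pipeline
stage.

Each generator emulates one input class of the analysis — SEC elution
traces, ideal α-helical-hairpin dimer coordinates, per-residue ¹⁵N
relaxation profiles, two-state dimer melt curves, and sedimentation-
equilibrium radial profiles — from an explicit parameter spec, so the
downstream estimators have parameter-recovery tests without any external
data. All randomness flows through ``numpy.random.default_rng(seed)``:
regenerating with the same spec is bit-identical, and noiseless outputs
are exact evaluations of the stated closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .equilibrium_models import MeltCurve, SedimentationProfile, melt_signal, sedimentation_profile
from .nmr_relaxation import DEFAULT_CONSTANTS, NMRConstants, RelaxationTable, model_free_rates
from .sec_hydrodynamics import Chromatogram
from .structure_geometry import Atom, Chain, Model, Residue, StructureEnsemble

__all__ = [
    "ChromatogramSpec",
    "HairpinGeometrySpec",
    "RelaxationSimSpec",
    "MeltSimSpec",
    "SedimentationSimSpec",
    "gen_chromatogram",
    "gen_hairpin_dimer",
    "gen_relaxation",
    "gen_melt_curve",
    "gen_sedimentation",
    "jitter_ensemble",
]


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatogramSpec:
    """Sum-of-Gaussians elution trace on a volume grid.

    ``peaks`` holds (elution volume mL, height AU, sigma mL) triples.
    """

    peaks: tuple[tuple[float, float, float], ...]
    volume_grid: tuple[float, float, float] = (0.8, 2.41, 0.002)  # start, stop, step
    baseline: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("at least one peak required")
        start, stop, step = self.volume_grid
        if step <= 0 or stop <= start:
            raise ValueError("invalid volume grid")
        for ve, height, sigma in self.peaks:
            if not 0 < ve <= stop:
                raise ValueError(f"peak position {ve} outside (0, {stop}]")
            if sigma <= 0:
                raise ValueError("peak sigma must be positive")


def gen_chromatogram(spec: ChromatogramSpec) -> Chromatogram:
    """Evaluate the spec's Gaussian mixture plus baseline and iid noise."""
    start, stop, step = spec.volume_grid
    v = np.arange(start, stop + 0.5 * step, step)
    y = np.full_like(v, float(spec.baseline))
    for ve, height, sigma in spec.peaks:
        y += height * np.exp(-0.5 * ((v - ve) / sigma) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=v.shape)
    return Chromatogram(v, y)


# ---------------------------------------------------------------------------
# Ideal helical-hairpin dimer coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinGeometrySpec:
    """Ideal backbone-only α-helical hairpin homodimer.

    Within each protomer the two helix axes cross at ``interhelix_angle``;
    the two protomers' hairpin principal axes cross at ``docking_angle``.
    Helix construction uses ideal α-helix internal coordinates (φ = −60°,
    ψ = −45°, ω = 180°), giving ~1.5 Å rise per residue and 3.6 residues
    per turn; ``rise_per_residue``/``residues_per_turn``/``helix_radius``
    document the nominal geometry rather than acting as free dials.
    """

    residues_per_helix: int = 14
    interhelix_angle: float = 31.0  # degrees
    docking_angle: float = 85.0  # degrees
    rise_per_residue: float = 1.5  # Angstrom (nominal)
    residues_per_turn: float = 3.6  # (nominal)
    helix_radius: float = 2.3  # Angstrom (nominal)
    inter_helix_separation: float = 10.0  # Angstrom between hairpin helices
    inter_protomer_gap: float = 4.0  # minimum allowed inter-protomer distance
    first_residue: int = 41  # author numbering of the first helix residue

    def __post_init__(self) -> None:
        if self.residues_per_helix < 6:
            raise ValueError("need at least 6 residues per helix")
        for name in ("interhelix_angle", "docking_angle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name} must lie in [0, 90] degrees")
        if self.inter_protomer_gap <= 0:
            raise ValueError("inter_protomer_gap must be positive")


def _nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place the next atom from three predecessors and internal coordinates."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_ideal_helix(n_res: int, phi: float = -60.0, psi: float = -45.0) -> np.ndarray:
    """Backbone (N, CA, C, O) of an ideal α-helix; shape (n_res, 4, 3)."""
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = _nerf(np.array([0.0, 1.0, 0.0]), N, CA, 1.525, 111.2, 0.0)
    res = [[N, CA, C]]
    for _ in range(1, n_res):
        Np = _nerf(res[-1][0], res[-1][1], res[-1][2], 1.329, 116.2, psi)
        CAp = _nerf(res[-1][1], res[-1][2], Np, 1.458, 121.7, 180.0)
        Cp = _nerf(res[-1][2], Np, CAp, 1.525, 111.2, phi)
        res.append([Np, CAp, Cp])
    out = []
    for i, (n_, ca, c) in enumerate(res):
        tor = psi + 180.0 if i + 1 < len(res) else 133.0
        O = _nerf(n_, ca, c, 1.231, 120.5, tor)
        out.append(np.array([n_, ca, c, O]))
    return np.array(out)


def _principal_axis(points: np.ndarray, orient: Optional[np.ndarray] = None) -> np.ndarray:
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    ax = vt[0]
    if orient is not None and np.dot(orient, ax) < 0:
        ax = -ax
    return ax


def _rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _canonical_helix(n_res: int) -> np.ndarray:
    """Ideal helix rotated so its Cα axis is +z and centroid at origin."""
    hel = _build_ideal_helix(n_res)
    cas = hel[:, 1, :]
    ax = _principal_axis(cas, orient=cas[-1] - cas[0])
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(ax, z)
    s = np.linalg.norm(v)
    d = float(ax @ z)
    if s < 1e-12:
        R = np.eye(3) if d > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - d) / s**2)
    centred = hel - cas.mean(axis=0)
    return centred @ R.T


def _build_protomer(spec: HairpinGeometrySpec) -> tuple[np.ndarray, np.ndarray]:
    """One hairpin: two antiparallel helices crossing at interhelix_angle.

    Returns (atoms (2, n_res, 4, 3), all CA (2*n_res, 3)).
    """
    n = spec.residues_per_helix
    h1 = _canonical_helix(n)  # axis +z
    h2 = _canonical_helix(n)
    x = np.array([1.0, 0.0, 0.0])
    h2 = h2 @ _rotation(x, 180.0).T  # antiparallel
    h2 = h2 @ _rotation(x, spec.interhelix_angle).T  # crossing angle
    h2 = h2 + np.array([spec.inter_helix_separation, 0.0, 0.0])
    atoms = np.stack([h1, h2])
    cas = np.vstack([h1[:, 1, :], h2[:, 1, :]])
    return atoms, cas


def gen_hairpin_dimer(spec: HairpinGeometrySpec) -> StructureEnsemble:
    """Build a backbone-only hairpin homodimer with the spec's angles.

    Protomer B is a copy of protomer A rotated by ``docking_angle`` about
    an axis perpendicular to A's hairpin principal axis and displaced
    along that axis until the closest inter-protomer approach is at least
    ``inter_protomer_gap``.
    """
    atoms_a, cas_a = _build_protomer(spec)
    centroid = cas_a.mean(axis=0)
    p_axis = _principal_axis(cas_a)
    # rotation axis perpendicular to the protomer principal axis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(float(p_axis @ seed_vec)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    r_axis = np.cross(p_axis, seed_vec)
    r_axis /= np.linalg.norm(r_axis)
    R = _rotation(r_axis, spec.docking_angle)

    flat_a = atoms_a.reshape(-1, 3)

    def _placed(sep: float) -> np.ndarray:
        return (flat_a - centroid) @ R.T + centroid + r_axis * sep

    def _min_dist(sep: float) -> float:
        cand = _placed(sep)
        return float(
            np.min(np.linalg.norm(flat_a[:, None, :] - cand[None, :, :], axis=-1))
        )

    # smallest displacement along the rotation axis whose closest
    # inter-protomer approach meets the requested gap
    lo, hi = 0.0, spec.inter_helix_separation + 2.0 * spec.inter_protomer_gap
    for _ in range(60):
        if _min_dist(hi) >= spec.inter_protomer_gap:
            break
        hi *= 1.5
    else:
        raise ValueError("could not place the second protomer without clashes")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _min_dist(mid) >= spec.inter_protomer_gap:
            hi = mid
        else:
            lo = mid
        if hi - lo < 0.02:
            break
    flat_b = _placed(hi)

    def _chain(flat: np.ndarray, chain_id: str) -> Chain:
        atoms = flat.reshape(2, spec.residues_per_helix, 4, 3)
        residues = []
        seq = spec.first_residue
        for h in range(2):
            for i in range(spec.residues_per_helix):
                n_, ca, c, o = atoms[h, i]
                residues.append(
                    Residue(
                        seq,
                        "ALA",
                        [
                            Atom("N", "N", n_),
                            Atom("CA", "C", ca),
                            Atom("C", "C", c),
                            Atom("O", "O", o),
                        ],
                    )
                )
                seq += 1
            seq += 4  # unmodelled connector between the hairpin helices
        return Chain(chain_id, residues)

    model = Model([_chain(flat_a, "A"), _chain(flat_b, "B")])
    return StructureEnsemble([model], id="synthetic-hairpin-dimer")


def jitter_ensemble(
    ensemble: StructureEnsemble,
    coord_sd: float,
    n_models: int,
    seed: int = 0,
    mode: str = "iid",
) -> StructureEnsemble:
    """Emulate an NMR-style ensemble from one template model.

    ``mode="iid"``: every atom receives iid Gaussian jitter of standard
    deviation ``coord_sd`` (Å per Cartesian component); simple analytic
    expectations, but per-atom noise scrambles backbone dihedrals at
    realistic amplitudes.

    ``mode="smooth"``: each model receives a low-frequency displacement
    field along the sequence (three random sinusoids per Cartesian
    component, shared by all atoms of a residue), rescaled so the RMS
    atomic displacement of the model is exactly ``coord_sd``. Neighbouring
    residues move together, so local covalent geometry and dihedrals stay
    essentially intact — the way conformers of a well-defined NMR ensemble
    actually differ.
    """
    if mode not in ("iid", "smooth"):
        raise ValueError("mode must be 'iid' or 'smooth'")
    rng = np.random.default_rng(seed)
    template = ensemble.models[0]
    models = []
    for _ in range(n_models):
        chains = []
        for chain in template.chains:
            n_res = len(chain.residues)
            if mode == "smooth":
                t = np.linspace(0.0, 1.0, n_res)
                disp = np.zeros((n_res, 3))
                for axis in range(3):
                    for k in (1, 2, 3):
                        amp = rng.normal(0.0, 1.0 / k)
                        phase = rng.uniform(0.0, 2 * np.pi)
                        disp[:, axis] += amp * np.sin(2 * np.pi * k * t + phase)
                rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
                disp *= coord_sd / max(rms, 1e-12)
            residues = []
            for i, res in enumerate(chain.residues):
                if mode == "iid":
                    atoms = [
                        Atom(a.name, a.element, a.pos + rng.normal(0.0, coord_sd, 3))
                        for a in res.atoms
                    ]
                else:
                    atoms = [
                        Atom(a.name, a.element, a.pos + disp[i]) for a in res.atoms
                    ]
                residues.append(Residue(res.seqid, res.name, atoms))
            chains.append(Chain(chain.id, residues))
        models.append(Model(chains))
    return StructureEnsemble(models, id=ensemble.id + "-jittered")


# ---------------------------------------------------------------------------
# Relaxation profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationSimSpec:
    """Isotropic-tumbling ¹⁵N relaxation profile with flexible termini.

    Core residues carry ``order_param_core`` (S²); ``flexible_termini``
    residues at each end ramp down to a low terminal S² with fast internal
    motion; ``rex_sites`` adds exchange broadening to R2 only. Noise is
    relative (fractional) iid Gaussian on each observable.
    """

    n_residues: int = 55  # 39-residue structured core + 8 flexible per end
    tau_c: float = 9.9e-9  # s
    field: float = 500.0  # MHz ¹H
    order_param_core: float = 0.86
    flexible_termini: int = 8
    terminal_s2: float = 0.3
    internal_tau: float = 50e-12  # s, effective internal motion of floppy sites
    rex_sites: tuple[tuple[int, float], ...] = ()  # (residue, s^-1)
    noise_fraction: float = 0.0
    first_residue: int = 33
    seed: int = 0
    constants: NMRConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.field <= 0:
            raise ValueError("field must be positive")
        for s2 in (self.order_param_core, self.terminal_s2):
            if not 0.0 <= s2 <= 1.0:
                raise ValueError("order parameters must lie in [0, 1]")
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")


def gen_relaxation(spec: RelaxationSimSpec) -> RelaxationTable:
    """Per-residue R1/R2/NOE from the model-free spectral densities."""
    import pandas as pd

    rex = dict(spec.rex_sites)
    rows = []
    rng = np.random.default_rng(spec.seed)
    nt = spec.flexible_termini
    for i in range(spec.n_residues):
        residue = spec.first_residue + i
        dist_from_end = min(i, spec.n_residues - 1 - i)
        if nt > 0 and dist_from_end < nt:
            # linear S² ramp from the floppy terminus into the core
            w = (dist_from_end + 0.5) / nt
            s2 = spec.terminal_s2 + (spec.order_param_core - spec.terminal_s2) * w
            tau_e = spec.internal_tau * 20  # slower local motion at termini
        else:
            s2 = spec.order_param_core
            tau_e = spec.internal_tau
        r1, r2, noe = model_free_rates(
            spec.tau_c,
            spec.field,
            s2=s2,
            tau_e=tau_e if s2 < 1.0 else None,
            rex=rex.get(residue, 0.0),
            constants=spec.constants,
        )
        if spec.noise_fraction > 0:
            r1 *= 1.0 + rng.normal(0.0, spec.noise_fraction)
            r2 *= 1.0 + rng.normal(0.0, spec.noise_fraction)
            noe += rng.normal(0.0, spec.noise_fraction * abs(noe))
        rows.append({"residue": residue, "r1": r1, "r2": r2, "noe": noe})
    return RelaxationTable(spec.field, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltSimSpec:
    """Two-state dimer melt with linear baselines and additive noise."""

    delta_h: float = 300e3  # J/mol
    t_m: float = 338.0  # K
    total_monomer_conc: float = 20e-6  # M
    native_baseline: tuple[float, float] = (-1.0, 0.001)  # intercept, slope
    unfolded_baseline: tuple[float, float] = (0.6, -0.002)
    noise_sd: float = 0.0  # AU, absolute
    temperature_grid: tuple[float, float, float] = (288.0, 368.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.temperature_grid
        if not lo < self.t_m < hi:
            raise ValueError("t_m must lie inside the temperature grid")
        if self.total_monomer_conc <= 0:
            raise ValueError("total_monomer_conc must be positive")
        if step <= 0:
            raise ValueError("temperature step must be positive")


def gen_melt_curve(spec: MeltSimSpec) -> MeltCurve:
    lo, hi, step = spec.temperature_grid
    T = np.arange(lo, hi + 0.5 * step, step)
    y = melt_signal(
        T,
        spec.delta_h,
        spec.t_m,
        spec.native_baseline[0],
        spec.native_baseline[1],
        spec.unfolded_baseline[0],
        spec.unfolded_baseline[1],
        spec.total_monomer_conc,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=T.shape)
    return MeltCurve(T, y)


# ---------------------------------------------------------------------------
# Sedimentation equilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SedimentationSimSpec:
    """Exponential radial concentration distributions, one per speed."""

    molar_mass: float = 12300.0  # Da
    vbar: float = 0.73  # mL/g
    solvent_density: float = 1.0  # g/mL
    rotor_speeds: tuple[float, ...] = (2 * np.pi * 20000 / 60, 2 * np.pi * 28000 / 60)
    temperature: float = 293.0  # K
    reference_radius: float = 6.9  # cm
    radial_grid: tuple[float, float, int] = (6.9, 7.15, 60)  # start, stop, points
    reference_conc: float = 0.4  # AU
    baseline: float = 0.02  # AU
    noise_sd: float = 0.0  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if not 0.0 < self.vbar * self.solvent_density < 1.0:
            raise ValueError("need 0 < vbar*density < 1 (positive buoyancy)")


def gen_sedimentation(spec: SedimentationSimSpec) -> list[SedimentationProfile]:
    lo, hi, n = spec.radial_grid
    r = np.linspace(lo, hi, int(n))
    rng = np.random.default_rng(spec.seed)
    profiles = []
    for omega in spec.rotor_speeds:
        c = sedimentation_profile(
            r,
            spec.molar_mass,
            spec.vbar,
            spec.solvent_density,
            omega,
            spec.temperature,
            spec.reference_radius,
            spec.reference_conc,
            spec.baseline,
        )
        if spec.noise_sd > 0:
            c = c + rng.normal(0.0, spec.noise_sd, size=r.shape)
        profiles.append(
            SedimentationProfile(r.copy(), c, omega, spec.reference_radius)
        )
    return profiles
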