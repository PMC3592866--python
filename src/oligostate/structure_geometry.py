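"""Geometry of multi-model structure ensembles of helical-hairpin dimers.

Reads and writes multi-model PDB coordinate ensembles (via gemmi), detects
helical segments from backbone dihedrals, fits helix axes, measures
inter-helix crossing and protomer docking angles, computes ensemble
coordinate precision (RMSD to the iteratively superposed mean structure),
solvent-accessible surface area (Shrake-Rupley), buried dimer-interface
area (PISA convention: half the SASA lost on association), per-residue
relative solvent exposure, and typed inter/intra-protomer contacts
(hydrogen bonds, salt bridges, non-polar packing) from heavy-atom criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "StructureEnsemble",
    "HelixSegment",
    "InterfaceContact",
    "InterfaceReport",
    "ContactCriteria",
    "read_structure",
    "write_structure",
    "assign_helices",
    "fit_helix_axis",
    "crossing_angle",
    "interhelix_angle",
    "docking_angle",
    "superpose",
    "ensemble_rmsd",
    "sasa",
    "buried_interface_area",
    "relative_exposure",
    "find_contacts",
    "ensemble_interface_report",
]

# Bondi van der Waals radii (Angstrom); configurable via the `radii`
# argument of `sasa`. Unknown elements fall back to `default_radius`.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# φ/ψ window (degrees) used to call α-helical residues from backbone
# dihedrals.
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-67.0, -7.0)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    seqid: int  # author numbering
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqid: int) -> Optional[Residue]:
        for r in self.residues:
            if r.seqid == seqid:
                return r
        return None

    def ca_coords(self, residue_range: Optional[tuple[int, int]] = None) -> np.ndarray:
        out = []
        for r in self.residues:
            if residue_range and not residue_range[0] <= r.seqid <= residue_range[1]:
                continue
            ca = r.atom("CA")
            if ca is not None:
                out.append(ca.pos)
        return np.array(out)


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def coords(
        self,
        chain_ids: Optional[Sequence[str]] = None,
        residue_range: Optional[tuple[int, int]] = None,
        atom_names: Optional[Sequence[str]] = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        out = []
        for c in self.chains:
            if chain_ids and c.id not in chain_ids:
                continue
            for r in c.residues:
                if residue_range and not residue_range[0] <= r.seqid <= residue_range[1]:
                    continue
                for a in r.atoms:
                    if atom_names and a.name not in atom_names:
                        continue
                    if heavy_only and a.element == "H":
                        continue
                    out.append(a.pos)
        return np.array(out)

    def atom_records(self) -> list[tuple[str, int, str, str]]:
        """(chain, seqid, residue name, atom name) topology signature."""
        recs = []
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    recs.append((c.id, r.seqid, r.name, a.name))
        return recs


@dataclass
class StructureEnsemble:
    """An ordered list of models sharing one atom topology."""

    models: list[Model]
    id: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        if self.models:
            ref = self.models[0].atom_records()
            for i, m in enumerate(self.models[1:], start=2):
                recs = m.atom_records()
                if recs != ref:
                    bad = next(
                        (a for a, b in zip(recs, ref) if a != b),
                        recs[len(ref):len(ref) + 1] or ref[len(recs):len(recs) + 1],
                    )
                    raise ValueError(f"model {i} topology diverges at atom {bad}")

    def __len__(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _from_gemmi(st) -> StructureEnsemble:
    models = []
    for gm in st:
        chains = []
        for gc in gm:
            residues = []
            for gr in gc:
                atoms = [
                    Atom(ga.name, ga.element.name.upper(), np.array([ga.pos.x, ga.pos.y, ga.pos.z]))
                    for ga in gr
                ]
                residues.append(Residue(gr.seqid.num, gr.name, atoms))
            chains.append(Chain(gc.name, residues))
        models.append(Model(chains))
    return StructureEnsemble(models, id=st.name, title=st.name)


def read_structure(path: str) -> StructureEnsemble:
    """Read a (multi-model) PDB or mmCIF file into a StructureEnsemble,
    preserving author residue numbering."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    ens = _from_gemmi(st)
    if not ens.models or not any(m.chains for m in ens.models):
        raise ValueError(f"no coordinates parsed from {path}")
    return ens


def write_structure(ensemble: StructureEnsemble, path: str) -> None:
    """Write a StructureEnsemble as a multi-model PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = ensemble.id or "ensemble"
    for i, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(i)
        for chain in model.chains:
            gc = gemmi.Chain(chain.id)
            for res in chain.residues:
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(res.seqid, " ")
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.pos)
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Helix detection and axes
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    # IUPAC sign convention (praxeolitic formula)
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1n, v), w), np.dot(v, w))))


def backbone_dihedrals(chain: Chain) -> dict[int, tuple[Optional[float], Optional[float]]]:
    """Author-numbered (phi, psi) per residue; None at chain breaks/termini."""
    out: dict[int, tuple[Optional[float], Optional[float]]] = {}
    res = chain.residues
    for i, r in enumerate(res):
        phi = psi = None
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        if None in (n, ca, c):
            warnings.warn(f"residue {r.seqid} missing backbone atoms; skipped")
            out[r.seqid] = (None, None)
            continue
        if i > 0 and res[i - 1].seqid == r.seqid - 1:
            cp = res[i - 1].atom("C")
            if cp is not None:
                phi = _dihedral(cp.pos, n.pos, ca.pos, c.pos)
        if i + 1 < len(res) and res[i + 1].seqid == r.seqid + 1:
            nn = res[i + 1].atom("N")
            if nn is not None:
                psi = _dihedral(n.pos, ca.pos, c.pos, nn.pos)
        out[r.seqid] = (phi, psi)
    return out


@dataclass
class HelixSegment:
    chain_id: str
    first_residue: int
    last_residue: int
    axis: np.ndarray  # unit vector, N -> C
    centroid: np.ndarray
    fit_rms: float

    @property
    def n_residues(self) -> int:
        return self.last_residue - self.first_residue + 1


def fit_helix_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a helix axis as the principal direction of the Cα cloud.

    Returns (unit axis oriented N->C, centroid, rms distance of the Cα
    positions from the axis line — approximately the helix radius).
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 2 or X.shape[0] < 6:
        raise ValueError("need at least 6 CA positions")
    centroid = X.mean(axis=0)
    Y = X - centroid
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("degenerate coordinates")
    axis = vt[0]
    if np.dot(X[-1] - X[0], axis) < 0:
        axis = -axis
    proj = Y @ axis
    perp = Y - np.outer(proj, axis)
    fit_rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return axis, centroid, fit_rms


def assign_helices(
    model: Model,
    chain_id: str,
    phi_window: tuple[float, float] = HELIX_PHI_WINDOW,
    psi_window: tuple[float, float] = HELIX_PSI_WINDOW,
    min_run: int = 4,
) -> list[HelixSegment]:
    """Call α-helical segments from backbone dihedrals.

    Residues whose (φ, ψ) fall inside the α-helical window are collected
    into runs of at least ``min_run`` residues; runs separated by a single
    non-helical residue are merged. Terminal residues lacking φ or ψ join a
    neighbouring run if their defined dihedral is helical. Segments shorter
    than 6 residues cannot carry an axis and are dropped with a warning.
    """
    chain = model.chain(chain_id)
    dihedrals = backbone_dihedrals(chain)

    def _is_helical(seqid: int) -> bool:
        phi, psi = dihedrals.get(seqid, (None, None))
        ok_phi = phi is not None and phi_window[0] <= phi <= phi_window[1]
        ok_psi = psi is not None and psi_window[0] <= psi <= psi_window[1]
        if phi is None and psi is not None:
            return ok_psi
        if psi is None and phi is not None:
            return ok_phi
        return ok_phi and ok_psi

    seqids = [r.seqid for r in chain.residues]
    helical = [s for s in seqids if _is_helical(s)]
    runs: list[list[int]] = []
    for s in helical:
        if runs and s - runs[-1][-1] == 1:
            runs[-1].append(s)
        elif runs and s - runs[-1][-1] == 2 and (s - 1) in seqids:
            runs[-1].extend([s - 1, s])  # bridge a single-residue gap
        else:
            runs.append([s])
    segments = []
    for run in runs:
        if len(run) < min_run:
            continue
        first, last = run[0], run[-1]
        cas = chain.ca_coords((first, last))
        if len(cas) < 6:
            warnings.warn(
                f"helical run {first}-{last} in chain {chain_id} too short for an axis fit"
            )
            continue
        axis, centroid, rms = fit_helix_axis(cas)
        segments.append(HelixSegment(chain_id, first, last, axis, centroid, rms))
    return segments


def crossing_angle(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Orientation-independent crossing angle between two axes, in [0, 90]°."""
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length axis")
    cosang = abs(float(np.dot(a, b)) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def interhelix_angle(model: Model, chain_id: str) -> float:
    """Crossing angle between the two longest helices of one protomer."""
    segs = assign_helices(model, chain_id)
    if len(segs) < 2:
        raise ValueError(f"chain {chain_id} has fewer than 2 helices")
    segs = sorted(segs, key=lambda s: -s.n_residues)[:2]
    return crossing_angle(segs[0].axis, segs[1].axis)


def _protomer_principal_axis(model: Model, chain_id: str) -> np.ndarray:
    segs = assign_helices(model, chain_id)
    if len(segs) < 2:
        raise ValueError(f"chain {chain_id} has fewer than 2 assigned helices")
    chain = model.chain(chain_id)
    cas = np.vstack([chain.ca_coords((s.first_residue, s.last_residue)) for s in segs])
    Y = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    return vt[0]


def docking_angle(model: Model, chain_a: str = "A", chain_b: str = "B") -> float:
    """Crossing angle between the two protomers' hairpin principal axes
    (principal direction of all helical Cα of each chain)."""
    if len(model.chains) < 2:
        raise ValueError("docking angle requires two chains")
    pa = _protomer_principal_axis(model, chain_a)
    pb = _protomer_principal_axis(model, chain_b)
    return crossing_angle(pa, pb)


# ---------------------------------------------------------------------------
# Superposition and ensemble precision
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch).

    Returns (rotation R, translation t, rmsd) such that mobile @ R.T + t
    best fits reference; R is a proper rotation.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need two equal-length sets of >=3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    chain_ids: Optional[Sequence[str]] = None,
    residue_range: Optional[tuple[int, int]] = None,
    mode: str = "backbone",
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Coordinate precision of an ensemble: mean ± sd of per-model RMSD to
    the iteratively superposed mean structure.

    ``mode`` selects "backbone" (N, CA, C, O) or "heavy" atoms.
    """
    if mode not in ("backbone", "heavy"):
        raise ValueError("mode must be 'backbone' or 'heavy'")
    atom_names = BACKBONE_ATOMS if mode == "backbone" else None
    coords = np.array(
        [
            m.coords(chain_ids, residue_range, atom_names, heavy_only=(mode == "heavy"))
            for m in ensemble.models
        ]
    )
    if coords.size == 0 or coords.shape[1] == 0:
        raise ValueError("empty atom selection")
    mean = coords[0].copy()
    for _ in range(max_iter):
        fitted = []
        for X in coords:
            R, t, _ = superpose(X, mean)
            fitted.append(X @ R.T + t)
        fitted = np.array(fitted)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        coords = fitted
        if shift < tol:
            break
    rmsds = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=1))
    return float(rmsds.mean()), float(rmsds.std(ddof=0))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden-spiral
    lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    model_or_atoms,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    radii: Optional[dict[str, float]] = None,
    default_radius: float = 1.70,
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley, Å²).

    Accepts a Model or a flat list of Atoms. Hydrogens are excluded by
    default (heavy-atom convention; NMR models carry protons). The result
    is ordered as the (filtered) atoms are encountered.
    """
    radii = radii or BONDI_RADII
    if isinstance(model_or_atoms, Model):
        atoms = [
            a
            for c in model_or_atoms.chains
            for r in c.residues
            for a in r.atoms
            if include_hydrogens or a.element != "H"
        ]
    else:
        atoms = [a for a in model_or_atoms if include_hydrogens or a.element != "H"]
    if not atoms:
        return np.zeros(0)
    pos = np.array([a.pos for a in atoms])
    rad = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = radii.get(a.element)
        if r is None:
            warnings.warn(f"unknown element {a.element!r}; using default radius")
            r = default_radius
        rad[i] = r + probe_radius
    pts = _sphere_points(sphere_points)
    tree = cKDTree(pos)
    out = np.empty(len(atoms))
    max_r = rad.max()
    for i in range(len(atoms)):
        neighbours = [j for j in tree.query_ball_point(pos[i], rad[i] + max_r) if j != i]
        surface = pos[i] + rad[i] * pts
        if neighbours:
            npos = pos[neighbours]
            nrad = rad[neighbours]
            d2 = np.sum((surface[:, None, :] - npos[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < nrad[None, :] ** 2, axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = sphere_points
        out[i] = 4.0 * np.pi * rad[i] ** 2 * accessible / sphere_points
    return out


def _chain_subset_model(model: Model, chain_ids: Sequence[str]) -> Model:
    return Model([c for c in model.chains if c.id in chain_ids])


def buried_interface_area(
    model: Model,
    chain_a: str = "A",
    chain_b: str = "B",
    per_protomer: bool = True,
    **sasa_kwargs,
) -> float:
    """Interface area buried on dimer formation.

    Computed as SASA(A alone) + SASA(B alone) - SASA(AB), halved by default
    (PISA convention: area buried per protomer). Set ``per_protomer=False``
    for the raw total.
    """
    a_alone = sasa(_chain_subset_model(model, [chain_a]), **sasa_kwargs).sum()
    b_alone = sasa(_chain_subset_model(model, [chain_b]), **sasa_kwargs).sum()
    both = sasa(_chain_subset_model(model, [chain_a, chain_b]), **sasa_kwargs).sum()
    buried = max(float(a_alone + b_alone - both), 0.0)
    return buried / 2.0 if per_protomer else buried


def relative_exposure(
    model: Model, chain_id: str, seqid: int, **sasa_kwargs
) -> float:
    """Fractional solvent exposure of one residue.

    The residue's SASA in the full model is divided by the SASA of the same
    residue (same conformation) computed in isolation, which makes a fully
    isolated residue score 1 by construction.
    """
    chain = model.chain(chain_id)
    res = chain.residue(seqid)
    if res is None:
        raise KeyError(f"no residue {seqid} in chain {chain_id}")
    atoms = [
        a
        for c in model.chains
        for r in c.residues
        for a in r.atoms
        if a.element != "H"
    ]
    areas = sasa(atoms, **sasa_kwargs)
    res_heavy = set(id(a) for a in res.heavy_atoms)
    in_context = sum(
        area for a, area in zip([a for a in atoms], areas) if id(a) in res_heavy
    )
    reference = sasa(res.heavy_atoms, **sasa_kwargs).sum()
    if reference <= 0:
        raise ValueError(f"residue {res.name}{seqid} has no reference surface")
    return float(in_context / reference)


# ---------------------------------------------------------------------------
# Interface contacts
# ---------------------------------------------------------------------------

class ContactKind(str, Enum):
    HBOND = "hbond"
    SALT_BRIDGE = "salt_bridge"
    NONPOLAR = "nonpolar"


@dataclass(frozen=True)
class ContactCriteria:
    """Heavy-atom contact criteria (Angstrom / degrees)."""

    hbond_distance: float = 3.5
    hbond_min_angle: float = 90.0  # antecedent-donor-acceptor
    salt_bridge_distance: float = 4.0
    nonpolar_distance: float = 4.5


@dataclass
class InterfaceContact:
    kind: ContactKind
    partner_a: tuple[str, int, str, str]  # chain, seqid, residue, atom
    partner_b: tuple[str, int, str, str]
    distance: float
    angle: Optional[float] = None  # hbond only
    inter_protomer: bool = False


@dataclass
class InterfaceReport:
    buried_area: float  # per-protomer, Å²
    buried_area_total: float  # unhalved
    per_residue_burial: dict[tuple[str, int], float]
    contacts: list[InterfaceContact]


# donor atom -> antecedent atom used for the angle test
_DONORS = {
    ("*", "N"): "CA",
    ("ARG", "NE"): "CD",
    ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ",
    ("LYS", "NZ"): "CE",
    ("HIS", "ND1"): "CG",
    ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1",
    ("ASN", "ND2"): "CG",
    ("GLN", "NE2"): "CD",
    ("SER", "OG"): "CB",
    ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ",
}

_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}

_NEG_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POS_GROUPS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
_APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_contacts(
    model: Model, criteria: ContactCriteria = ContactCriteria()
) -> list[InterfaceContact]:
    """Detect hydrogen bonds, salt bridges and non-polar contacts between
    residues (heavy atoms only; hydrogen positions are not required)."""
    entries = []  # (chain, residue, atom)
    for c in model.chains:
        for r in c.residues:
            for a in r.heavy_atoms:
                entries.append((c, r, a))
    if not entries:
        return []
    pos = np.array([a.pos for _, _, a in entries])
    tree = cKDTree(pos)
    max_cut = max(
        criteria.hbond_distance, criteria.salt_bridge_distance, criteria.nonpolar_distance
    )
    pairs = tree.query_pairs(max_cut)

    def _tag(c, r, a):
        return (c.id, r.seqid, r.name, a.name)

    contacts: list[InterfaceContact] = []
    for i, j in sorted(pairs):
        ci, ri, ai = entries[i]
        cj, rj, aj = entries[j]
        if ci.id == cj.id and ri.seqid == rj.seqid:
            continue
        if ci.id == cj.id and abs(ri.seqid - rj.seqid) == 1 and ai.name in ("C", "O") and aj.name in ("N", "CA"):
            continue  # peptide-bond neighbours
        dist = float(np.linalg.norm(ai.pos - aj.pos))
        inter = ci.id != cj.id
        # salt bridge
        made_salt = False
        for (rn, an, ro, ao) in ((ri, ai, rj, aj), (rj, aj, ri, ai)):
            if (
                rn.name in _NEG_GROUPS
                and an.name in _NEG_GROUPS[rn.name]
                and ro.name in _POS_GROUPS
                and ao.name in _POS_GROUPS[ro.name]
                and dist <= criteria.salt_bridge_distance
            ):
                contacts.append(
                    InterfaceContact(
                        ContactKind.SALT_BRIDGE,
                        _tag(ci, ri, ai),
                        _tag(cj, rj, aj),
                        dist,
                        inter_protomer=inter,
                    )
                )
                made_salt = True
                break
        if made_salt:
            continue
        # hydrogen bond (either direction)
        made_hbond = False
        if dist <= criteria.hbond_distance:
            for (rd, ad, cd), (ra, aa, ca_) in (
                ((ri, ai, ci), (rj, aj, cj)),
                ((rj, aj, cj), (ri, ai, ci)),
            ):
                ante_name = _DONORS.get((rd.name, ad.name)) or _DONORS.get(("*", ad.name))
                if ante_name is None:
                    continue
                if (ra.name, aa.name) not in _ACCEPTORS and ("*", aa.name) not in _ACCEPTORS:
                    continue
                ante = rd.atom(ante_name)
                if ante is None:
                    continue
                ang = _angle(ante.pos, ad.pos, aa.pos)
                if ang >= criteria.hbond_min_angle:
                    contacts.append(
                        InterfaceContact(
                            ContactKind.HBOND,
                            _tag(cd, rd, ad),
                            _tag(ca_, ra, aa),
                            dist,
                            angle=ang,
                            inter_protomer=inter,
                        )
                    )
                    made_hbond = True
                    break
        if made_hbond:
            continue
        # non-polar packing between apolar side chains
        if (
            dist <= criteria.nonpolar_distance
            and ai.element == "C"
            and aj.element == "C"
            and ai.name not in BACKBONE_ATOMS
            and aj.name not in BACKBONE_ATOMS
            and ri.name in _APOLAR_RESIDUES
            and rj.name in _APOLAR_RESIDUES
        ):
            contacts.append(
                InterfaceContact(
                    ContactKind.NONPOLAR,
                    _tag(ci, ri, ai),
                    _tag(cj, rj, aj),
                    dist,
                    inter_protomer=inter,
                )
            )
    return contacts


def ensemble_interface_report(
    model: Model,
    chain_a: str = "A",
    chain_b: str = "B",
    criteria: ContactCriteria = ContactCriteria(),
    **sasa_kwargs,
) -> InterfaceReport:
    """Buried area, per-residue burial and typed contacts for one model."""
    buried_total = buried_interface_area(
        model, chain_a, chain_b, per_protomer=False, **sasa_kwargs
    )
    per_res: dict[tuple[str, int], float] = {}
    for cid in (chain_a, chain_b):
        single = _chain_subset_model(model, [cid])
        atoms = [a for c in single.chains for r in c.residues for a in r.heavy_atoms]
        alone = sasa(atoms, **sasa_kwargs)
        pair = _chain_subset_model(model, [chain_a, chain_b])
        pair_atoms = [a for c in pair.chains for r in c.residues for a in r.heavy_atoms]
        together = sasa(pair_atoms, **sasa_kwargs)
        area_alone: dict[tuple[str, int], float] = {}
        area_pair: dict[tuple[str, int], float] = {}
        i = 0
        for c in single.chains:
            for r in c.residues:
                key = (c.id, r.seqid)
                n = len(r.heavy_atoms)
                area_alone[key] = float(alone[i : i + n].sum())
                i += n
        i = 0
        for c in pair.chains:
            for r in c.residues:
                key = (c.id, r.seqid)
                n = len(r.heavy_atoms)
                if c.id == cid:
                    area_pair[key] = float(together[i : i + n].sum())
                i += n
        for key, a0 in area_alone.items():
            if a0 > 0:
                per_res[key] = float(np.clip((a0 - area_pair.get(key, a0)) / a0, 0.0, 1.0))
            else:
                per_res[key] = 0.0
    contacts = find_contacts(model, criteria)
    return InterfaceReport(
        buried_area=buried_total / 2.0,
        buried_area_total=buried_total,
        per_residue_burial=per_res,
        contacts=contacts,
    )
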