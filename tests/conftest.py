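"""Shared fixtures: printed reference data and synthetic ground-truth inputs.

All structural/NMR fixtures are generated programmatically by the
synthetic-data module; the SEC fixtures are the printed elution-volume /
mass / radius pairs for the maltose-binding-protein (MltBP) fusion
constructs on a 2.41 mL analytical column.
"""

import numpy as np
import pytest

import oligostate as og

VT = 2.41  # mL, analytical column total volume

# Printed Rs calibration pairs (Ve mL, Rs A) for the S200 column
RS_PAIRS = [(1.27, 54.0), (1.40, 44.0), (1.47, 42.0), (1.57, 32.0)]
# Printed (Ve mL, AMW Da) pairs: tetramer, dimer fusion peaks
MW_PAIRS = [(1.27, 234e3), (1.40, 131e3), (1.42, 120e3)]
MONOMER_MASS = 48e3  # Da, half the 96 kDa expected fusion-dimer mass

# Published AAN table: construct, Ve (mL), printed AAN, state label
AAN_TABLE = [
    ("wild-type peak 1", 1.27, 4.8, og.OligomerState.HIGHER_ORDER),
    ("wild-type peak 2", 1.42, 2.4, og.OligomerState.DIMER),
    ("C59S", 1.40, 2.7, og.OligomerState.DIMER),
    ("C59S/E72G", 1.57, 1.2, og.OligomerState.MONOMER),
    ("C59S/R67A", 1.50, 1.7, og.OligomerState.MONOMER_DIMER),
    ("C59S/R67A/E72G peak 1", 1.39, 2.8, og.OligomerState.DIMER),
    ("C59S/R67A/E72G peak 2", 1.53, 1.5, og.OligomerState.MONOMER_DIMER),
    ("C59S/R67E/E72R", 1.46, 2.1, og.OligomerState.MONOMER_DIMER),
]


@pytest.fixture(scope="session")
def geometry():
    return og.ColumnGeometry(total_volume=VT, name="S200 PC 3.2/30")


@pytest.fixture(scope="session")
def rs_calibration(geometry):
    standards = [
        og.CalibrationStandard(mr, ve, rs)
        for (ve, rs), mr in zip(RS_PAIRS, (234e3, 131e3, 120e3, 96e3))
    ]
    return og.fit_calibration(standards, geometry)


@pytest.fixture(scope="session")
def mw_calibration(geometry):
    standards = [og.CalibrationStandard(mr, ve) for ve, mr in MW_PAIRS]
    return og.fit_calibration(standards, geometry)


@pytest.fixture(scope="session")
def fusion_species():
    return og.SpeciesSpec("MltBP fusion", MONOMER_MASS, rs_monomer=32.0, rs_dimer=44.0)


@pytest.fixture(scope="session")
def hairpin_spec():
    return og.HairpinGeometrySpec(
        residues_per_helix=14, interhelix_angle=31.0, docking_angle=85.0
    )


@pytest.fixture(scope="session")
def hairpin_dimer(hairpin_spec):
    return og.gen_hairpin_dimer(hairpin_spec)


@pytest.fixture(scope="session")
def rigid_relaxation():
    """Noiseless rigid-rotor table: every residue identical."""
    return og.gen_relaxation(
        og.RelaxationSimSpec(order_param_core=1.0, flexible_termini=0)
    )


@pytest.fixture(scope="session")
def default_relaxation():
    """Study-like profile: 39-residue structured core, 8 floppy residues
    per terminus, tau_c 9.9 ns at 500 MHz."""
    return og.gen_relaxation(og.RelaxationSimSpec())
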