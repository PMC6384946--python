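"""Shared fixtures: an independent transcription of the published gradient
design table, plus session-scoped synthetic datasets used across modules."""

from __future__ import annotations

import pytest

import gradret as g

# Independent row-by-row transcription of the published A/B design table:
# (run_id, split, pH_i, dpH_dt, phi_i, dphi_dt).  Kept separate from the
# packaged fixture so the two can be compared cell by cell.
TABLE1 = (
    ("1A", "train", 2.8, 0.0, 0.20, 0.06),
    ("2A", "val", 2.8, 0.0, 0.20, 0.03),
    ("3A", "train", 2.8, 0.0, 0.20, 0.015),
    ("4A", "test", 3.3, 0.0, 0.20, 0.03),
    ("5A", "test", 3.3, 0.0, 0.20, 0.02),
    ("6A", "train", 3.3, 0.0, 0.20, 0.015),
    ("7A", "test", 3.3, 0.0, 0.20, 0.01),
    ("8A", "train", 3.82, 0.0, 0.20, 0.06),
    ("9A", "test", 3.82, 0.0, 0.20, 0.018),
    ("10A", "train", 3.82, 0.0, 0.20, 0.012),
    ("11A", "train", 4.2, 0.0, 0.20, 0.03),
    ("12A", "train", 4.2, 0.0, 0.20, 0.015),
    ("13A", "val", 4.2, 0.0, 0.20, 0.01),
    ("14A", "val", 5.85, 0.0, 0.20, 0.015),
    ("15A", "train", 5.85, 0.0, 0.20, 0.01),
    ("16A", "test", 5.85, 0.0, 0.20, 0.0075),
    ("17A", "train", 7.8, 0.0, 0.20, 0.015),
    ("18A", "test", 7.8, 0.0, 0.20, 0.01),
    ("19A", "train", 7.8, 0.0, 0.20, 0.0075),
    ("1B", "train", 2.8, 0.79, 0.35, 0.0),
    ("2B", "val", 2.8, 0.527, 0.35, 0.0),
    ("3B", "test", 2.8, 0.395, 0.35, 0.0),
    ("4B", "train", 2.8, 0.263, 0.35, 0.0),
    ("5B", "val", 2.8, 0.527, 0.25, 0.0),
    ("6B", "train", 2.8, 0.527, 0.27, 0.0),
    ("7B", "test", 2.8, 0.527, 0.30, 0.0),
    ("8B", "train", 2.8, 0.263, 0.25, 0.0),
    ("9B", "test", 2.8, 0.263, 0.27, 0.0),
    ("10B", "train", 2.8, 0.263, 0.30, 0.0),
    ("11B", "train", 3.2, 0.580, 0.25, 0.0),
    ("12B", "train", 3.2, 0.387, 0.25, 0.0),
    ("13B", "val", 3.2, 0.290, 0.25, 0.0),
    ("14B", "train", 3.2, 0.193, 0.25, 0.0),
    ("15B", "train", 3.2, 0.387, 0.27, 0.0),
    ("16B", "test", 3.2, 0.387, 0.30, 0.0),
    ("17B", "test", 3.2, 0.387, 0.35, 0.0),
    ("18B", "train", 3.2, 0.290, 0.30, 0.0),
    ("19B", "val", 3.2, 0.290, 0.35, 0.0),
    ("20B", "test", 3.2, 0.193, 0.27, 0.0),
    ("21B", "train", 3.2, 0.193, 0.30, 0.0),
    ("22B", "train", 3.2, 0.193, 0.35, 0.0),
)


@pytest.fixture(scope="session")
def library():
    return g.default_solute_library()


@pytest.fixture(scope="session")
def sim_cfg():
    return g.SimulatorConfig(t0=2.0, noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def design_a():
    return g.load_design_fixture("A")


@pytest.fixture(scope="session")
def design_b():
    return g.load_design_fixture("B")


@pytest.fixture(scope="session")
def design_c():
    return g.load_design_fixture("C")


@pytest.fixture(scope="session")
def records_a(design_a, library, sim_cfg):
    return g.generate_retention_dataset(design_a, library, sim_cfg)


@pytest.fixture(scope="session")
def records_b(design_b, library, sim_cfg):
    return g.generate_retention_dataset(design_b, library, sim_cfg)


@pytest.fixture(scope="session")
def records_c(design_c, library, sim_cfg):
    return g.generate_retention_dataset(design_c, library, sim_cfg)


@pytest.fixture(scope="session")
def data_a(design_a, records_a):
    return g.assemble("A", design_a, records_a)


@pytest.fixture(scope="session")
def data_b(design_b, records_b):
    return g.assemble("B", design_b, records_b)


@pytest.fixture(scope="session")
def data_c(design_c, records_c):
    return g.assemble("C", design_c, records_c)
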