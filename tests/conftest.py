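"""Shared fixtures: simulated acquisitions reused across the suite.

The gain/dynamic-range invariance checks compare full re-acquisitions of
the *same* simulated bead preparation: bead-brightness draws are shared
(beads are physical objects), while photon shot noise, detector noise and
event order are redrawn with distinct seeds per acquisition.  Those checks
run at 250,000 events per control so that percentile sampling noise
(~1% between two acquisitions) sits well inside the asserted bounds;
reproducibility and gating-recovery checks use the 35,000-event acquisition
size the method prescribes.
"""

from __future__ import annotations

import numpy as np
import pytest

import sqiflow
from sqiflow.cli_report import controls_from_simulation

N_INVARIANCE = 250_000
#: PMT-voltage scenario moving the positive populations from ~110K to ~50K MFI.
GAIN_FACTOR_110K_TO_50K = 50_000 / 110_000
BIG_DYNAMIC_RANGE = 16_777_215.0


def run_pipeline(out: sqiflow.SimOutput):
    """Compensate, gate and compute both spread matrices for a panel."""
    controls = controls_from_simulation(out)
    return (
        sqiflow.compute_sqi_matrix(controls),
        sqiflow.compute_ssm(controls),
    )


def entry_map(matrix):
    return {(e.source_fluor, e.secondary_detector): e for e in matrix.entries}


def two_fluor_config(n_events: int, seed: int, spill: float = 0.05) -> sqiflow.SimConfig:
    """Minimal donor/acceptor pair: one fluorochrome spilling into the other's detector."""
    return sqiflow.SimConfig(
        fluorochromes=[
            sqiflow.FluorSpec("PE-Cy5", "YG670", 9000.0),
            sqiflow.FluorSpec("APC", "R670", 9000.0),
        ],
        spillover={
            "PE-Cy5": {"YG670": 1.0, "R670": spill},
            "APC": {"R670": 1.0, "YG670": 0.002},
        },
        n_events=n_events,
        seed=seed,
    )


@pytest.fixture(scope="session")
def invariance_config() -> sqiflow.SimConfig:
    return sqiflow.reference_config(n_events=N_INVARIANCE, seed=0)


@pytest.fixture(scope="session")
def shared_beads(invariance_config):
    return sqiflow.draw_brightness(invariance_config, seed=101)


@pytest.fixture(scope="session")
def base_acquisition(invariance_config, shared_beads):
    out = sqiflow.simulate_panel(invariance_config, seed=201, brightness=shared_beads)
    return run_pipeline(out)


@pytest.fixture(scope="session")
def lowgain_acquisition(invariance_config, shared_beads):
    cfg = sqiflow.gain_scenario(invariance_config, GAIN_FACTOR_110K_TO_50K)
    out = sqiflow.simulate_panel(cfg, seed=202, brightness=shared_beads)
    return run_pipeline(out)


@pytest.fixture(scope="session")
def highrange_acquisition(invariance_config, shared_beads):
    # Same photon-level panel rendered on a 7.2-decade-style scale, gains set
    # so the positive medians sit at the same relative scale position.
    factor = BIG_DYNAMIC_RANGE / 262_144.0
    cfg = sqiflow.gain_scenario(invariance_config, factor)
    cfg.dynamic_range = {d: BIG_DYNAMIC_RANGE for d in cfg.detectors}
    cfg.__post_init__()
    out = sqiflow.simulate_panel(cfg, seed=203, brightness=shared_beads)
    return run_pipeline(out)


@pytest.fixture(scope="session")
def fixtures_35k() -> sqiflow.SimOutput:
    return sqiflow.make_reference_fixtures(seed=5)
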