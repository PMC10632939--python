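import numpy as np
import pytest

import smokesim as ss
from smokesim.calibration import calibrate
from smokesim.sensitivity import one_way_grid


@pytest.fixture(scope="session")
def calibrated():
    """Baseline calibrated to the published status-quo anchors (shared)."""
    return calibrate(settings={"budget": 700, "restarts": 1})


@pytest.fixture(scope="session")
def baseline(calibrated):
    return calibrated.baseline


@pytest.fixture(scope="session")
def scenario_runs(baseline):
    """All seven scenario projections from the calibrated baseline."""
    return {
        name: ss.run_scenario(baseline, ss.build_scenario(name))
        for name in ss.SCENARIO_NAMES
    }


@pytest.fixture(scope="session")
def oneway(baseline):
    """Full one-way sensitivity grid under the combined endgame scenario."""
    return one_way_grid(baseline, ss.build_scenario("powe_tfg_r8000_r10"))


@pytest.fixture(scope="session")
def recovery_result():
    """Calibration against anchors produced by a known synthetic truth."""
    from smokesim.calibration import (
        CalibrationAnchors,
        SyntheticParams,
        make_synthetic_baseline,
        status_quo_projection,
    )

    truth = SyntheticParams(
        init_scale_male=0.097, init_scale_female=0.0105, init_peak_age=17.2
    )
    sq = status_quo_projection(make_synthetic_baseline(truth))
    years = (2025, 2030, 2035, 2040, 2045, 2050)
    anchors = CalibrationAnchors(
        start_prevalence=(35.3, 3.6),
        status_quo_path_male={y: sq.value(y, "male") for y in years},
        status_quo_path_female={y: sq.value(y, "female") for y in years},
    )
    fit = calibrate(
        anchors,
        settings={"budget": 900, "restarts": 1, "fatol": 1e-9, "xatol": 1e-5},
    )
    return truth, fit


@pytest.fixture()
def quick_baseline():
    """Uncalibrated synthetic baseline (fast, deterministic)."""
    return ss.make_synthetic_baseline()


@pytest.fixture()
def toy_grid():
    """Single male cohort of 1000 never-smokers aged 30."""
    g = ss.PopulationGrid(2022)
    g.counts[30, 0, 0] = 1000.0
    return g


def zero_demo():
    return ss.DemographicRates(np.zeros(86), np.zeros((86, 2)))


def zero_rates():
    return ss.TransitionRates(np.zeros((86, 2)), np.zeros((86, 2)), np.zeros((5, 2)))
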