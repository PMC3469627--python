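import numpy as np
import pytest

import copdsim as cs


@pytest.fixture(scope="session")
def defaults() -> cs.ParamSet:
    """Uncalibrated packaged defaults."""
    return cs.default_paramset()


@pytest.fixture(scope="session")
def calibrated() -> cs.ParamSet:
    """Defaults with the demography calibrated to the printed anchors."""
    return cs.default_demography()


@pytest.fixture(scope="session")
def base_run(calibrated) -> cs.ProjectionResult:
    """The no-intervention base-case projection."""
    return cs.simulate(calibrated)


@pytest.fixture(scope="session")
def intervention_runs(calibrated, base_run):
    """Incremental results for all nine intervention scenarios."""
    out = {}
    for iv in ("I", "II", "III"):
        for e in (0.10, 0.25, 0.50):
            res = cs.run_scenario(calibrated, cs.ScenarioSpec(iv, e))
            out[(iv, e)] = cs.compare_scenarios(base_run, res,
                                                calibrated.economics, e)
    return out


@pytest.fixture(scope="session")
def tornado_entries(calibrated):
    """One-way sensitivity at the conventional +/-25% range."""
    from copdsim.sensitivity import one_way_sensitivity
    return one_way_sensitivity(calibrated, relative_range=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(20110101)
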