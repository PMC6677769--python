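import pytest

import neuroreadout as nr


@pytest.fixture(scope="session")
def prf_two_area():
    """V1 + MT response functions at the passive-viewing group sensitivities."""
    return nr.default_prf_set(("V1", "MT"))


@pytest.fixture(scope="session")
def prf_eight_area():
    return nr.default_prf_set(nr.AREAS)


@pytest.fixture(scope="session")
def truth_two_area():
    """Flexible-readout ground-truth observer over V1 and MT."""
    return nr.default_truth(("V1", "MT"))


@pytest.fixture(scope="session")
def behavior_4000(prf_two_area, truth_two_area):
    """4,000 choice trials simulated from the flexible two-area truth."""
    cfg = nr.TaskConfig(n_runs=8, trials_per_run=500, catch_run_fraction=0.0)
    trials, _ = nr.generate_task_schedule(cfg, seed=11)
    return nr.simulate_observer(trials, truth_two_area, prf_two_area, seed=17)


def simulate_flexible_trials(seed, n_runs=8, trials_per_run=500, truth=None, prf=None):
    """Fresh simulated session; used where tests need many independent seeds."""
    prf = prf or nr.default_prf_set(("V1", "MT"))
    truth = truth or nr.default_truth(("V1", "MT"))
    cfg = nr.TaskConfig(n_runs=n_runs, trials_per_run=trials_per_run, catch_run_fraction=0.0)
    trials, _ = nr.generate_task_schedule(cfg, seed=seed)
    return nr.simulate_observer(trials, truth, prf, seed=seed + 1000)
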