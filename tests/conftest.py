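import numpy as np
import pytest

import caulocycle as cc


@pytest.fixture(scope="session")
def params():
    return cc.default_parameters()


@pytest.fixture(scope="session")
def init_state():
    return cc.default_initial_state()


@pytest.fixture(scope="session")
def box():
    return cc.default_search_box()


@pytest.fixture(scope="session")
def wt600(params):
    """One transient-plus-three-cycles wild-type run for fixtures and misfits."""
    return cc.simulate(params, duration=600.0, rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def settled_wt(params):
    """Long wild-type run, settled onto the limit cycle (default tolerances)."""
    return cc.simulate(params, duration=4000.0)


@pytest.fixture(scope="session")
def panel_summary(params):
    """Phenotype summary of the full builtin mutant panel plus wild type."""
    return cc.run_panel(params, duration=2500.0, rtol=1e-7, atol=1e-9)


@pytest.fixture(scope="session")
def panel_trajectories(params):
    """Raw trajectories for the mutants whose tests need time courses."""
    from caulocycle.mutants import apply_mutant, get_mutant

    out = {}
    for name in ("ccrM_del", "dnaA_del", "ctrA_proteolysis_const"):
        p = apply_mutant(params, get_mutant(name))
        out[name] = cc.simulate(p, duration=2500.0, rtol=1e-7, atol=1e-9)
    return out


@pytest.fixture(scope="session")
def noiseless_obs(wt600):
    return cc.generate_fixture(wt600, n_points=10, noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def mutant_periods(params):
    """Settled cycle periods (6000 min, 10 discarded cycles) for wild type and
    the two knockouts with quantitative period benchmarks."""
    from caulocycle.mutants import apply_mutant, get_mutant

    out = {}
    for name, p in [
        ("wildtype", params),
        ("ccrM_del", apply_mutant(params, get_mutant("ccrM_del"))),
        ("gcrA_del", apply_mutant(params, get_mutant("gcrA_del"))),
    ]:
        traj = cc.simulate(p, duration=6000.0)
        out[name] = cc.cycle_period(traj, discard=10).period
    return out


@pytest.fixture(scope="session")
def qssa_pair(params):
    """Matched full/QSSA runs for reduction-accuracy checks."""
    full = cc.simulate(params, duration=2000.0, rtol=1e-7, atol=1e-9)
    red = cc.simulate_qssa(params, duration=2000.0, rtol=1e-7, atol=1e-9)
    return full, red


@pytest.fixture(scope="session")
def recovery_errors(params, box, wt600):
    """Max relative parameter error of the 5-parameter noiseless refit,
    one entry per seed."""
    from caulocycle.fitting import refit_parameters

    errors = []
    for seed in (7, 8, 9):
        rng = np.random.default_rng(seed)
        names = list(rng.choice(box.names, size=5, replace=False))
        truth = np.array([params[n] for n in names])
        start = truth * (1 + 0.2 * rng.choice([-1.0, 1.0], size=5))
        obs = cc.generate_fixture(wt600, n_points=12, noise_sd=0.0, seed=seed)
        x, _ = refit_parameters(obs, params, box.subset(names), start=start)
        errors.append(float(np.max(np.abs(x - truth) / truth)))
    return errors


@pytest.fixture(scope="session")
def random_valid_states(params):
    """100 random physically valid states for two-implementation checks."""
    rng = np.random.default_rng(2024)
    states = []
    for _ in range(100):
        vals = {}
        for name in cc.STATE_NAMES:
            if name in ("hCori", "hccrM", "hctrA", "Elong", "Zring"):
                vals[name] = rng.uniform(0, 1)
            elif name == "Ini":
                vals[name] = rng.uniform(0, 0.05)
            elif name == "CckAP":
                vals[name] = rng.uniform(0, params.CckA_T)
            else:
                vals[name] = rng.uniform(0, 15.0)
        states.append(cc.CellState.from_mapping({**vals, "DNA": 1.0, "Count": 1}))
    return states
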