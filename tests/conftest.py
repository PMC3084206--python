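"""Shared fixtures: the bundled scenarios and expensive simulations are
computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from luxpulse import bundled_scenario
from luxpulse.kinetics import activity_deconvolved, growth_rate
from luxpulse.plate import align_replicates, blank_correct, from_run
from luxpulse.simulate import render_plate_run, simulate_diauxic_growth


@pytest.fixture(scope="session")
def dsm_scenario():
    return bundled_scenario("dsm")


@pytest.fixture(scope="session")
def dsm_traj(dsm_scenario):
    """Noiseless ground truth of the sporulation-medium scenario."""
    return simulate_diauxic_growth(dsm_scenario)


@pytest.fixture(scope="session")
def diauxie_trajs():
    return {
        name: simulate_diauxic_growth(bundled_scenario(name))
        for name in ("diauxie_low_glucose", "diauxie_mid_glucose",
                     "diauxie_glucose_only")
    }


def analyze_rendered_run(scenario, traj, seed, wells=2):
    """Measurement-layer analysis used by several tests: render a noisy
    plate run, blank-correct, average replicates, and estimate mu-hat and
    deconvolved activity per promoter with the default settings, trimming
    half a smoothing window at each end."""
    run = render_plate_run(traj, scenario, n_replicate_wells=wells, seed=seed)
    table = blank_correct(from_run(run), run.metadata["blank_wells"])
    groups: dict[str, list[str]] = {}
    for well, prom in run.metadata["well_map"].items():
        groups.setdefault(prom, []).append(well)
    agg = align_replicates(table, groups)
    delta = scenario.reporter.delta
    out = {}
    trim = 5
    sl = slice(trim, -trim)
    for prom in groups:
        sub = agg[agg["group"] == prom]
        od = sub[sub["channel"] == "OD600"].sort_values("time_h")
        rlu = sub[sub["channel"] == "RLU"].sort_values("time_h")
        t = od["time_h"].to_numpy()
        mu = growth_rate(t, od["mean"].to_numpy()).value
        act = activity_deconvolved(t, rlu["mean"].to_numpy(),
                                   od["mean"].to_numpy(), delta).value
        out[prom] = {"time": t[sl], "mu": mu[sl], "activity": act[sl]}
    return out


@pytest.fixture(scope="session")
def dsm_noisy_analyses(dsm_scenario, dsm_traj):
    """Default-settings analyses of noisy renderings for seeds 1..10."""
    return {seed: analyze_rendered_run(dsm_scenario, dsm_traj, seed)
            for seed in range(1, 11)}


@pytest.fixture(scope="session")
def dsm_pipeline_dir(tmp_path_factory):
    """One full pipeline run of the bundled scenario at seed 1."""
    from luxpulse.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline({"scenario": "dsm", "seed": 1}, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
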