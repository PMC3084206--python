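"""Generative model of luciferase plate-reader experiments.

The simulator produces ground-truth :class:`Trajectory` objects and
measurement-layer :class:`PlateRun` objects for a :class:`~luxpulse.scenarios.Scenario`:

1. **Growth**: batch diauxic growth on a ranked mixture of substrates,
   ``dX/dt = mu X`` with ``mu = sum_i g_i mu_max_i S_i / (K_i + S_i)`` and
   ``dS_i/dt = -mu_i X / Y_i``.  A less-preferred substrate is gated by an
   induction variable ``E_i`` (``dE_i/dt = k_ind * [preferred exhausted] -
   k_dec * E_i``), so exhaustion of the preferred source produces a growth
   pause of finite width before metabolism switches over.
2. **Polymerase allocation**: the fraction of RNA polymerase committed to
   rRNA synthesis rises with growth rate, ``f_rrn = f_max mu/(mu + K_mu)``;
   the free pool ``R_free = R_total (1 - f_rrn)`` is what passively
   regulated promoters compete for.  A growth pause therefore releases
   polymerase and bursts every polymerase-limited promoter.
3. **Promoters**: algebraic response laws per promoter class (see
   :class:`~luxpulse.scenarios.PromoterSpec`), an optional initiating-nucleotide
   (GTP-pool) factor, and scripted stationary-phase activity steps.
4. **Spo0A~P**: the master-regulator cascade driven by the spo0A-like
   promoter's activity; its phosphoform gates repressed/activated targets.
5. **Reporter**: per-cell destabilized luciferase ``dl/dt = A(t) - delta l``;
   emitted light ``L = light_coeff * l * X``.
6. **Measurement**: sampling on the plate-reader grid with independent
   multiplicative log-normal noise and an additive OD background.

All linear ODEs driven by gridded inputs (reporter, Spo0A protein and
phosphoform) are integrated with an exact piecewise-linear exponential
update, so constant-input solutions are reproduced to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, DomainError, IntegrationError
from .scenarios import (
    GtpDip,
    PromoterSpec,
    ReporterSpec,
    RnapParams,
    Scenario,
    Spo0AParams,
)

__all__ = [
    "Trajectory",
    "PlateRun",
    "allocate_rnap",
    "gtp_factor_series",
    "promoter_activity",
    "simulate_reporter",
    "simulate_spo0A_response",
    "simulate_diauxic_growth",
    "render_plate_run",
    "simulate_arrest",
]

# Substrate concentration (mg/ml) at which a pool counts as half exhausted;
# the indicator is a steep Hill function so the switch is sharp but smooth
# enough for a stiff integrator.
_EXHAUST_SCALE = 0.002
_EXHAUST_HILL = 4


@dataclass
class Trajectory:
    """Ground truth of one simulated run, sampled on the plate-reader grid."""

    time: np.ndarray
    biomass: np.ndarray
    substrates: dict[str, np.ndarray]
    induction: dict[str, np.ndarray]
    mu: np.ndarray
    f_rrn: np.ndarray
    R_free: np.ndarray
    gtp_factor: np.ndarray
    activity: dict[str, np.ndarray]
    reporter: dict[str, np.ndarray]
    light: dict[str, np.ndarray]
    spo0a_protein: np.ndarray
    spo0a_p: np.ndarray
    scenario: Scenario
    mass_balance_error: float = 0.0

    @property
    def growth_end(self) -> float:
        """First time every substrate is below 1% of its initial amount."""
        ok = np.ones_like(self.time, dtype=bool)
        for sub in self.scenario.medium.substrates:
            if sub.conc > 0:
                ok &= self.substrates[sub.name] < 0.01 * sub.conc
        idx = np.nonzero(ok)[0]
        return float(self.time[idx[0]]) if idx.size else float(self.time[-1])


@dataclass
class PlateRun:
    """Simulated dual-channel plate-reader output in long format.

    ``data`` has columns ``time_h, well, channel, value`` with channels
    ``OD600`` and ``RLU``; ``metadata`` records scenario name, seed, blank
    wells and the well -> promoter map.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def series(self, well: str, channel: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[(self.data["well"] == well) & (self.data["channel"] == channel)]
        return sub["time_h"].to_numpy(), sub["value"].to_numpy()

    def wells_for(self, promoter: str) -> list[str]:
        wm = self.metadata.get("well_map", {})
        return [w for w, p in wm.items() if p == promoter]


# ---------------------------------------------------------------------------
# Elementary model pieces


def allocate_rnap(mu, params: RnapParams):
    """Partition polymerase at growth rate ``mu`` (1/h).

    Returns ``(f_rrn, R_free)`` where ``f_rrn = f_max mu/(mu + K_mu)`` and
    ``R_free = R_total (1 - f_rrn)``.  ``mu`` may be a scalar or array;
    negative values are outside the model's domain.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("allocate_rnap: mu must be >= 0")
    f_rrn = params.f_max * mu / (mu + params.K_mu)
    r_free = params.R_total * (1.0 - f_rrn)
    if f_rrn.ndim == 0:
        return float(f_rrn), float(r_free)
    return f_rrn, r_free


def gtp_factor_series(time: np.ndarray, schedule: tuple[GtpDip, ...]) -> np.ndarray:
    """GTP-pool level in [0, 1] on the grid; scripted dips are imposed directly."""
    g = np.ones_like(np.asarray(time, dtype=float))
    for dip in schedule:
        mask = (time >= dip.start) & (time < dip.end)
        g[mask] = np.minimum(g[mask], 1.0 - dip.depth)
    return g


def _intp_factor(spec: PromoterSpec, gtp_factor) -> np.ndarray | float:
    """Initiating-nucleotide sensitivity, normalized to 1 at a full GTP pool."""
    if spec.initiating_nucleotide != "G":
        return 1.0
    g = np.asarray(gtp_factor, dtype=float)
    return (g * (1.0 + spec.intp_K)) / (g + spec.intp_K)


def promoter_activity(spec: PromoterSpec, f_rrn, R_free, gtp_factor=1.0, spo0A_P=0.0):
    """Instantaneous promoter activity (units/h) for one promoter class.

    All inputs may be scalars or arrays on a common grid.  ``gtp_factor``
    must lie in [0, 1]; it only matters for G-initiating promoters.
    """
    g = np.asarray(gtp_factor, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise DomainError("promoter_activity: gtp_factor must lie in [0, 1]")
    f_rrn = np.asarray(f_rrn, dtype=float)
    r_free = np.asarray(R_free, dtype=float)
    sp = np.asarray(spo0A_P, dtype=float)

    if spec.kind == "constitutive":
        act = spec.strength * r_free / (r_free + spec.K_R)
    elif spec.kind == "rrn_like":
        act = spec.strength * f_rrn
    elif spec.kind == "repressed":
        base = spec.strength * r_free / (r_free + spec.K_R)
        act = base / (1.0 + (sp / spec.regulator_K) ** spec.hill_n)
    elif spec.kind == "activated":
        with np.errstate(divide="ignore", invalid="ignore"):
            num = sp ** spec.hill_n
            act = spec.strength * num / (spec.regulator_K ** spec.hill_n + num)
        act = np.where(sp <= 0, 0.0, act)
    else:  # pragma: no cover - guarded by PromoterSpec validation
        raise ConfigurationError(f"unknown promoter class {spec.kind!r}")

    act = act * _intp_factor(spec, g)
    if np.ndim(act) == 0:
        return float(act)
    return np.asarray(act, dtype=float)


def _linear_ode_response(time: np.ndarray, u: np.ndarray, rate: float,
                         y0: float = 0.0) -> np.ndarray:
    """Solve ``dy/dt = u(t) - rate*y`` exactly for piecewise-linear ``u``."""
    t = np.asarray(time, dtype=float)
    u = np.asarray(u, dtype=float)
    y = np.empty_like(u)
    y[0] = y0
    h = np.diff(t)
    if rate > 0:
        eh = np.exp(-rate * h)
        b = (u[1:] - u[:-1]) / h
        c1 = (1.0 - eh) / rate
        for k in range(h.size):
            y[k + 1] = y[k] * eh[k] + u[k] * c1[k] + b[k] * (h[k] - c1[k]) / rate
    else:
        incr = 0.5 * (u[:-1] + u[1:]) * h
        y[1:] = y0 + np.cumsum(incr)
    return y


def _delay_series(time: np.ndarray, values: np.ndarray, delay: float) -> np.ndarray:
    if delay <= 0:
        return values
    return np.interp(time - delay, time, values, left=0.0)


def simulate_reporter(time, activity, biomass, reporter: ReporterSpec):
    """Integrate the per-cell reporter and return ``(per_cell, light)``.

    ``dl/dt = A(t) - delta l`` with ``l(0) = 0``; light is
    ``light_coeff * l * X``.  The three series must share one grid.
    """
    time = np.asarray(time, dtype=float)
    activity = np.asarray(activity, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    if not (time.shape == activity.shape == biomass.shape):
        raise DomainError("simulate_reporter: series must share the time grid")
    a = _delay_series(time, activity, reporter.maturation_delay)
    per_cell = _linear_ode_response(time, a, reporter.delta)
    light = reporter.light_coeff * per_cell * biomass
    return per_cell, light


def simulate_spo0A_response(time, activity, params: Spo0AParams, kappa=None):
    """Spo0A synthesis and phosphorylation driven by a promoter-activity series.

    ``dP/dt = A(t) - gamma_P P``; ``dSp/dt = k_phos P kappa(t) - k_deph Sp``.
    ``kappa`` is a kinase-availability profile on the same grid (default 1).
    Returns ``(protein, phosphoform)``.
    """
    time = np.asarray(time, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if kappa is None:
        kappa = np.ones_like(time)
    kappa = np.asarray(kappa, dtype=float)
    protein = _linear_ode_response(time, activity, params.gamma_P)
    drive = params.k_phos * protein * kappa
    phospho = _linear_ode_response(time, drive, params.k_deph)
    return protein, phospho


# ---------------------------------------------------------------------------
# Growth ODE


def _exhausted(s: np.ndarray) -> np.ndarray:
    """Smooth indicator that a substrate pool is gone (1 when S << scale)."""
    s = np.maximum(s, 0.0)
    return _EXHAUST_SCALE**_EXHAUST_HILL / (_EXHAUST_SCALE**_EXHAUST_HILL + s**_EXHAUST_HILL)


def _growth_rhs_factory(scenario: Scenario):
    med = scenario.medium
    subs = med.substrates
    n = len(subs)
    mu_max = np.array([s.mu_max for s in subs])
    ks = np.array([s.K_s for s in subs])
    yld = np.array([s.yield_od for s in subs])
    rank = np.array([med.preference_rank(s.name) for s in subs])
    k_ind, k_dec, k_lys = med.induction_rate, med.decay_rate, med.lysis_rate

    def rhs(_t, y):
        x = y[0]
        s = np.maximum(y[1 : 1 + n], 0.0)
        e = y[1 + n :]
        mono = mu_max * s / (ks + s)
        exh = _exhausted(s)
        gate = np.empty(n)
        ind = np.zeros(n)
        for i in range(n):
            higher = rank < rank[i]
            if not higher.any():
                gate[i] = 1.0
            else:
                ind[i] = float(np.prod(exh[higher]))
                gate[i] = min(max(e[i], 0.0), 1.0)
        mu_i = gate * mono
        lysis = k_lys * float(np.prod(exh)) if k_lys > 0 else 0.0
        dx = (mu_i.sum() - lysis) * x
        ds = -mu_i * x / yld
        de = k_ind * ind - k_dec * e
        return np.concatenate(([dx], ds, de))

    return rhs, subs, yld


def simulate_diauxic_growth(scenario: Scenario) -> Trajectory:
    """Run the full generative model and return the ground-truth trajectory.

    Integrates the batch growth ODE with a stiff-capable solver
    (rtol 1e-8), then evaluates polymerase allocation, per-promoter
    activities (including scripted stationary-phase steps), the Spo0A~P
    cascade, and the per-cell reporter on the sampling grid.
    """
    med = scenario.medium
    if not any(s.conc > 0 for s in med.substrates):
        positive = False
    else:
        positive = True
    dt = scenario.sampling_interval
    grid = np.arange(0.0, scenario.duration + dt / 2, dt)

    rhs, subs, _ = _growth_rhs_factory(scenario)
    n = len(subs)
    y0 = np.concatenate(([scenario.initial_biomass],
                         [s.conc for s in subs],
                         np.zeros(n)))
    if positive:
        sol = solve_ivp(rhs, (grid[0], grid[-1]), y0, method="LSODA",
                        t_eval=grid, rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise IntegrationError(f"growth integration failed: {sol.message}",
                                   time=float(sol.t[-1]) if sol.t.size else 0.0)
        ybad = ~np.isfinite(sol.y)
        if ybad.any():
            t_fail = float(grid[np.nonzero(ybad.any(axis=0))[0][0]])
            raise IntegrationError(f"non-finite ODE state at t = {t_fail:.3f} h",
                                   time=t_fail)
        states = sol.y
    else:
        states = np.tile(y0[:, None], (1, grid.size))

    biomass = states[0]
    s_arr = np.maximum(states[1 : 1 + n], 0.0)
    e_arr = states[1 + n :]

    # growth rate recomputed algebraically from the state
    mu = np.zeros_like(grid)
    rank = {s.name: med.preference_rank(s.name) for s in subs}
    exh = _exhausted(s_arr)
    for i, sub in enumerate(subs):
        mono = sub.mu_max * s_arr[i] / (sub.K_s + s_arr[i])
        if rank[sub.name] == 0:
            gate = 1.0
        else:
            gate = np.clip(e_arr[i], 0.0, 1.0)
        mu += gate * mono

    # mass balance: X - X0 = sum_i Y_i (S_i(0) - S_i(t)); exact when lysis = 0
    consumed = sum(sub.yield_od * (sub.conc - s_arr[i]) for i, sub in enumerate(subs))
    mb_err = float(np.max(np.abs(biomass - scenario.initial_biomass - consumed))) \
        if med.lysis_rate == 0 else float("nan")

    f_rrn, r_free = allocate_rnap(np.maximum(mu, 0.0), scenario.rnap)
    gtp = gtp_factor_series(grid, scenario.gtp_dip_schedule)

    def program_offset(name: str) -> np.ndarray:
        off = np.zeros_like(grid)
        for step in scenario.stationary_program:
            if step.promoter == name:
                off[grid >= step.time] += step.step
        return off

    # Spo0A~P cascade, driven by the designated promoter (must not itself be
    # Spo0A-regulated, or the cascade would be circular).
    if scenario.spo0a_promoter is not None:
        drv = scenario.promoter(scenario.spo0a_promoter)
        if drv.kind in ("repressed", "activated"):
            raise ConfigurationError(
                "spo0a_promoter must be constitutive or rrn_like")
        a_drv = promoter_activity(drv, f_rrn, r_free, gtp, 0.0)
        a_drv = np.maximum(a_drv + program_offset(drv.name), 0.0)
        protein, sp = simulate_spo0A_response(grid, a_drv, scenario.spo0a)
    else:
        protein = np.zeros_like(grid)
        sp = np.zeros_like(grid)

    activity: dict[str, np.ndarray] = {}
    reporter: dict[str, np.ndarray] = {}
    light: dict[str, np.ndarray] = {}
    for prom in scenario.promoters:
        act = promoter_activity(prom, f_rrn, r_free, gtp, sp)
        act = np.maximum(np.asarray(act) + program_offset(prom.name), 0.0)
        activity[prom.name] = act
        per_cell, lum = simulate_reporter(grid, act, biomass, scenario.reporter)
        reporter[prom.name] = per_cell
        light[prom.name] = lum

    return Trajectory(
        time=grid,
        biomass=biomass,
        substrates={sub.name: s_arr[i] for i, sub in enumerate(subs)},
        induction={sub.name: e_arr[i] for i, sub in enumerate(subs)},
        mu=mu,
        f_rrn=np.asarray(f_rrn),
        R_free=np.asarray(r_free),
        gtp_factor=gtp,
        activity=activity,
        reporter=reporter,
        light=light,
        spo0a_protein=protein,
        spo0a_p=sp,
        scenario=scenario,
        mass_balance_error=mb_err,
    )


# ---------------------------------------------------------------------------
# Measurement layer


def render_plate_run(trajectory: Trajectory, scenario: Scenario | None = None,
                     n_replicate_wells: int = 2, seed: int = 0,
                     n_blank_wells: int = 2,
                     extra_metadata: Mapping | None = None) -> PlateRun:
    """Sample a trajectory into a noisy dual-channel plate run.

    Each promoter gets ``n_replicate_wells`` wells named ``<promoter>.<i>``;
    blank wells carry medium only (OD background, zero light).  Every
    reading receives independent multiplicative log-normal noise with
    coefficient of variation ``scenario.noise_cv`` (mean-preserving), then
    the OD background is added.  Deterministic for a fixed seed.
    """
    if n_replicate_wells < 1:
        raise DomainError("n_replicate_wells must be >= 1")
    scenario = scenario or trajectory.scenario
    rng = np.random.default_rng(seed)
    cv = scenario.noise_cv
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0

    def noisy(values: np.ndarray) -> np.ndarray:
        if sigma == 0.0:
            return values
        z = rng.standard_normal(values.shape)
        return values * np.exp(sigma * z - 0.5 * sigma * sigma)

    t = trajectory.time
    frames = []
    well_map: dict[str, str] = {}
    for prom in scenario.promoters:
        for i in range(1, n_replicate_wells + 1):
            well = f"{prom.name}.{i}"
            well_map[well] = prom.name
            od = scenario.od_background + noisy(trajectory.biomass)
            rlu = noisy(trajectory.light[prom.name])
            frames.append(pd.DataFrame({"time_h": t, "well": well,
                                        "channel": "OD600", "value": od}))
            frames.append(pd.DataFrame({"time_h": t, "well": well,
                                        "channel": "RLU", "value": rlu}))
    blanks = []
    for i in range(1, n_blank_wells + 1):
        well = f"blank.{i}"
        blanks.append(well)
        od = scenario.od_background + noisy(np.zeros_like(t))
        rlu = noisy(np.zeros_like(t))
        frames.append(pd.DataFrame({"time_h": t, "well": well,
                                    "channel": "OD600", "value": od}))
        frames.append(pd.DataFrame({"time_h": t, "well": well,
                                    "channel": "RLU", "value": rlu}))
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "scenario": scenario.name,
        "seed": int(seed),
        "noise_cv": cv,
        "od_background": scenario.od_background,
        "blank_wells": blanks,
        "well_map": well_map,
        "reporter_half_life_h": scenario.reporter.half_life,
    }
    if extra_metadata:
        meta.update(dict(extra_metadata))
    return PlateRun(data=data, metadata=meta)


def arrest_trajectory(scenario: Scenario, t_arrest: float) -> Trajectory:
    """Ground truth of a translation-arrest (puromycin-like) experiment.

    From ``t_arrest`` on, all promoter activities are zero and biomass is
    frozen; the reporter keeps decaying with rate ``delta``, so the
    post-arrest light trace is a pure exponential.
    """
    traj = simulate_diauxic_growth(scenario)
    t = traj.time
    if not (t[0] <= t_arrest <= t[-1]):
        raise DomainError(
            f"t_arrest = {t_arrest} h lies outside the run [0, {t[-1]:.3f}] h")
    idx = int(np.searchsorted(t, t_arrest))
    biomass = traj.biomass.copy()
    biomass[idx:] = biomass[idx - 1] if idx > 0 else scenario.initial_biomass
    mu = traj.mu.copy()
    mu[idx:] = 0.0

    activity = {}
    reporter = {}
    light = {}
    for name, act in traj.activity.items():
        a = act.copy()
        a[idx:] = 0.0
        activity[name] = a
        per_cell, lum = simulate_reporter(t, a, biomass, scenario.reporter)
        reporter[name] = per_cell
        light[name] = lum
    if scenario.spo0a_promoter is not None:
        a_drv = activity[scenario.spo0a_promoter]
        protein, sp = simulate_spo0A_response(t, a_drv, scenario.spo0a)
    else:
        protein, sp = traj.spo0a_protein, traj.spo0a_p
    return Trajectory(
        time=t, biomass=biomass, substrates=traj.substrates,
        induction=traj.induction, mu=mu, f_rrn=traj.f_rrn, R_free=traj.R_free,
        gtp_factor=traj.gtp_factor, activity=activity, reporter=reporter,
        light=light, spo0a_protein=protein, spo0a_p=sp, scenario=scenario,
        mass_balance_error=traj.mass_balance_error,
    )


def simulate_arrest(scenario: Scenario, t_arrest: float, seed: int = 0,
                    n_replicate_wells: int = 2) -> PlateRun:
    """Simulate a translation-arrest run and render it as a plate run."""
    traj = arrest_trajectory(scenario, t_arrest)
    return render_plate_run(traj, scenario, n_replicate_wells=n_replicate_wells,
                            seed=seed, extra_metadata={"t_arrest_h": t_arrest})
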