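"""Stochastic simulation of elastically coupled motor-protein teams.

A team of ``n_dimers`` motors is modelled as a star: every engaged motor is
attached through an identical linear spring of stiffness ``k_stiff`` to a
massless cargo node, so force balance places the node at the mean of the
engaged head positions.  Each motor carries a persistent intrinsic velocity
drawn once per run, advances with a linear force-velocity relation that
stalls at ``f_stall``, and detaches with a force-accelerated (capped
exponential) rate.  Detached motors re-engage at the node position with rate
``k_on``.  A run ends when no motor is engaged.

Positions are in nm (positive toward the microtubule minus end), forces in
pN, stiffness in pN/nm, rates in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TeamParams",
    "TeamRun",
    "SizeStats",
    "force_velocity",
    "unbinding_rate",
    "simulate_run",
    "simulate_batch",
    "size_sweep",
    "fit_team_params",
]

# per-step event probabilities above this indicate dt is too coarse
_MAX_STEP_PROB = 0.1


@dataclass(frozen=True)
class TeamParams:
    """Parameters of the coupled-team simulation.

    ``f_detach`` defaults to ``f_stall / ln(k_off_max / k_off0)`` so the
    unbinding rate reaches its cap exactly at stall.
    """

    v_mean: float = 50.0          # unloaded velocity (nm/s)
    v_sd: float = 20.0            # per-motor velocity SD (nm/s)
    f_stall: float = 1.0          # stall force (pN)
    k_on: float = 0.55            # re-engagement rate (1/s)
    k_off0: float = 0.08          # unloaded unbinding rate (1/s)
    k_off_max: float = 4.0        # saturated unbinding rate (1/s)
    k_stiff: float = 0.03         # linker stiffness (pN/nm)
    f_detach: float | None = None  # force scale of unbinding exponential (pN)
    dt: float = 1e-3              # integration step (s)
    force_dependent: bool = True  # full model vs force-independent variant
    n_dimers: int = 1
    all_bound_start: bool = False  # start with every motor engaged at x=0
    record_stride: int = 1        # trajectory sampling stride (steps)
    max_time: float | None = None  # optional hard cap (censors the run)

    def __post_init__(self) -> None:
        for name in ("v_mean", "f_stall", "k_off0", "k_off_max", "k_stiff", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.v_sd < 0:
            raise ValueError("v_sd must be >= 0")
        if self.k_on < 0:
            raise ValueError("k_on must be >= 0")
        if self.k_off_max < self.k_off0:
            raise ValueError("k_off_max must be >= k_off0")
        if self.n_dimers < 1:
            raise ValueError("n_dimers must be >= 1")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.f_detach is None:
            object.__setattr__(
                self, "f_detach", self.f_stall / math.log(self.k_off_max / self.k_off0)
            ) if self.k_off_max > self.k_off0 else object.__setattr__(
                self, "f_detach", math.inf
            )
        elif self.f_detach <= 0:
            raise ValueError("f_detach must be strictly positive")
        # event probabilities per step must stay well below 1
        p_max = max(self.k_off_max, self.k_on) * self.dt
        if p_max >= _MAX_STEP_PROB:
            raise ValueError(
                f"dt={self.dt} too large for the rates: max per-step "
                f"probability {p_max:.3f} >= {_MAX_STEP_PROB}"
            )


@dataclass
class TeamRun:
    """Outcome of a single team run."""

    time_s: np.ndarray            # sampled times
    x_node_nm: np.ndarray         # node trajectory at the sampled times
    bound_count: np.ndarray       # number of engaged motors at the samples
    run_length: float             # nm, node displacement start -> end
    run_time: float               # s
    mean_velocity: float          # nm/s, least-squares slope of trajectory
    censored: bool = False        # ended by max_time, not full detachment


@dataclass
class SizeStats:
    """Per-team-size motility summary."""

    sizes: np.ndarray
    velocity_mean: np.ndarray
    velocity_sd: np.ndarray
    run_length_mean: np.ndarray
    run_length_sd: np.ndarray
    n_runs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_dimers": self.sizes,
                "velocity_mean_nm_s": self.velocity_mean,
                "velocity_sd_nm_s": self.velocity_sd,
                "run_length_mean_nm": self.run_length_mean,
                "run_length_sd_nm": self.run_length_sd,
                "n_runs": self.n_runs,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SizeStats":
        return cls(
            sizes=df["n_dimers"].to_numpy(),
            velocity_mean=df["velocity_mean_nm_s"].to_numpy(float),
            velocity_sd=df["velocity_sd_nm_s"].to_numpy(float),
            run_length_mean=df["run_length_mean_nm"].to_numpy(float),
            run_length_sd=df["run_length_sd_nm"].to_numpy(float),
            n_runs=df["n_runs"].to_numpy(),
        )


def force_velocity(f_load: float, nu_i: float, params: TeamParams):
    """Velocity of one motor under the spring force acting on it.

    ``f_load`` is the signed spring force (positive pulls the motor forward,
    toward the minus end).  Only the opposing component ``L = max(0, -f)``
    slows the motor; the relation is linear down to zero at ``f_stall`` and
    the result is clamped to ``[0, nu_i]`` (assisting load does not speed the
    motor up and there is no backward stepping).
    """
    nu = np.asarray(nu_i, dtype=float)
    if np.any(nu < 0):
        raise ValueError("intrinsic velocity must be >= 0")
    if not params.force_dependent:
        return nu_i
    load = np.maximum(0.0, -np.asarray(f_load, dtype=float))
    v = nu * np.clip(1.0 - load / params.f_stall, 0.0, 1.0)
    return float(v) if np.isscalar(f_load) and np.isscalar(nu_i) else v


def unbinding_rate(f_mag, params: TeamParams):
    """Detachment rate at spring-force magnitude ``f_mag`` (pN).

    Capped exponential: ``min(k_off0 * exp(f/f_detach), k_off_max)``;
    constant ``k_off0`` in the force-independent variant.
    """
    f = np.asarray(f_mag, dtype=float)
    if np.any(f < 0):
        raise ValueError("force magnitude must be >= 0")
    if not params.force_dependent:
        out = np.full_like(f, params.k_off0)
    else:
        out = np.minimum(params.k_off0 * np.exp(f / params.f_detach), params.k_off_max)
    return float(out) if np.isscalar(f_mag) else out


def _draw_velocities(rng: np.random.Generator, shape, mean: float, sd: float) -> np.ndarray:
    """Normal(mean, sd) truncated at zero by redrawing."""
    v = rng.normal(mean, sd, size=shape)
    while True:
        neg = v < 0
        if not neg.any():
            return v
        v[neg] = rng.normal(mean, sd, size=int(neg.sum()))


def simulate_batch(
    params: TeamParams,
    n_runs: int,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Simulate ``n_runs`` independent runs; return per-run summary table.

    Columns: run_id, n_dimers, run_length_nm, run_time_s, velocity_nm_s,
    censored.  All runs advance in lockstep on vectorised state arrays;
    finished runs are compacted away.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n, dt = params.n_dimers, params.dt

    nu = _draw_velocities(rng, (n_runs, n), params.v_mean, params.v_sd)
    x = np.zeros((n_runs, n))
    bound = np.zeros((n_runs, n), dtype=bool)
    if params.all_bound_start:
        bound[:] = True
    else:
        bound[:, 0] = True

    # per-run accumulators for the least-squares slope of x_node vs t
    s1 = np.zeros(n_runs)
    st = np.zeros(n_runs)
    stt = np.zeros(n_runs)
    sx = np.zeros(n_runs)
    stx = np.zeros(n_runs)

    run_length = np.zeros(n_runs)
    run_time = np.zeros(n_runs)
    censored = np.zeros(n_runs, dtype=bool)
    idx = np.arange(n_runs)  # original run ids of the active rows

    p_on = params.k_on * dt
    t = 0.0
    while idx.size:
        nb = bound.sum(axis=1)
        x_node = np.where(bound, x, 0.0).sum(axis=1) / nb
        f = np.where(bound, params.k_stiff * (x_node[:, None] - x), 0.0)
        v = force_velocity(f, nu, params) if params.force_dependent else nu
        x = np.where(bound, x + v * dt, x)
        x_new = np.where(bound, x, 0.0).sum(axis=1) / nb
        t += dt

        s1[idx] += 1.0
        st[idx] += t
        stt[idx] += t * t
        sx[idx] += x_new
        stx[idx] += t * x_new

        p_off = unbinding_rate(np.abs(f), params) * dt
        u = rng.random((idx.size, n))
        unbind = bound & (u < p_off)
        rebind = ~bound & (u < p_on)
        bound ^= unbind
        x = np.where(rebind, x_new[:, None], x)
        bound |= rebind

        done = ~bound.any(axis=1)
        if params.max_time is not None and t >= params.max_time:
            censored[idx[~done]] = True
            done[:] = True
        if done.any():
            fin = idx[done]
            run_length[fin] = x_new[done]
            run_time[fin] = t
            keep = ~done
            idx, x, bound, nu = idx[keep], x[keep], bound[keep], nu[keep]

    denom = s1 * stt - st * st
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (s1 * stx - st * sx) / denom
    slope = np.where(denom > 0, slope, 0.0)

    return pd.DataFrame(
        {
            "run_id": np.arange(n_runs),
            "n_dimers": params.n_dimers,
            "run_length_nm": run_length,
            "run_time_s": run_time,
            "velocity_nm_s": slope,
            "censored": censored,
        }
    )


def simulate_run(params: TeamParams, seed: int | np.random.Generator) -> TeamRun:
    """Simulate one run, recording the node trajectory.

    The scheme is fixed-step: at each step the node is placed at the mean of
    the engaged head positions, spring forces are evaluated, engaged heads
    advance by ``force_velocity * dt``, then Bernoulli detachment and
    re-engagement draws are made.  Terminates when no head is engaged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, dt = params.n_dimers, params.dt

    nu = _draw_velocities(rng, n, params.v_mean, params.v_sd)
    x = np.zeros(n)
    bound = np.ones(n, dtype=bool) if params.all_bound_start else np.array(
        [True] + [False] * (n - 1)
    )

    times = [0.0]
    nodes = [0.0]
    counts = [int(bound.sum())]
    s1 = st = stt = sx = stx = 0.0
    t = 0.0
    step = 0
    censored = False
    p_on = params.k_on * dt

    while bound.any():
        nb = bound.sum()
        x_node = x[bound].mean()
        f = np.where(bound, params.k_stiff * (x_node - x), 0.0)
        v = force_velocity(f, nu, params) if params.force_dependent else nu
        x = np.where(bound, x + v * dt, x)
        x_new = x[bound].mean()
        t += dt
        step += 1

        s1 += 1.0
        st += t
        stt += t * t
        sx += x_new
        stx += t * x_new

        p_off = unbinding_rate(np.abs(f), params) * dt
        u = rng.random(n)
        unbind = bound & (u < p_off)
        rebind = ~bound & (u < p_on)
        bound = (bound & ~unbind) | rebind
        x = np.where(rebind, x_new, x)

        if step % params.record_stride == 0 or not bound.any():
            times.append(t)
            nodes.append(x_new)
            counts.append(int(bound.sum()))
        if params.max_time is not None and t >= params.max_time and bound.any():
            censored = True
            break

    denom = s1 * stt - st * st
    slope = (s1 * stx - st * sx) / denom if denom > 0 else 0.0
    return TeamRun(
        time_s=np.asarray(times),
        x_node_nm=np.asarray(nodes),
        bound_count=np.asarray(counts),
        run_length=nodes[-1] - nodes[0],
        run_time=t,
        mean_velocity=slope,
        censored=censored,
    )


def size_sweep(
    params: TeamParams,
    sizes: Sequence[int],
    n_runs: int,
    seed: int | np.random.Generator,
) -> SizeStats:
    """Mean/SD of run velocity and run length for each team size."""
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes list must not be empty")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vm, vs, rm, rs = [], [], [], []
    for size in sizes:
        runs = simulate_batch(replace(params, n_dimers=int(size)), n_runs, rng)
        vm.append(runs["velocity_nm_s"].mean())
        vs.append(runs["velocity_nm_s"].std(ddof=1))
        rm.append(runs["run_length_nm"].mean())
        rs.append(runs["run_length_nm"].std(ddof=1))
    return SizeStats(
        sizes=np.asarray(sizes),
        velocity_mean=np.asarray(vm),
        velocity_sd=np.asarray(vs),
        run_length_mean=np.asarray(rm),
        run_length_sd=np.asarray(rs),
        n_runs=np.full(len(sizes), n_runs),
    )


def _objective(sim: SizeStats, obs: SizeStats) -> float:
    eps = np.finfo(float).eps
    total = 0.0
    for stat in ("velocity_mean", "velocity_sd", "run_length_mean", "run_length_sd"):
        s = getattr(sim, stat)
        o = getattr(obs, stat)
        if np.any(~np.isfinite(s)) or np.any(~np.isfinite(o)):
            raise ValueError(f"non-finite {stat} in objective")
        total += float(np.sum(((s - o) / (np.abs(o) + eps)) ** 2))
    return total


def fit_team_params(
    observed: SizeStats,
    grid: dict[str, Sequence[float]],
    fixed: TeamParams,
    n_runs: int,
    seed: int,
) -> tuple[TeamParams, pd.DataFrame]:
    """Grid search over (f_stall, k_on, k_off_max) against observed size stats.

    The objective is the sum over team sizes and over the four statistics
    (mean/SD of velocity and run length) of squared relative deviations.
    Every grid point is simulated with the same seed (common random numbers)
    so the surface is comparable across points.  Returns the best-fitting
    parameter set and the full objective table.
    """
    if observed.sizes.size < 2:
        raise ValueError("observed table must cover at least 2 sizes")
    allowed = {"f_stall", "k_on", "k_off_max"}
    if not grid or not set(grid) <= allowed:
        raise ValueError(f"grid keys must be a non-empty subset of {sorted(allowed)}")
    keys = sorted(grid)
    rows = []
    best: tuple[float, TeamParams] | None = None
    for values in product(*(grid[k] for k in keys)):
        candidate = replace(fixed, **dict(zip(keys, values)))
        sim = size_sweep(candidate, observed.sizes, n_runs, np.random.default_rng(seed))
        obj = _objective(sim, observed)
        rows.append(dict(zip(keys, values), objective=obj))
        if best is None or obj < best[0]:
            best = (obj, candidate)
    assert best is not None
    return best[1], pd.DataFrame(rows)
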