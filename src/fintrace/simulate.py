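"""Synthetic cohorts: behavioral-state trajectories and respiration counts.

The generator emulates the structure of single-fish free-swimming
recordings: a hidden three-state behavioral process (rest / moderate /
fast, the same classes the speed-activity-profile analysis recovers)
drives per-second swimming speeds, which are realised as a correlated
random walk inside a rectangular tank at a fixed frame rate.

Model
-----
* **States.** A semi-Markov process with exponential dwell times.  The
  next state is drawn independently of the current one with probability
  ``q_j ∝ occupancy_j / dwell_j``, which makes the long-run fraction of
  time in state *j* exactly ``occupancy_j`` (renewal-reward identity);
  the initial state is drawn from the occupancy vector itself, so the
  process is stationary from the first frame.  The behavioral state of a
  1 s analysis window is the state occupying the window's start time.
* **Speeds.** Within each 1 s window a speed is drawn from the state's
  truncated-normal distribution, truncated to that state's band
  ([0, 0.5), [0.5, 3), [3, cap) body lengths/s), so the hidden state is
  recoverable from the realised speed by construction.
* **Positions.** The window speed is realised as ``fps`` equal steps
  along a heading that evolves by von-Mises increments between windows.
  Tank walls reflect by flipping the offending step component, which
  preserves every inter-frame step length exactly — per-second path
  length equals the drawn speed, the oracle used by the test suite.
* **Vertical recordings.** Depth follows a mean-reverting Gaussian
  copula AR(1) whose stationary marginal is a truncated normal solved so
  that the probability of being in the upper quarter equals the
  configured target exactly.

Every fish also gets a hidden-truth sidecar (per-second state and
speed); it is test scaffolding and is never read by the analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy import stats as sps

from .trajectory import RespirationRecord, Trajectory

STATE_NAMES = ("rest", "moderate", "fast")

#: SAP band edges in body lengths per second (rest < 0.5 <= moderate < 3 <= fast)
REST_UPPER_BL_S = 0.5
FAST_LOWER_BL_S = 3.0
#: upper truncation of the fast-state speed distribution (bl/s); adult
#: zebrafish rarely sustain more than ~6 bl/s outside startle responses
FAST_SPEED_CAP_BL_S = 6.0

#: spread (fraction of water-column height) of the stationary depth marginal
VERTICAL_SIGMA = 0.2


class ConfigError(ValueError):
    """Raised for invalid or unreachable simulator configurations."""


@dataclass(frozen=True)
class SpeedParams:
    """Truncated-normal speed distribution for one state, in bl/s."""

    mean_bl_s: float
    sd_bl_s: float


@dataclass(frozen=True)
class GenotypeParams:
    """Behavioral parameters for one genotype block of a cohort.

    ``state_occupancy`` are long-run time fractions (must sum to 1);
    ``state_mean_dwell_s`` are mean bout durations in seconds;
    ``vertical_preference`` is the target fraction of time in the upper
    quarter of the water column (vertical recordings only).
    """

    state_occupancy: tuple[float, float, float]
    state_mean_dwell_s: tuple[float, float, float] = (8.0, 6.0, 2.5)
    state_speed_params: tuple[SpeedParams, SpeedParams, SpeedParams] = (
        SpeedParams(0.15, 0.12),
        SpeedParams(1.2, 0.6),
        SpeedParams(3.8, 0.7),
    )
    turning_concentration: float = 4.0
    vertical_preference: float = 0.25
    vertical_reversion_time_s: float = 5.0
    respiration_rate_per_min: float = 120.0
    respiration_scatter_sigma: float = 0.10  # between-fish lognormal scatter

    def __post_init__(self) -> None:
        occ = np.asarray(self.state_occupancy, dtype=float)
        if occ.shape != (3,) or (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
            raise ConfigError("state_occupancy must be 3 non-negative fractions summing to 1")
        if any(d <= 0 for d in self.state_mean_dwell_s):
            raise ConfigError("state_mean_dwell_s must be positive")
        bands = state_speed_bands_bl_s()
        for name, sp, (lo, hi) in zip(STATE_NAMES, self.state_speed_params, bands):
            inside = lo < sp.mean_bl_s < hi or (sp.mean_bl_s == lo == 0.0)
            if not inside:
                raise ConfigError(
                    f"{name} speed mean {sp.mean_bl_s} bl/s outside its band [{lo}, {hi})"
                )
            if sp.sd_bl_s < 0:
                raise ConfigError("speed sd must be >= 0")
        if not 0.0 < self.vertical_preference < 1.0:
            raise ConfigError(
                "vertical_preference must lie strictly between 0 and 1 "
                "(the target occupancy is unreachable otherwise)"
            )
        if self.respiration_rate_per_min <= 0:
            raise ConfigError("respiration_rate_per_min must be positive")


def state_speed_bands_bl_s() -> tuple[tuple[float, float], ...]:
    """Half-open speed band per state in body lengths per second."""
    return (
        (0.0, REST_UPPER_BL_S),
        (REST_UPPER_BL_S, FAST_LOWER_BL_S),
        (FAST_LOWER_BL_S, FAST_SPEED_CAP_BL_S),
    )


@dataclass(frozen=True)
class CohortConfig:
    """A full simulated cohort: one parameter block per genotype."""

    genotype_params: dict[str, GenotypeParams]
    n_fish: int = 10
    duration_s: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish <= 0 or self.duration_s <= 0:
            raise ConfigError("n_fish and duration_s must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Hidden per-second truth for one simulated fish (test scaffolding)."""

    fish_id: str
    second: np.ndarray
    state: np.ndarray  # integer index into STATE_NAMES
    speed_cm_s: np.ndarray


def write_sidecar(truth: SimTruth, path) -> None:
    pd.DataFrame(
        {"second": truth.second, "state": truth.state, "speed_cm_s": truth.speed_cm_s}
    ).to_csv(path, index=False, float_format="%.17g")


def read_sidecar(path, fish_id: str = "") -> SimTruth:
    df = pd.read_csv(path)
    return SimTruth(
        fish_id,
        df["second"].to_numpy(np.int64),
        df["state"].to_numpy(np.int64),
        df["speed_cm_s"].to_numpy(float),
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_states(
    params: GenotypeParams, duration_s: int, rng
) -> np.ndarray:
    """Per-second hidden state sequence (stationary semi-Markov sample)."""
    rng = _rng(rng)
    occ = np.asarray(params.state_occupancy, float)
    dwell = np.asarray(params.state_mean_dwell_s, float)
    q = np.where(occ > 0, occ / dwell, 0.0)
    q /= q.sum()
    # first bout from the time-stationary law (exponential dwells are
    # memoryless, so a fresh dwell is also the correct residual dwell);
    # subsequent bouts i.i.d. from q, drawn in chunks until covered
    s0 = int(rng.choice(3, p=occ))
    states: list[np.ndarray] = [np.array([s0])]
    durs: list[np.ndarray] = [rng.exponential(dwell[s0], size=1)]
    covered = float(durs[0][0])
    mean_bout = float(q @ dwell)
    while covered < duration_s:
        k = max(16, int(1.5 * (duration_s - covered) / mean_bout))
        s = rng.choice(3, size=k, p=q)
        d = rng.exponential(dwell[s])
        states.append(s)
        durs.append(d)
        covered += float(d.sum())
    s_all = np.concatenate(states)
    cum = np.cumsum(np.concatenate(durs))
    t = np.arange(duration_s, dtype=float)
    return s_all[np.searchsorted(cum, t, side="right")]


def _draw_speeds_bl_s(params: GenotypeParams, states: np.ndarray, rng) -> np.ndarray:
    speeds = np.zeros(len(states))
    bands = state_speed_bands_bl_s()
    for i, (sp, (lo, hi)) in enumerate(zip(params.state_speed_params, bands)):
        mask = states == i
        n = int(mask.sum())
        if n == 0:
            continue
        if sp.sd_bl_s == 0:
            speeds[mask] = sp.mean_bl_s
        else:
            a = (lo - sp.mean_bl_s) / sp.sd_bl_s
            b = (hi - sp.mean_bl_s) / sp.sd_bl_s
            speeds[mask] = sps.truncnorm.rvs(
                a, b, loc=sp.mean_bl_s, scale=sp.sd_bl_s, size=n, random_state=rng
            )
    return speeds


def simulate_speed_series(
    params: GenotypeParams, duration_s: int, rng, body_length_cm: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Hidden states and per-second speeds (cm/s) without positions.

    Fast path for statistical calibration studies, where only the
    per-second speed record matters; identical in law to the speeds
    embedded in a full simulated trajectory.
    """
    rng = _rng(rng)
    states = simulate_states(params, duration_s, rng)
    speeds = _draw_speeds_bl_s(params, states, rng) * body_length_cm
    return states, speeds


def _crw_positions(
    x0: float,
    y0: float,
    headings: np.ndarray,
    speeds_cm_s: np.ndarray,
    fps: int,
    width: float,
    height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Realise per-second speeds as equal steps with reflecting walls."""
    n_sec = len(speeds_cm_s)
    xs = np.empty(n_sec * fps + 1)
    ys = np.empty(n_sec * fps + 1)
    x, y = x0, y0
    xs[0], ys[0] = x, y
    k = 1
    cos, sin = math.cos, math.sin
    for s in range(n_sec):
        step = speeds_cm_s[s] / fps
        h = headings[s]
        dx = step * cos(h)
        dy = step * sin(h)
        for _ in range(fps):
            nx = x + dx
            if nx < 0.0 or nx > width:
                dx = -dx
                nx = x + dx
            ny = y + dy
            if ny < 0.0 or ny > height:
                dy = -dy
                ny = y + dy
            x, y = nx, ny
            xs[k] = x
            ys[k] = y
            k += 1
    return xs, ys


def _vertical_positions(
    params: GenotypeParams, n_frames: int, fps: int, height: float, rng
) -> np.ndarray:
    """Depth series with exact stationary upper-quarter probability."""
    p = params.vertical_preference
    sigma = VERTICAL_SIGMA
    # truncated normal on [0, 1]; solve the location so that P(Y >= 0.75) = p
    def tail(mu: float) -> float:
        a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
        return sps.truncnorm.sf(0.75, a, b, loc=mu, scale=sigma) - p

    mu = optimize.brentq(tail, -3.0, 4.0, xtol=1e-12)
    rho = math.exp(-1.0 / (fps * params.vertical_reversion_time_s))
    eps = rng.standard_normal(n_frames) * math.sqrt(1.0 - rho * rho)
    eps[0] = rng.standard_normal()  # stationary start
    z = signal.lfilter([1.0], [1.0, -rho], eps)
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    u = sps.norm.cdf(z)
    return height * sps.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def simulate_fish(
    params: GenotypeParams,
    body_length_cm: float,
    tank_width_cm: float,
    tank_height_cm: float,
    fps: int = 25,
    duration_s: int = 600,
    seed=0,
    fish_id: str = "fish",
    genotype: str = "WT",
    age_group: str = "9mpf",
    vertical: bool = False,
) -> tuple[Trajectory, SimTruth]:
    """Simulate one fish; returns the trajectory and its hidden truth.

    Deterministic given ``seed``.  In vertical mode the second coordinate
    is the mean-reverting depth and the drawn speed drives the horizontal
    coordinate only (the sidecar then records the horizontal command).
    """
    rng = _rng(seed)
    fps = int(fps)
    duration_s = int(duration_s)
    if fps <= 0 or duration_s <= 0:
        raise ConfigError("fps and duration_s must be positive integers")
    max_step = FAST_SPEED_CAP_BL_S * body_length_cm / fps
    if max_step >= min(tank_width_cm, tank_height_cm) / 2:
        raise ConfigError("per-frame step would exceed half the tank; raise fps or tank size")
    states, speeds = simulate_speed_series(params, duration_s, rng, body_length_cm)
    n_frames = duration_s * fps + 1
    if vertical:
        x0 = rng.uniform(0, tank_width_cm)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        xs = np.empty(n_frames)
        xs[0] = x = x0
        k = 1
        for s in range(duration_s):
            dx = direction * speeds[s] / fps
            for _ in range(fps):
                nx = x + dx
                if nx < 0.0 or nx > tank_width_cm:
                    dx = -dx
                    nx = x + dx
                x = nx
                xs[k] = x
                k += 1
            direction = math.copysign(1.0, dx)
        ys = _vertical_positions(params, n_frames, fps, tank_height_cm, rng)
    else:
        x0 = rng.uniform(0, tank_width_cm)
        y0 = rng.uniform(0, tank_height_cm)
        headings = rng.uniform(-math.pi, math.pi) + np.concatenate(
            [[0.0], np.cumsum(rng.vonmises(0.0, params.turning_concentration, duration_s - 1))]
        )
        xs, ys = _crw_positions(x0, y0, headings, speeds, fps, tank_width_cm, tank_height_cm)
    traj = Trajectory(
        fish_id=fish_id,
        genotype=genotype,
        age_group=age_group,
        fps=float(fps),
        body_length_cm=body_length_cm,
        tank_width_cm=tank_width_cm,
        tank_height_cm=tank_height_cm,
        frame_index=np.arange(n_frames, dtype=np.int64),
        x_cm=xs,
        y_cm=ys,
    )
    truth = SimTruth(fish_id, np.arange(duration_s, dtype=np.int64), states, speeds)
    return traj, truth


def simulate_respiration(
    rate_per_min: float,
    n_fish: int,
    seed=0,
    genotype: str = "WT",
    scatter_sigma: float = 0.10,
    id_prefix: str = "fish",
) -> list[RespirationRecord]:
    """Seeded per-fish opercular counts per minute.

    Counts are Poisson around a per-fish rate; the per-fish rates carry a
    mean-preserving lognormal scatter (``scatter_sigma`` on the log
    scale) emulating between-fish heterogeneity.
    """
    if rate_per_min <= 0:
        raise ConfigError("rate_per_min must be positive")
    rng = _rng(seed)
    log_rates = rng.normal(
        math.log(rate_per_min) - 0.5 * scatter_sigma**2, scatter_sigma, n_fish
    )
    counts = rng.poisson(np.exp(log_rates))
    return [
        RespirationRecord(f"{id_prefix}_{i:03d}", genotype, int(c))
        for i, c in enumerate(counts)
    ]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPreset:
    """Bundled genotype parameters plus the matching recording geometry."""

    name: str
    genotype: str
    age_group: str
    body_length_cm: float
    tank_width_cm: float  # horizontal-plane footprint
    tank_height_cm: float
    vertical_tank_width_cm: float
    vertical_tank_height_cm: float  # water-column height
    params: GenotypeParams


def _nine_mpf(name: str, genotype: str, params: GenotypeParams) -> CohortPreset:
    return CohortPreset(
        name=name,
        genotype=genotype,
        age_group="9mpf",
        body_length_cm=4.0,
        tank_width_cm=18.0,
        tank_height_cm=24.0,
        vertical_tank_width_cm=22.5,
        vertical_tank_height_cm=12.5,
        params=params,
    )


_WT_9 = GenotypeParams(
    state_occupancy=(0.70, 0.25, 0.05),
    vertical_preference=0.25,
    respiration_rate_per_min=120.0,
)
_HT_9 = GenotypeParams(
    state_occupancy=(0.70, 0.25, 0.05),
    vertical_preference=0.50,
    respiration_rate_per_min=125.0,
)
_HM_9 = GenotypeParams(
    state_occupancy=(0.05, 0.75, 0.20),
    vertical_preference=0.60,
    respiration_rate_per_min=170.0,
)
_3MPF = GenotypeParams(
    state_occupancy=(0.15, 0.70, 0.15),
    vertical_preference=0.25,
    respiration_rate_per_min=120.0,
)


def _three_mpf(name: str, genotype: str) -> CohortPreset:
    return CohortPreset(
        name=name,
        genotype=genotype,
        age_group="3mpf",
        body_length_cm=2.0,
        tank_width_cm=8.8,
        tank_height_cm=11.8,
        vertical_tank_width_cm=11.8,
        vertical_tank_height_cm=4.6,
        params=_3MPF,
    )


PRESETS: dict[str, CohortPreset] = {
    "wt_9mpf": _nine_mpf("wt_9mpf", "WT", _WT_9),
    "ht_9mpf": _nine_mpf("ht_9mpf", "HT", _HT_9),
    "hm_9mpf": _nine_mpf("hm_9mpf", "HM", _HM_9),
    "wt_3mpf": _three_mpf("wt_3mpf", "WT"),
    "ht_3mpf": _three_mpf("ht_3mpf", "HT"),
    "hm_3mpf": _three_mpf("hm_3mpf", "HM"),
}


def preset(name: str) -> CohortPreset:
    """Look up a shipped preset (illustrative fixtures, not fitted values)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class CohortSim:
    """One simulated genotype cohort."""

    preset: CohortPreset
    trajectories: tuple[Trajectory, ...]
    truths: tuple[SimTruth, ...]
    respiration: tuple[RespirationRecord, ...] = field(default_factory=tuple)


def simulate_cohort(
    p: CohortPreset,
    n_fish: int,
    duration_s: int,
    seed=0,
    vertical: bool = False,
    with_respiration: bool = True,
) -> CohortSim:
    """Simulate ``n_fish`` independent fish from one preset block."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_fish + 1)
    trajs = []
    truths = []
    if vertical:
        tank_w, tank_h = p.vertical_tank_width_cm, p.vertical_tank_height_cm
    else:
        tank_w, tank_h = p.tank_width_cm, p.tank_height_cm
    for i in range(n_fish):
        traj, truth = simulate_fish(
            p.params,
            p.body_length_cm,
            tank_w,
            tank_h,
            fps=25,
            duration_s=duration_s,
            seed=np.random.default_rng(children[i]),
            fish_id=f"{p.name}_{i:03d}",
            genotype=p.genotype,
            age_group=p.age_group,
            vertical=vertical,
        )
        trajs.append(traj)
        truths.append(truth)
    resp: tuple[RespirationRecord, ...] = ()
    if with_respiration:
        resp = tuple(
            simulate_respiration(
                p.params.respiration_rate_per_min,
                n_fish,
                seed=np.random.default_rng(children[-1]),
                genotype=p.genotype,
                scatter_sigma=p.params.respiration_scatter_sigma,
                id_prefix=p.name,
            )
        )
    return CohortSim(p, tuple(trajs), tuple(truths), resp)
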