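"""Three-state hidden-Markov movement simulation for reptile archetypes.

Movement alternates between three behavioural states — sheltering (1),
moving (2) and resting (3).  Step lengths are Gamma, turning angles are
von Mises with near-zero concentration (kappa ~ 0.01, so movement has
almost no directional persistence).  Transition probabilities follow a
multinomial logit with the within-state diagonal as reference: entries
into resting carry a 24-h cosinor (circadian rest), entries into
sheltering carry a long-period cosinor (multi-day shelter cycles), and
entries into moving are modulated by a spatially autocorrelated habitat
covariate.

Three archetypes are parameterised:

* species 1 — highly mobile active hunter with long-term shelter sites
  (monitor lizards, king cobras);
* species 2 — ambush forager capable of long moves with long sheltering
  (pythons);
* species 3 — small ambush predator, short moves, short shelter bouts
  (small vipers).

Dwell-time targets behind the default transition intercepts: sheltering
bouts on the scale of days (nominally 3 / 5 / 1.5 days for species 1/2/3;
realized bouts run longer because animals preferentially halt in poor
habitat), movement bouts of one to two hours, overnight rests of roughly
ten hours — an activity budget in which sheltering dominates occupancy,
the pattern VHF field studies report for these taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .landscape import LandscapeRaster, sample_covariate_clamped

__all__ = [
    "ArchetypeParams",
    "Trajectory",
    "archetype_presets",
    "transition_probs",
    "draw_step",
    "simulate_individual",
    "simulate_population",
]

N_STATES = 3
SECONDS_PER_DAY = 86_400
DAY_PERIOD_S = 24 * 3600.0


class ParameterError(ValueError):
    pass


@dataclass
class ArchetypeParams:
    """Parameters of one species archetype.

    ``trans_intercept[i, j]``, ``trans_amp_cos[i, j]`` and
    ``trans_amp_sin[i, j]`` parameterise the logit of the i->j transition
    (diagonal fixed at 0); the cosinor period is 24 h for transitions into
    state 3 and ``shelter_period_h`` for transitions into state 1.
    ``trans_cov_coef[i, j]`` multiplies the habitat covariate and is
    nonzero only for transitions into state 2.
    """

    species_id: int
    step_mean: np.ndarray  # metres per 30-min step, per state
    step_sd: np.ndarray
    turn_mean: np.ndarray  # radians
    turn_conc: np.ndarray  # von Mises kappa
    trans_intercept: np.ndarray  # 3x3, diagonal 0
    trans_amp_cos: np.ndarray
    trans_amp_sin: np.ndarray
    trans_cov_coef: np.ndarray
    shelter_period_h: float
    buffer_width: float  # metres; half-width of the true-pathway buffer
    activity_window: tuple[float, float] = (6.0, 18.0)

    def __post_init__(self) -> None:
        for name in ("step_mean", "step_sd", "turn_mean", "turn_conc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("trans_intercept", "trans_amp_cos", "trans_amp_sin", "trans_cov_coef"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_STATES, N_STATES):
                raise ParameterError(f"{name} must be 3x3")
            setattr(self, name, arr)
        shape = self.gamma_shape
        if shape[0] > 1.0 + 1e-12 or shape[2] > 1.0 + 1e-12:
            raise ParameterError("states 1 and 3 need Gamma shape <= 1 (monotone density)")
        if shape[1] <= 1.0:
            raise ParameterError("state 2 needs Gamma shape > 1 (interior mode)")

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_scale(self) -> np.ndarray:
        return self.step_sd**2 / self.step_mean

    def replace(self, **kwargs) -> "ArchetypeParams":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """Timestamped planar relocations of one individual.

    ``state[k]`` is the behavioural state that produced the step into fix
    ``k`` (``state[0]`` is the initial state); it is present for simulated
    truth and dropped by regime thinning.
    """

    individual_id: str
    species_id: int
    t: np.ndarray  # seconds since study start, strictly increasing
    x: np.ndarray
    y: np.ndarray
    state: np.ndarray | None = None
    loc_error: float = 5.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ParameterError("t, x, y must have equal length")
        if self.state is not None:
            self.state = np.asarray(self.state, dtype=int)
            if len(self.state) != len(self.t):
                raise ParameterError("state vector length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ParameterError("timestamps must be strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.t)

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def subset(self, idx: np.ndarray, drop_state: bool = False) -> "Trajectory":
        return Trajectory(
            individual_id=self.individual_id,
            species_id=self.species_id,
            t=self.t[idx],
            x=self.x[idx],
            y=self.y[idx],
            state=None if (drop_state or self.state is None) else self.state[idx],
            loc_error=self.loc_error,
        )


def _intercepts(dwell_steps: dict[int, float], splits: dict[tuple[int, int], float]) -> np.ndarray:
    """Logit intercepts giving target mean dwell (in steps) and exit splits."""
    eta = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        total = 1.0 / (dwell_steps[i + 1] - 1.0)  # sum of exp(eta_ij), j != i
        for j in range(N_STATES):
            if i == j:
                continue
            eta[i, j] = np.log(splits[(i + 1, j + 1)] * total)
    return eta


# Exit-destination splits shared across archetypes: leaving shelter almost
# always starts a movement bout; movement bouts usually end at a rest site
# (occasionally straight back into shelter); after an overnight rest the
# animal usually moves on, sometimes re-sheltering.
_SPLITS = {
    (1, 2): 0.85,
    (1, 3): 0.15,
    (2, 1): 0.2,
    (2, 3): 0.8,
    (3, 1): 0.25,
    (3, 2): 0.75,
}


def _preset(
    species_id: int,
    step_mean: tuple[float, float, float],
    dwell_steps: dict[int, float],
    shelter_period_h: float,
    buffer_width: float,
) -> ArchetypeParams:
    mu = np.array(step_mean, dtype=float)
    # sigma >= mu for the stationary states (monotone Gamma density),
    # sigma = (2/3) mu for moving (interior mode).
    sd = np.array([1.5 * mu[0], (2.0 / 3.0) * mu[1], 1.5 * mu[2]])
    amp_cos = np.zeros((3, 3))
    amp_cos[1, 0] = amp_cos[2, 0] = 1.5  # shelter entries wave with the long cosinor
    amp_cos[0, 2] = amp_cos[1, 2] = 1.5  # rest entries peak at midnight (24-h cosinor)
    cov_coef = np.zeros((3, 3))
    cov_coef[0, 1] = cov_coef[2, 1] = 0.75  # movement starts preferentially in good habitat
    return ArchetypeParams(
        species_id=species_id,
        step_mean=mu,
        step_sd=sd,
        turn_mean=np.zeros(3),
        turn_conc=np.full(3, 0.01),
        trans_intercept=_intercepts(dwell_steps, _SPLITS),
        trans_amp_cos=amp_cos,
        trans_amp_sin=np.zeros((3, 3)),
        trans_cov_coef=cov_coef,
        shelter_period_h=shelter_period_h,
        buffer_width=buffer_width,
    )


# Shelter dwells reflect digestion of large prey (1-2 weeks for the large
# archetypes, ~2 days for the small one); movement bouts last one to two
# hours; overnight rests last ~10 h (dusk to dawn for diurnal reptiles).
_PRESETS = {
    1: dict(step_mean=(1.0, 150.0, 5.0), dwell_steps={1: 144.0, 2: 2.0, 3: 20.0},
            shelter_period_h=240.0, buffer_width=40.0),
    2: dict(step_mean=(1.0, 75.0, 3.0), dwell_steps={1: 240.0, 2: 3.0, 3: 20.0},
            shelter_period_h=336.0, buffer_width=20.0),
    3: dict(step_mean=(0.5, 30.0, 2.0), dwell_steps={1: 72.0, 2: 2.0, 3: 20.0},
            shelter_period_h=72.0, buffer_width=10.0),
}


def archetype_presets(species_id: int) -> ArchetypeParams:
    """Default parameter set for archetype 1, 2 or 3."""
    if species_id not in _PRESETS:
        raise ParameterError(f"unknown species_id {species_id}; must be 1, 2 or 3")
    return _preset(species_id, **_PRESETS[species_id])


def transition_probs(params: ArchetypeParams, t: float, covariate: float) -> np.ndarray:
    """Row-stochastic 3x3 transition matrix at study time ``t`` (seconds)."""
    if not np.isfinite(covariate):
        raise ParameterError("covariate must be finite")
    shelter_period_s = params.shelter_period_h * 3600.0
    # cosinor phase by destination column: state 1 <- long period, state 3 <- 24 h
    wc = np.zeros(N_STATES)
    wc[0] = np.cos(2.0 * np.pi * t / shelter_period_s)
    wc[2] = np.cos(2.0 * np.pi * t / DAY_PERIOD_S)
    ws = np.zeros(N_STATES)
    ws[0] = np.sin(2.0 * np.pi * t / shelter_period_s)
    ws[2] = np.sin(2.0 * np.pi * t / DAY_PERIOD_S)
    eta = (
        params.trans_intercept
        + params.trans_amp_cos * wc[None, :]
        + params.trans_amp_sin * ws[None, :]
        + params.trans_cov_coef * covariate
    )
    np.fill_diagonal(eta, 0.0)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite transition logits")
    e = np.exp(eta - eta.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def draw_step(params: ArchetypeParams, state: int, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (step length, turning angle) for a state: Gamma and von Mises."""
    if state not in (1, 2, 3):
        raise ParameterError(f"state must be 1, 2 or 3, got {state}")
    s = state - 1
    length = rng.gamma(params.gamma_shape[s], params.gamma_scale[s])
    angle = rng.vonmises(params.turn_mean[s], params.turn_conc[s])
    return float(length), float(angle)


def simulate_individual(
    params: ArchetypeParams,
    landscape: LandscapeRaster,
    start_xy: tuple[float, float] | None = None,
    duration_days: int = 365,
    dt: float = 1800.0,
    seed: int = 0,
    individual_id: str | None = None,
) -> Trajectory:
    """Simulate one individual's trajectory on a 30-min (default) clock.

    The study clock starts at 00:00 on day 1; the fix count is
    ``duration_days * 86400/dt + 1`` (both endpoints included).  The state
    is sampled first, then step length, then turning angle, from a single
    per-individual RNG stream, so output is reproducible for a fixed seed.
    """
    if duration_days <= 0 or int(duration_days) != duration_days:
        raise ParameterError("duration_days must be a positive whole number")
    if SECONDS_PER_DAY % dt != 0:
        raise ParameterError("dt must divide 24 h")
    if start_xy is None:
        start_xy = landscape.center
    xmin, ymin, xmax, ymax = landscape.extent
    if not (xmin <= start_xy[0] < xmax and ymin <= start_xy[1] < ymax):
        raise ParameterError("start position outside landscape")

    rng = np.random.default_rng(seed)
    n_steps = int(duration_days * SECONDS_PER_DAY / dt)
    t = np.arange(n_steps + 1) * dt
    # cosinor carriers precomputed for speed
    shelter_period_s = params.shelter_period_h * 3600.0
    cos24 = np.cos(2.0 * np.pi * t / DAY_PERIOD_S)
    sin24 = np.sin(2.0 * np.pi * t / DAY_PERIOD_S)
    cosL = np.cos(2.0 * np.pi * t / shelter_period_s)
    sinL = np.sin(2.0 * np.pi * t / shelter_period_s)

    icpt = params.trans_intercept
    ac = params.trans_amp_cos
    asn = params.trans_amp_sin
    cc = params.trans_cov_coef
    shape = params.gamma_shape
    scale = params.gamma_scale
    tmean = params.turn_mean
    tconc = params.turn_conc

    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    states = np.empty(n_steps + 1, dtype=int)
    x[0], y[0] = start_xy
    states[0] = 1  # start sheltering
    heading = rng.uniform(-np.pi, np.pi)
    cur = 0  # 0-based current state
    for k in range(n_steps):
        cov = sample_covariate_clamped(landscape, x[k], y[k])
        eta = (
            icpt[cur]
            + ac[cur] * np.array([cosL[k], 0.0, cos24[k]])
            + asn[cur] * np.array([sinL[k], 0.0, sin24[k]])
            + cc[cur] * cov
        )
        eta[cur] = 0.0
        e = np.exp(eta - eta.max())
        p = e / e.sum()
        u = rng.random()
        nxt = int(np.searchsorted(np.cumsum(p), u))
        nxt = min(nxt, N_STATES - 1)
        length = rng.gamma(shape[nxt], scale[nxt])
        turn = rng.vonmises(tmean[nxt], tconc[nxt])
        heading = heading + turn
        x[k + 1] = x[k] + length * np.cos(heading)
        y[k + 1] = y[k] + length * np.sin(heading)
        states[k + 1] = nxt + 1
        cur = nxt

    return Trajectory(
        individual_id=individual_id or f"sp{params.species_id}_ind{seed}",
        species_id=params.species_id,
        t=t,
        x=x,
        y=y,
        state=states,
        loc_error=5.0,
    )


def simulate_population(
    landscape: LandscapeRaster,
    n_per_species: int = 32,
    seed: int = 0,
    duration_days: int = 365,
    dt: float = 1800.0,
    overrides: dict[int, ArchetypeParams] | None = None,
) -> list[Trajectory]:
    """Simulate ``3 * n_per_species`` individuals (all three archetypes).

    Per-individual seeds are ``seed + global index`` so the population is
    reproducible under a fixed master seed.
    """
    if n_per_species < 1:
        raise ParameterError("n_per_species must be >= 1")
    out: list[Trajectory] = []
    idx = 0
    for species_id in (1, 2, 3):
        params = (overrides or {}).get(species_id) or archetype_presets(species_id)
        for i in range(n_per_species):
            out.append(
                simulate_individual(
                    params,
                    landscape,
                    duration_days=duration_days,
                    dt=dt,
                    seed=seed + idx,
                    individual_id=f"sp{species_id}_ind{i + 1:02d}",
                )
            )
            idx += 1
    return out


def mean_dwell_steps(states: np.ndarray, state: int) -> float:
    """Mean run length (in fixes) of a state in a simulated state sequence."""
    runs = []
    count = 0
    for s in states:
        if s == state:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    if not runs:
        return 0.0
    return float(np.mean(runs))
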