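"""Baseline dung beetle optimizer (DBO) over a bounded continuous search space.

The swarm is split into four behavioural roles, each with its own position
update:

* **roller** -- rolls its ball along a line influenced by the global worst
  position (a proxy for "light intensity"), occasionally *dancing* (a
  tangent-direction reorientation) when blocked;
* **brood** -- places a brood ball inside a spawning region that contracts
  around the current local best as iterations progress;
* **small** -- a juvenile foraging inside a region contracting around the
  global best;
* **thief** -- jumps near the global best with a spread set by its distance
  to both the local and global best.

All updates are followed by hard clipping to the search box.  Minimization
throughout; the best-so-far position is tracked greedily so the best fitness
is non-increasing across iterations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SearchSpace",
    "DBOParams",
    "Role",
    "SwarmState",
    "OptimizationResult",
    "clip_to_bounds",
    "roll_ball",
    "dance",
    "spawn_bounds",
    "update_brood",
    "forage_bounds",
    "update_small",
    "update_thief",
    "assign_roles",
    "init_swarm",
    "dbo_step",
    "dbo_optimize",
]


@dataclass
class SearchSpace:
    """Axis-aligned box [lower, upper] in R^dim."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class DBOParams:
    """Behavioural constants of the four strategies.

    k in (0, 0.2) is the rolling deflection coefficient, b_roll in (0, 1) the
    fixed light-intensity weight, thief_scale the constant S of the stealing
    jump.  p_alpha is the probability that the natural coefficient alpha
    equals -1 (direction deviation), p_dance the probability a roller dances
    instead of rolling.  role_fractions follow the 6:6:7:11 split of the
    original 30-beetle swarm (rollers, brood, small, thieves).
    """

    k: float = 0.1
    b_roll: float = 0.3
    thief_scale: float = 0.5
    p_alpha: float = 0.1
    p_dance: float = 0.1
    role_fractions: tuple[float, float, float, float] = (6 / 30, 6 / 30, 7 / 30, 11 / 30)

    def __post_init__(self) -> None:
        if not 0 < self.k < 0.2:
            raise ValueError("k must be in (0, 0.2)")
        if not 0 < self.b_roll < 1:
            raise ValueError("b_roll must be in (0, 1)")
        if self.thief_scale <= 0:
            raise ValueError("thief_scale must be positive")
        fr = np.asarray(self.role_fractions, dtype=float)
        if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("role_fractions must be nonnegative and sum to 1")


class Role(enum.IntEnum):
    ROLLER = 0
    BROOD = 1
    SMALL = 2
    THIEF = 3


@dataclass
class SwarmState:
    """Population snapshot: positions, previous positions, fitness, roles.

    ``best_position/best_fitness`` are the best seen anywhere so far (greedy);
    ``worst_position`` the worst member of the current population;
    ``local_best`` the best member of the current population.
    """

    positions: np.ndarray          # (N, D)
    prev_positions: np.ndarray     # (N, D)
    fitness: np.ndarray            # (N,)
    roles: np.ndarray              # (N,) of Role
    best_position: np.ndarray
    best_fitness: float
    worst_position: np.ndarray
    local_best: np.ndarray
    t: int
    t_max: int

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class OptimizationResult:
    """Outcome of an optimizer run: incumbent and its convergence history."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray            # best-so-far fitness per iteration
    iterations: int

    def history_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"iteration": np.arange(1, len(self.history) + 1), "best_fitness": self.history}
        ).to_csv(path, index=False)


def clip_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    return np.clip(position, space.lower, space.upper)


def roll_ball(
    x: np.ndarray,
    x_prev: np.ndarray,
    worst: np.ndarray,
    params: DBOParams,
    space: SearchSpace,
    rng: np.random.Generator,
    alpha: float | None = None,
) -> np.ndarray:
    """Ball-rolling update: x + alpha*k*x_prev + b*|x - worst|.

    alpha is drawn as -1 with probability ``p_alpha`` (else +1) unless given
    explicitly; |x - worst| is the elementwise change-of-light term.
    """
    if alpha is None:
        alpha = -1.0 if rng.random() < params.p_alpha else 1.0
    delta = np.abs(x - worst)
    return clip_to_bounds(x + alpha * params.k * x_prev + params.b_roll * delta, space)


def dance(
    x: np.ndarray,
    x_prev: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
    theta: float | None = None,
) -> np.ndarray:
    """Dancing reorientation: x + tan(theta)*|x - x_prev|, theta ~ U[0, pi].

    At theta in {0, pi/2, pi} the position is left unchanged (tan is zero or
    undefined there).
    """
    if theta is None:
        theta = rng.uniform(0.0, np.pi)
    if theta in (0.0, np.pi / 2, np.pi):
        return x.copy()
    return clip_to_bounds(x + np.tan(theta) * np.abs(x - x_prev), space)


def spawn_bounds(
    local_best: np.ndarray, t: int, t_max: int, space: SearchSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Spawning-region bounds around the local best, shrinking as R = 1 - t/Tmax."""
    r = 1.0 - t / t_max
    lb = np.maximum(local_best * (1.0 - r), space.lower)
    ub = np.minimum(local_best * (1.0 + r), space.upper)
    return lb, np.maximum(ub, lb)


def update_brood(
    brood: np.ndarray,
    local_best: np.ndarray,
    lb_star: np.ndarray,
    ub_star: np.ndarray,
    rng: np.random.Generator,
    b1: np.ndarray | None = None,
    b2: np.ndarray | None = None,
) -> np.ndarray:
    """Brood-ball move X* + b1*(B - Lb*) + b2*(B - Ub*), clipped into the region.

    b1, b2 are independent U(0,1) vectors of the problem dimension.
    """
    d = brood.size
    if b1 is None:
        b1 = rng.random(d)
    if b2 is None:
        b2 = rng.random(d)
    pos = local_best + b1 * (brood - lb_star) + b2 * (brood - ub_star)
    return np.clip(pos, lb_star, ub_star)


def forage_bounds(
    best: np.ndarray, t: int, t_max: int, space: SearchSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Foraging-region bounds: as :func:`spawn_bounds` but centred on the global best."""
    return spawn_bounds(best, t, t_max, space)


def update_small(
    x: np.ndarray,
    lb_b: np.ndarray,
    ub_b: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
    c1: float | None = None,
    c2: np.ndarray | None = None,
) -> np.ndarray:
    """Juvenile forage move x + C1*(x - Lb^b) + C2*(x - Ub^b).

    C1 is a scalar standard-normal draw, C2 a U(0,1) vector; result clipped to
    the global box.
    """
    if c1 is None:
        c1 = rng.standard_normal()
    if c2 is None:
        c2 = rng.random(x.size)
    return clip_to_bounds(x + c1 * (x - lb_b) + c2 * (x - ub_b), space)


def update_thief(
    x: np.ndarray,
    best: np.ndarray,
    local_best: np.ndarray,
    params: DBOParams,
    space: SearchSpace,
    rng: np.random.Generator,
    g: np.ndarray | None = None,
) -> np.ndarray:
    """Stealing move Xb + S*g*(|x - X*| + |x - Xb|) with g standard normal."""
    if g is None:
        g = rng.standard_normal(x.size)
    pos = best + params.thief_scale * g * (np.abs(x - local_best) + np.abs(x - best))
    return clip_to_bounds(pos, space)


def assign_roles(n: int, params: DBOParams, rng: np.random.Generator) -> np.ndarray:
    """Split the swarm into roles by the configured fractions.

    Counts follow the largest-remainder rounding of fractions * n; when n is
    too small for every role to get a member the assignment degrades to
    round-robin so all four strategies stay exercised.
    """
    fr = np.asarray(params.role_fractions, dtype=float)
    if n < 4:
        roles = np.array([Role(i % 4) for i in range(n)])
    else:
        counts = np.floor(fr * n).astype(int)
        rem = fr * n - counts
        for i in np.argsort(-rem)[: n - counts.sum()]:
            counts[i] += 1
        roles = np.repeat(np.arange(4), counts)
    rng.shuffle(roles)
    return roles.astype(int)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(objective(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[int(np.argmax(~np.isfinite(vals)))]
        raise ValueError(f"objective returned a non-finite value at position {bad}")
    return vals


def init_swarm(
    objective,
    space: SearchSpace,
    params: DBOParams,
    n: int,
    t_max: int,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> SwarmState:
    """Build the initial swarm; uniform random positions unless given."""
    if positions is None:
        positions = rng.uniform(space.lower, space.upper, size=(n, space.dim))
    fitness = _evaluate(objective, positions)
    i_best = int(np.argmin(fitness))
    i_worst = int(np.argmax(fitness))
    return SwarmState(
        positions=positions.copy(),
        prev_positions=positions.copy(),
        fitness=fitness,
        roles=assign_roles(n, params, rng),
        best_position=positions[i_best].copy(),
        best_fitness=float(fitness[i_best]),
        worst_position=positions[i_worst].copy(),
        local_best=positions[i_best].copy(),
        t=0,
        t_max=t_max,
    )


def dbo_step(
    swarm: SwarmState,
    objective,
    params: DBOParams,
    space: SearchSpace,
    rng: np.random.Generator,
    roller_update=None,
) -> SwarmState:
    """Advance the swarm one iteration, updating every beetle per its role.

    ``roller_update(i, swarm, rng) -> position`` optionally replaces the
    rolling/dancing move (used by the osprey-exploration variant).
    """
    if swarm.t >= swarm.t_max:
        raise ValueError("swarm already at t_max")
    t_next = swarm.t + 1
    lb_s, ub_s = spawn_bounds(swarm.local_best, t_next, swarm.t_max, space)
    lb_b, ub_b = forage_bounds(swarm.best_position, t_next, swarm.t_max, space)

    new_positions = np.empty_like(swarm.positions)
    for i in range(swarm.n):
        x = swarm.positions[i]
        role = swarm.roles[i]
        if role == Role.ROLLER:
            if roller_update is not None:
                new_positions[i] = roller_update(i, swarm, rng)
            elif rng.random() < params.p_dance:
                new_positions[i] = dance(x, swarm.prev_positions[i], space, rng)
            else:
                new_positions[i] = roll_ball(
                    x, swarm.prev_positions[i], swarm.worst_position, params, space, rng
                )
        elif role == Role.BROOD:
            new_positions[i] = update_brood(x, swarm.local_best, lb_s, ub_s, rng)
        elif role == Role.SMALL:
            new_positions[i] = update_small(x, lb_b, ub_b, space, rng)
        else:
            new_positions[i] = update_thief(
                x, swarm.best_position, swarm.local_best, params, space, rng
            )

    fitness = _evaluate(objective, new_positions)
    i_loc = int(np.argmin(fitness))
    i_worst = int(np.argmax(fitness))
    best_position = swarm.best_position
    best_fitness = swarm.best_fitness
    if fitness[i_loc] < best_fitness:
        best_fitness = float(fitness[i_loc])
        best_position = new_positions[i_loc].copy()
    return SwarmState(
        positions=new_positions,
        prev_positions=swarm.positions.copy(),
        fitness=fitness,
        roles=swarm.roles.copy(),
        best_position=best_position,
        best_fitness=best_fitness,
        worst_position=new_positions[i_worst].copy(),
        local_best=new_positions[i_loc].copy(),
        t=t_next,
        t_max=swarm.t_max,
    )


def dbo_optimize(
    objective,
    space: SearchSpace,
    n: int = 30,
    t_max: int = 100,
    params: DBOParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OptimizationResult:
    """Run the baseline DBO loop; returns incumbent + per-iteration history."""
    params = params or DBOParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    swarm = init_swarm(objective, space, params, n, t_max, rng)
    history = np.empty(t_max)
    for t in range(t_max):
        swarm = dbo_step(swarm, objective, params, space, rng)
        history[t] = swarm.best_fitness
    return OptimizationResult(swarm.best_position, swarm.best_fitness, history, t_max)
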