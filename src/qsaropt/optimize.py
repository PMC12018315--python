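"""Phase-4 reward-constrained particle swarm search.

The decision space is the first-occurrence-ordered union of the activity
panel and the five ADMET panels (106 distinct descriptors for the
published panels), searched in normalized [0, 1] coordinates.  The
objective maximizes the activity surrogate's predicted pIC50 subject to
the ADMET reward constraint

    Reward(g) = g1 + g2 + (1 - g3) + g4 + (1 - g5) >= threshold (default 3)

where g1..g5 are the binary Caco-2, CYP3A4, hERG, HOB, MN surrogate
outputs and the favorable orientation is 1, 1, 0, 1, 0.  The constraint
is handled by an additive penalty, so the scalar objective minimized is

    value(x) = -pIC50_hat(x) + penalty * max(0, threshold - Reward(g(x))).

Particle swarm optimization uses the inertia form of the velocity update,
v <- w*v + c1*r1*(p_i - x) + c2*r2*(p_g - x), with fresh uniform r1, r2
per particle per dimension, velocity clamped to +/-20% of the box range,
and positions clamped to the box with velocity zeroed on clamped
dimensions.  Defaults w = 0.8, c1 = c2 = 0.5.  Each surrogate reads
exactly its own feature sublist from a particle position by descriptor
name; descriptors outside a surrogate's panel do not affect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .names import normalize_names
from .selection import NormalizationParams

ADMET_ORDER = ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")


@dataclass(frozen=True)
class RewardSpec:
    """Favorable ADMET orientations and the feasibility threshold."""

    orientation: tuple[int, int, int, int, int] = (1, 1, 0, 1, 0)
    threshold: int = 3

    def __post_init__(self) -> None:
        if not all(o in (0, 1) for o in self.orientation):
            raise ValueError("orientation entries must be 0 or 1")
        if not (0 <= self.threshold <= 5):
            raise ValueError(f"threshold must be in 0..5, got {self.threshold}")


def reward(labels, spec: RewardSpec = RewardSpec()) -> int:
    """Count of favorably oriented ADMET labels, an integer in [0, 5].

    ``labels`` are the five binary surrogate outputs in the order
    (Caco-2, CYP3A4, hERG, HOB, MN).
    """
    labels = tuple(labels)
    if len(labels) != 5 or not all(l in (0, 1) for l in labels):
        raise ValueError(f"labels must be five binary values, got {labels!r}")
    return sum(l if o == 1 else 1 - l for l, o in zip(labels, spec.orientation))


def reward_batch(label_matrix: np.ndarray, spec: RewardSpec = RewardSpec()) -> np.ndarray:
    """Vectorized reward over an (n, 5) binary label matrix."""
    L = np.asarray(label_matrix, dtype=int)
    orient = np.asarray(spec.orientation, dtype=int)
    return (np.where(orient == 1, L, 1 - L)).sum(axis=1)


@dataclass
class DecisionSpace:
    """Named, bounded search box for the swarm.

    ``lower``/``upper`` are the per-dimension search bounds (normalized
    [0, 1] for the assembled descriptor space; arbitrary for synthetic
    benchmark boxes).  ``orig_min``/``orig_max`` carry the original
    descriptor units for de-normalization when known.
    """

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    duplicate_count: int = 0
    orig_min: np.ndarray | None = None
    orig_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("decision-space names must be unique")
        if self.lower.shape != self.upper.shape or self.lower.size != len(self.names):
            raise ValueError("bounds do not match names")
        if (self.lower > self.upper).any():
            raise ValueError("lower bound exceeds upper bound")

    @property
    def dim(self) -> int:
        return len(self.names)

    def denormalize(self, x: np.ndarray) -> np.ndarray:
        """Map normalized coordinates to original descriptor units."""
        if self.orig_min is None or self.orig_max is None:
            return np.asarray(x, dtype=float)
        return self.orig_min + np.asarray(x, dtype=float) * (self.orig_max - self.orig_min)


def assemble_decision_space(activity_list, admet_lists: dict,
                            bounds_source: NormalizationParams | None = None,
                            ) -> DecisionSpace:
    """Union of the six descriptor panels into one decision space.

    Names are normalized, ordered by first occurrence (activity panel
    first, then the ADMET panels in canonical property order), and
    deduplicated; ``duplicate_count`` is total entries minus distinct
    names.  Bounds are [0, 1] in normalized space; original min/max are
    attached when a ``bounds_source`` is given.
    """
    if len(activity_list) == 0 or any(len(v) == 0 for v in admet_lists.values()):
        raise ValueError("empty feature list")
    ordered_lists = [list(activity_list)] + [list(admet_lists[p]) for p in ADMET_ORDER
                                             if p in admet_lists]
    if len(ordered_lists) - 1 != len(admet_lists):
        ordered_lists = [list(activity_list)] + [list(v) for v in admet_lists.values()]
    all_entries: list[str] = []
    for lst in ordered_lists:
        all_entries.extend(normalize_names(lst))
    seen: dict[str, None] = {}
    for n in all_entries:
        seen.setdefault(n)
    names = list(seen)
    dup = len(all_entries) - len(names)
    lower = np.zeros(len(names))
    upper = np.ones(len(names))
    orig_min = orig_max = None
    if bounds_source is not None:
        missing = [n for n in names if n not in bounds_source.x_min.index]
        if missing:
            raise KeyError(f"no normalization bounds for descriptors: {missing}")
        orig_min = bounds_source.x_min[names].to_numpy(dtype=float)
        orig_max = bounds_source.x_max[names].to_numpy(dtype=float)
    return DecisionSpace(names=names, lower=lower, upper=upper, duplicate_count=dup,
                         orig_min=orig_min, orig_max=orig_max)


class ConstrainedObjective:
    """Penalty-scalarized surrogate objective over a decision space.

    Evaluates the activity surrogate and the five ADMET surrogates on a
    batch of positions, returning the scalar value to minimize together
    with feasibility, predicted pIC50 and reward per point.
    """

    def __init__(self, space: DecisionSpace, activity_surrogate, admet_surrogates: dict,
                 reward_spec: RewardSpec = RewardSpec(), penalty: float = 10.0):
        if penalty <= 0:
            raise ValueError(f"penalty must be positive, got {penalty}")
        self.space = space
        self.activity = activity_surrogate
        self.admet = dict(admet_surrogates)
        self.reward_spec = reward_spec
        self.penalty = float(penalty)
        name_pos = {n: i for i, n in enumerate(space.names)}

        def index_of(feature_list, owner: str) -> np.ndarray:
            try:
                return np.array([name_pos[n] for n in feature_list], dtype=int)
            except KeyError as exc:
                raise KeyError(f"{owner}: descriptor {exc.args[0]!r} not in the "
                               "decision space") from None

        self._act_idx = index_of(activity_surrogate.feature_list, "activity")
        self._admet_idx = {p: index_of(s.feature_list, p) for p, s in self.admet.items()}

    def evaluate(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pic50 = np.asarray(self.activity.predict(X[:, self._act_idx]), dtype=float)
        labels = np.column_stack([
            self.admet[p].predict_label(X[:, self._admet_idx[p]])
            for p in ADMET_ORDER if p in self.admet
        ])
        rewards = reward_batch(labels, self.reward_spec)
        shortfall = np.maximum(0, self.reward_spec.threshold - rewards)
        values = -pic50 + self.penalty * shortfall
        feasible = rewards >= self.reward_spec.threshold
        return values, feasible, pic50, rewards

    def __call__(self, x: np.ndarray):
        """Scalar form: (value, feasible, predicted_pic50, reward_value)."""
        v, f, p, r = self.evaluate(np.atleast_2d(x))
        return float(v[0]), bool(f[0]), float(p[0]), int(r[0])


class _FunctionObjective:
    """Adapter wrapping a plain batch function f(X) -> values (all feasible)."""

    def __init__(self, fn):
        self.fn = fn

    def evaluate(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        values = np.asarray(self.fn(X), dtype=float)
        n = values.shape[0]
        return values, np.ones(n, bool), np.full(n, np.nan), np.zeros(n, int)


@dataclass
class SwarmState:
    """Positions, velocities and best records of one PSO swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_pos: np.ndarray
    pbest_val: np.ndarray
    gbest_pos: np.ndarray
    gbest_val: float
    w: float
    c1: float
    c2: float
    v_min: np.ndarray
    v_max: np.ndarray


@dataclass
class OptimizationResult:
    """Outcome of a swarm run: trace, best point, feasible history."""

    trace: np.ndarray                  # per-iteration global best value
    best_position: np.ndarray          # in search (normalized) space
    best_position_denorm: np.ndarray   # in original units when known
    best_value: float
    best_pic50: float
    feasible_positions: np.ndarray     # all feasible evaluated points
    feasible_values: np.ndarray
    feasible_pic50: np.ndarray


def pso_step(state: SwarmState, objective, rng: np.random.Generator,
             lower: np.ndarray, upper: np.ndarray):
    """One synchronous velocity/position/best update of the whole swarm.

    Returns the updated state together with the objective evaluation of
    the new positions (values, feasible, pic50, rewards).
    """
    m, d = state.positions.shape
    r1 = rng.uniform(size=(m, d))
    r2 = rng.uniform(size=(m, d))
    v = (state.w * state.velocities
         + state.c1 * r1 * (state.pbest_pos - state.positions)
         + state.c2 * r2 * (state.gbest_pos - state.positions))
    v = np.clip(v, state.v_min, state.v_max)
    x = state.positions + v
    clamped = (x < lower) | (x > upper)
    x = np.clip(x, lower, upper)
    v = np.where(clamped, 0.0, v)

    values, feasible, pic50, rewards = objective.evaluate(x)
    improved = values < state.pbest_val
    state.pbest_pos[improved] = x[improved]
    state.pbest_val[improved] = values[improved]
    best_i = int(np.argmin(state.pbest_val))
    if state.pbest_val[best_i] < state.gbest_val:
        state.gbest_val = float(state.pbest_val[best_i])
        state.gbest_pos = state.pbest_pos[best_i].copy()
    state.positions = x
    state.velocities = v
    return state, (values, feasible, pic50, rewards)


def run_pso(space: DecisionSpace, objective, *, m: int = 50, iters: int = 80,
            w: float = 0.8, c1: float = 0.5, c2: float = 0.5, seed: int = 0,
            v_frac: float = 0.2) -> OptimizationResult:
    """Run PSO over the decision space, minimizing the objective value.

    ``objective`` is a :class:`ConstrainedObjective` or any object with
    an ``evaluate(X) -> (values, feasible, pic50, rewards)`` method; a
    plain batch function ``f(X) -> values`` is also accepted.  The swarm
    initializes uniformly in the box, velocities at zero.  Returns the
    per-iteration global-best trace (monotone nonincreasing), the best
    position, and every feasible evaluated point for range derivation.
    """
    if m < 2:
        raise ValueError(f"swarm size must be >= 2, got {m}")
    if iters < 1:
        raise ValueError(f"iters must be >= 1, got {iters}")
    if not hasattr(objective, "evaluate"):
        objective = _FunctionObjective(objective)
    rng = np.random.default_rng(seed)
    lower, upper = space.lower, space.upper
    span = upper - lower
    d = space.dim

    positions = rng.uniform(lower, upper, size=(m, d))
    velocities = np.zeros((m, d))
    values, feasible, pic50, rewards = objective.evaluate(positions)

    feas_pos = [positions[feasible]]
    feas_val = [values[feasible]]
    feas_pic = [pic50[feasible]]

    state = SwarmState(
        positions=positions.copy(), velocities=velocities,
        pbest_pos=positions.copy(), pbest_val=values.copy(),
        gbest_pos=positions[np.argmin(values)].copy(),
        gbest_val=float(values.min()),
        w=w, c1=c1, c2=c2,
        v_min=-v_frac * span, v_max=v_frac * span,
    )
    trace = np.empty(iters + 1)
    trace[0] = state.gbest_val
    for t in range(1, iters + 1):
        state, (vals, feas, pic, _) = pso_step(state, objective, rng, lower, upper)
        trace[t] = state.gbest_val
        feas_pos.append(state.positions[feas])
        feas_val.append(vals[feas])
        feas_pic.append(pic[feas])

    best_x = state.gbest_pos
    best_vals, _, best_pic, _ = objective.evaluate(best_x[None, :])
    return OptimizationResult(
        trace=trace,
        best_position=best_x,
        best_position_denorm=space.denormalize(best_x),
        best_value=float(state.gbest_val),
        best_pic50=float(best_pic[0]),
        feasible_positions=np.vstack(feas_pos) if feas_pos else np.empty((0, d)),
        feasible_values=np.concatenate(feas_val),
        feasible_pic50=np.concatenate(feas_pic),
    )


def derive_ranges(result: OptimizationResult, space: DecisionSpace,
                  top_fraction: float = 0.1) -> pd.DataFrame:
    """Per-descriptor optimal value ranges from the feasible search history.

    Pools every feasible evaluated point, keeps the best ``top_fraction``
    by objective value, and takes elementwise min/max, de-normalized to
    original descriptor units when the space carries them.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    n = result.feasible_positions.shape[0]
    if n == 0:
        raise ValueError("no feasible point was evaluated; increase the swarm "
                         "size/iterations or review the penalty and constraint")
    keep = max(1, int(np.ceil(top_fraction * n)))
    order = np.argsort(result.feasible_values, kind="stable")[:keep]
    pts = result.feasible_positions[order]
    lo = space.denormalize(pts.min(axis=0))
    hi = space.denormalize(pts.max(axis=0))
    return pd.DataFrame({"descriptor": space.names, "optimal_min": lo, "optimal_max": hi})
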