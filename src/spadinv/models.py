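"""Extreme learning machine (ELM) regression and its PSO-optimized variant.

An ELM is a single-hidden-layer network whose input weights W (n x t) and
hidden thresholds b (t) are random in [-1, 1] and never tuned; only the
linear readout beta is solved, by (ridge-stabilized) least squares on the
hidden activations H = act(X W + b).

PSO-ELM replaces the random draw: each particle's position encodes one
(W, b) pair laid out row-major as

    theta = (w_11 .. w_1t, w_21 .. w_2t, ..., w_n1 .. w_nt, b_1 .. b_t)

of dimension D = t (n + 1).  Velocities and positions follow the standard
inertia-weight update

    v <- omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x),    x <- x + v

with fresh r1, r2 ~ U[0, 1] per particle and dimension, and the fitness of
a position is the RMSE of the ELM it encodes (readout refit at every
evaluation).  The global best fitness is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELMModel",
    "Particle",
    "Swarm",
    "elm_train",
    "elm_predict",
    "encode",
    "decode",
    "init_swarm",
    "pso_step",
    "fitness_rmse",
    "pso_elm_train",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "linear": lambda z: z,
}


@dataclass
class ELMModel:
    """Trained ELM: fixed hidden layer plus least-squares readout."""

    input_weights: np.ndarray       # (n_inputs, n_hidden)
    hidden_thresholds: np.ndarray   # (n_hidden,)
    output_weights: np.ndarray      # (n_hidden [+1],)
    activation: str = "sigmoid"
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    include_intercept: bool = True

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[1]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
                f"model expects {self.n_inputs}"
            )
        if self.x_mean is not None:
            X = (X - self.x_mean) / self.x_scale
        act = _ACTIVATIONS[self.activation]
        return act(X @ self.input_weights + self.hidden_thresholds)

    def predict(self, X: np.ndarray) -> np.ndarray:
        H = self.hidden(X)
        if self.include_intercept:
            H = np.column_stack([H, np.ones(len(H))])
        return H @ self.output_weights


def _solve_readout(H: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    gram = H.T @ H + ridge * np.eye(H.shape[1])
    return np.linalg.solve(gram, H.T @ y)


def elm_train(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 20,
    activation: str = "sigmoid",
    seed: int | np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
    ridge: float = 1e-8,
    include_intercept: bool = True,
    standardize: bool = True,
) -> ELMModel:
    """Train an ELM; hidden parameters are U[-1,1] draws unless given.

    Passing ``weights`` and ``thresholds`` explicitly makes training fully
    deterministic (the PSO path); otherwise ``seed`` fixes the draw.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")

    n_inputs = X.shape[1]
    if weights is None or thresholds is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        weights = rng.uniform(-1.0, 1.0, size=(n_inputs, n_hidden))
        thresholds = rng.uniform(-1.0, 1.0, size=n_hidden)
    else:
        weights = np.asarray(weights, dtype=float).reshape(n_inputs, -1)
        thresholds = np.asarray(thresholds, dtype=float).ravel()
        if weights.shape[1] != thresholds.size:
            raise ValueError("weights and thresholds disagree on the hidden size")

    if standardize:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
    else:
        x_mean = x_scale = None

    model = ELMModel(
        input_weights=weights,
        hidden_thresholds=thresholds,
        output_weights=np.zeros(0),
        activation=activation,
        x_mean=x_mean,
        x_scale=x_scale,
        include_intercept=include_intercept,
    )
    H = model.hidden(X)
    if include_intercept:
        H = np.column_stack([H, np.ones(len(H))])
    model.output_weights = _solve_readout(H, y, ridge)
    return model


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Forward pass act(X W + b) beta; alias for ``model.predict``."""
    return model.predict(X)


def encode(W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flatten (W, b) into a particle position (row-major weights, then
    thresholds); length t (n + 1)."""
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if W.ndim != 2 or W.shape[1] != b.size:
        raise ValueError("W must be (n_inputs, n_hidden) matching len(b)")
    return np.concatenate([W.reshape(-1), b])


def decode(position: np.ndarray, n: int, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode`; requires len(position) == t (n + 1)."""
    position = np.asarray(position, dtype=float).ravel()
    if position.size != t * (n + 1):
        raise ValueError(
            f"position length {position.size} != t(n+1) = {t * (n + 1)}"
        )
    W = position[: n * t].reshape(n, t)
    b = position[n * t:]
    return W, b


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    omega: float = 0.9
    c1: float = 1.4
    c2: float = 1.4
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    v_clamp: float | None = 1.0
    x_clamp: tuple[float, float] | None = (-1.0, 1.0)
    iteration: int = 0

    def __post_init__(self) -> None:
        if min(self.omega, self.c1, self.c2) <= 0:
            raise ValueError("omega, c1 and c2 must be positive")


def init_swarm(
    fitness,
    dim: int,
    swarm_size: int = 30,
    seed: int | np.random.Generator | None = None,
    omega: float = 0.9,
    c1: float = 1.4,
    c2: float = 1.4,
    v_clamp: float | None = 1.0,
    x_clamp: tuple[float, float] | None = (-1.0, 1.0),
) -> Swarm:
    """Uniform [-1, 1] positions, zero velocities, fitness evaluated once."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    particles = []
    gbest_pos, gbest_fit = None, np.inf
    for i in range(swarm_size):
        pos = rng.uniform(-1.0, 1.0, size=dim)
        fit = float(fitness(pos))
        if not np.isfinite(fit):
            raise ValueError(f"non-finite fitness for particle {i} at initialization")
        particles.append(Particle(pos, np.zeros(dim), pos.copy(), fit))
        if fit < gbest_fit:
            gbest_pos, gbest_fit = pos.copy(), fit
    return Swarm(
        particles=particles, gbest_position=gbest_pos, gbest_fitness=gbest_fit,
        omega=omega, c1=c1, c2=c2, rng=rng, v_clamp=v_clamp, x_clamp=x_clamp,
    )


def pso_step(swarm: Swarm, fitness, r1=None, r2=None) -> Swarm:
    """One synchronous PSO iteration (in place; the swarm is also returned).

    ``r1``/``r2`` default to fresh U[0,1] draws per particle and dimension;
    scalars or arrays may be injected for deterministic checks.  Velocity
    and position clamps apply only if the swarm configures them.
    """
    for i, p in enumerate(swarm.particles):
        d = p.position.size
        rr1 = swarm.rng.random(d) if r1 is None else np.broadcast_to(np.asarray(r1, float), (d,))
        rr2 = swarm.rng.random(d) if r2 is None else np.broadcast_to(np.asarray(r2, float), (d,))
        p.velocity = (
            swarm.omega * p.velocity
            + swarm.c1 * rr1 * (p.pbest_position - p.position)
            + swarm.c2 * rr2 * (swarm.gbest_position - p.position)
        )
        if swarm.v_clamp is not None:
            p.velocity = np.clip(p.velocity, -swarm.v_clamp, swarm.v_clamp)
        p.position = p.position + p.velocity
        if swarm.x_clamp is not None:
            p.position = np.clip(p.position, *swarm.x_clamp)
        fit = float(fitness(p.position))
        if not np.isfinite(fit):
            raise ValueError(f"non-finite fitness for particle {i} at iteration "
                             f"{swarm.iteration + 1}")
        if fit < p.pbest_fitness:
            p.pbest_fitness = fit
            p.pbest_position = p.position.copy()
        if fit < swarm.gbest_fitness:
            swarm.gbest_fitness = fit
            swarm.gbest_position = p.position.copy()
    swarm.iteration += 1
    return swarm


def fitness_rmse(
    position: np.ndarray,
    n: int,
    t: int,
    activation: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray | None = None,
    y_eval: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> float:
    """RMSE of the ELM encoded by ``position``: decode (W, b), refit the
    readout on the training data, score on the evaluation data (training
    data by default)."""
    W, b = decode(position, n, t)
    model = elm_train(
        X_train, y_train, activation=activation,
        weights=W, thresholds=b, ridge=ridge,
    )
    if X_eval is None:
        X_eval, y_eval = X_train, y_train
    pred = model.predict(X_eval)
    return float(np.sqrt(np.mean((np.asarray(y_eval, float) - pred) ** 2)))


def pso_elm_train(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 20,
    activation: str = "sigmoid",
    swarm_size: int = 30,
    omega: float = 0.9,
    c1: float = 1.4,
    c2: float = 1.4,
    max_iter: int = 100,
    tol: float = 1e-4,
    patience: int = 10,
    seed: int | None = None,
    fitness_data: tuple[np.ndarray, np.ndarray] | None = None,
    ridge: float = 1e-8,
    v_clamp: float | None = 1.0,
    x_clamp: tuple[float, float] | None = (-1.0, 1.0),
) -> tuple[ELMModel, np.ndarray]:
    """ELM whose hidden parameters are chosen by PSO minimizing RMSE.

    Fitness uses the training set itself unless ``fitness_data`` supplies a
    held-out (X, y).  Iteration stops at ``max_iter`` or once the global
    best has improved by less than ``tol`` (relative) over ``patience``
    consecutive iterations.  Returns the ELM decoded from the global best
    (readout refit) and the per-iteration trace of the global best fitness
    (element 0 is the initialization).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, t = X.shape[1], n_hidden
    Xe, ye = fitness_data if fitness_data is not None else (None, None)

    def fitness(pos):
        return fitness_rmse(pos, n, t, activation, X, y, Xe, ye, ridge=ridge)

    swarm = init_swarm(
        fitness, dim=t * (n + 1), swarm_size=swarm_size, seed=seed,
        omega=omega, c1=c1, c2=c2, v_clamp=v_clamp, x_clamp=x_clamp,
    )
    trace = [swarm.gbest_fitness]
    stall = 0
    for _ in range(max_iter):
        prev = swarm.gbest_fitness
        pso_step(swarm, fitness)
        trace.append(swarm.gbest_fitness)
        rel_gain = (prev - swarm.gbest_fitness) / max(prev, 1e-30)
        stall = 0 if rel_gain > tol else stall + 1
        if stall >= patience:
            break
    W, b = decode(swarm.gbest_position, n, t)
    model = elm_train(X, y, activation=activation, weights=W, thresholds=b, ridge=ridge)
    return model, np.asarray(trace)
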