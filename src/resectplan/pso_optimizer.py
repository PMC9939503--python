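"""Bounded particle-swarm minimization of bone waste.

The default swarm configuration is 50 particles,
personal and global learning coefficients of 1.49, per-particle inertia
initialized uniformly in [0.1, 1.1] and adapted during the run, an iteration
cap of 200 x n_parameters, early termination after 20 iterations without
improvement of the global best, and 10 independent restarts per resection
geometry to hedge against local minima.

The search box is static (PSO needs fixed bounds) while the translation
bounds of the resection parameters are defined in the *rotated* local frame
and therefore move with the rotation variables.  The static box uses the
tumor's circumscribing extents; every candidate is clamped to the exact
local bounds of its own rotation before evaluation, so all evaluated
resections are feasible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .mesh_model import Scene
from .resection_geometry import (
    RG_TYPES,
    T_Z_LOWER_BOUND,
    DegenerateHullError,
    RGParams,
    build_rg,
    local_translation_bounds,
    rotation_zyx,
)

__all__ = [
    "SwarmConfig",
    "OptimizationResult",
    "bounds_for",
    "clamp_to_local_bounds",
    "minimize_pso",
    "optimize",
    "optimize_all",
]


@dataclasses.dataclass
class SwarmConfig:
    """Particle-swarm hyper-parameters (see module docstring for defaults)."""

    n_particles: int = 50
    c_personal: float = 1.49
    c_global: float = 1.49
    inertia_range: tuple = (0.1, 1.1)
    max_iter: int | None = None  # defaults to 200 * n_params
    stall_limit: int = 20
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2 or self.n_restarts < 1:
            raise ValueError("need >= 2 particles and >= 1 restart")
        lo, hi = self.inertia_range
        if not (0 < lo <= hi < 2):
            raise ValueError("inertia_range must lie within (0, 2)")
        if self.c_personal <= 0 or self.c_global <= 0:
            raise ValueError("learning coefficients must be positive")

    def resolved_max_iter(self, n_params: int) -> int:
        return self.max_iter if self.max_iter is not None else 200 * n_params

    @classmethod
    def from_file(cls, path) -> "SwarmConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "inertia_range" in data:
            data["inertia_range"] = tuple(data["inertia_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inertia_range"] = list(d["inertia_range"])
        return d


@dataclasses.dataclass
class OptimizationResult:
    """Best parameters, per-restart bests and convergence bookkeeping."""

    rg_type: str
    best_params: RGParams | None
    best_vector: np.ndarray
    best_waste_pct: float
    per_restart_best: list
    per_restart_vectors: list
    convergence_trace: list  # best-so-far per iteration, one list per restart
    evaluations: int
    failed_evaluations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "rg_type": self.rg_type,
            "best_vector": np.asarray(self.best_vector).tolist(),
            "best_waste_pct": float(self.best_waste_pct),
            "per_restart_best": [float(v) for v in self.per_restart_best],
            "per_restart_vectors": [np.asarray(v).tolist()
                                    for v in self.per_restart_vectors],
            "convergence_trace": [[float(x) for x in tr]
                                  for tr in self.convergence_trace],
            "evaluations": int(self.evaluations),
            "failed_evaluations": int(self.failed_evaluations),
            "seed": int(self.seed),
        }


def bounds_for(rg_type: str, scene: Scene):
    """Static search box for a resection type on a centered scene.

    Rotations span +/-180 deg (plus +/-90 deg local z for contoured).  The
    translation entries use the tumor's circumscribing radius about its
    centroid, the widest the rotated extents can be; candidates are clamped
    to the exact rotation-dependent bounds at evaluation time.
    """
    if rg_type not in RG_TYPES:
        raise ValueError(f"unknown rg_type {rg_type!r}")
    verts = scene.tumor_mesh.vertices - scene.tumor_mesh.centroid
    radius = float(np.linalg.norm(verts, axis=1).max())
    if radius <= 0:
        raise ValueError("degenerate tumor: zero extent")
    lb = [-180.0, -180.0, -180.0, -radius, -radius, T_Z_LOWER_BOUND]
    ub = [180.0, 180.0, 180.0, radius, radius, 0.0]
    if rg_type == "contoured":
        lb.append(-90.0)
        ub.append(90.0)
    return np.asarray(lb), np.asarray(ub)


def clamp_to_local_bounds(vec: np.ndarray, scene: Scene,
                          rg_type: str) -> RGParams:
    """Clamp the translation entries to the exact bounds of their rotation."""
    vec = np.asarray(vec, float).copy()
    vec[:3] = np.clip(vec[:3], -180.0, 180.0)
    R = rotation_zyx(vec[0], vec[1], vec[2])
    (xlo, xhi), (ylo, yhi), zhi = local_translation_bounds(
        R, scene.tumor_mesh.vertices)
    vec[3] = np.clip(vec[3], xlo, xhi)
    vec[4] = np.clip(vec[4], ylo, yhi)
    vec[5] = np.clip(vec[5], T_Z_LOWER_BOUND, zhi)
    if rg_type == "contoured":
        vec[6] = np.clip(vec[6], -90.0, 90.0)
    return RGParams.from_vector(vec, rg_type)


def minimize_pso(fun, lb, ub, config: SwarmConfig, seed=None,
                 vectorized: bool = False, warm_start=None):
    """One swarm: minimize ``fun`` over the box ``[lb, ub]``.

    Velocity update ``v <- w v + c1 r1 (p - x) + c2 r2 (g - x)`` with
    positions clamped to the box and the violating velocity component
    zeroed.  Per-particle inertia starts uniform in ``inertia_range`` and is
    scaled x1.25 (capped) after an iteration that improves the global best,
    x0.75 (floored) while the swarm has stalled for >= 2 iterations.

    Returns ``(best_x, best_f, trace, n_evals)`` where ``trace`` is the
    best-so-far value after every iteration.
    """
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    d = len(lb)
    rng = np.random.default_rng(seed)
    n = config.n_particles
    w_lo, w_hi = config.inertia_range
    max_iter = config.resolved_max_iter(d)

    X = lb + (ub - lb) * rng.uniform(size=(n, d))
    if warm_start is not None:
        X[0] = np.clip(np.asarray(warm_start, float), lb, ub)
    V = np.zeros((n, d))
    w = rng.uniform(w_lo, w_hi, size=n)

    def evaluate(P):
        if vectorized:
            return np.asarray(fun(P), float)
        return np.array([fun(p) for p in P], float)

    F = evaluate(X)
    n_evals = n
    pbest_x = X.copy()
    pbest_f = F.copy()
    g = int(np.argmin(F))
    gbest_x = X[g].copy()
    gbest_f = float(F[g])
    trace = [gbest_f]
    stall = 0

    for _ in range(max_iter - 1):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        V = (w[:, None] * V
             + config.c_personal * r1 * (pbest_x - X)
             + config.c_global * r2 * (gbest_x[None, :] - X))
        X = X + V
        low = X < lb
        high = X > ub
        X = np.clip(X, lb, ub)
        V[low | high] = 0.0

        F = evaluate(X)
        n_evals += n
        better = F < pbest_f
        pbest_x[better] = X[better]
        pbest_f[better] = F[better]
        g = int(np.argmin(pbest_f))
        improved = pbest_f[g] < gbest_f - 1e-12 * max(abs(gbest_f), 1.0)
        if improved:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
            stall = 0
            w = np.minimum(w * 1.25, w_hi)
        else:
            stall += 1
            if stall >= 2:
                w = np.maximum(w * 0.75, w_lo)
        trace.append(gbest_f)
        if stall >= config.stall_limit:
            break
    return gbest_x, gbest_f, trace, n_evals


def _waste_objective(scene: Scene, rg_type: str):
    """Memoized bone-waste objective over clamped parameter vectors."""
    cache: dict = {}
    failures = [0]

    def fun(vec):
        key = tuple(np.round(np.asarray(vec, float) / 1e-6).astype(np.int64))
        if key in cache:
            return cache[key]
        params = clamp_to_local_bounds(vec, scene, rg_type)
        try:
            _, waste = build_rg(scene, params, profile=False, validate=False)
            val = waste.bone_waste_pct
        except DegenerateHullError:
            failures[0] += 1
            val = np.inf
        cache[key] = val
        return val

    return fun, failures


def optimize(scene: Scene, rg_type: str,
             config: SwarmConfig | None = None,
             warm_start=None) -> OptimizationResult:
    """Minimize bone waste for one resection type with restarted PSO.

    Runs ``config.n_restarts`` independent swarms whose generators are
    spawned from ``(config.seed, restart_index)``, so the result is
    reproducible and invariant to restart order.  ``warm_start`` (off by
    default) seeds one particle of every restart with a given vector.
    """
    config = config or SwarmConfig()
    lb, ub = bounds_for(rg_type, scene)
    fun, failures = _waste_objective(scene, rg_type)

    per_best, per_vec, traces = [], [], []
    n_evals = 0
    for r in range(config.n_restarts):
        x, f, tr, ne = minimize_pso(
            fun, lb, ub, config, seed=[int(config.seed), r],
            warm_start=warm_start)
        per_best.append(f)
        per_vec.append(x)
        traces.append(tr)
        n_evals += ne
    k = int(np.argmin(per_best))
    best_params = clamp_to_local_bounds(per_vec[k], scene, rg_type)
    return OptimizationResult(
        rg_type=rg_type,
        best_params=best_params,
        best_vector=best_params.to_vector(),
        best_waste_pct=float(per_best[k]),
        per_restart_best=per_best,
        per_restart_vectors=per_vec,
        convergence_trace=traces,
        evaluations=n_evals,
        failed_evaluations=failures[0],
        seed=config.seed,
    )


def optimize_all(scene: Scene, config: SwarmConfig | None = None,
                 rg_types=RG_TYPES) -> dict:
    """Optimize every resection type and report pairwise improvements.

    Returns ``{"results": {rg: OptimizationResult}, "waste":
    {rg: pct}, "improvements": {"a_vs_b": percentage points}}``.
    """
    config = config or SwarmConfig()
    results = {rg: optimize(scene, rg, config) for rg in rg_types}
    waste = {rg: res.best_waste_pct for rg, res in results.items()}
    improvements = {}
    for a in rg_types:
        for b in rg_types:
            if a != b:
                improvements[f"{a}_vs_{b}"] = waste[a] - waste[b]
    return {"results": results, "waste": waste,
            "improvements": improvements}
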