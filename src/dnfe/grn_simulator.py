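"""Stochastic GRN simulator with a controlled bifurcation.

Dynamics follow Hill-kinetics stochastic differential equations

    dx_i = [ sum_j A_ij h_act(x_j) + sum_j R_ij h_rep(x_j)
             - (d0 - p) x_i + b_i(p) ] dt + sigma dB_i

with activation ``h_act(u) = u^h / (K^h + u^h)``, repression
``h_rep(u) = K^h / (K^h + u^h)`` (defaults h = 2, K = 1), uniform
degradation ``d0 - p`` controlled by the bifurcation parameter p, and basal
production ``b_i(p)`` chosen so that a fixed operating point ``x*`` solves
the deterministic system at every p. Because the basal term pins ``x*``,
the Jacobian at the operating point is ``J_P(x*) - (d0 - p) I`` where
``J_P`` is the production Jacobian; setting ``d0`` to the largest real part
of ``J_P``'s spectrum makes the leading eigenvalue exactly p. The operating
branch is therefore stable for p < 0, loses stability at the constructed
critical value p = 0, and trajectories escape to a distant attractor for
p > 0 — the abrupt transition the DNFE score is designed to anticipate.

Samples are end states of independent Euler–Maruyama replicate
trajectories, so draws at one parameter value are mutually independent.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse

from .data_io import ExpressionMatrix, SampleDesign

__all__ = [
    "GRNModel",
    "SimulationRun",
    "SimulationError",
    "make_eleven_node_model",
    "make_random_model",
    "simulate_sde",
    "sweep",
    "leading_eigenvalue",
]

DEFAULT_DT = 0.02
DEFAULT_BURN_IN = 7500
DEFAULT_SIGMA = 0.01
DIVERGENCE_BOUND = 1e6
#: minimum baseline degradation so it stays positive across the sweep range
MIN_D0 = 0.35


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class GRNModel:
    """Signed Hill-kinetics regulatory network pinned to an operating point."""

    node_ids: list[str]
    act: scipy.sparse.csr_matrix  #: act[i, j] = 1 when gene j activates gene i
    rep: scipy.sparse.csr_matrix  #: rep[i, j] = 1 when gene j represses gene i
    x_star: np.ndarray
    d0: float
    hill_n: float = 2.0
    hill_k: float = 1.0
    critical_value: float = 0.0

    def __post_init__(self) -> None:
        self.x_star = np.asarray(self.x_star, dtype=float)
        small = self.n_nodes <= 256
        self._act_dense = self.act.toarray() if small else None
        self._rep_dense = self.rep.toarray() if small else None
        self._prod_star = self.production(self.x_star)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def _hill(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = np.maximum(x, 0.0) ** self.hill_n
        kh = self.hill_k ** self.hill_n
        act = u / (kh + u)
        return act, 1.0 - act

    def production(self, x: np.ndarray) -> np.ndarray:
        """Summed Hill regulation input per gene; x is (N,) or (m, N)."""
        ha, hr = self._hill(np.asarray(x, dtype=float))
        if self._act_dense is not None:
            return ha @ self._act_dense.T + hr @ self._rep_dense.T
        return (self.act @ ha.T).T + (self.rep @ hr.T).T

    def basal(self, p: float) -> np.ndarray:
        """Basal production keeping x* a fixed point at control value p."""
        return (self.d0 - p) * self.x_star - self._prod_star

    def drift(self, x: np.ndarray, p: float) -> np.ndarray:
        return self.production(x) - (self.d0 - p) * x + self.basal(p)

    def production_jacobian(self, x: np.ndarray) -> np.ndarray:
        dact = _hill_slope(np.asarray(x, dtype=float), self.hill_n, self.hill_k)
        return self.act.toarray() * dact - self.rep.toarray() * dact

    def jacobian(self, x: np.ndarray, p: float) -> np.ndarray:
        return self.production_jacobian(x) - (self.d0 - p) * np.eye(self.n_nodes)

    def to_json(self, path: str | Path) -> None:
        acoo = self.act.tocoo()
        rcoo = self.rep.tocoo()
        edges = [[int(i), int(j), 1, float(w)]
                 for i, j, w in zip(acoo.row, acoo.col, acoo.data)]
        edges += [[int(i), int(j), -1, float(w)]
                  for i, j, w in zip(rcoo.row, rcoo.col, rcoo.data)]
        payload = {
            "node_ids": self.node_ids,
            "edges": edges,  # [target, source, sign, weight]
            "x_star": self.x_star.tolist(),
            "hill_n": self.hill_n,
            "hill_k": self.hill_k,
            "critical_value": self.critical_value,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "GRNModel":
        payload = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        node_ids = list(payload["node_ids"])
        n = len(node_ids)
        act = scipy.sparse.lil_matrix((n, n))
        rep = scipy.sparse.lil_matrix((n, n))
        for tgt, src, sign, *w in payload["edges"]:
            (act if sign > 0 else rep)[tgt, src] = w[0] if w else 1.0
        x_star = np.asarray(payload["x_star"], dtype=float)
        model = cls(node_ids, act.tocsr(), rep.tocsr(), x_star, d0=1.0,
                    hill_n=payload.get("hill_n", 2.0),
                    hill_k=payload.get("hill_k", 1.0),
                    critical_value=payload.get("critical_value", 0.0))
        model.d0 = _leading_real_part(model.production_jacobian(x_star))
        model._prod_star = model.production(x_star)
        return model


def _leading_real_part(matrix: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(matrix).real))


def leading_eigenvalue(model: GRNModel, p: float,
                       x: np.ndarray | None = None) -> float:
    """Largest real part of the Jacobian spectrum at the operating point.

    By construction this equals p at ``x = x*``; supply ``x`` to probe
    other states.
    """
    state = model.x_star if x is None else np.asarray(x, dtype=float)
    return _leading_real_part(model.jacobian(state, p))


def make_eleven_node_model() -> GRNModel:
    """The packaged 11-node mixed activation/repression network.

    Topology, Hill constants and operating point are stored in
    ``models/eleven_node.json``; the deterministic drift loses stability at
    the documented critical value p = 0, inside the sweep range
    (-0.5, 0.23)."""
    with resources.files("dnfe").joinpath("models/eleven_node.json").open() as fh:
        payload = json.load(fh)
    return GRNModel.from_json(payload)


#: Perron eigenvalue every regulator module is normalized to; with uniform
#: degradation tuned to it, all modules destabilize together at p = 0.
MODULE_EIGENVALUE = 2.0


def make_random_model(n_nodes: int, mean_degree: float = 4.0,
                      seed: int | None = None,
                      activation_fraction: float = 0.6,
                      module_size: int = 10,
                      module_coverage: float = 0.3,
                      module_degree: int = 5,
                      max_retries: int = 20) -> GRNModel:
    """Random signed regulatory network destabilizing at p = 0.

    The network combines an Erdős–Rényi signed background (expected
    in-degree ``mean_degree``; each edge an activation with probability
    ``activation_fraction``) with planted positively coupled regulator
    modules covering about ``module_coverage`` of the genes. Each module
    of ``module_size`` genes is wired as a cyclic activation motif (every
    module gene activates the next ``module_degree`` module genes);
    modules receive no regulation from outside but do regulate downstream
    background genes, so the production Jacobian is block-triangular with
    the module blocks on top. Each module's internal edge gain is scaled
    so its Perron eigenvalue equals ``MODULE_EIGENVALUE`` exactly; tuning
    the uniform degradation to that value therefore makes every module a
    carrier of the critical mode simultaneously. As p approaches 0 the
    modules — and the background genes they drive — show the collective
    variance and correlation surge of a dynamic-network-biomarker group,
    while the rest of the background stays stiff and weakly correlated.

    The operating point is drawn uniformly from [1.5, 4.5]^N with Hill
    constant K = 3 (noise of strength ~0.01-0.05 is then small relative to
    the attractor basin), basal production pins the operating point for
    every p, and the leading Jacobian eigenvalue of the full system is
    exactly p — it crosses 0 at p = 0. Draws whose background spectrum
    reaches too close to the module eigenvalue are redrawn; repeated
    failure raises with a suggestion to change the seed.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    module_size = min(module_size, max(3, n_nodes // 2))
    module_degree = min(module_degree, module_size - 1)
    n_modules = max(1, round(module_coverage * n_nodes / module_size))
    n_modules = min(n_modules, n_nodes // module_size)
    p_edge = min(1.0, mean_degree / (n_nodes - 1))
    node_ids = [f"g{i:04d}" for i in range(n_nodes)]
    hill_k = 3.0
    for _ in range(max_retries):
        mask = rng.random((n_nodes, n_nodes)) < p_edge
        np.fill_diagonal(mask, False)
        signs = rng.random((n_nodes, n_nodes)) < activation_fraction
        member = rng.permutation(n_nodes)[: n_modules * module_size]
        modules = [member[m * module_size:(m + 1) * module_size]
                   for m in range(n_modules)]
        # module genes are regulated only from within their own module
        mask[member, :] = False
        act_w = np.where(mask & signs, 1.0, 0.0)
        rep_w = np.where(mask & ~signs, 1.0, 0.0)
        x_star = rng.uniform(1.5, 4.5, n_nodes)
        dact = _hill_slope(x_star, 2.0, hill_k)
        ok = True
        for module in modules:
            ring = np.zeros((module_size, module_size))
            for i in range(module_size):
                for k in range(1, module_degree + 1):
                    ring[(i + k) % module_size, i] = 1.0
            perron = np.max(np.linalg.eigvals(ring * dact[module]).real)
            if perron <= 0.1:
                ok = False
                break
            gain = MODULE_EIGENVALUE / perron
            act_w[np.ix_(module, module)] = ring * gain
        if not ok:
            continue
        model = GRNModel(node_ids, scipy.sparse.csr_matrix(act_w),
                         scipy.sparse.csr_matrix(rep_w), x_star, d0=1.0,
                         hill_k=hill_k)
        model.d0 = _leading_real_part(model.production_jacobian(x_star))
        model._prod_star = model.production(x_star)
        # modules must own the leading mode with a clear spectral gap
        if abs(model.d0 - MODULE_EIGENVALUE) < 1e-8 and model.d0 >= MIN_D0:
            return model
    raise SimulationError(
        f"could not tune a {n_nodes}-node model after {max_retries} draws; "
        "try a different seed or a higher mean degree"
    )


def _hill_slope(x: np.ndarray, h: float, k: float) -> np.ndarray:
    kh = k ** h
    return h * kh * np.maximum(x, 1e-12) ** (h - 1) / (kh + x ** h) ** 2


def simulate_sde(model: GRNModel, p: float, sigma: float, n_samples: int,
                 dt: float = DEFAULT_DT, burn_in: int = DEFAULT_BURN_IN,
                 seed: int | np.random.Generator | None = None) -> ExpressionMatrix:
    """Draw n_samples independent end states of the SDE at control value p.

    Euler–Maruyama integration from the operating point over ``burn_in``
    steps; every sample is a separate replicate trajectory, so samples are
    independent draws from the (quasi-)stationary law at p.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.tile(model.x_star, (n_samples, 1))
    decay = model.d0 - p
    basal = model.basal(p)
    noise_scale = sigma * np.sqrt(dt)
    for step in range(burn_in):
        drift = model.production(x) - decay * x + basal
        x = x + drift * dt
        if sigma > 0:
            x += noise_scale * rng.standard_normal(x.shape)
        if step % 500 == 0 and np.abs(x).max() > DIVERGENCE_BOUND:
            node = model.node_ids[int(np.argmax(np.abs(x).max(axis=0)))]
            raise SimulationError(
                f"trajectory diverged at node {node} (p = {p}); reduce dt or p"
            )
    if np.abs(x).max() > DIVERGENCE_BOUND:
        node = model.node_ids[int(np.argmax(np.abs(x).max(axis=0)))]
        raise SimulationError(f"trajectory diverged at node {node} (p = {p})")
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    return ExpressionMatrix(list(model.node_ids), sample_ids, x.T.copy())


@dataclasses.dataclass
class SimulationRun:
    """A control-parameter sweep packaged for the DNFE pipeline."""

    grid: list[float]
    sigma: float
    seed: int | None
    expression: ExpressionMatrix
    design: list[SampleDesign]
    time_points: list[str]

    @staticmethod
    def label(p: float) -> str:
        return f"{p:+.4f}"


def sweep(model: GRNModel, grid: Sequence[float], sigma: float = DEFAULT_SIGMA,
          n_ref: int = 20, n_case: int = 20, seed: int | None = None,
          dt: float = DEFAULT_DT, burn_in: int = DEFAULT_BURN_IN) -> SimulationRun:
    """Simulate reference and case samples across the control-parameter grid.

    Reference samples are drawn at the grid minimum — the most stable,
    pre-transition condition — and case samples at each grid value, giving
    one reference-vs-case contrast per "time point" exactly as the scoring
    pipeline expects.
    """
    grid = [float(g) for g in grid]
    if sorted(grid) != grid:
        raise ValueError("grid must be sorted ascending")
    if n_ref < 3 or n_case < 3:
        raise ValueError("need at least 3 reference and 3 case samples")
    streams = np.random.SeedSequence(seed).spawn(len(grid) + 1)
    ref = simulate_sde(model, grid[0], sigma, n_ref, dt, burn_in,
                       np.random.default_rng(streams[0]))
    labels = [SimulationRun.label(g) for g in grid]
    columns = [ref.values]
    sample_ids = [f"ref_{i:03d}" for i in range(n_ref)]
    design = [SampleDesign(s, labels[0], "reference") for s in sample_ids]
    for k, (g, label) in enumerate(zip(grid, labels)):
        case = simulate_sde(model, g, sigma, n_case, dt, burn_in,
                            np.random.default_rng(streams[k + 1]))
        ids = [f"case{k:02d}_{i:03d}" for i in range(n_case)]
        sample_ids.extend(ids)
        columns.append(case.values)
        design.extend(SampleDesign(s, label, "case") for s in ids)
    expr = ExpressionMatrix(list(model.node_ids), sample_ids, np.hstack(columns))
    return SimulationRun(grid, sigma, seed, expr, design, labels)
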