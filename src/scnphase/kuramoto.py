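"""Connectivity, Kuramoto dynamics, virtual slicing and deviation sweeps.

Connectivity is short-range (all neuron pairs within 20 μm) plus
long-range rewiring: every unordered pair is additionally connected
with probability q.  On that graph the phases evolve under the
Kuramoto model

    dθ_i/dt = ω + K Σ_j A_ij sin(θ_j − θ_i),

with a common intrinsic frequency ω = 2π/24 h⁻¹, integrated by
classical fourth-order Runge–Kutta at a 30 s step over 24 h.

A virtual slice keeps the neurons inside a 100 μm slab centred on the
mean of one coordinate (coronal: y, sagittal: x, horizontal: z) and
the induced subgraph — slicing removes edges, it does not resample
them.  The damage done by a slice is the deviation statistic: the mean
absolute principal-value angular difference, at the 24 h mark, between
the sliced and intact simulations over the slab's neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import ConfigError, InsufficientDataError, SimulationError
from .types import SnapshotNeuronTable

__all__ = [
    "ConnectivityGraph",
    "KuramotoConfig",
    "SimulationTrajectory",
    "DeviationSummary",
    "build_connectivity",
    "simulate",
    "virtual_slice",
    "deviation_statistic",
    "orientation_sweep",
    "wrap_angle",
]

SLAB_AXIS = {"sagittal": 0, "coronal": 1, "horizontal": 2}

OMEGA_CIRCADIAN = 2 * np.pi / 24.0  # rad/h


def wrap_angle(x: np.ndarray | float) -> np.ndarray | float:
    """Principal value of an angle difference, in (−π, π]."""
    wrapped = -((-np.asarray(x) + np.pi) % (2 * np.pi) - np.pi)
    return wrapped if np.ndim(x) else float(wrapped)


@dataclass
class ConnectivityGraph:
    """Symmetric 0/1 adjacency over the neurons of one snapshot."""

    adjacency: sparse.csr_matrix
    neuron_id: np.ndarray
    radius_um: float
    q: float
    seed: int | None

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def subgraph(self, idx: np.ndarray) -> "ConnectivityGraph":
        """Induced subgraph on ``idx`` (edge removal, no resampling)."""
        sub = self.adjacency[idx][:, idx].tocsr()
        return ConnectivityGraph(
            adjacency=sub,
            neuron_id=self.neuron_id[idx],
            radius_um=self.radius_um,
            q=self.q,
            seed=self.seed,
        )


def build_connectivity(
    table: SnapshotNeuronTable,
    radius_um: float = 20.0,
    q: float = 0.0,
    seed: int | None = None,
) -> ConnectivityGraph:
    """Distance edges (≤ radius) plus Bernoulli(q) long-range edges.

    Each unordered pair is independently a random edge with probability
    q (a draw landing on an existing distance edge is a no-op), giving
    q = 0 exactly the 20 μm graph and q = 1 the complete graph.
    """
    if radius_um <= 0:
        raise ConfigError("connection radius must be positive")
    if not 0.0 <= q <= 1.0:
        raise ConfigError("q must lie in [0, 1]")
    pos = table.positions
    n = len(table)
    pairs = cKDTree(pos).query_pairs(r=radius_um, output_type="ndarray")
    rows = [pairs[:, 0]] if pairs.size else []
    cols = [pairs[:, 1]] if pairs.size else []

    if q > 0:
        rng = np.random.default_rng(seed)
        total = n * (n - 1) // 2
        if q >= 1.0:
            i, j = np.triu_indices(n, k=1)
        else:
            k = rng.binomial(total, q)
            # uniform distinct unordered pairs via linear-index rejection
            chosen: set[int] = set()
            while len(chosen) < k:
                draw = rng.integers(0, total, size=k - len(chosen))
                chosen.update(int(v) for v in draw)
            lin = np.fromiter(chosen, dtype=np.int64, count=len(chosen))
            # invert linear index of the upper triangle (row-major, k=1)
            i = (
                n
                - 2
                - np.floor(
                    np.sqrt(-8.0 * lin + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
                )
            ).astype(np.int64)
            j = lin + i + 1 - (n * (n - 1) // 2) + ((n - i) * (n - i - 1)) // 2
        rows.append(i)
        cols.append(j)

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.empty(0, dtype=np.int64)
        c = np.empty(0, dtype=np.int64)
    data = np.ones(r.size, dtype=np.int8)
    A = sparse.coo_matrix((data, (r, c)), shape=(n, n))
    A = A + A.T
    A = (A > 0).astype(np.int8).tocsr()  # pairs all have i < j: no diagonal
    return ConnectivityGraph(
        adjacency=A,
        neuron_id=table.neuron_id.copy(),
        radius_um=radius_um,
        q=q,
        seed=seed,
    )


@dataclass
class KuramotoConfig:
    """Integrator settings: coupling K, common ω, 30 s RK4 step, 24 h run."""

    K: float = 1.0
    omega: float = OMEGA_CIRCADIAN
    dt_h: float = 30.0 / 3600.0
    duration_h: float = 24.0
    checkpoint_every_h: float = 1.0

    def validate(self) -> None:
        if self.K < 0:
            raise ConfigError("coupling K must be nonnegative")
        steps = self.checkpoint_every_h / self.dt_h
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigError("dt must divide the checkpoint spacing")


@dataclass
class SimulationTrajectory:
    """Unwrapped phases at hourly checkpoints, shape (n_checkpoints, N)."""

    times_h: np.ndarray
    theta: np.ndarray
    config: KuramotoConfig

    def final(self) -> np.ndarray:
        return self.theta[-1]


def simulate(
    theta0: np.ndarray,
    graph: ConnectivityGraph,
    cfg: KuramotoConfig | None = None,
) -> SimulationTrajectory:
    """Integrate the Kuramoto system with classical RK4.

    Phases are kept unwrapped; the coupling term is evaluated as
    Im(e^{−iθ} (A e^{iθ})), one sparse matvec per stage.  A NaN state
    aborts with a diagnostic.
    """
    cfg = cfg or KuramotoConfig()
    cfg.validate()
    theta = np.asarray(theta0, dtype=float).copy()
    if theta.shape != (graph.n,):
        raise ConfigError(
            f"theta0 has {theta.shape} entries for a {graph.n}-node graph"
        )
    A = graph.adjacency.astype(float)
    K, omega, dt = cfg.K, cfg.omega, cfg.dt_h

    def deriv(th: np.ndarray) -> np.ndarray:
        if K == 0.0:
            return np.full_like(th, omega)
        e = np.exp(1j * th)
        return omega + K * (np.conj(e) * (A @ e)).imag

    steps_per_cp = int(round(cfg.checkpoint_every_h / dt))
    n_cp = int(round(cfg.duration_h / cfg.checkpoint_every_h))
    times = np.arange(n_cp + 1) * cfg.checkpoint_every_h
    out = np.empty((n_cp + 1, graph.n))
    out[0] = theta
    for cp in range(1, n_cp + 1):
        for _ in range(steps_per_cp):
            k1 = deriv(theta)
            k2 = deriv(theta + 0.5 * dt * k1)
            k3 = deriv(theta + 0.5 * dt * k2)
            k4 = deriv(theta + dt * k3)
            theta = theta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(theta).all():
            raise SimulationError(
                f"non-finite phase at t={times[cp]} h (K={K}, q={graph.q})"
            )
        out[cp] = theta
    return SimulationTrajectory(times_h=times, theta=out, config=cfg)


def virtual_slice(
    table: SnapshotNeuronTable,
    orientation: str,
    width_um: float = 100.0,
) -> np.ndarray:
    """Indices of neurons inside the central slab of one orientation.

    The slab is centred at the mean of the slicing coordinate
    (coronal: y, sagittal: x, horizontal: z); membership is
    |coord − mean| ≤ width/2, boundary inclusive.
    """
    if orientation not in SLAB_AXIS:
        raise ConfigError(f"unknown orientation {orientation!r}")
    if len(table) == 0:
        raise InsufficientDataError("empty neuron table")
    coord = table.positions[:, SLAB_AXIS[orientation]]
    idx = np.flatnonzero(np.abs(coord - coord.mean()) <= width_um / 2.0)
    if idx.size == 0:
        raise InsufficientDataError(f"empty {orientation} slab")
    return idx


def deviation_statistic(
    intact: SimulationTrajectory,
    sliced: SimulationTrajectory,
    slice_idx: np.ndarray,
) -> float:
    """Mean |principal angle difference| at 24 h over the slab neurons.

    Lies in [0, π] radians; multiply by 24/2π for hours.
    """
    slice_idx = np.asarray(slice_idx)
    if sliced.theta.shape[1] != slice_idx.size:
        raise ConfigError("slice index does not match the sliced trajectory")
    diff = wrap_angle(sliced.final() - intact.final()[slice_idx])
    return float(np.abs(diff).mean())


@dataclass
class DeviationSummary:
    """Sweep results: one row per (q, K, orientation) plus winner map."""

    table: pd.DataFrame  # q, K, orientation, deviation_rad, deviation_h
    winners: pd.DataFrame  # q, K, winner
    differences: dict  # (q, K, orientation) -> per-neuron |Δθ| array

    def winner(self, q: float, K: float) -> str:
        w = self.winners
        row = w[(w["q"] == q) & (w["K"] == K)]
        return str(row["winner"].iloc[0])


def orientation_sweep(
    table: SnapshotNeuronTable,
    theta0: np.ndarray,
    q_grid,
    k_grid,
    seed: int = 0,
    radius_um: float = 20.0,
    slab_width_um: float = 100.0,
    dt_h: float = 30.0 / 3600.0,
    duration_h: float = 24.0,
) -> DeviationSummary:
    """Deviation statistics for every (q, K) cell and slab orientation.

    For each q one random-edge realisation is drawn (child seed of
    ``seed``) and shared across the K values and across intact/slab
    runs; slab runs use the induced subgraph with the same initial
    phases restricted to the slab.  Per-cell failures are flagged in
    the output rather than aborting the sweep.
    """
    theta0 = np.asarray(theta0, dtype=float)
    if theta0.size != len(table):
        raise ConfigError("theta0 length must match the neuron table")
    slabs = {
        o: virtual_slice(table, o, width_um=slab_width_um) for o in SLAB_AXIS
    }
    child_seeds = np.random.SeedSequence(seed).generate_state(len(list(q_grid)))
    rows = []
    win_rows = []
    diffs: dict = {}
    for qi, q in enumerate(q_grid):
        graph = build_connectivity(
            table, radius_um=radius_um, q=float(q),
            seed=int(child_seeds[qi] % (2**31)),
        )
        subgraphs = {o: graph.subgraph(idx) for o, idx in slabs.items()}
        for K in k_grid:
            cfg = KuramotoConfig(K=float(K), dt_h=dt_h, duration_h=duration_h)
            try:
                intact = simulate(theta0, graph, cfg)
                devs = {}
                for o, idx in slabs.items():
                    sliced = simulate(theta0[idx], subgraphs[o], cfg)
                    d = wrap_angle(sliced.final() - intact.final()[idx])
                    diffs[(float(q), float(K), o)] = np.abs(d)
                    devs[o] = float(np.abs(d).mean())
            except SimulationError as exc:
                for o in SLAB_AXIS:
                    rows.append(
                        dict(q=float(q), K=float(K), orientation=o,
                             deviation_rad=np.nan, deviation_h=np.nan,
                             ok=False, note=str(exc))
                    )
                win_rows.append(dict(q=float(q), K=float(K), winner="failed"))
                continue
            for o, d in devs.items():
                rows.append(
                    dict(q=float(q), K=float(K), orientation=o,
                         deviation_rad=d, deviation_h=d * 24.0 / (2 * np.pi),
                         ok=True, note="")
                )
            vals = np.array([devs[o] for o in SLAB_AXIS])
            if np.ptp(vals) == 0:
                winner = "tie"
            else:
                winner = list(SLAB_AXIS)[int(np.argmax(vals))]
            win_rows.append(dict(q=float(q), K=float(K), winner=winner))
    return DeviationSummary(
        table=pd.DataFrame(rows),
        winners=pd.DataFrame(win_rows),
        differences=diffs,
    )
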