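"""Joint optimisation of voxel labels and the Mahalanobis kernel metric.

The objective couples the label scores ``f`` and the 4x4 symmetric PSD
kernel matrix ``M``::

    min_{M >= 0, f}  J(M, f) = f^T L(M) f,   f_i = y_i on seeds,

where ``L(M)`` is the normalized Laplacian of the graph weighted by
``w_ij = exp(-d_ij^T M d_ij)``. The problem is solved by alternation:

1. label stage — with ``M`` fixed, ``f`` is the exact solution of the
   hard-constrained quadratic program (:func:`~dtiseg.propagate.solve_labels`);
2. metric stage — with ``f`` fixed, one projected gradient step
   ``M <- proj_PSD(M - alpha * dJ/dM)``, where the projection clamps
   negative eigenvalues of the symmetrised update to zero (the nearest
   PSD matrix in Frobenius norm).

The metric stage is a greedy adaptive descent: each step that lowers the
cost (labels held fixed) is accepted and the step length doubles; the
first step that fails to lower it is rejected, ``M`` reverts, the length
halves and the stage ends. Because both stages can only decrease a cost
bounded below by zero, the per-alternation cost sequence converges; the
alternation stops once the cost decrease of a full iteration falls below
the threshold ``eps``.

The gradient treats the degree matrix as a function of ``M`` (it is —
degrees are row sums of ``W``); ``freeze_degree=True`` drops those terms
for a cheaper approximate gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp

from .graph import VoxelGraph, build_graph, normalized_laplacian, weights_learned
from .propagate import decide, solve_labels
from .tensorfield import TensorField

__all__ = [
    "OptimizerParams", "OptimizerTrace", "LearnResult",
    "cost", "metric_gradient", "psd_project", "adapt_step",
    "learn", "learn_on_graph",
]


@dataclass
class OptimizerParams:
    """Settings for the alternating optimisation.

    ``alpha0`` initial gradient step length; ``eps`` stopping threshold
    on the per-alternation cost decrease; ``max_iter`` safety cap on
    alternations; ``M0`` initial kernel matrix (identity gives all four
    distance components equal weight); ``max_stage_steps`` caps the
    doubling steps inside one metric stage; ``freeze_degree`` uses the
    cheaper fixed-degree gradient. The optimiser itself is deterministic;
    ``seed`` is reserved for callers that randomise inputs.
    """

    alpha0: float = 0.01
    eps: float = 0.1
    max_iter: int = 50
    M0: np.ndarray | None = None
    max_stage_steps: int = 60
    freeze_degree: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.M0 is None:
            self.M0 = np.eye(4)
        self.M0 = np.asarray(self.M0, dtype=float)
        if np.linalg.eigvalsh((self.M0 + self.M0.T) / 2)[0] < -1e-10:
            raise ValueError("M0 must be positive semi-definite")


@dataclass
class OptimizerTrace:
    """Per-iteration history of the alternating optimisation."""

    iteration: list = dc_field(default_factory=list)
    cost: list = dc_field(default_factory=list)        # cost after the iteration
    alpha: list = dc_field(default_factory=list)       # step length attempted
    accepted: list = dc_field(default_factory=list)
    metric_eigenvalues: list = dc_field(default_factory=list)
    label_changes: list = dc_field(default_factory=list)

    def record(self, it, cost_val, alpha, accepted, eigvals, changes):
        self.iteration.append(int(it))
        self.cost.append(float(cost_val))
        self.alpha.append(float(alpha))
        self.accepted.append(bool(accepted))
        self.metric_eigenvalues.append(np.asarray(eigvals, float))
        self.label_changes.append(int(changes))

    def accepted_costs(self) -> np.ndarray:
        """Cost sequence at accepted iterations (including the initial solve)."""
        return np.array([c for c, a in zip(self.cost, self.accepted) if a])

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("iteration,cost,alpha,accepted,label_changes\n")
            for i, c, a, ok, ch in zip(self.iteration, self.cost, self.alpha,
                                       self.accepted, self.label_changes):
                fh.write(f"{i},{c:.12g},{a:.12g},{int(ok)},{ch}\n")


@dataclass
class LearnResult:
    """Output of :func:`learn`: final metric, scores, segmentation, history."""

    M: np.ndarray
    f: np.ndarray           # per-node scores
    seg: np.ndarray         # grid-shaped boolean segmentation
    trace: OptimizerTrace
    converged: bool
    n_iter: int
    graph: VoxelGraph | None = None


def cost(f: np.ndarray, L: sp.spmatrix) -> float:
    """Smoothness energy ``f^T L f`` (nonnegative: L is PSD)."""
    f = np.asarray(f, dtype=float)
    return float(f @ (L @ f))


def metric_gradient(f: np.ndarray, edges: np.ndarray,
                    edge_dvecs: np.ndarray, M: np.ndarray,
                    freeze_degree: bool = False) -> np.ndarray:
    """Gradient of ``f^T L(M) f`` with respect to the kernel matrix ``M``.

    Assembled from per-edge terms: each weight contributes
    ``dw_ij/dM = -w_ij d_ij d_ij^T``, chained through both the weight
    matrix and (unless ``freeze_degree``) the degree matrix inside
    ``L = I - Dg^{-1/2} W Dg^{-1/2}``. The returned 4x4 matrix is exactly
    symmetric.
    """
    f = np.asarray(f, dtype=float)
    M = np.asarray(M, dtype=float)
    n = f.shape[0]

    q = np.einsum("ek,kl,el->e", edge_dvecs, M, edge_dvecs)
    w = np.exp(-np.clip(q, 0.0, None))
    p, r = edges[:, 0], edges[:, 1]

    deg = np.zeros(n)
    np.add.at(deg, p, w)
    np.add.at(deg, r, w)
    if np.any(deg <= 0):
        raise ValueError("graph has an isolated vertex; gradient undefined")
    dinv = 1.0 / np.sqrt(deg)

    # S = sum_{ordered pairs} w_ij f_i f_j / sqrt(d_i d_j); J = ||f||^2 - S
    g = f * dinv
    # dS/dw_pq (symmetric pair): direct term
    coef = 2.0 * g[p] * g[r]
    if not freeze_degree:
        # h_i = sum_j w_ij f_j / sqrt(d_j);  dS/dd_i = -f_i h_i d_i^{-3/2}
        h = np.zeros(n)
        np.add.at(h, p, w * g[r])
        np.add.at(h, r, w * g[p])
        dS_dd = -f * h * dinv ** 3
        coef = coef + dS_dd[p] + dS_dd[r]

    # dJ/dM = sum_edges (-dS/dw) * (-w d d^T) = sum_edges dS/dw * w d d^T
    scaled = (coef * w)[:, None] * edge_dvecs
    grad = scaled.T @ edge_dvecs
    return (grad + grad.T) / 2.0


def psd_project(M: np.ndarray) -> np.ndarray:
    """Nearest PSD matrix: symmetrise, then clamp negative eigenvalues to 0."""
    M = np.asarray(M, dtype=float)
    Ms = (M + M.T) / 2.0
    w, v = np.linalg.eigh(Ms)
    if w[0] >= 0.0:
        return Ms
    w = np.maximum(w, 0.0)
    out = (v * w) @ v.T
    return (out + out.T) / 2.0


def adapt_step(cost_prev: float, cost_new: float, alpha: float):
    """Accept/reject rule with step adaptation.

    A strict cost decrease accepts the step and doubles ``alpha``;
    otherwise (including an exact tie) the step is rejected, the metric
    reverts, and ``alpha`` halves.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if cost_new < cost_prev:
        return 2.0 * alpha, True
    return alpha / 2.0, False


def learn_on_graph(edges: np.ndarray, edge_dvecs: np.ndarray,
                   y: np.ndarray, params: OptimizerParams | None = None,
                   n: int | None = None):
    """Run the alternating optimisation on a prebuilt edge structure.

    Returns ``(M, f, trace, converged, n_iter)``. ``y`` is the per-node
    constraint vector in {+1, -1, 0}.
    """
    if params is None:
        params = OptimizerParams()
    y = np.asarray(y)
    if n is None:
        n = y.shape[0]

    def _laplacian(M):
        W = weights_learned(edges, edge_dvecs, M, n=n)
        return normalized_laplacian(W)

    M = psd_project(params.M0)
    alpha = params.alpha0
    L = _laplacian(M)
    f = solve_labels(L, y)
    J = cost(f, L)

    trace = OptimizerTrace()
    trace.record(0, J, alpha, True, np.linalg.eigvalsh(M), 0)

    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # metric stage: adaptive gradient descent with f held fixed;
        # doubling while the cost drops, stage ends at the first rejection
        J_stage = J
        for _ in range(params.max_stage_steps):
            grad = metric_gradient(f, edges, edge_dvecs, M,
                                   freeze_degree=params.freeze_degree)
            M_new = psd_project(M - alpha * grad)
            L_new = _laplacian(M_new)
            J_new = cost(f, L_new)
            alpha, accept = adapt_step(J_stage, J_new, alpha)
            if not accept:
                break
            M, L, J_stage = M_new, L_new, J_new

        # label stage: exact solve at the updated metric
        f_new = solve_labels(L, y)
        J_next = cost(f_new, L)
        changes = int(np.sum(decide(f_new) != decide(f)))
        f = f_new
        delta = J - J_next
        J = J_next
        trace.record(it, J, alpha, True, np.linalg.eigvalsh(M), changes)
        if abs(delta) < params.eps:
            converged = True
            break

    if not converged:
        warnings.warn("metric learning hit max_iter without meeting the "
                      "cost-decrease threshold; returning best-so-far",
                      RuntimeWarning)
    return M, f, trace, converged, it


def learn(field: TensorField, y_grid: np.ndarray,
          params: OptimizerParams | None = None) -> LearnResult:
    """Learned-metric segmentation of a tensor field from seed labels.

    ``y_grid`` is a grid of {+1 foreground, -1 background, 0 unlabeled}
    constraints on the same lattice as ``field``. Builds the voxel graph,
    alternates label propagation and projected gradient steps on the
    kernel matrix, and returns the final metric, scores, binary
    segmentation and optimisation trace.
    """
    graph = build_graph(field)
    y = graph.labels_to_nodes(y_grid)
    M, f, trace, converged, n_iter = learn_on_graph(
        graph.edges, graph.edge_dvecs, y, params, n=graph.n)
    seg = graph.nodes_to_grid(decide(f), fill=False)
    return LearnResult(M=M, f=f, seg=seg, trace=trace,
                       converged=converged, n_iter=n_iter, graph=graph)
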