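"""Penalized-likelihood chronogram estimation and calibration handling.

The dating model maximizes a Poisson branch-substitution log-likelihood minus
a smoothing penalty on ancestor-descendant rate changes, with the root age
fixed by a secondary calibration and tips at age zero:

    psi = sum_j [ x_j * ln(r_j * tau_j) - r_j * tau_j ]  -  lambda * phi

where x_j = b_j * L is the (continuous) substitution count on branch j,
tau_j its duration, r_j its substitution rate (per sequence per Myr), and

    phi = sum_{j: parent(j) not root} (rho_j - rho_parent(j))^2
          + popvar({rho_k : k child of root})

with rho_j = r_j * root_age. Expressing the roughness term in root-age units
makes the whole objective invariant under a rescaling of the time axis, so a
chronogram estimated with one root calibration maps *exactly* onto any other
root calibration by linear scaling of ages (and inverse scaling of rates).
This matches the dual-calibration design of the analysis, where the 20-Myr
and 25-Myr age columns are in exact 0.8 ratio.

Optimization is multi-start quasi-Newton (L-BFGS-B) over log rates and node
ages parameterized as fractions of their parent's age, which enforces the
age ordering by construction. The strict-clock solution is always included
as the first start, so the returned objective can never fall below it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .phylo_io import CladeDefinition, Phylogram, TreeNode, _copy_subtree

logger = logging.getLogger(__name__)

ULTRAMETRIC_RTOL = 1e-6


class ConvergenceError(RuntimeError):
    """Raised when no optimizer restart converged.

    Carries the best solution found (``best``, a :class:`Chronogram`) and the
    per-restart objective trace (``trace``).
    """

    def __init__(self, message: str, best: "Chronogram", trace: list[dict]):
        super().__init__(message)
        self.best = best
        self.trace = trace


@dataclass
class PLConfig:
    """Settings for penalized-likelihood dating."""

    smoothing: float = 1.0
    seq_length: int = 1000
    min_duration: Optional[float] = None  # default: 1e-6 * root_age
    tol: float = 1e-10
    max_iter: int = 2000
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.min_duration is not None and self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")


@dataclass
class CalibrationSpec:
    """Secondary root calibration: fixed age plus a 95% interval."""

    root_age: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.root_age <= self.ci_high):
            raise ValueError(
                f"calibration CI [{self.ci_low}, {self.ci_high}] must bracket "
                f"root age {self.root_age}"
            )
        if self.root_age <= 0:
            raise ValueError("root_age must be > 0")


class Chronogram(Phylogram):
    """Ultrametric tree: node ages in Myr, branch lengths are durations.

    Each node carries ``age`` (Myr above the present); non-root nodes carry
    ``rate`` (substitutions per site per Myr on the edge above) when the
    chronogram came from dating, and ``length`` equal to the edge duration.
    """

    def __init__(
        self,
        root: TreeNode,
        root_age: float,
        seq_length: Optional[int] = None,
        objective: Optional[float] = None,
        trace: Optional[list[dict]] = None,
        validate: bool = True,
    ):
        self.root_age = float(root_age)
        self.seq_length = seq_length
        self.objective = objective
        self.trace = trace
        super().__init__(root, validate=False)
        _set_durations_from_ages(root)
        if validate:
            self.validate_chronogram()

    def validate_chronogram(self) -> None:
        if self.root.age is None or not math.isclose(
            self.root.age, self.root_age, rel_tol=1e-12
        ):
            raise ValueError("root node age must equal root_age exactly")
        scale = max(self.root_age, 1e-300)
        for node in self.preorder():
            if node.age is None:
                raise ValueError("every node must carry an age")
            if node.is_leaf and abs(node.age) > ULTRAMETRIC_RTOL * scale:
                raise ValueError(f"tip {node.label!r} not at age 0 (age={node.age})")
            if node.parent is not None:
                if node.parent.age <= node.age:
                    raise ValueError(
                        f"parent age {node.parent.age} not greater than child "
                        f"age {node.age}"
                    )
                if node.rate is not None and node.rate <= 0:
                    raise ValueError("branch rates must be > 0")

    # stable node ids: tips use their label, internals a postorder index
    def node_ids(self) -> dict[int, str]:
        ids: dict[int, str] = {}
        for i, node in enumerate(self.postorder()):
            ids[id(node)] = node.label if node.is_leaf else f"n{i}"
        return ids

    def rate_table(self):
        """Per-branch table: child node id, duration (Myr), rate (subs/site/Myr)."""
        import pandas as pd

        ids = self.node_ids()
        rows = []
        for node in self.postorder():
            if node.parent is None:
                continue
            rows.append(
                {
                    "child_node_id": ids[id(node)],
                    "duration_myr": node.parent.age - node.age,
                    "rate": node.rate,
                }
            )
        return pd.DataFrame(rows, columns=["child_node_id", "duration_myr", "rate"])

    def copy(self) -> "Chronogram":
        return Chronogram(
            _copy_subtree(self.root),
            self.root_age,
            seq_length=self.seq_length,
            objective=self.objective,
            trace=self.trace,
            validate=False,
        )


def _set_durations_from_ages(root: TreeNode) -> None:
    stack = list(root.children)
    while stack:
        node = stack.pop()
        if node.age is not None and node.parent.age is not None:
            node.length = node.parent.age - node.age
        stack.extend(node.children)


# ---------------------------------------------------------------------
# objective


def _indexed(tree: Phylogram):
    """Preorder node list (root first) with parent indices."""
    nodes = list(tree.preorder())
    pos = {id(n): i for i, n in enumerate(nodes)}
    parent = np.array(
        [-1 if n.parent is None else pos[id(n.parent)] for n in nodes], dtype=int
    )
    return nodes, parent


def pl_objective(
    tree: Phylogram,
    ages: Mapping[int, float],
    rates: Mapping[int, float],
    cfg: PLConfig,
) -> float:
    """Penalized log-likelihood of (ages, rates) for a phylogram.

    ``ages`` maps ``id(node)`` -> age in Myr for every node (tips must be 0);
    ``rates`` maps ``id(node)`` -> substitution rate of the edge above the
    node, in expected substitutions per sequence per Myr, for every non-root
    node. Constant terms in x_j alone (the log-factorials) are omitted.
    """
    nodes, parent = _indexed(tree)
    root_age = ages[id(nodes[0])]
    if root_age <= 0:
        raise ValueError("root age must be > 0")
    loglik = 0.0
    rho: dict[int, float] = {}
    for i, node in enumerate(nodes):
        if parent[i] < 0:
            continue
        tau = ages[id(node.parent)] - ages[id(node)]
        r = rates[id(node)]
        if tau <= 0:
            raise ValueError(f"non-positive duration on edge to {node.label!r}")
        if r <= 0:
            raise ValueError(f"non-positive rate on edge to {node.label!r}")
        x = node.length * cfg.seq_length
        mu = r * tau
        loglik += (x * math.log(mu) if x > 0 else 0.0) - mu
    for node in nodes:
        if node.parent is not None:
            rho[id(node)] = rates[id(node)] * root_age
    phi = 0.0
    for node in nodes:
        if node.parent is not None and node.parent.parent is not None:
            phi += (rho[id(node)] - rho[id(node.parent)]) ** 2
    root_children = [rho[id(c)] for c in nodes[0].children]
    if root_children:
        phi += float(np.var(root_children))  # population variance
    return loglik - cfg.smoothing * phi


# ---------------------------------------------------------------------
# estimation


class _PLProblem:
    """Vectorized objective in normalized time (root age = 1)."""

    def __init__(self, tree: Phylogram, cfg: PLConfig, min_frac: float):
        self.nodes, self.parent = _indexed(tree)
        n = len(self.nodes)
        self.is_tip = np.array([nd.is_leaf for nd in self.nodes])
        self.nonroot = np.arange(1, n)  # preorder: index 0 is the root
        self.free = np.array(
            [i for i in range(1, n) if not self.is_tip[i]], dtype=int
        )
        self.x = np.array(
            [self.nodes[i].length * cfg.seq_length for i in self.nonroot]
        )
        # edge index of the parent edge, -1 when the parent is the root
        edge_pos = {i: k for k, i in enumerate(self.nonroot)}
        self.parent_edge = np.array(
            [-1 if self.parent[i] == 0 else edge_pos[self.parent[i]] for i in self.nonroot],
            dtype=int,
        )
        self.root_child_edges = np.array(
            [edge_pos[i] for i in self.nonroot if self.parent[i] == 0], dtype=int
        )
        self.pair_mask = self.parent_edge >= 0
        self.lam = cfg.smoothing
        self.min_frac = min_frac
        self.nf = len(self.free)
        self.ne = len(self.nonroot)
        self.has_x = self.x > 0

    def ages_from_fractions(self, f: np.ndarray) -> np.ndarray:
        ages = np.zeros(len(self.nodes))
        ages[0] = 1.0
        for k, i in enumerate(self.free):  # preorder: parents precede children
            ages[i] = ages[self.parent[i]] * f[k]
        ages[self.is_tip] = 0.0
        return ages

    def durations(self, ages: np.ndarray) -> np.ndarray:
        return ages[self.parent[self.nonroot]] - ages[self.nonroot]

    def neg_psi(self, params: np.ndarray) -> float:
        f = params[: self.nf]
        rho = np.exp(params[self.nf:])
        ages = self.ages_from_fractions(f)
        tau = self.durations(ages)
        mu = rho * tau
        loglik = np.sum(np.where(self.has_x, self.x * np.log(mu), 0.0) - mu)
        phi = np.sum(
            (rho[self.pair_mask] - rho[self.parent_edge[self.pair_mask]]) ** 2
        )
        rc = rho[self.root_child_edges]
        phi += rc.var()
        return -(loglik - self.lam * phi)

    def clock_start(self) -> tuple[np.ndarray, np.ndarray]:
        """Fractions from node heights of the input phylogram; one shared rate."""
        pos = {id(n): i for i, n in enumerate(self.nodes)}
        height = np.zeros(len(self.nodes))
        for i in range(len(self.nodes) - 1, -1, -1):  # reverse preorder = children first
            node = self.nodes[i]
            if not node.is_leaf:
                height[i] = max(
                    height[pos[id(c)]] + c.length for c in node.children
                )
        f = np.empty(self.nf)
        for k, i in enumerate(self.free):
            hp = height[self.parent[i]]
            f[k] = height[i] / hp if hp > 0 else 0.5
        f = np.clip(f, self.min_frac, 1.0 - self.min_frac)
        ages = self.ages_from_fractions(f)
        tau = self.durations(ages)
        total_rate = max(self.x.sum(), 1e-8) / tau.sum()
        logrho = np.full(self.ne, math.log(total_rate))
        return f, logrho


def estimate_chronogram(
    tree: Phylogram, calib: CalibrationSpec, cfg: PLConfig
) -> Chronogram:
    """Date a phylogram by penalized likelihood with a fixed root age.

    Deterministic given ``cfg.seed``: the strict-clock initialization is
    always the first start, followed by ``cfg.n_restarts - 1`` seeded random
    perturbations; the best objective wins, ties broken by first-found.
    """
    if len(tree.tip_labels()) < 2:
        raise ValueError("dating requires a tree with at least 2 tips")
    T = calib.root_age
    min_dur = cfg.min_duration if cfg.min_duration is not None else 1e-6 * T
    min_frac = min(min_dur / T, 0.49)

    prob = _PLProblem(tree, cfg, min_frac)
    f0, logrho0 = prob.clock_start()
    x0 = np.concatenate([f0, logrho0])
    bounds = [(min_frac, 1.0 - min_frac)] * prob.nf + [
        (lr - 20.0, lr + 20.0) for lr in logrho0
    ]

    rng = np.random.default_rng(cfg.seed)
    starts = [x0]
    for _ in range(max(cfg.n_restarts - 1, 0)):
        f = np.clip(
            f0 + rng.uniform(-0.3, 0.3, prob.nf), min_frac, 1.0 - min_frac
        )
        logrho = logrho0 + rng.normal(0.0, 0.5, prob.ne)
        starts.append(np.concatenate([f, logrho]))

    best = None
    best_psi = -np.inf
    trace: list[dict] = []
    any_success = False
    clock_psi = -prob.neg_psi(x0)
    for k, start in enumerate(starts):
        res = minimize(
            prob.neg_psi,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-9},
        )
        psi = -res.fun
        trace.append(
            {"restart": k, "objective": psi, "converged": bool(res.success),
             "n_iter": int(res.nit)}
        )
        any_success = any_success or res.success
        if psi > best_psi:
            best_psi = psi
            best = res.x
    # the clock start itself is an admissible solution: never return worse
    if best_psi < clock_psi:
        best, best_psi = x0, clock_psi

    chrono = _build_chronogram(tree, prob, best, best_psi, T, cfg, trace)
    if not any_success:
        raise ConvergenceError(
            f"no restart converged within {cfg.max_iter} iterations",
            best=chrono,
            trace=trace,
        )
    return chrono


def _build_chronogram(
    tree: Phylogram,
    prob: _PLProblem,
    params: np.ndarray,
    psi: float,
    root_age: float,
    cfg: PLConfig,
    trace: list[dict],
) -> Chronogram:
    ages = prob.ages_from_fractions(params[: prob.nf]) * root_age
    rho = np.exp(params[prob.nf:])
    root = _copy_subtree(tree.root)
    new_nodes = list(_preorder_nodes(root))
    for i, node in enumerate(new_nodes):
        node.age = float(ages[i])
        node.rate = None
    for k, i in enumerate(prob.nonroot):
        # rho is per normalized time unit; convert to subs/site/Myr
        new_nodes[i].rate = float(rho[k] / (root_age * cfg.seq_length))
    return Chronogram(
        root,
        root_age,
        seq_length=cfg.seq_length,
        objective=float(psi),
        trace=trace,
    )


def _preorder_nodes(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


# ---------------------------------------------------------------------
# calibration handling


def rescale_chronogram(chrono: Chronogram, new_root_age: float) -> Chronogram:
    """Move a chronogram to a different root calibration.

    Ages scale by ``new_root_age / root_age``; rates scale inversely. This
    is exact for penalized-likelihood dating under a single fixed root age
    (the objective is invariant under the rescaling).
    """
    if new_root_age <= 0:
        raise ValueError("new_root_age must be > 0")
    k = new_root_age / chrono.root_age
    root = _copy_subtree(chrono.root)
    for node in _preorder_nodes(root):
        node.age = node.age * k
        if node.rate is not None:
            node.rate = node.rate / k
    return Chronogram(
        root,
        new_root_age,
        seq_length=chrono.seq_length,
        objective=chrono.objective,
        trace=chrono.trace,
    )


def propagate_calibration_ci(
    age: float, calib: CalibrationSpec
) -> tuple[float, float]:
    """Confidence limits of a clade age from the root-calibration interval.

    Linear scaling: (age * ci_low / root_age, age * ci_high / root_age).
    Full precision; rounding happens only at report time.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    return (
        age * calib.ci_low / calib.root_age,
        age * calib.ci_high / calib.root_age,
    )


def crown_age(chrono: Chronogram, clade: CladeDefinition) -> float:
    """Age of the MRCA of the clade's tips (crown-group age)."""
    clade.validate_against(chrono)
    if len(clade.tips) == 1:
        logger.warning(
            "clade %r has a single tip; crown age is 0 by convention", clade.name
        )
        return 0.0
    return float(chrono.mrca(sorted(clade.tips)).age)
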