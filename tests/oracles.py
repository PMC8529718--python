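"""Independent oracles used to cross-check the implementation.

Deliberately different algorithms from the code under test: the
penalized-likelihood oracle is a staged exhaustive grid search over
node ages with rates profiled out by 1-D Newton coordinate ascent
(the package optimiser is a joint quasi-Newton method); the MRCA
oracle intersects explicit ancestor sets.
"""

from __future__ import annotations

import math

import numpy as np

from chronoscreen.pl import CalibrationConstraint, PLProblem
from chronoscreen.trees import ArrayTree, NodeQuery, PhylogramTree


def brute_force_mrca(at: ArrayTree, label_a: str, label_b: str) -> int:
    """MRCA by ancestor-set intersection: deepest shared ancestor."""
    ia, ib = at.tip_index[label_a], at.tip_index[label_b]
    anc_a = {ia} | set(at.ancestors(ia))
    shared = [ib] if ib in anc_a else []
    j = ib
    while at.parent[j] >= 0:
        j = at.parent[j]
        if j in anc_a:
            shared.append(j)
    # ancestors() walks rootward, so the first shared node is the MRCA
    return shared[0]


def _profile_rates(problem: PLProblem, ages_full: np.ndarray, lam: float,
                   r0: np.ndarray | None = None, sweeps: int = 400, tol: float = 1e-12):
    """Maximise the objective over rates at fixed ages.

    Coordinate ascent with exact coordinate updates: holding the other
    rates fixed, dPhi/dr_j is linear in r_j, so the stationarity
    condition x/r - t - lam * dPhi/dr = 0 is a quadratic in r_j with a
    unique positive root.
    """
    at = problem.at
    n = at.n_nodes
    x = problem.x
    t = np.empty(n)
    t[0] = np.nan
    t[1:] = ages_full[at.parent[1:]] - ages_full[1:]
    root_children = at.children[0]
    k_root = len(root_children)
    r = np.empty(n)
    r[0] = np.nan
    if r0 is None:
        r[1:] = (x[1:] + 0.5) / np.maximum(t[1:], 1e-9)
    else:
        r[1:] = r0[1:]
    children = at.children
    parent = at.parent
    for _ in range(sweeps):
        max_rel = 0.0
        for j in range(1, n):
            # dPhi/dr_j = h*r_j + b (linear in r_j)
            h = 0.0
            b = 0.0
            if parent[j] != 0:
                h += 2.0
                b -= 2.0 * r[parent[j]]
            for c in children[j]:
                h += 2.0
                b -= 2.0 * r[c]
            if j in root_children:
                s_other = sum(r[c] for c in root_children) - r[j]
                h += (2.0 / k_root) * (1.0 - 1.0 / k_root)
                b -= (2.0 / (k_root * k_root)) * s_other
            # solve lam*h*r^2 + (t + lam*b)*r - x = 0 for r >= 0
            A = lam * h
            B = t[j] + lam * b
            if A < 1e-300:
                new = x[j] / B if B > 1e-300 else (x[j] + 0.5) * 1e12
            else:
                new = (-B + math.sqrt(B * B + 4.0 * A * x[j])) / (2.0 * A)
            new = max(new, 0.0)
            max_rel = max(max_rel, abs(new - r[j]) / (1.0 + abs(r[j])))
            r[j] = new
        if max_rel < tol:
            break
    return r


def _objective(problem: PLProblem, r: np.ndarray, ages_full: np.ndarray, lam: float) -> float:
    from chronoscreen.pl import pl_objective

    return pl_objective(problem, np.nan_to_num(r), ages_full, lam)


def grid_oracle(tree: PhylogramTree, constraints, lam: float = 1.0,
                grid: int = 30, stages: int = 3, refine: float = 1.5):
    """Exhaustive staged grid search over the free internal node ages.

    Supports trees whose root age is point-constrained and whose other
    internal ages are free (the 4-taxon fixture suite). Returns the
    full age vector at the grid optimum.
    """
    problem = PLProblem(tree, constraints)
    at = problem.at
    free = [int(i) for i in at.internal if problem.eff_max[i] - problem.eff_min[i] > 1e-9]
    fixed = {int(i): problem.eff_min[i] for i in at.internal if int(i) not in free}
    assert len(free) <= 2, "grid oracle supports at most two free ages"

    ages = np.zeros(at.n_nodes)
    for i, v in fixed.items():
        ages[i] = v

    def feasible(vals) -> bool:
        for i, v in zip(free, vals):
            ages[i] = v
        for j in range(1, at.n_nodes):
            if not at.is_tip[j] and ages[at.parent[j]] < ages[j]:
                return False
        return True

    lo = [max(problem.eff_min[i], 1e-6) for i in free]
    hi = [min(problem.eff_max[i], ages[0] if 0 in fixed else problem.eff_max[i]) for i in free]
    best_vals, best_obj = None, -math.inf
    for _stage in range(stages):
        axes = [np.linspace(l, h, grid) for l, h in zip(lo, hi)]
        if len(free) == 1:
            points = [(v,) for v in axes[0]]
        else:
            points = [(v1, v2) for v1 in axes[0] for v2 in axes[1]]
        for vals in points:
            if not feasible(vals):
                continue
            # cold start at the per-branch Poisson MLE: with the penalty
            # it reconciles in a handful of sweeps, and a degenerate grid
            # point cannot poison its neighbours
            r = _profile_rates(problem, ages, lam, sweeps=60)
            obj = _objective(problem, r, ages, lam)
            if obj > best_obj:
                best_obj, best_vals = obj, vals
        # refine around the incumbent
        new_lo, new_hi = [], []
        for k, (l, h) in enumerate(zip(lo, hi)):
            cell = (h - l) / (grid - 1)
            new_lo.append(max(l, best_vals[k] - refine * cell))
            new_hi.append(min(h, best_vals[k] + refine * cell))
        lo, hi = new_lo, new_hi
    for i, v in zip(free, best_vals):
        ages[i] = v
    return ages.copy(), best_obj


def make_four_taxon_problem(seed: int, alignment_length: int = 5000):
    """Random rooted 4-taxon dating problem with a point-constrained root.

    Topology is balanced or pectinate at random; true ages are drawn
    top-down; branch rates are mildly relaxed around a clock; observed
    expected counts carry Poisson noise. Returns (phylogram,
    constraints, truth ages).
    """
    rng = np.random.default_rng(seed)
    root_age = 100.0
    balanced = rng.uniform() < 0.5
    if balanced:
        #      0
        #    1   2
        #  A B   C D
        parent = [-1, 0, 0, 1, 1, 2, 2]
        children = [[1, 2], [3, 4], [5, 6], [], [], [], []]
        labels = ["", "", "", "A", "B", "C", "D"]
        a = np.zeros(7)
        a[0] = root_age
        a[1] = rng.uniform(0.25, 0.9) * root_age
        a[2] = rng.uniform(0.25, 0.9) * root_age
    else:
        #      0
        #    1    D
        #   2  C
        #  A B
        parent = [-1, 0, 1, 2, 2, 1, 0]
        children = [[1, 6], [2, 5], [3, 4], [], [], [], []]
        labels = ["", "", "", "A", "B", "C", "D"]
        a = np.zeros(7)
        a[0] = root_age
        a[1] = rng.uniform(0.35, 0.9) * root_age
        a[2] = rng.uniform(0.3, 0.9) * a[1]
    rate = 0.003
    n = len(parent)
    blen = np.zeros(n)
    for j in range(1, n):
        t = a[parent[j]] - a[j]
        r_j = rate * rng.lognormal(0.0, 0.15)
        blen[j] = rng.poisson(r_j * t * alignment_length) / alignment_length
    at = ArrayTree(parent, children, labels, blen)
    tree = PhylogramTree(tree=at, alignment_length=alignment_length)
    root_query = NodeQuery("A", "D", "root")
    constraints = [CalibrationConstraint(root_query, root_age, root_age)]
    return tree, constraints, a
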