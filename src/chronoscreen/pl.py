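"""Penalized-likelihood rate smoothing: phylogram -> chronogram.

Estimates internal node ages and per-branch substitution rates by
maximizing

    F(r, a) = sum_j [ x_j * log(r_j * t_j) - r_j * t_j ]  -  lambda * Phi(r)

where x_j is the expected substitution count on branch j (ML branch
length times alignment length, kept real-valued), t_j is the branch
duration implied by the node ages a, and Phi penalises rate changes
between adjacent branches: the sum of squared differences between every
non-root branch rate and its parent branch rate, plus the variance of
the rates on the root's immediate descendant branches. lambda = 0 is a
free-rates model; lambda -> infinity approaches a strict clock.

Rates here are count-scale (expected substitutions across the alignment
per MY); the returned :class:`~chronoscreen.trees.Chronogram` stores
per-site rates (divided by alignment length).

Age constraints (minimum and/or maximum, addressed by MRCA taxon pairs)
are enforced exactly. At least one node must carry both a finite
minimum and a finite maximum, otherwise the time scale is not
identifiable from branch lengths alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .trees import Chronogram, NodeQuery, PhylogramTree

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationConstraint",
    "SmoothingConfig",
    "PLProblem",
    "InfeasibleConstraintsError",
    "pl_objective",
    "estimate_chronogram",
    "cross_validate_lambda",
]

_UBOUND = (-46.0, 23.0)  # log-rate box; e^23 ~ 1e10 counts/MY


class InfeasibleConstraintsError(ValueError):
    """The calibration set admits no feasible age assignment."""


def load_calibrations(path) -> list["CalibrationConstraint"]:
    """Calibrations CSV: node_label, taxonA, taxonB, min_age, max_age.

    Empty min_age means 0 (no minimum); empty max_age means unbounded.
    """
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(
            CalibrationConstraint(
                node=NodeQuery(str(r.taxonA), str(r.taxonB), str(r.node_label)),
                min_age=0.0 if pd.isna(r.min_age) else float(r.min_age),
                max_age=float("inf") if pd.isna(r.max_age) else float(r.max_age),
            )
        )
    return out


def write_calibrations(constraints: list["CalibrationConstraint"], path) -> None:
    rows = [
        {
            "node_label": c.node.label,
            "taxonA": c.node.taxon_a,
            "taxonB": c.node.taxon_b,
            "min_age": c.min_age,
            "max_age": c.max_age if np.isfinite(c.max_age) else "",
        }
        for c in constraints
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationConstraint:
    """Min and/or max age bound (MYA) on the MRCA of a taxon pair."""

    node: NodeQuery
    min_age: float = 0.0
    max_age: float = float("inf")

    def __post_init__(self):
        if not self.min_age <= self.max_age:
            raise InfeasibleConstraintsError(
                f"constraint on {self.node}: min {self.min_age} > max {self.max_age}"
            )


@dataclass
class SmoothingConfig:
    """Optimiser settings for penalized-likelihood dating.

    lam is the smoothing weight (default 1.0, recorded in output
    metadata); restarts are independent optimiser starts from jittered
    feasible initialisations, deterministic given seed.
    """

    lam: float = 1.0
    cross_validate: bool = False
    lambda_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    tol: float = 1e-12
    restarts: int = 5
    seed: int = 0
    max_iter: int = 2000

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


class PLProblem:
    """Arrays and effective bounds for one dating problem.

    Effective per-node bounds fold the calibration bounds through the
    topology: a node's effective minimum is the max of its own minimum
    and all descendant minima; its effective maximum is the min of its
    own maximum and all ancestral maxima. Infeasibility is detected
    here, before any optimisation.
    """

    def __init__(
        self,
        tree: PhylogramTree,
        constraints: list[CalibrationConstraint],
        big_factor: float = 10.0,
    ):
        self.phylogram = tree
        at = tree.tree
        self.at = at
        self.x = tree.expected_counts()  # indexed by child node; [0] unused
        self.loo_mask = np.ones(at.n_nodes)  # LL weight per branch (CV uses 0/1)
        self.loo_mask[0] = 0.0

        n = at.n_nodes
        cal_min = np.zeros(n)
        cal_max = np.full(n, np.inf)
        finite_vals = []
        has_two_sided = False
        for c in constraints:
            idx = at.mrca_index(c.node.taxon_a, c.node.taxon_b)
            if at.is_tip[idx]:
                raise InfeasibleConstraintsError(
                    f"constraint {c.node} resolves to a tip, not an internal node"
                )
            cal_min[idx] = max(cal_min[idx], c.min_age)
            cal_max[idx] = min(cal_max[idx], c.max_age)
            if c.min_age > 0:
                finite_vals.append(c.min_age)
            if np.isfinite(c.max_age):
                finite_vals.append(c.max_age)
            if c.min_age > 0 and np.isfinite(c.max_age):
                has_two_sided = True
        if not has_two_sided:
            raise InfeasibleConstraintsError(
                "need at least one node with both a finite minimum and a finite "
                "maximum age: the time scale is otherwise not identifiable"
            )
        self.scale = max(finite_vals)
        big = big_factor * self.scale

        eff_min = cal_min.copy()
        for i in at.postorder:  # children before parents
            for ch in at.children[i]:
                eff_min[i] = max(eff_min[i], eff_min[ch])
        eff_max = np.minimum(cal_max, big)
        for i in range(1, n):  # parents before children (preorder indices)
            eff_max[i] = min(eff_max[i], eff_max[at.parent[i]])
        for i in at.internal:
            if eff_min[i] > eff_max[i] + 1e-12:
                raise InfeasibleConstraintsError(
                    f"constraints infeasible at internal node {i}: effective "
                    f"min {eff_min[i]:.6g} > effective max {eff_max[i]:.6g}"
                )
        self.cal_min, self.cal_max = cal_min, cal_max
        self.eff_min, self.eff_max = eff_min, eff_max
        self.m = len(at.internal)  # free ages (root included)
        self.B = n - 1  # branches
        self.t_floor = 1e-9 * self.scale
        # optimiser scalings: ages in units of self.scale, objective O(1)
        self.f_scale = max(1.0, float(self.x[1:].sum()))
        # internal-internal edges need explicit parent-minus-child rows
        self._int_pos = {int(i): k for k, i in enumerate(at.internal)}
        rows = []
        for j in range(1, n):
            if not at.is_tip[j]:
                rows.append((self._int_pos[at.parent[j]], self._int_pos[j]))
        self._edge_rows = rows

    # -- age vector helpers --------------------------------------------
    def full_ages(self, ages_internal: np.ndarray) -> np.ndarray:
        a = np.zeros(self.at.n_nodes)
        a[self.at.internal] = ages_internal
        return a

    def durations(self, a_full: np.ndarray) -> np.ndarray:
        t = np.empty(self.at.n_nodes)
        t[0] = np.nan
        t[1:] = a_full[self.at.parent[1:]] - a_full[1:]
        return t


def pl_objective(problem: PLProblem, rates: np.ndarray, ages: np.ndarray, lam: float) -> float:
    """The penalized log-likelihood at (rates, ages); larger is better.

    ``rates`` indexed by child node (entry 0 ignored), ``ages`` a full
    per-node vector (tips 0). Returns -inf when a branch with positive
    expected count has zero or negative duration (infeasible proposal).
    """
    at = problem.at
    x = problem.x
    t = ages[at.parent[1:]] - ages[1:]
    r = np.asarray(rates, dtype=float)[1:]
    w = problem.loo_mask[1:]
    xm = x[1:] * w
    if np.any((t <= 0) & (xm > 0)):
        return -np.inf
    mu = r * t
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_log = np.where(xm > 0, xm * np.log(mu), 0.0)
    ll = float(np.sum(ll_log - w * mu))
    return ll - lam * _penalty(problem, np.asarray(rates, dtype=float))[0]


def _penalty(problem: PLProblem, r_full: np.ndarray):
    """Phi(r) and dPhi/dr (full-node indexing)."""
    at = problem.at
    g = np.zeros(at.n_nodes)
    par = at.parent
    j = np.arange(2, at.n_nodes)
    inner = j[par[j] != 0]
    d = r_full[inner] - r_full[par[inner]]
    phi = float(np.dot(d, d))
    np.add.at(g, inner, 2.0 * d)
    np.add.at(g, par[inner], -2.0 * d)
    rc = at.children[0]
    rr = r_full[rc]
    v = rr - rr.mean()
    phi += float(np.dot(v, v) / len(rc))
    g[rc] += 2.0 * v / len(rc)
    return phi, g


def _objective_and_grad(problem: PLProblem, z: np.ndarray, lam: float):
    """Smoothed objective (negated and rescaled, for minimisation) with gradient.

    ``z`` holds internal node ages in units of ``problem.scale``
    followed by log rates; the objective is divided by the total
    expected count so its magnitude is O(1) regardless of alignment
    length (neither rescaling moves the optimum). Durations below a
    tiny floor are handled by a linear extension of the log, so trial
    points that graze the feasibility boundary return finite values and
    gradients that push back inside.
    """
    at = problem.at
    m, B = problem.m, problem.B
    ages_int = z[:m] * problem.scale
    u = z[m:]
    a = problem.full_ages(ages_int)
    t = a[at.parent[1:]] - a[1:]
    r = np.exp(u)
    tf = problem.t_floor
    safe = t > tf
    tl = np.where(safe, t, tf)
    log_t = np.log(tl) + np.where(safe, 0.0, (t - tf) / tf)
    dlog_t = np.where(safe, 1.0 / tl, 1.0 / tf)
    x = problem.x[1:] * problem.loo_mask[1:]
    w = problem.loo_mask[1:]
    mu = r * t
    F = float(np.sum(x * (u + log_t) - w * mu))
    r_full = np.zeros(at.n_nodes)
    r_full[1:] = r
    phi, gphi = _penalty(problem, r_full)
    F -= lam * phi
    # gradient wrt u (log rates)
    gu = x - w * mu - lam * gphi[1:] * r
    # gradient wrt ages via durations
    dFdt = x * dlog_t - w * r
    ga_full = np.zeros(at.n_nodes)
    np.add.at(ga_full, at.parent[1:], dFdt)
    ga_full[1:] -= dFdt
    ga = ga_full[at.internal] * problem.scale
    fs = problem.f_scale
    return -F / fs, -np.concatenate([ga, gu]) / fs


def _initial_point(problem: PLProblem, rng: np.random.Generator, jitter: float):
    at = problem.at
    a = np.zeros(at.n_nodes)
    S = problem.scale
    lo0, hi0 = problem.eff_min[0], problem.eff_max[0]
    hi_draw = min(hi0, max(2.0 * S, 1.2 * lo0 + 1e-9))
    hi_draw = max(hi_draw, lo0)
    a[0] = lo0 + (hi_draw - lo0) * rng.uniform(0.4, 0.9)
    if a[0] <= 0:
        a[0] = max(S, 1.0)
    for i in range(1, at.n_nodes):
        if at.is_tip[i]:
            continue
        lo = problem.eff_min[i]
        hi = min(problem.eff_max[i], a[at.parent[i]])
        frac = min(max(rng.uniform(0.45, 0.75) + jitter * rng.normal() * 0.1, 0.05), 0.95)
        a[i] = lo + frac * max(hi - lo, 0.0)
    t = problem.durations(a)
    r0 = (problem.x[1:] + 0.5) / np.maximum(t[1:], problem.t_floor * 10)
    u0 = np.log(r0) + jitter * rng.normal(size=problem.B) * 0.1
    u0 = np.clip(u0, _UBOUND[0] + 1, _UBOUND[1] - 1)
    return np.concatenate([a[at.internal] / problem.scale, u0])


def _project_feasible(problem: PLProblem, ages_int: np.ndarray) -> np.ndarray:
    """Clip a near-feasible age vector exactly into the constraint set."""
    at = problem.at
    a = problem.full_ages(ages_int)
    a[at.internal] = np.clip(
        a[at.internal], problem.eff_min[at.internal], problem.eff_max[at.internal]
    )
    for i in range(1, at.n_nodes):  # preorder: parents first
        if not at.is_tip[i]:
            a[i] = min(a[i], a[at.parent[i]])
    return a


def _fit_once(problem: PLProblem, lam: float, config: SmoothingConfig, z0: np.ndarray):
    m = problem.m
    at = problem.at
    S = problem.scale
    eps = problem.t_floor / S  # scaled units
    rows = problem._edge_rows
    if rows:
        A = np.zeros((len(rows), m + problem.B))
        for k, (pi, ci) in enumerate(rows):
            A[k, pi] = 1.0
            A[k, ci] = -1.0
        cons = [
            {
                "type": "ineq",
                "fun": lambda z, A=A: A @ z - eps,
                "jac": lambda z, A=A: A,
            }
        ]
    else:
        cons = []
    bounds = [
        (max(problem.eff_min[i], 0.0) / S, problem.eff_max[i] / S)
        for i in at.internal
    ] + [_UBOUND] * problem.B
    res = minimize(
        lambda z: _objective_and_grad(problem, z, lam),
        z0,
        jac=True,
        method="SLSQP",
        bounds=bounds,
        constraints=cons,
        options={"maxiter": config.max_iter, "ftol": config.tol},
    )
    return res


def estimate_chronogram(
    tree: PhylogramTree,
    constraints: list[CalibrationConstraint],
    config: SmoothingConfig | None = None,
) -> Chronogram:
    """Fit a chronogram under penalized-likelihood rate smoothing.

    Deterministic given ``config.seed``. The returned chronogram
    satisfies all calibration bounds and parent>=child ordering exactly
    (solutions are projected onto the constraint set after
    optimisation); its metadata records lambda, seed, the final
    objective, and the convergence flag. Non-convergence after all
    restarts yields a flagged result, never a silent one.
    """
    config = config or SmoothingConfig()
    problem = PLProblem(tree, constraints)
    lam = config.lam
    cv_table = None
    if config.cross_validate:
        lam, cv_table = cross_validate_lambda(
            tree, constraints, list(config.lambda_grid), config.seed,
            config=replace(config, cross_validate=False),
        )
    rng = np.random.default_rng(config.seed)
    best = None
    best_obj = -np.inf
    init_obj = None
    n_ok = 0
    for k in range(config.restarts):
        z0 = _initial_point(problem, rng, jitter=0.0 if k == 0 else 1.0)
        f0 = -_objective_and_grad(problem, z0, lam)[0]
        if init_obj is None:
            init_obj = f0
        res = _fit_once(problem, lam, config, z0)
        f = -res.fun
        if res.success:
            n_ok += 1
        if f > best_obj:
            best_obj, best = f, res
    converged = n_ok > 0
    if not converged:
        logger.warning(
            "penalized-likelihood fit did not converge in %d restarts (status: %s)",
            config.restarts,
            best.message if best is not None else "n/a",
        )
    z = best.x
    ages = _project_feasible(problem, z[: problem.m] * problem.scale)
    rates_full = np.full(problem.at.n_nodes, np.nan)
    rates_full[1:] = np.exp(z[problem.m :])
    final_obj = pl_objective(problem, np.nan_to_num(rates_full), ages, lam)
    meta = {
        "lambda": lam,
        "seed": config.seed,
        "objective": final_obj,
        "objective_init": init_obj * problem.f_scale,
        "converged": bool(converged),
        "restarts": config.restarts,
        "optimizer": "SLSQP",
        "n_constraints": len(constraints),
    }
    if cv_table is not None:
        meta["cv_table"] = cv_table.to_dict("records")
    return Chronogram(
        tree=problem.at,
        ages=ages,
        rates=rates_full / tree.alignment_length,
        metadata=meta,
    )


def cross_validate_lambda(
    tree: PhylogramTree,
    constraints: list[CalibrationConstraint],
    lambda_grid: list[float],
    seed: int = 0,
    config: SmoothingConfig | None = None,
):
    """Pick a smoothing weight by leave-one-terminal-branch-out CV.

    For each candidate lambda and each terminal branch, the branch's
    substitution count is dropped from the likelihood and refit; the
    smoothing penalty then pulls the orphaned branch's rate toward its
    neighbours, so r_hat * t_hat is the model's prediction for the
    held-out count. The score is the chi-square-style sum of
    (x - mu_hat)^2 / mu_hat; ties are broken toward the larger (smoother)
    lambda. Returns (best_lambda, score table).
    """
    if not lambda_grid:
        raise ValueError("lambda_grid must be non-empty")
    base = config or SmoothingConfig(restarts=2)
    grid = sorted(set(float(l) for l in lambda_grid))
    if len(grid) == 1:
        table = pd.DataFrame(
            [{"lambda": grid[0], "cv_score": np.nan, "note": "degenerate grid"}]
        )
        return grid[0], table
    problem_probe = PLProblem(tree, constraints)
    at = problem_probe.at
    terminal = [j for j in range(1, at.n_nodes) if at.is_tip[j]]
    rows = []
    for lam in grid:
        score = 0.0
        ok = True
        for j in terminal:
            prob = PLProblem(tree, constraints)
            prob.loo_mask[j] = 0.0
            cfg = replace(base, lam=lam, cross_validate=False,
                          seed=seed + 1000, restarts=base.restarts)
            rng = np.random.default_rng(cfg.seed)
            best, best_f = None, -np.inf
            for k in range(cfg.restarts):
                z0 = _initial_point(prob, rng, jitter=0.0 if k == 0 else 1.0)
                res = _fit_once(prob, lam, cfg, z0)
                if -res.fun > best_f:
                    best_f, best = -res.fun, res
                ok = ok and res.success
            ages = _project_feasible(prob, best.x[: prob.m] * prob.scale)
            r = np.exp(best.x[prob.m :])
            t = prob.durations(ages)[1:]
            mu = r[j - 1] * t[j - 1]
            score += (prob.x[j] - mu) ** 2 / max(mu, 1e-12)
        rows.append({"lambda": lam, "cv_score": score, "converged": ok})
    table = pd.DataFrame(rows)
    smin, smax = table["cv_score"].min(), table["cv_score"].max()
    # the score is chi-square-scaled, so differences below ~1 sit under
    # the Poisson noise floor: treat them as ties and resolve ties to
    # the smoother (larger) lambda
    tol = 1.0 + 1e-3 * (smax - smin)
    best_lam = float(table.loc[table["cv_score"] <= smin + tol, "lambda"].max())
    return best_lam, table
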