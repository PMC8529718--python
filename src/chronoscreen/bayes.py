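"""Bayesian node dating under an independent-rates relaxed clock.

A deliberately small Metropolis-Hastings sampler over internal node
ages and per-branch rates:

* **Likelihood** — the same generalized-Poisson branch-length model as
  the penalized-likelihood stage: the expected substitution count on
  branch j is rate_j x duration_j x alignment length, and the observed
  count is the ML branch length times the alignment length (kept
  real-valued). This stands in for a full alignment likelihood and
  keeps the two dating stages internally consistent.
* **Rates** — i.i.d. lognormal across branches with a fixed mean
  substitution rate (default 0.290696 substitutions/site per time unit)
  and configurable log-scale spread.
* **Node-age prior** — root age uniform below the hard root maximum;
  every other internal age uniform between its effective lower bound
  (calibration minima folded through the topology) and its parent's
  age, cascading from the root. Calibration minima and the root
  maximum are hard bounds: no sampled state ever violates them.
* **Time unit** — 1 internal time unit = 100 MY by default (the
  convention implied by a mean rate of ~0.29 with ages in the low
  hundreds of MYA); all I/O is in MYA.

Moves: per-node age slides within the local feasibility window,
per-branch log-rate slides, and a whole-tree age scaling; step sizes
adapt during burn-in only, so the post-burn-in kernel is fixed and the
chain is a deterministic function of the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pl import CalibrationConstraint, InfeasibleConstraintsError
from .trees import ArrayTree, Chronogram, PhylogramTree

logger = logging.getLogger(__name__)

__all__ = [
    "McmcSettings",
    "Chain",
    "PosteriorSummary",
    "run_mcmc",
    "run_replicates",
    "sample_prior_direct",
    "summarize_posterior",
]


@dataclass
class McmcSettings:
    """Sampler settings; defaults follow the package's reference protocol."""

    generations: int = 500_000  # one generation = one full update sweep
    sample_every: int = 50
    burn_in: int = 50_000
    seed: int = 0
    mean_rate: float = 0.290696  # substitutions/site per time unit
    root_max: float = 334.0  # MYA, hard upper bound on the root age
    rate_sigma: float = 0.5  # lognormal spread of branch rates (log scale)
    replicates: int = 2
    time_unit_my: float = 100.0
    prior_only: bool = False
    adapt_interval: int = 50

    def __post_init__(self):
        if not self.burn_in < self.generations:
            raise ValueError("burn_in must be smaller than generations")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.mean_rate <= 0 or self.rate_sigma <= 0:
            raise ValueError("mean_rate and rate_sigma must be positive")


@dataclass
class Chain:
    """Posterior samples from one run.

    ages are MYA, one column per internal node (tree preorder); rates
    are substitutions/site per time unit, one column per branch.
    """

    tree: ArrayTree
    generations: np.ndarray
    ages: np.ndarray
    rates: np.ndarray
    log_post: np.ndarray
    acceptance: dict
    settings: McmcSettings
    warnings: list = field(default_factory=list)

    def to_chronogram(self, alignment_length: int) -> Chronogram:
        """Chronogram at posterior-mean ages and rates."""
        at = self.tree
        a = np.zeros(at.n_nodes)
        a[at.internal] = self.ages.mean(axis=0)
        r = np.full(at.n_nodes, np.nan)
        r[1:] = self.rates.mean(axis=0) / self.settings.time_unit_my
        for i in range(1, at.n_nodes):  # guard fp ties
            if not at.is_tip[i]:
                a[i] = min(a[i], a[at.parent[i]])
        return Chronogram(tree=at, ages=a, rates=r, metadata={"source": "mcmc-mean"})


@dataclass
class PosteriorSummary:
    """Per-node posterior summaries (MYA) plus replicate agreement."""

    table: pd.DataFrame
    replicate_delta: pd.DataFrame | None = None
    flags: list = field(default_factory=list)


def _effective_bounds(
    at: ArrayTree, tree: PhylogramTree, calibrations, settings: McmcSettings
):
    """Fold calibrations through the topology; MYA units. Raises if infeasible."""
    n = at.n_nodes
    lo = np.zeros(n)
    hi = np.full(n, np.inf)
    for c in calibrations:
        idx = at.mrca_index(c.node.taxon_a, c.node.taxon_b)
        if at.is_tip[idx]:
            raise InfeasibleConstraintsError(f"calibration {c.node} resolves to a tip")
        lo[idx] = max(lo[idx], c.min_age)
        hi[idx] = min(hi[idx], c.max_age)
    hi[0] = min(hi[0], settings.root_max)
    for i in at.postorder:
        for ch in at.children[i]:
            lo[i] = max(lo[i], lo[ch])
    for i in range(1, n):
        hi[i] = min(hi[i], hi[at.parent[i]])
    for i in at.internal:
        if lo[i] >= hi[i]:
            raise InfeasibleConstraintsError(
                f"calibrations infeasible at node {i}: min {lo[i]:.4g} >= max {hi[i]:.4g}"
            )
    if lo[0] >= settings.root_max:
        raise InfeasibleConstraintsError(
            f"root maximum {settings.root_max} MYA does not exceed the oldest "
            f"calibration minimum {lo[0]:.4g} MYA"
        )
    return lo, hi


def sample_prior_direct(
    tree: PhylogramTree,
    calibrations: list[CalibrationConstraint],
    settings: McmcSettings,
    n_draws: int,
    seed: int = 0,
) -> np.ndarray:
    """Direct Monte-Carlo draws of internal node ages from the prior (MYA).

    Constructive counterpart of the sampler's target prior: the root is
    uniform on (effective minimum, root max); each internal node,
    visited root-down, is uniform between its effective minimum and the
    smaller of its parent's age and its effective maximum. Used as the
    independent reference in prior-recovery checks.
    """
    at = tree.tree
    lo, hi = _effective_bounds(at, tree, calibrations, settings)
    rng = np.random.default_rng(seed)
    m = len(at.internal)
    out = np.empty((n_draws, m))
    pos = {int(i): k for k, i in enumerate(at.internal)}
    for d in range(n_draws):
        a = np.zeros(at.n_nodes)
        a[0] = rng.uniform(lo[0], hi[0])
        for i in at.internal[1:]:
            upper = min(a[at.parent[i]], hi[i])
            a[i] = rng.uniform(lo[i], upper)
        out[d] = a[at.internal]
    return out


def run_mcmc(
    tree: PhylogramTree,
    calibrations: list[CalibrationConstraint],
    settings: McmcSettings | None = None,
) -> Chain:
    """Sample node ages and branch rates; deterministic given the seed.

    Infeasible calibration sets fail before any sampling. After
    adaptation, a mean acceptance rate outside [0.05, 0.8] for any move
    class is recorded as a warning in the chain (poor mixing), never
    silently ignored.
    """
    settings = settings or McmcSettings()
    at = tree.tree
    lo_my, hi_my = _effective_bounds(at, tree, calibrations, settings)
    U = settings.time_unit_my
    lo = lo_my / U
    hi = hi_my / U
    L = float(tree.alignment_length)
    x = tree.expected_counts()  # counts per branch (child-node indexed)
    rng = np.random.default_rng(settings.seed)

    internal = [int(i) for i in at.internal]
    pos = {i: k for k, i in enumerate(internal)}
    m = len(internal)
    parent = [int(p) for p in at.parent]
    children = [list(map(int, c)) for c in at.children]
    int_children = [[c for c in children[i] if not at.is_tip[c]] for i in range(at.n_nodes)]
    like_on = 0.0 if settings.prior_only else 1.0

    mu_u = math.log(settings.mean_rate) - 0.5 * settings.rate_sigma**2
    sig = settings.rate_sigma

    # --- initial state: prior draw for ages, prior mean rates -------------
    a = [0.0] * at.n_nodes
    a[0] = lo[0] + 0.5 * (hi[0] - lo[0])
    for i in internal[1:]:
        upper = min(a[parent[i]], hi[i])
        a[i] = lo[i] + 0.618 * (upper - lo[i])
    u = [mu_u] * at.n_nodes  # log rates, child-node indexed; [0] unused
    r = [math.exp(v) for v in u]

    def branch_ll(j: int) -> float:
        t = a[parent[j]] - a[j]
        mu = r[j] * t * L
        if mu <= 0:
            return 0.0 if x[j] <= 0 else -math.inf
        return x[j] * math.log(mu) - mu

    def child_prior_terms(i: int) -> float:
        # conditional-uniform normalisers of i's internal children
        s = 0.0
        for c in int_children[i]:
            s -= math.log(min(a[i], hi[c]) - lo[c])
        return s

    ll = [0.0] * at.n_nodes
    for j in range(1, at.n_nodes):
        ll[j] = branch_ll(j)

    # adaptive step sizes (frozen after burn-in)
    d_age = [0.0] * at.n_nodes
    for i in internal:
        upper = hi[i] if i == 0 else min(a[parent[i]], hi[i])
        d_age[i] = max(0.25 * (upper - lo[i]), 1e-4)
    d_rate = 0.5 * sig
    d_scale = 0.05
    d_ridge = 0.1
    local_mult = 3.0  # local transform move takes larger steps than plain slides
    acc = {"age": [0, 0], "local": [0, 0], "rate": [0, 0], "scale": [0, 0], "ridge": [0, 0]}

    n_samples = settings.generations // settings.sample_every
    S_ages = np.empty((n_samples, m))
    S_rates = np.empty((n_samples, at.n_nodes - 1))
    S_gen = np.empty(n_samples, dtype=int)
    S_lp = np.empty(n_samples)
    k_out = 0

    def log_post_full() -> float:
        lp = like_on * sum(ll[1:])
        lp -= math.log(hi[0] - lo[0])
        for i in internal:
            lp += child_prior_terms(i)
        for j in range(1, at.n_nodes):
            z = (u[j] - mu_u) / sig
            lp += -0.5 * z * z
        return lp

    # batched uniforms: one python-level rng call per ~chunk, not per move
    _buf = np.empty(0)
    _pos = [0]

    def uni() -> float:
        nonlocal _buf
        k = _pos[0]
        if k >= _buf.size:
            _buf = rng.random(16384)
            _pos[0] = 0
            k = 0
        _pos[0] = k + 1
        return _buf[k]

    for gen in range(1, settings.generations + 1):
        # -- age slides ------------------------------------------------
        for i in internal:
            cur = a[i]
            prop = cur + d_age[i] * (2.0 * uni() - 1.0)
            lo_w = lo[i]
            for c in children[i]:
                if not at.is_tip[c] and a[c] > lo_w:
                    lo_w = a[c]
            hi_w = hi[i] if i == 0 else min(a[parent[i]], hi[i])
            acc["age"][1] += 1
            if prop <= lo_w or prop >= hi_w:
                continue
            delta = -child_prior_terms(i)
            old_ll = []
            if i != 0:
                old_ll.append((i, ll[i]))
            for c in children[i]:
                old_ll.append((c, ll[c]))
            d_like = 0.0
            a[i] = prop
            ok = True
            for j, prev in old_ll:
                new = branch_ll(j)
                if new == -math.inf:
                    ok = False
                    break
                d_like += new - prev
            if ok:
                delta += child_prior_terms(i) + like_on * d_like
            if ok and (delta >= 0 or uni() < math.exp(delta)):
                for j, _ in old_ll:
                    ll[j] = branch_ll(j)
                acc["age"][0] += 1
            else:
                a[i] = cur

        # -- local age/rate transform ------------------------------------
        # slide a node's age and rescale the adjacent branch rates so
        # every expected count stays fixed (likelihood-invariant); the
        # Jacobian of the rate rescaling is prod(t_old / t_new)
        for i in internal:
            cur = a[i]
            prop = cur + local_mult * d_age[i] * (2.0 * uni() - 1.0)
            lo_w = lo[i]
            for c in children[i]:
                if not at.is_tip[c] and a[c] > lo_w:
                    lo_w = a[c]
            hi_w = hi[i] if i == 0 else min(a[parent[i]], hi[i])
            acc["local"][1] += 1
            if prop <= lo_w or prop >= hi_w:
                continue
            adj = list(children[i]) + ([i] if i != 0 else [])
            t_old = [a[parent[i]] - cur if b == i else cur - a[b] for b in adj]
            t_new = [a[parent[i]] - prop if b == i else prop - a[b] for b in adj]
            if any(t <= 0 for t in t_old) or any(t <= 0 for t in t_new):
                continue
            delta = -child_prior_terms(i)
            log_jac = 0.0
            du_new = []
            for b, to, tn in zip(adj, t_old, t_new):
                lj = math.log(to / tn)
                log_jac += lj
                un = u[b] + lj
                z0 = (u[b] - mu_u) / sig
                z1 = (un - mu_u) / sig
                delta += -0.5 * (z1 * z1 - z0 * z0)
                du_new.append(un)
            a[i] = prop
            delta += child_prior_terms(i) + log_jac
            if delta >= 0 or uni() < math.exp(delta):
                for b, un in zip(adj, du_new):
                    u[b] = un
                    r[b] = math.exp(un)
                    ll[b] = branch_ll(b)
                acc["local"][0] += 1
            else:
                a[i] = cur

        # -- rate slides -----------------------------------------------
        for j in range(1, at.n_nodes):
            cur_u = u[j]
            prop_u = cur_u + d_rate * (2.0 * uni() - 1.0)
            acc["rate"][1] += 1
            z0 = (cur_u - mu_u) / sig
            z1 = (prop_u - mu_u) / sig
            delta = -0.5 * (z1 * z1 - z0 * z0)
            old = ll[j]
            u[j] = prop_u
            r[j] = math.exp(prop_u)
            new = branch_ll(j)
            delta += like_on * (new - old)
            if delta >= 0 or uni() < math.exp(delta):
                ll[j] = new
                acc["rate"][0] += 1
            else:
                u[j] = cur_u
                r[j] = math.exp(cur_u)

        # -- whole-tree age scaling -------------------------------------
        c_log = d_scale * (2.0 * uni() - 1.0)
        c = math.exp(c_log)
        acc["scale"][1] += 1
        feasible = True
        for i in internal:
            ai = a[i] * c
            if ai <= lo[i] or ai >= hi[i]:
                feasible = False
                break
        if feasible:
            old_a = [a[i] for i in internal]
            old_terms = sum(child_prior_terms(i) for i in internal)
            old_ll_sum = sum(ll[1:])
            for i in internal:
                a[i] *= c
            new_ll = [branch_ll(j) for j in range(1, at.n_nodes)]
            if -math.inf in new_ll:
                feasible = False
            else:
                new_terms = sum(child_prior_terms(i) for i in internal)
                delta = (
                    like_on * (sum(new_ll) - old_ll_sum)
                    + (new_terms - old_terms)
                    + m * c_log
                )
                feasible = delta >= 0 or uni() < math.exp(delta)
            if feasible:
                for j in range(1, at.n_nodes):
                    ll[j] = new_ll[j - 1]
                acc["scale"][0] += 1
            else:
                for k, i in enumerate(internal):
                    a[i] = old_a[k]

        # -- age/rate ridge move: ages * c, rates / c ---------------------
        # leaves every expected count invariant, so it explores the
        # time-scale/rate ridge the data alone cannot resolve
        c_log = d_ridge * (2.0 * uni() - 1.0)
        c = math.exp(c_log)
        acc["ridge"][1] += 1
        feasible = True
        for i in internal:
            ai = a[i] * c
            if ai <= lo[i] or ai >= hi[i]:
                feasible = False
                break
        if feasible:
            old_terms = sum(child_prior_terms(i) for i in internal)
            old_a = [a[i] for i in internal]
            for i in internal:
                a[i] *= c
            new_terms = sum(child_prior_terms(i) for i in internal)
            dprior_u = 0.0
            for j in range(1, at.n_nodes):
                z0 = (u[j] - mu_u) / sig
                z1 = (u[j] - c_log - mu_u) / sig
                dprior_u += -0.5 * (z1 * z1 - z0 * z0)
            delta = (new_terms - old_terms) + dprior_u + m * c_log
            if delta >= 0 or uni() < math.exp(delta):
                for j in range(1, at.n_nodes):
                    u[j] -= c_log
                    r[j] = math.exp(u[j])
                for j in range(1, at.n_nodes):
                    ll[j] = branch_ll(j)
                acc["ridge"][0] += 1
            else:
                for k, i in enumerate(internal):
                    a[i] = old_a[k]

        # -- adaptation (burn-in only) ----------------------------------
        if gen <= settings.burn_in and gen % settings.adapt_interval == 0:
            for key in ("age", "local", "rate", "scale", "ridge"):
                hits, trials = acc[key]
                if trials == 0:
                    continue
                rate = hits / trials
                f = math.exp(0.6 * (rate - 0.3))
                if key == "age":
                    for i in internal:
                        d_age[i] = min(max(d_age[i] * f, 1e-5), hi[0] - lo[0] + 1.0)
                elif key == "local":
                    local_mult = min(max(local_mult * f, 1e-2), 100.0)
                elif key == "rate":
                    d_rate = min(max(d_rate * f, 1e-4), 10.0)
                elif key == "scale":
                    d_scale = min(max(d_scale * f, 1e-4), 1.0)
                else:
                    d_ridge = min(max(d_ridge * f, 1e-4), 2.0)
            if gen < settings.burn_in:
                acc = {"age": [0, 0], "local": [0, 0], "rate": [0, 0], "scale": [0, 0], "ridge": [0, 0]}

        if gen % settings.sample_every == 0:
            S_ages[k_out] = [a[i] * U for i in internal]
            S_rates[k_out] = [r[j] for j in range(1, at.n_nodes)]
            S_gen[k_out] = gen
            S_lp[k_out] = log_post_full()
            k_out += 1

    rates_acc = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in acc.items()}
    warnings = []
    for k, v in rates_acc.items():
        if not (0.05 <= v <= 0.8):
            msg = f"{k}-move acceptance rate {v:.3f} outside [0.05, 0.8] after adaptation"
            warnings.append(msg)
            logger.warning(msg)
    return Chain(
        tree=at,
        generations=S_gen[:k_out],
        ages=S_ages[:k_out],
        rates=S_rates[:k_out],
        log_post=S_lp[:k_out],
        acceptance=rates_acc,
        settings=settings,
        warnings=warnings,
    )


def run_replicates(
    tree: PhylogramTree,
    calibrations: list[CalibrationConstraint],
    settings: McmcSettings | None = None,
) -> list[Chain]:
    """Independent replicate chains (seeds seed, seed+1, ...)."""
    settings = settings or McmcSettings()
    chains = []
    for k in range(settings.replicates):
        s = McmcSettings(**{**settings.__dict__, "seed": settings.seed + k})
        chains.append(run_mcmc(tree, calibrations, s))
    return chains


def _ess(x: np.ndarray) -> float:
    import arviz

    return float(arviz.ess(np.asarray(x)[None, :]))


def summarize_posterior(
    chains: Chain | list[Chain],
    burn_in: int | None = None,
    sample_every: int | None = None,
) -> PosteriorSummary:
    """Burned-in, thinned posterior summaries per internal node.

    With two or more chains, per-node median deltas across replicates
    are reported (the convergence criterion: rerun and compare). Nodes
    with ESS < 100 are flagged, not fatal.
    """
    if isinstance(chains, Chain):
        chains = [chains]
    settings = chains[0].settings
    burn_in = settings.burn_in if burn_in is None else burn_in
    thin = 1 if sample_every is None else max(1, sample_every // settings.sample_every)
    kept = []
    for ch in chains:
        mask = ch.generations > burn_in
        if not mask.any():
            raise ValueError("chain shorter than burn-in: nothing to summarise")
        kept.append(ch.ages[mask][::thin])
    pooled = np.vstack(kept)
    at = chains[0].tree
    rows, flags = [], []
    for k, i in enumerate(at.internal):
        col = pooled[:, k]
        ess = _ess(col) if col.size > 3 and col.std() > 0 else float(col.size)
        lo_ci, hi_ci = np.percentile(col, [2.5, 97.5])
        if ess < 100:
            flags.append(f"node index {int(i)}: ESS {ess:.0f} < 100")
        rows.append(
            {
                "node_index": int(i),
                "mean": float(col.mean()),
                "median": float(np.median(col)),
                "ci2.5": float(lo_ci),
                "ci97.5": float(hi_ci),
                "ess": ess,
            }
        )
    table = pd.DataFrame(rows)
    rep = None
    if len(kept) >= 2:
        med = np.array([np.median(k, axis=0) for k in kept])
        delta = med.max(axis=0) - med.min(axis=0)
        denom = np.maximum(med.mean(axis=0), 1e-12)
        rep = pd.DataFrame(
            {
                "node_index": [int(i) for i in at.internal],
                "median_delta": delta,
                "median_delta_rel": delta / denom,
            }
        )
    for f in flags:
        logger.warning("low effective sample size: %s", f)
    return PosteriorSummary(table=table, replicate_delta=rep, flags=flags)
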