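"""Ground-truthed synthetic data: trees, branch lengths, fossil registries.

The generator emulates the statistical structure the screening method
assumes: a dated species tree (birth-death), per-branch substitution
rates from a clock model (strict or independent lognormal), observed
branch lengths with Poisson substitution noise at a finite alignment
length, and a fossil registry in which a known fraction of records
carries misleading (inflated) ages. Ground-truth labels are written to
a separate truth table, never into the registry itself.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import FossilRecord, NodeAssignmentRules
from .trees import ArrayTree, Chronogram, NodeQuery, PhylogramTree

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedFossils",
    "simulate_tree",
    "simulate_fossils",
    "default_reference_nodes",
    "node_definitions",
]

_REGIONS = ["North America", "Europe", "Africa", "Asia", "Australia"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Defaults mirror a small family-level shark phylogeny: a ~200 MYA
    root, a mitochondrial-gene alignment of ~1 kb, a slow per-site rate
    (0.0029 substitutions/site/MY), and a registry of 100 fossils of
    which 20% carry ages inflated 2x — the planted-outlier condition
    the screening stage is meant to catch. Fossil age-range widths of
    5-15 MY mimic stage-level geologic resolution.
    """

    n_tips: int = 16
    birth_rate: float = 0.04  # per lineage per MY
    death_rate: float = 0.015
    root_age: float = 200.0  # MYA
    clock: str = "strict"  # "strict" | "lognormal"
    log_sd: float = 0.3  # lognormal clock spread (log scale)
    mean_rate: float = 0.0029  # substitutions/site/MY
    alignment_length: float = 1044  # sites; math.inf switches noise off
    n_fossils: int = 100
    misleading_fraction: float = 0.2
    misleading_multiplier: float = 2.0
    age_width: tuple = (5.0, 15.0)  # MY, uniform
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth rate must be > 0 and death rate >= 0")
        if not 0 <= self.misleading_fraction <= 1:
            raise ValueError("misleading_fraction must be in [0, 1]")
        if self.clock not in ("strict", "lognormal"):
            raise ValueError(f"unknown clock model {self.clock!r}")
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")


def _forward_birth_death(cfg: SimulationConfig, rng: np.random.Generator):
    """One forward pass; returns (nodes, present time) or None on extinction.

    nodes: dict id -> (parent id, event time); tips carry time = present.
    """
    b, d = cfg.birth_rate, cfg.death_rate
    total = b + d
    nodes = {0: (-1, 0.0), 1: (0, None), 2: (0, None)}
    active = [1, 2]
    nxt = 3
    t = 0.0
    while True:
        k = len(active)
        if k == 0:
            return None
        if k == cfg.n_tips:
            # freeze the present inside the waiting interval to the next event
            t += rng.exponential(1.0 / (total * k)) * rng.uniform()
            break
        t += rng.exponential(1.0 / (total * k))
        idx = rng.integers(k)
        lin = active[idx]
        if rng.uniform() < b / total:
            nodes[lin] = (nodes[lin][0], t)
            nodes[nxt] = (lin, None)
            nodes[nxt + 1] = (lin, None)
            active[idx] = nxt
            active.append(nxt + 1)
            nxt += 2
        else:
            nodes[lin] = (nodes[lin][0], t)  # extinct at t
            active.pop(idx)
    for lin in active:
        nodes[lin] = (nodes[lin][0], t)
    return nodes, t, set(active)


def _prune_to_extant(nodes, extant):
    """Keep lineages ancestral to extant tips; suppress unifurcations.

    Returns (children mapping, times, new root id).
    """
    keep = set()
    for tip in extant:
        i = tip
        while i != -1 and i not in keep:
            keep.add(i)
            i = nodes[i][0]
    children = {i: [] for i in keep}
    for i in keep:
        p = nodes[i][0]
        if p != -1:
            children[p].append(i)
    # drop pass-through nodes
    def resolve(i):
        while i not in extant and len(children[i]) == 1:
            i = children[i][0]
        return i

    root = resolve(0)
    out_children = {}

    def build(i):
        if i in extant:
            out_children[i] = []
            return
        kids = [resolve(c) for c in children[i]]
        out_children[i] = kids
        for c in kids:
            build(c)

    build(root)
    times = {i: nodes[i][1] for i in out_children}
    return out_children, times, root


def simulate_tree(config: SimulationConfig):
    """Simulate (truth chronogram, observed phylogram).

    Birth-death forward simulation conditioned on the tip count by
    rejection (all-extinct passes are resampled and counted), pruned to
    extant lineages, and rescaled so the extant MRCA sits at
    ``config.root_age``. Per-branch rates come from the clock model;
    observed branch lengths are Poisson(rate * duration * sites) / sites,
    or exactly rate * duration when the alignment length is infinite.
    """
    rng = np.random.default_rng(config.seed)
    retries = 0
    while True:
        out = _forward_birth_death(config, rng)
        if out is not None:
            nodes, present, extant = out
            children, times, root = _prune_to_extant(nodes, extant)
            if len([i for i in children if children[i]]) >= 2:
                break
        retries += 1
        if retries % 50 == 0:
            logger.info("birth-death rejection: %d resamples so far", retries)
    if retries:
        logger.debug("birth-death simulation used %d resamples", retries)

    scale = config.root_age / (present - times[root])
    # preorder arrays
    order = []
    stack = [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    pos = {i: k for k, i in enumerate(order)}
    n = len(order)
    parent = [-1] * n
    kids = [[] for _ in range(n)]
    ages = np.zeros(n)
    tip_counter = 0
    labels = [""] * n
    for i in order:
        k = pos[i]
        ages[k] = (present - times[i]) * scale
        for c in children[i]:
            parent[pos[c]] = k
            kids[k].append(pos[c])
        if not children[i]:
            tip_counter += 1
            labels[k] = f"t{tip_counter:02d}"
            ages[k] = 0.0

    durations = np.full(n, np.nan)
    durations[1:] = ages[np.array(parent[1:])] - ages[1:]

    B = n - 1
    if config.clock == "strict":
        rates = np.full(B, config.mean_rate)
    else:
        mu = math.log(config.mean_rate) - 0.5 * config.log_sd**2
        rates = rng.lognormal(mean=mu, sigma=config.log_sd, size=B)
    expected = rates * durations[1:]

    L = config.alignment_length
    if math.isinf(L):
        observed = expected.copy()
        L_int = 10**6  # nominal sites for downstream count scaling
    else:
        L_int = int(L)
        observed = rng.poisson(expected * L_int) / L_int

    rates_full = np.concatenate([[np.nan], rates])
    truth = Chronogram(
        tree=ArrayTree(parent, kids, labels, np.concatenate([[np.nan], durations[1:]])),
        ages=ages,
        rates=rates_full,
        metadata={"seed": config.seed, "retries": retries, "clock": config.clock},
    )
    obs_tree = ArrayTree(parent, kids, labels, np.concatenate([[0.0], observed]))
    observed_phylogram = PhylogramTree(tree=obs_tree, alignment_length=L_int)
    return truth, observed_phylogram


def node_definitions(chronogram: Chronogram) -> dict[str, NodeQuery]:
    """Stable MRCA-pair labels for every internal node.

    The root is node1; the rest follow in preorder. Each node is
    addressed by one tip from its first child clade and one from its
    last, so the labels survive newick round trips.
    """
    at = chronogram.tree
    defs = {}
    for k, i in enumerate(at.internal, start=1):
        first = at.tips_under(at.children[i][0])[0]
        last = at.tips_under(at.children[i][-1])[0]
        defs[f"node{k}"] = NodeQuery(at.labels[first], at.labels[last], f"node{k}")
    return defs


def default_reference_nodes(chronogram: Chronogram) -> list[NodeQuery]:
    """Three monitored reference nodes at distinct, resolvable time frames.

    Picks the internal nodes whose true ages are nearest 10%, 40% and
    100% of the root age, so a miscalibrated fossil distorts at least
    one of them. Very shallow nodes are deliberately avoided: a node
    whose subtending branches expect less than a handful of
    substitutions has an unidentifiable age and would only add noise to
    the screen.
    """
    defs = node_definitions(chronogram)
    at = chronogram.tree
    root_age = chronogram.root_age
    aged = sorted(defs.items(), key=lambda kv: chronogram.age_of(kv[1]))
    picked: list[NodeQuery] = []
    for frac in (0.1, 0.4, 1.0):
        target = frac * root_age
        for _, q in sorted(
            aged, key=lambda kv: abs(chronogram.age_of(kv[1]) - target)
        ):
            if all(mrca_key(at, q) != mrca_key(at, p) for p in picked):
                picked.append(q)
                break
    return picked[:3]


def mrca_key(at: ArrayTree, q: NodeQuery) -> int:
    return at.mrca_index(q.taxon_a, q.taxon_b)


@dataclass
class SimulatedFossils:
    """A synthetic registry plus everything needed to consume and audit it."""

    records: list[FossilRecord]
    truth: pd.DataFrame  # record_id, assigned_node, true_node_age, misleading
    node_defs: dict[str, NodeQuery]
    rules: NodeAssignmentRules = field(default_factory=NodeAssignmentRules)


def simulate_fossils(
    truth: Chronogram, config: SimulationConfig, seed: int | None = None
) -> SimulatedFossils:
    """Plant a fossil registry on a true chronogram.

    Informative fossils get a minimum age uniform on (0.5, 1.0) x the
    true age of their node and a coarse width of 5-15 MY; a configured
    fraction is misleading, with ages scaled by the misleading
    multiplier. Ground-truth labels live only in the returned truth
    table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    defs = node_definitions(truth)
    # fossils attach to family-level divergences: deep internal splits,
    # never the root and never shallow within-genus nodes, whose ages a
    # coarse (5-15 MY) fossil range could not meaningfully bound
    floor = 0.25 * truth.root_age
    eligible = [
        lab
        for lab in defs
        if lab != "node1" and truth.age_of(defs[lab]) >= floor
    ]
    if not eligible:  # degenerate topology: fall back to all non-root nodes
        eligible = [lab for lab in defs if lab != "node1"]
    n = config.n_fossils
    n_bad = int(round(config.misleading_fraction * n))
    bad = np.zeros(n, dtype=bool)
    bad[rng.permutation(n)[:n_bad]] = True

    records, rows = [], []
    fam = {lab: f"Family{lab[4:]}" for lab in eligible}
    for i in range(n):
        lab = eligible[rng.integers(len(eligible))]
        true_age = truth.age_of(defs[lab])
        lo = rng.uniform(0.5, 1.0) * true_age
        if bad[i]:
            lo *= config.misleading_multiplier
        width = rng.uniform(*config.age_width)
        hi = lo + width
        rec = FossilRecord(
            record_id=f"S{i:03d}",
            taxon=f"Sim. species {i}",
            family=fam[lab],
            genus=f"Genus{lab[4:]}",
            region=_REGIONS[rng.integers(len(_REGIONS))],
            geologic_age=f"{lo:.3f}–{hi:.3f} MYA",
            min_age=float(lo),
            max_age=float(hi),
            assigned_node=lab,
            source="synthetic",
        )
        records.append(rec)
        rows.append(
            {
                "record_id": rec.record_id,
                "assigned_node": lab,
                "true_node_age": true_age,
                "misleading": bool(bad[i]),
            }
        )
    rules = NodeAssignmentRules(family_to_node={fam[lab]: lab for lab in eligible})
    return SimulatedFossils(
        records=records,
        truth=pd.DataFrame(rows),
        node_defs=defs,
        rules=rules,
    )
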