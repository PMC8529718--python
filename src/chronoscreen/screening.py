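"""Per-fossil calibration screening.

The core procedure: every node-assigned fossil record is used, alone,
to date the tree (its resolved minimum and maximum age bound its
assigned node), and the resulting chronogram's ages at three monitored
reference nodes are recorded. A fossil is culled when its chronogram
puts any reference node outside that node's interquartile range over
the whole run population (bounds inclusive: a fossil exactly at Q1 or
Q3 survives). Fossils at weakly supported nodes — three or fewer
surviving fossils — are then removed, and each remaining node's
calibration is the oldest surviving minimum age at that node.

Culling is a single pass (quartiles are computed once over all
successful runs, then applied), is order-independent in the fossil
input, and uses only the IQR and node-support rules: any expected-age
intervals attached to the reference nodes are echoed into the report
for context but never influence survivor flags.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pl import CalibrationConstraint, SmoothingConfig, estimate_chronogram
from .registry import UNASSIGNED, FossilRecord
from .trees import NodeQuery, PhylogramTree, mrca

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceNodeSet",
    "ScreeningReport",
    "ScreeningError",
    "iqr_bounds",
    "iqr_survivor_flags",
    "run_per_fossil_screen",
    "apply_node_support_filter",
    "select_calibrations",
    "load_node_definitions",
    "load_reference_nodes",
]

REASON_RUN_FAILED = "RUN_FAILED"
REASON_LOW_SUPPORT = "LOW_NODE_SUPPORT"


def _reason_outlier(label: str) -> str:
    return f"OUTLIER_AT_{label}"


class ScreeningError(RuntimeError):
    """Screening could not produce a usable report."""


@dataclass
class ReferenceNodeSet:
    """Exactly three monitored reference nodes.

    ``expected`` optionally maps a node label to an (lo, hi) MYA
    interval for reporting only; it must never affect exclusion.
    """

    queries: list[NodeQuery]
    expected: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.queries) != 3:
            raise ValueError("a reference node set holds exactly three nodes")
        labels = [q.label or f"ref{i}" for i, q in enumerate(self.queries)]
        self.queries = [replace(q, label=lab) for q, lab in zip(self.queries, labels)]

    @property
    def labels(self) -> list[str]:
        return [q.label for q in self.queries]


@dataclass
class ScreeningReport:
    """Everything the screen decided and why.

    per_fossil has one row per attempted run: status, the three
    reference-node ages, the survivor flag and semicolon-joined reason
    codes. ``iqr`` maps reference label -> (Q1, Q3); ``selected`` are
    the minimum-age calibrations chosen per node; ``summary`` holds the
    per-reference-node population means/medians before and after
    culling.
    """

    per_fossil: pd.DataFrame
    iqr: dict[str, tuple[float, float]]
    selected: list[CalibrationConstraint]
    summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def survivors(self) -> pd.DataFrame:
        return self.per_fossil[self.per_fossil["survivor"]]


def iqr_bounds(ages, method: str = "linear") -> tuple[float, float]:
    """(Q1, Q3) of a population of node ages.

    ``method="linear"`` interpolates between order statistics
    (numpy's default quantile rule); ``method="tukey"`` uses Tukey
    hinges (medians of the lower/upper halves). Needs at least four
    finite values — with fewer, quartiles are too unstable to cull on,
    and the caller should skip culling instead.
    """
    a = np.asarray(ages, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 4:
        raise ValueError(
            f"need >= 4 finite ages to form interquartile bounds (got {a.size}); "
            "skip culling for this population"
        )
    if method == "linear":
        q1, q3 = np.quantile(a, [0.25, 0.75])
    elif method == "tukey":
        s = np.sort(a)
        n = s.size
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    return float(q1), float(q3)


def _fossil_seed(base_seed: int, record_id: str) -> int:
    """Stable per-fossil seed: independent of input order, < 2**31."""
    return (int(base_seed) * 2654435761 + zlib.crc32(record_id.encode())) % (2**31 - 1)


def iqr_survivor_flags(
    df: pd.DataFrame, labels: list[str], method: str = "linear"
) -> tuple[pd.Series, dict, pd.Series]:
    """Single-pass IQR cull over a per-fossil age table.

    ``df`` needs a ``status`` column and one ``age_<label>`` column per
    reference node. Quartiles are computed once over all successful
    runs; a run survives iff its age lies inside [Q1, Q3] at every
    reference node — bounds inclusive, so a run exactly at a quartile
    is kept. Returns (survivor flags, {label: (Q1, Q3)}, reason codes).
    """
    ok = df["status"] == "ok"
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[~ok] = REASON_RUN_FAILED
    iqr: dict[str, tuple[float, float]] = {}
    flags = ok.copy()
    for lab in labels:
        q1, q3 = iqr_bounds(df.loc[ok, f"age_{lab}"], method=method)
        iqr[lab] = (q1, q3)
        out = ok & ((df[f"age_{lab}"] < q1) | (df[f"age_{lab}"] > q3))
        reasons[out] = reasons[out].where(reasons[out] == "", reasons[out] + ";") + _reason_outlier(lab)
        flags &= ~out
    return flags, iqr, reasons


def run_per_fossil_screen(
    tree: PhylogramTree,
    fossils: list[FossilRecord],
    node_defs: dict[str, NodeQuery],
    refs: ReferenceNodeSet,
    pl_config: SmoothingConfig | None = None,
    quantile_method: str = "linear",
    min_node_support: int = 4,
) -> ScreeningReport:
    """Run one penalized-likelihood dating per fossil and screen.

    Every fossil must be node-assigned and every reference node
    resolvable in the tree. Failed runs are recorded with a reason,
    excluded from quantile computation, and never counted as
    survivors. Raises :class:`ScreeningError` if no run succeeds.
    """
    pl_config = pl_config or SmoothingConfig(restarts=2)
    for q in refs.queries:
        mrca(tree, q)  # raises naming the missing taxon
    unassigned = [f.record_id for f in fossils if f.assigned_node == UNASSIGNED]
    if unassigned:
        raise ScreeningError(
            f"{len(unassigned)} fossil(s) are unassigned (e.g. {unassigned[:3]}); "
            "assign or drop them before screening"
        )
    missing = sorted({f.assigned_node for f in fossils} - set(node_defs))
    if missing:
        raise ScreeningError(f"fossils assigned to undefined node(s): {missing}")

    labels = refs.labels
    rows = []
    for rec in sorted(fossils, key=lambda r: r.record_id):
        row = {
            "record_id": rec.record_id,
            "assigned_node": rec.assigned_node,
            "min_age": rec.min_age,
            "max_age": rec.max_age,
            "status": "ok",
            "reasons": "",
        }
        try:
            cons = [
                CalibrationConstraint(
                    node_defs[rec.assigned_node], rec.min_age, rec.max_age
                )
            ]
            cfg = replace(pl_config, seed=_fossil_seed(pl_config.seed, rec.record_id))
            chrono = estimate_chronogram(tree, cons, cfg)
            if not chrono.metadata["converged"]:
                raise RuntimeError("optimizer did not converge")
            for q in refs.queries:
                row[f"age_{q.label}"] = chrono.age_of(q)
        except Exception as err:  # failed runs are data, not crashes
            logger.warning("PL run failed for fossil %s: %s", rec.record_id, err)
            row["status"] = "failed"
            row["reasons"] = REASON_RUN_FAILED
            for lab in labels:
                row[f"age_{lab}"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["status"] == "ok"
    if not ok.any():
        diag = df[["record_id", "status", "reasons"]].to_dict("records")
        raise ScreeningError(f"all {len(df)} per-fossil runs failed: {diag[:10]}")

    # single-pass IQR culling over the full successful-run population
    iqr: dict[str, tuple[float, float]] = {}
    try:
        culled, iqr, reasons = iqr_survivor_flags(df, labels, method=quantile_method)
        df["reasons"] = reasons  # covers RUN_FAILED and per-node outlier codes
        culling_applied = True
    except ValueError as err:
        logger.warning("IQR culling skipped: %s", err)
        culled = ok.copy()
        culling_applied = False
    df["survivor"] = culled

    # node-support filter AFTER the IQR cull
    support = df.loc[df["survivor"], "assigned_node"].value_counts()
    weak = set(support[support < min_node_support].index)
    low = df["survivor"] & df["assigned_node"].isin(weak)
    df.loc[low, "reasons"] = df.loc[low, "reasons"].where(
        df.loc[low, "reasons"] == "", df.loc[low, "reasons"] + ";"
    ) + REASON_LOW_SUPPORT
    df.loc[low, "survivor"] = False

    surviving_records = [
        rec for rec in fossils
        if rec.record_id in set(df.loc[df["survivor"], "record_id"])
    ]
    selected = (
        select_calibrations(surviving_records, node_defs) if surviving_records else []
    )
    if not surviving_records:
        logger.warning("no fossils survived screening; no calibrations selected")

    srows = []
    for lab in labels:
        before = df.loc[ok, f"age_{lab}"]
        after = df.loc[df["survivor"], f"age_{lab}"]
        srows.append(
            {
                "reference_node": lab,
                "n_before": int(before.size),
                "mean_before": float(before.mean()),
                "median_before": float(before.median()),
                "n_after": int(after.size),
                "mean_after": float(after.mean()) if after.size else np.nan,
                "median_after": float(after.median()) if after.size else np.nan,
                "expected_min": refs.expected.get(lab, (np.nan, np.nan))[0],
                "expected_max": refs.expected.get(lab, (np.nan, np.nan))[1],
            }
        )
    summary = pd.DataFrame(srows)
    meta = {
        "n_fossils": len(fossils),
        "n_attempted": len(df),
        "n_failed": int((~ok).sum()),
        "n_survivors": int(df["survivor"].sum()),
        "quantile_method": quantile_method,
        "min_node_support": min_node_support,
        "culling_applied": culling_applied,
        "lambda": pl_config.lam,
        "seed": pl_config.seed,
    }
    if len(df) == 1:
        logger.warning(
            "single-fossil population: interquartile bounds are undefined, "
            "no culling was possible"
        )
    return ScreeningReport(
        per_fossil=df, iqr=iqr, selected=selected, summary=summary, metadata=meta
    )


def apply_node_support_filter(
    survivors: list[FossilRecord], min_count: int = 4
) -> tuple[list[FossilRecord], list[FossilRecord]]:
    """Drop fossils at nodes with fewer than ``min_count`` survivors.

    The default removes nodes with three or fewer fossils: a lone
    handful of records at a node gives no internal consistency check.
    Returns (kept, removed).
    """
    counts: dict[str, int] = {}
    for r in survivors:
        counts[r.assigned_node] = counts.get(r.assigned_node, 0) + 1
    kept, removed = [], []
    for r in survivors:
        (kept if counts[r.assigned_node] >= min_count else removed).append(r)
    for node in sorted({r.assigned_node for r in removed}):
        n = counts[node]
        logger.info(
            "node-support filter removed %d fossil(s) at %s (%s)",
            n, node, REASON_LOW_SUPPORT,
        )
    return kept, removed


def select_calibrations(
    survivors: list[FossilRecord], node_defs: dict[str, NodeQuery]
) -> list[CalibrationConstraint]:
    """Oldest surviving minimum age per node, as min-age calibrations."""
    if not survivors:
        raise ValueError("cannot select calibrations from an empty survivor set")
    best: dict[str, float] = {}
    for r in survivors:
        best[r.assigned_node] = max(best.get(r.assigned_node, 0.0), r.min_age)
    return [
        CalibrationConstraint(node=node_defs[node], min_age=age)
        for node, age in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# config-table loaders


def load_node_definitions(path) -> dict[str, NodeQuery]:
    """CSV (node_label, taxonA, taxonB) -> NodeQuery mapping."""
    df = pd.read_csv(path, dtype=str)
    need = {"node_label", "taxonA", "taxonB"}
    if not need <= set(df.columns):
        raise ValueError(f"node-definition table needs columns {sorted(need)}")
    return {
        row.node_label: NodeQuery(row.taxonA, row.taxonB, row.node_label)
        for row in df.itertuples()
    }


def load_reference_nodes(path) -> ReferenceNodeSet:
    """CSV (node_label, taxonA, taxonB[, expected_min, expected_max])."""
    df = pd.read_csv(path)
    queries = [
        NodeQuery(str(r.taxonA), str(r.taxonB), str(r.node_label))
        for r in df.itertuples()
    ]
    expected = {}
    if {"expected_min", "expected_max"} <= set(df.columns):
        for r in df.itertuples():
            if pd.notna(r.expected_min) and pd.notna(r.expected_max):
                expected[str(r.node_label)] = (float(r.expected_min), float(r.expected_max))
    return ReferenceNodeSet(queries=queries, expected=expected)
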