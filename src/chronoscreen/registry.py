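"""Fossil occurrence registry: loading, age resolution, node assignment.

A registry is a CSV of fossil occurrences, one row per unique
(locality, age, species) combination. Each record carries a geologic
age — either a chronostratigraphic unit name ("Cenomanian",
"Campanian–Maastrichtian") or an explicit numeric range ("66–72 MYA") —
which is resolved to a coarse interval in MYA against a
chronostratigraphic lookup table. Coarse ranges are deliberate: shark
teeth often accumulate in lag deposits that mix ages, so narrow ranges
would overstate precision.

Each record is then assigned to a calibratable node of the reference
tree from its taxonomy: a family→node map, genus-level overrides that
beat the family rule (e.g. a genus whose placement contradicts its
described family), and an exclusion list (extinct side-lineages, or
records with no family given) that beats both.
"""

from __future__ import annotations

import csv
import difflib
import importlib.resources
import logging
import re
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

REGISTRY_COLUMNS = [
    "record_id",
    "taxon",
    "family",
    "genus",
    "region",
    "geologic_age",
    "min_age",
    "max_age",
    "assigned_node",
    "source",
    "suspect",
]
REQUIRED_COLUMNS = ["record_id", "taxon", "family", "genus", "region", "geologic_age"]

_TRUTHY = {"true", "1", "yes", "y", "t"}

# numeric range like "66–72 MYA", "66 - 72", "70.6—83.5 Ma"
_NUMERIC_RANGE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*[–—-]\s*(\d+(?:\.\d+)?)\s*(?:mya?|ma)?\s*$",
    re.IGNORECASE,
)


class RegistryError(ValueError):
    """Structured registry-level failure (e.g. a missing column)."""


class AgeResolutionError(ValueError):
    """Unknown chronostratigraphic unit; carries nearest-match candidates."""

    def __init__(self, unit: str, candidates: list[str]):
        self.unit = unit
        self.candidates = candidates
        hint = f" (did you mean: {', '.join(candidates)}?)" if candidates else ""
        super().__init__(f"unknown chronostratigraphic unit {unit!r}{hint}")


@dataclass
class FossilRecord:
    """One fossil occurrence."""

    record_id: str
    taxon: str
    family: str = ""
    genus: str = ""
    region: str = ""
    geologic_age: str = ""
    min_age: float = float("nan")
    max_age: float = float("nan")
    assigned_node: str = UNASSIGNED
    source: str = ""
    suspect: bool = False

    def age_resolved(self) -> bool:
        return (
            self.min_age == self.min_age
            and self.max_age == self.max_age
            and 0 < self.min_age < self.max_age
        )


def _norm(name: str) -> str:
    return " ".join(name.strip().split()).casefold()


class GeoTimeScale:
    """Chronostratigraphic unit name → (min MYA, max MYA) lookup.

    Keys are case-insensitive and whitespace-normalised. The package
    bundles one explicit table (:meth:`builtin`); a user-supplied table
    with identical columns can replace it, since published conversions
    differ between time-scale editions.
    """

    def __init__(self, mapping: dict[str, tuple[float, float]], version: str = "custom"):
        self.version = version
        self._map: dict[str, tuple[float, float]] = {}
        for name, (lo, hi) in mapping.items():
            lo, hi = float(lo), float(hi)
            if not lo < hi:
                raise RegistryError(
                    f"time-scale unit {name!r} has min {lo} >= max {hi}"
                )
            self._map[_norm(name)] = (lo, hi)

    def __contains__(self, unit: str) -> bool:
        return _norm(unit) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, unit: str) -> tuple[float, float]:
        key = _norm(unit)
        if key not in self._map:
            cands = difflib.get_close_matches(key, list(self._map), n=3, cutoff=0.6)
            raise AgeResolutionError(unit, cands)
        return self._map[key]

    @classmethod
    def from_csv(cls, path, version: str | None = None) -> "GeoTimeScale":
        mapping = {}
        label = version
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    m = re.search(r"version:\s*(\S+)", line)
                    if m and label is None:
                        label = m.group(1)
                    continue
                parts = next(csv.reader([line]))
                if header is None:
                    header = parts
                    continue
                row = dict(zip(header, parts))
                mapping[row["unit"]] = (float(row["min_mya"]), float(row["max_mya"]))
        return cls(mapping, version=label or "custom")

    @classmethod
    def builtin(cls) -> "GeoTimeScale":
        ref = importlib.resources.files("chronoscreen.data") / "timescale_builtin.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)


def resolve_age_range(geologic_age: str, gts: GeoTimeScale) -> tuple[float, float]:
    """Resolve an age string to a (min MYA, max MYA) interval.

    Accepts an explicit numeric range (passed through, idempotent), a
    single unit name, or a hyphen/en-dash separated span of unit names;
    a span resolves to the union of the named intervals.
    """
    s = geologic_age.strip()
    if not s:
        raise AgeResolutionError(geologic_age, [])
    m = _NUMERIC_RANGE.match(s)
    if m:
        a, b = float(m.group(1)), float(m.group(2))
        return (min(a, b), max(a, b))
    if s in gts:
        return gts.lookup(s)
    parts = [p for p in re.split(r"\s*[–—-]\s*", s) if p]
    if len(parts) > 1:
        try:
            intervals = [gts.lookup(p) for p in parts]
        except AgeResolutionError:
            # fall through to report the whole string with candidates
            return gts.lookup(s)
        return (min(lo for lo, _ in intervals), max(hi for _, hi in intervals))
    return gts.lookup(s)  # raises with nearest-match candidates


@dataclass
class NodeAssignmentRules:
    """Taxonomy → tree-node assignment policy.

    Precedence: exclusion list (genus or family) > genus override >
    family map. Records with an empty family are always unassigned:
    family-level tooth morphology is what makes the classification
    trustworthy in the first place.
    """

    family_to_node: dict[str, str] = field(default_factory=dict)
    genus_overrides: dict[str, str] = field(default_factory=dict)
    exclude: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.family_to_node = {_norm(k): v for k, v in self.family_to_node.items()}
        self.genus_overrides = {_norm(k): v for k, v in self.genus_overrides.items()}
        self.exclude = {_norm(x) for x in self.exclude}

    def mapped_nodes(self) -> set[str]:
        return set(self.family_to_node.values()) | set(self.genus_overrides.values())

    def validate_against(self, node_labels) -> None:
        missing = self.mapped_nodes() - set(node_labels)
        if missing:
            raise RegistryError(
                f"assignment rules map to undefined nodes: {sorted(missing)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "NodeAssignmentRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            family_to_node=raw.get("family_to_node", {}) or {},
            genus_overrides=raw.get("genus_overrides", {}) or {},
            exclude=set(raw.get("exclude", []) or []),
        )


def assign_node(record: FossilRecord, rules: NodeAssignmentRules) -> str:
    """Node label for a record, or UNASSIGNED.

    UNASSIGNED is a valid outcome, not an error: records that cannot be
    tied to a divergence are kept for the biogeographic summary.
    """
    fam, gen = _norm(record.family), _norm(record.genus)
    if not fam or fam in rules.exclude or (gen and gen in rules.exclude):
        return UNASSIGNED
    if gen and gen in rules.genus_overrides:
        return rules.genus_overrides[gen]
    if fam in rules.family_to_node:
        return rules.family_to_node[fam]
    logger.warning(
        "family %r (record %s) has no node-assignment rule; left unassigned",
        record.family,
        record.record_id,
    )
    return UNASSIGNED


@dataclass
class LoadResult:
    """Outcome of loading a registry.

    records = assigned + unassigned (all age-resolved); quarantined
    rows had unresolvable or degenerate ages and are excluded from all
    downstream computation but never silently dropped.
    """

    records: list[FossilRecord]
    quarantined: list[tuple[FossilRecord, str]]
    timescale_version: str

    @property
    def n_assigned(self) -> int:
        return sum(1 for r in self.records if r.assigned_node != UNASSIGNED)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for r in self.records if r.assigned_node == UNASSIGNED)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)

    def assigned(self) -> list[FossilRecord]:
        return [r for r in self.records if r.assigned_node != UNASSIGNED]

    def counts(self) -> dict:
        return {
            "assigned": self.n_assigned,
            "unassigned": self.n_unassigned,
            "quarantined": self.n_quarantined,
        }


def load_registry(path, rules: NodeAssignmentRules, gts: GeoTimeScale) -> LoadResult:
    """Load a registry CSV, resolve ages, and assign nodes.

    min_age/max_age columns, when present and populated, take priority
    over the geologic_age string (explicit beats derived). A row whose
    age cannot be resolved to a valid 0 < min < max interval is
    quarantined with a reason, so one bad row cannot kill a long run.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"registry is missing required column(s): {missing}")
    seen = set()
    records: list[FossilRecord] = []
    quarantined: list[tuple[FossilRecord, str]] = []
    for _, row in df.iterrows():
        rec = FossilRecord(
            record_id=row["record_id"].strip(),
            taxon=row["taxon"].strip(),
            family=row["family"].strip(),
            genus=row["genus"].strip(),
            region=row["region"].strip(),
            geologic_age=row["geologic_age"].strip(),
            source=row.get("source", "").strip() if "source" in df.columns else "",
            suspect=(
                row.get("suspect", "").strip().casefold() in _TRUTHY
                if "suspect" in df.columns
                else False
            ),
        )
        if rec.record_id in seen:
            raise RegistryError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        # explicit numeric columns win over the geologic-age string
        explicit = (
            "min_age" in df.columns
            and "max_age" in df.columns
            and row["min_age"].strip() != ""
            and row["max_age"].strip() != ""
        )
        try:
            if explicit:
                rec.min_age = float(row["min_age"])
                rec.max_age = float(row["max_age"])
            else:
                rec.min_age, rec.max_age = resolve_age_range(rec.geologic_age, gts)
        except (AgeResolutionError, ValueError) as err:
            quarantined.append((rec, f"age resolution failed: {err}"))
            continue
        if not rec.age_resolved():
            quarantined.append(
                (rec, f"degenerate age interval ({rec.min_age}, {rec.max_age})")
            )
            continue
        rec.assigned_node = assign_node(rec, rules)
        records.append(rec)
    res = LoadResult(records=records, quarantined=quarantined, timescale_version=gts.version)
    logger.info(
        "registry %s: %d assigned, %d unassigned, %d quarantined (time scale %s)",
        path,
        res.n_assigned,
        res.n_unassigned,
        res.n_quarantined,
        gts.version,
    )
    return res


def read_resolved_registry(path) -> list[FossilRecord]:
    """Read a registry whose ages and node assignments are already populated.

    The strict counterpart of :func:`write_registry`: no time-scale
    lookup, no rules — every row must carry usable min_age/max_age.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("record_id", "min_age", "max_age") if c not in df.columns]
    if missing:
        raise RegistryError(f"resolved registry is missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            FossilRecord(
                record_id=row["record_id"],
                taxon=row.get("taxon", ""),
                family=row.get("family", ""),
                genus=row.get("genus", ""),
                region=row.get("region", ""),
                geologic_age=row.get("geologic_age", ""),
                min_age=float(row["min_age"]),
                max_age=float(row["max_age"]),
                assigned_node=row.get("assigned_node", UNASSIGNED) or UNASSIGNED,
                source=row.get("source", ""),
                suspect=row.get("suspect", "").casefold() in _TRUTHY,
            )
        )
    return out


def write_registry(records: list[FossilRecord], path) -> None:
    """Write records with all derived columns populated (round-trips)."""
    rows = []
    for r in records:
        d = asdict(r)
        d["suspect"] = "true" if r.suspect else "false"
        rows.append(d)
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, index=False)


def records_to_frame(records: list[FossilRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=REGISTRY_COLUMNS)
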