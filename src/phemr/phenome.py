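"""Phenome construction.

Two representations of the diagnosis phenome are built here: (i) phecode
case/control sets, with hierarchical rollup of dotted phecodes and
exclusion-range removal of overlapping disease states from control pools;
(ii) the ICD-10 classification tree (chapter → block → 3-character →
4-character) with per-node case indicator vectors, consumed by the
tree-structured Bayesian scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    DiagnosisRecord,
    PhecodeMapEntry,
    ValidationError,
    normalize_code,
    read_hierarchy,
    read_phecode_map,
)

logger = logging.getLogger(__name__)


def packaged_map() -> list[PhecodeMapEntry]:
    """The mini phecode↔ICD map shipped with the package."""
    with resources.as_file(resources.files("phemr") / "data" / "phecode_map.csv") as p:
        return read_phecode_map(p)


def packaged_hierarchy() -> list[tuple[str, str]]:
    """The mini ICD-10 hierarchy edge list shipped with the package."""
    with resources.as_file(resources.files("phemr") / "data" / "icd10_hierarchy.tsv") as p:
        return read_hierarchy(p)


# ---------------------------------------------------------------------------
# phecode assignment
# ---------------------------------------------------------------------------


def phecode_ancestors(phecode: str) -> list[str]:
    """Dotted ancestors of a phecode, most specific first (411.2 → [411])."""
    out = []
    if "." in phecode:
        integer, decimals = phecode.split(".")
        for k in range(len(decimals) - 1, 0, -1):
            out.append(f"{integer}.{decimals[:k]}")
        out.append(integer)
    return out


def map_to_phecodes(
    diagnoses: Sequence[DiagnosisRecord],
    map_entries: Sequence[PhecodeMapEntry],
) -> pd.DataFrame:
    """Assign phecodes to persons by longest-prefix ICD match plus rollup.

    Each diagnosis code is matched against the map patterns of its coding
    system by longest normalized prefix; the matched phecode and all its
    dotted ancestors are assigned.  Returns the unique (person_id,
    phecode) pairs; unmapped codes are counted and logged.
    """
    patterns: dict[str, dict[str, str]] = {"ICD9": {}, "ICD10": {}}
    for e in map_entries:
        patterns[e.system][e.code_pattern] = e.phecode
    pairs: set[tuple[str, str]] = set()
    unmapped: dict[str, int] = {}
    for rec in diagnoses:
        table = patterns.get(rec.system, {})
        phecode = None
        for k in range(len(rec.code), 0, -1):
            phecode = table.get(rec.code[:k])
            if phecode is not None:
                break
        if phecode is None:
            unmapped[rec.code] = unmapped.get(rec.code, 0) + 1
            continue
        pairs.add((rec.person_id, phecode))
        for anc in phecode_ancestors(phecode):
            pairs.add((rec.person_id, anc))
    if unmapped:
        logger.warning(
            "map_to_phecodes: %d episodes over %d distinct codes unmapped",
            sum(unmapped.values()), len(unmapped),
        )
    df = pd.DataFrame(sorted(pairs), columns=["person_id", "phecode"])
    df.attrs["n_unmapped_episodes"] = sum(unmapped.values())
    df.attrs["unmapped_codes"] = sorted(unmapped)
    return df


# ---------------------------------------------------------------------------
# case/control sets
# ---------------------------------------------------------------------------


@dataclass
class CaseControlSet:
    phecode: str
    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.control_ids):
            raise ValidationError(f"{self.phecode}: cases and controls overlap")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


@dataclass(frozen=True)
class FilteredOut:
    """Marker for a phecode excluded from analysis (too few cases)."""

    phecode: str
    n_cases: int
    reason: str = "below-min-cases"


def _exclusion_ranges(
    map_entries: Sequence[PhecodeMapEntry],
) -> dict[str, list[tuple[float, float]]]:
    ranges: dict[str, list[tuple[float, float]]] = {}
    for e in map_entries:
        if e.exclusion_range is not None:
            lst = ranges.setdefault(e.phecode, [])
            if e.exclusion_range not in lst:
                lst.append(e.exclusion_range)
    return ranges


def build_case_control(
    phecode: str,
    assignments: pd.DataFrame,
    map_entries: Sequence[PhecodeMapEntry],
    all_person_ids: Sequence[str],
    min_cases: int = 20,
) -> CaseControlSet | FilteredOut:
    """Case/control set for one phecode.

    Cases are the persons assigned the phecode.  Controls are all other
    persons with no assignment inside the phecode's exclusion range
    (similar or overlapping disease states never enter the control pool).
    Sets with fewer than ``min_cases`` cases are returned as
    :class:`FilteredOut` markers.
    """
    known = {e.phecode for e in map_entries}
    known.update(a for p in known.copy() for a in phecode_ancestors(p))
    if phecode not in known:
        raise ValidationError(f"phecode {phecode} absent from map")
    by_phecode = assignments.groupby("phecode")["person_id"]
    cases = set(by_phecode.get_group(phecode)) if phecode in by_phecode.groups else set()
    if len(cases) < min_cases:
        return FilteredOut(phecode, len(cases))
    ranges = _exclusion_ranges(map_entries).get(phecode, [])
    # direct rollup ancestors inherit the union of their descendants' ranges
    if not ranges:
        for e in map_entries:
            if phecode in phecode_ancestors(e.phecode) and e.exclusion_range is not None:
                if e.exclusion_range not in ranges:
                    ranges.append(e.exclusion_range)
    excluded: set[str] = set()
    if ranges:
        assigned_codes = assignments["phecode"].unique()
        in_range = [
            c for c in assigned_codes
            if any(lo <= float(c) <= hi for lo, hi in ranges)
        ]
        for c in in_range:
            excluded.update(by_phecode.get_group(c))
    controls = [p for p in all_person_ids if p not in cases and p not in excluded]
    return CaseControlSet(phecode, sorted(cases), controls)


def build_all_case_controls(
    assignments: pd.DataFrame,
    map_entries: Sequence[PhecodeMapEntry],
    all_person_ids: Sequence[str],
    min_cases: int = 20,
) -> tuple[dict[str, CaseControlSet], list[FilteredOut]]:
    """Case/control sets for every assigned phecode, plus the filtered list."""
    kept: dict[str, CaseControlSet] = {}
    filtered: list[FilteredOut] = []
    for phecode in sorted(assignments["phecode"].unique()):
        ccs = build_case_control(phecode, assignments, map_entries, all_person_ids, min_cases)
        if isinstance(ccs, FilteredOut):
            filtered.append(ccs)
        else:
            kept[phecode] = ccs
    return kept, filtered


# ---------------------------------------------------------------------------
# ICD-10 tree
# ---------------------------------------------------------------------------


ROOT = "ROOT"


@dataclass
class PhenoTree:
    """Rooted ICD-10 classification tree over the observed codes.

    ``graph`` is a directed tree (edges parent → child).  After
    :func:`propagate_cases`, ``indicators[node]`` is a boolean vector over
    ``person_ids`` marking the cases at that node.
    """

    graph: nx.DiGraph
    root: str = ROOT
    person_ids: list[str] = field(default_factory=list)
    indicators: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def parent(self, node: str) -> Optional[str]:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def children(self, node: str) -> list[str]:
        return list(self.graph.successors(node))

    def leaves(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def n_cases(self, node: str) -> int:
        return int(self.indicators[node].sum())


def _display_code(normalized: str) -> str:
    """I210 → I21.0; 3-character codes unchanged."""
    return normalized if len(normalized) <= 3 else f"{normalized[:3]}.{normalized[3:]}"


def build_icd_tree(
    observed_codes: Iterable[str],
    hierarchy_edges: Sequence[tuple[str, str]],
) -> PhenoTree:
    """Tree over the observed ICD-10 codes plus all their ancestors.

    ``hierarchy_edges`` must provide the chapter/block ancestry of every
    observed 3-character stem; 4-character codes hang off their stem and
    are the most specific level represented.
    """
    parent_of = {child: parent for parent, child in hierarchy_edges}
    g = nx.DiGraph()
    g.add_node(ROOT)
    for code in sorted({normalize_code(c) for c in observed_codes}):
        stem = code[:3]
        if stem not in parent_of:
            raise ValidationError(f"code {code} has no hierarchy entry for stem {stem}")
        node = _display_code(code[:4])  # depth capped at 4-character codes
        chain = [node] if node != stem else []
        chain.append(stem)
        up = stem
        while up != ROOT:
            parent = parent_of.get(up)
            if parent is None:
                raise ValidationError(f"hierarchy is missing an ancestor of {up}")
            chain.append(parent)
            up = parent
        for child, parent in zip(chain[:-1], chain[1:]):
            g.add_edge(parent, child)
    if not nx.is_arborescence(g):
        raise ValidationError("hierarchy edges do not form a rooted tree")
    return PhenoTree(graph=g)


def propagate_cases(
    tree: PhenoTree, diagnoses: Sequence[DiagnosisRecord],
    person_ids: Sequence[str],
) -> PhenoTree:
    """Fill per-node case indicators: a person is a case at a node iff
    they carry any observed code at or below it."""
    idx = pd.Index(person_ids)
    n = len(idx)
    indicators = {node: np.zeros(n, dtype=bool) for node in tree.graph.nodes}
    for rec in diagnoses:
        if rec.system != "ICD10":
            continue
        node = _display_code(normalize_code(rec.code)[:4])
        if node not in indicators and node[:3] in indicators:
            node = node[:3]
        if node not in indicators:
            continue
        pos = idx.get_loc(rec.person_id)
        indicators[node][pos] = True
    for node in reversed(list(nx.topological_sort(tree.graph))):
        for child in tree.graph.successors(node):
            indicators[node] |= indicators[child]
    tree.person_ids = list(person_ids)
    tree.indicators = indicators
    return tree
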