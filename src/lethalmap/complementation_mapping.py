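"""Interpretation of lethality, deficiency, knock-out and allelism crosses.

Every cross in the screen is scored by wing phenotype: curly-winged offspring
carry the CyO balancer, straight-winged offspring are balancer-free. In a
deficiency cross, straight-winged survivors are wild/Df trans-heterozygotes,
so a single straight fly proves the wild chromosome's lethal lies outside the
deleted interval (complementation), while zero straight among a sufficient
number of curly flies maps a lethal inside it. Allelism crosses between two
lethal lines follow the same logic: only balanced offspring means the two
chromosomes carry lethal lesions in the same functional unit.

Allelic sets are connected components of the graph whose edges are
failure-to-complement results. Complementation can be transcript-specific,
so the raw graph is preserved and intransitive triads (A~B, B~C allelic but
A-C tested and complementing) are surfaced rather than silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CrossResult",
    "MappingCall",
    "DeficiencyPanel",
    "AllelismGraph",
    "AllelicSet",
    "call_line_lethality",
    "call_deficiency_mapping",
    "call_deficiency_mapping_table",
    "distinct_regions_per_line",
    "multiplicity_histogram",
    "build_allelism_graph",
    "allelic_sets_from_graph",
    "allelic_set_frequency",
]

#: Minimum curly-winged offspring required before a 0-straight cross counts
#: as a mapped/lethal call (guards against undersampled crosses).
MIN_CURLY = 35

#: Maximum wildtype (straight-winged) fraction compatible with lethality:
#: 10% of the expected one-third straight class among survivors.
WILDTYPE_MAX_FRACTION = 0.033


@dataclass(frozen=True)
class CrossResult:
    """Offspring counts for one cross."""

    line_id: str
    tester_id: str
    tester_kind: str  # balancer_sibling | deficiency | knockout | allelism
    curly_n: int
    straight_n: int

    def __post_init__(self) -> None:
        if self.curly_n < 0 or self.straight_n < 0:
            raise ValueError("offspring counts must be >= 0")


@dataclass(frozen=True)
class MappingCall:
    line_id: str
    tester_id: str
    call: str  # mapped | complemented | inconclusive
    reason: str


@dataclass
class DeficiencyPanel:
    """A panel of deletion stocks over one chromosome.

    ``deficiencies`` columns: ``deficiency_id, start, end`` (1-based
    inclusive) and optionally ``n_crosses``.
    """

    deficiencies: pd.DataFrame
    chromosome_length: int

    def __post_init__(self) -> None:
        df = self.deficiencies
        if (df["start"] >= df["end"]).any():
            raise ValueError("deficiency intervals need start < end")
        if (df["end"] > self.chromosome_length).any() or (df["start"] < 1).any():
            raise ValueError("deficiency intervals exceed chromosome bounds")

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.deficiencies["start"], self.deficiencies["end"]))

    def union_coverage(self) -> float:
        from .intervals import union_length

        return union_length(self.intervals()) / self.chromosome_length

    def coverage_for(self, deficiency_ids: Iterable[str]) -> float:
        """Fraction of the chromosome covered by a subset of the panel
        (e.g., the deficiencies actually crossed to one line)."""
        from .intervals import union_length

        ids = set(deficiency_ids)
        sub = self.deficiencies[self.deficiencies["deficiency_id"].isin(ids)]
        unknown = ids - set(sub["deficiency_id"])
        if unknown:
            raise KeyError(f"unknown deficiency ids: {sorted(unknown)}")
        return union_length(list(zip(sub["start"], sub["end"]))) / self.chromosome_length


@dataclass
class AllelismGraph:
    graph: nx.Graph
    components: list[frozenset]
    intransitive_triads: list[tuple[str, str, str]]


@dataclass
class AllelicSet:
    member_lines: frozenset
    gene_label: str | None = None
    years: frozenset = field(default_factory=frozenset)
    sample_frequency: float | None = None


def call_line_lethality(
    result: CrossResult,
    wildtype_max_fraction: float = WILDTYPE_MAX_FRACTION,
    min_curly: int = MIN_CURLY,
    strict: bool = True,
) -> str:
    """Score a balancer-sibling cross as lethal / non_lethal / inconclusive.

    Strict practice: lethal requires 0 straight-winged and >= ``min_curly``
    curly-winged offspring. The relaxed rule (``strict=False``) calls lethal
    whenever the straight fraction is below ``wildtype_max_fraction`` with
    enough offspring scored, admitting rare escapers.
    """
    if result.tester_kind != "balancer_sibling":
        raise ValueError(
            f"lethality is scored on balancer_sibling crosses, got {result.tester_kind!r}"
        )
    total = result.curly_n + result.straight_n
    if total == 0:
        return "inconclusive"
    frac = result.straight_n / total
    if frac >= wildtype_max_fraction:
        return "non_lethal"
    if strict:
        if result.straight_n == 0 and result.curly_n >= min_curly:
            return "lethal"
        return "inconclusive"
    if total >= min_curly:
        return "lethal"
    return "inconclusive"


def call_deficiency_mapping(
    result: CrossResult, min_curly: int = MIN_CURLY
) -> MappingCall:
    """Score one deficiency or knock-out cross.

    A single straight-winged survivor complements (the trans-heterozygote
    lived); zero straight with enough curly maps the lethal inside the
    deletion; anything else is inconclusive.
    """
    if result.tester_kind not in ("deficiency", "knockout"):
        raise ValueError(
            f"mapping is scored on deficiency/knockout crosses, got {result.tester_kind!r}"
        )
    if result.straight_n >= 1:
        call, reason = "complemented", "straight-winged survivors present"
    elif result.curly_n >= min_curly:
        call, reason = "mapped", f"0 straight with >= {min_curly} curly"
    else:
        call, reason = "inconclusive", f"fewer than {min_curly} curly scored"
    return MappingCall(result.line_id, result.tester_id, call, reason)


def call_deficiency_mapping_table(
    crosses: pd.DataFrame, min_curly: int = MIN_CURLY
) -> pd.DataFrame:
    """Vectorized :func:`call_deficiency_mapping` over a cross table.

    ``crosses`` needs columns ``line_id, tester_id, curly_n, straight_n``;
    returns the same frame with a ``call`` column added.
    """
    out = crosses.copy()
    out["call"] = np.select(
        [out["straight_n"] >= 1, out["curly_n"] >= min_curly],
        ["complemented", "mapped"],
        default="inconclusive",
    )
    return out


def distinct_regions_per_line(
    calls: pd.DataFrame | Sequence[MappingCall], panel: DeficiencyPanel
) -> pd.Series:
    """Number of distinct mapped regions per line.

    Overlapping deficiencies are merged into overlap-connected clusters, so
    a line failing to complement two overlapping deletions counts a single
    region (the conservative de-duplication used when tallying how many
    distinct lethal mutations a chromosome carries). Lines whose calls are
    all complemented/inconclusive report 0.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            [{"line_id": c.line_id, "tester_id": c.tester_id, "call": c.call} for c in calls]
        )
    panel_df = panel.deficiencies.drop_duplicates("deficiency_id")
    unknown = set(calls["tester_id"]) - set(panel_df["deficiency_id"])
    if unknown:
        raise KeyError(f"calls reference unknown deficiency ids: {sorted(unknown)}")
    all_lines = pd.Index(calls["line_id"].unique())

    mapped = calls.loc[calls["call"] == "mapped", ["line_id", "tester_id"]]
    mapped = mapped.drop_duplicates().merge(
        panel_df.rename(columns={"deficiency_id": "tester_id"}), on="tester_id"
    )
    if not len(mapped):
        return pd.Series(0, index=all_lines, dtype=int)
    # Per line, sweep its mapped intervals in start order: a new cluster
    # begins whenever an interval starts beyond the running max end. Only
    # the line's own mapped deficiencies merge — an unmapped deficiency
    # bridging two mapped ones does not join them.
    mapped = mapped.sort_values(["line_id", "start", "end"], kind="mergesort")
    cummax_end = mapped.groupby("line_id")["end"].cummax()
    prev_end = cummax_end.groupby(mapped["line_id"]).shift(1)
    new_cluster = prev_end.isna() | (mapped["start"] > prev_end)
    counts = new_cluster.groupby(mapped["line_id"]).sum()
    return counts.reindex(all_lines, fill_value=0).astype(int)


def multiplicity_histogram(per_line_counts: pd.Series, n_lines: int | None = None) -> pd.Series:
    """Proportion of lines mapping to 0, 1, 2, ... distinct regions."""
    if n_lines is None:
        n_lines = len(per_line_counts)
    if n_lines < len(per_line_counts):
        raise ValueError("n_lines smaller than the number of lines with counts")
    counts = per_line_counts.value_counts().sort_index()
    counts.loc[0] = counts.get(0, 0) + (n_lines - len(per_line_counts))
    full = counts.reindex(range(int(counts.index.max()) + 1), fill_value=0).sort_index()
    return full / n_lines


def build_allelism_graph(
    results: Iterable[CrossResult] | pd.DataFrame, min_curly: int = MIN_CURLY
) -> AllelismGraph:
    """Build the allelism graph from pairwise lethal x lethal crosses.

    Edge label ``allelic=True`` when only balanced offspring were produced
    (0 straight with >= ``min_curly`` curly); ``allelic=False`` when any
    straight survivor appeared; undersampled crosses contribute no edge.
    Components are computed over allelic edges only.
    """
    if isinstance(results, pd.DataFrame):
        results = [
            CrossResult(r.line_id, r.tester_id, "allelism", int(r.curly_n), int(r.straight_n))
            for r in results.itertuples()
        ]
    g = nx.Graph()
    for r in results:
        if r.tester_kind != "allelism":
            raise ValueError(f"expected allelism crosses, got {r.tester_kind!r}")
        if r.line_id == r.tester_id:
            raise ValueError(f"self-cross supplied for line {r.line_id!r}")
        g.add_node(r.line_id)
        g.add_node(r.tester_id)
        if r.straight_n >= 1:
            g.add_edge(r.line_id, r.tester_id, allelic=False)
        elif r.curly_n >= min_curly:
            g.add_edge(r.line_id, r.tester_id, allelic=True)

    allelic_sub = g.edge_subgraph(
        [(u, v) for u, v, d in g.edges(data=True) if d["allelic"]]
    ).copy()
    components = [frozenset(c) for c in nx.connected_components(allelic_sub)]

    triads = []
    for u, v, d in g.edges(data=True):
        if d["allelic"] or u not in allelic_sub or v not in allelic_sub:
            continue
        # complementing pair with a common allelic neighbor: intransitive
        common = set(allelic_sub.neighbors(u)) & set(allelic_sub.neighbors(v))
        for w in common:
            triads.append(tuple(sorted((u, v, w))))
    return AllelismGraph(
        graph=g,
        components=components,
        intransitive_triads=sorted(set(triads)),
    )


def allelic_sets_from_graph(
    graph: AllelismGraph,
    years_by_line: dict[str, int] | None = None,
    sample_n: int = 555,
    excluded_lines: Iterable[str] = (),
) -> list[AllelicSet]:
    """Turn allelic components of size >= 2 into reported allelic sets."""
    years_by_line = years_by_line or {}
    sets = []
    for comp in graph.components:
        if len(comp) < 2:
            continue
        sets.append(
            AllelicSet(
                member_lines=comp,
                years=frozenset(
                    years_by_line[l] for l in comp if l in years_by_line
                ),
                sample_frequency=allelic_set_frequency(
                    comp, sample_n=sample_n, excluded_lines=excluded_lines
                ),
            )
        )
    return sorted(sets, key=lambda s: (-len(s.member_lines), sorted(s.member_lines)))


def allelic_set_frequency(
    allelic_set: Iterable[str] | AllelicSet,
    sample_n: int = 555,
    excluded_lines: Iterable[str] = (),
) -> float:
    """Sample frequency of one lethal gene disruption, in percent.

    Set size (after dropping lines excluded by the female-duplicate rule)
    over the distinct-chromosome sample size, reported to one decimal.
    """
    if sample_n <= 0:
        raise ValueError(f"sample_n must be > 0, got {sample_n!r}")
    members = (
        allelic_set.member_lines if isinstance(allelic_set, AllelicSet) else set(allelic_set)
    )
    k = len(set(members) - set(excluded_lines))
    return round(100.0 * k / sample_n, 1)
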