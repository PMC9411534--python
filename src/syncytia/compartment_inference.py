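"""Inference of a compartment map from pairwise bleach experiments.

Each bleach experiment gives, for every observed zone, a significance call on
its %FL.  Significant loss in an observed zone is direct evidence of
cytoplasmic continuity with the bleached zone; absence of significant loss in
a zone that shares a border with the bleached zone is evidence of a full
diffusion barrier (absence of loss in a distant zone is too weak to call).
Contradictory evidence on one pair — connected in one experiment, barrier in
another — is kept and flagged "dynamic": the connectivity of fused units can
remodel over time, so a contradiction is read as temporal change rather than
measurement error.

Zones are merged by union-find over the connected evidence; a barrier pair
that ends up inside one merged block is a violation, again interpreted as
remodelling.  The minimum number of distinct compartments consistent with
the evidence is found by exhaustive search over set partitions (exact for up
to 10 zones): a feasible block contains no barrier pair and, if it has more
than one zone, is internally connected through the connected evidence —
zones are never merged on the strength of an untested pair alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .flip_analysis import SignificanceCall

__all__ = [
    "EvidenceRecord",
    "CompartmentMap",
    "CONNECTED",
    "BARRIER",
    "DYNAMIC",
    "UNTESTED",
    "accumulate_evidence",
    "build_map",
    "count_distinct_compartments",
    "example_fusion_evidence",
    "run_bleach_survey",
    "infer_map_from_graph",
]

CONNECTED = "connected"
BARRIER = "barrier"
DYNAMIC = "dynamic"
UNTESTED = "untested"


@dataclass(frozen=True)
class EvidenceRecord:
    """One observed zone in one bleach experiment."""

    bleached_zone: str
    bleached_channel: str
    observed_zone: str
    call: SignificanceCall
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.observed_zone == self.bleached_zone:
            raise ValueError("relation evidence requires observed_zone != bleached_zone")
        if self.call is None:
            raise ValueError("record carries no resolved significance call")


@dataclass
class CompartmentMap:
    zones: list[str]
    relations: dict[frozenset, str]  # pair -> CONNECTED/BARRIER/DYNAMIC
    merged_blocks: list[set[str]]
    violations: list[frozenset]
    evidence: dict[frozenset, list[EvidenceRecord]] = field(default_factory=dict)

    def relation(self, a: str, b: str) -> str:
        return self.relations.get(frozenset((a, b)), UNTESTED)


def accumulate_evidence(
    records: Iterable[EvidenceRecord],
    adjacency: Optional[Iterable[frozenset]] = None,
) -> tuple[dict[frozenset, str], dict[frozenset, list[EvidenceRecord]]]:
    """Reduce evidence records to pairwise relations.

    Significant loss => connected; non-significant loss in an adjacent zone
    => barrier; pairs never probed stay untested; one pair with both kinds of
    evidence is flagged dynamic.  ``adjacency`` is the set of zone pairs that
    share a border (required for barrier calls); if None every probed pair is
    treated as adjacent.
    """
    adj = None if adjacency is None else {frozenset(p) for p in adjacency}
    votes: dict[frozenset, set[str]] = {}
    by_pair: dict[frozenset, list[EvidenceRecord]] = {}
    for rec in records:
        pair = frozenset((rec.bleached_zone, rec.observed_zone))
        by_pair.setdefault(pair, []).append(rec)
        if rec.call.significant:
            votes.setdefault(pair, set()).add(CONNECTED)
        elif adj is None or pair in adj:
            votes.setdefault(pair, set()).add(BARRIER)
        # non-significant loss in a non-adjacent zone: too weak, stays untested
    relations: dict[frozenset, str] = {}
    for pair, kinds in votes.items():
        relations[pair] = DYNAMIC if len(kinds) > 1 else next(iter(kinds))
    return relations, by_pair


def build_map(
    zones: Sequence[str],
    relations: Mapping[frozenset, str],
    evidence: Optional[Mapping[frozenset, list[EvidenceRecord]]] = None,
) -> CompartmentMap:
    """Merge zones by union-find over connected edges; flag barrier pairs that
    land inside one merged block as violations (temporally dynamic
    connectivity)."""
    g = nx.Graph()
    g.add_nodes_from(zones)
    for pair, rel in relations.items():
        a, b = sorted(pair)
        if a not in g or b not in g:
            raise ValueError(f"relation references unknown zone in {pair}")
        if rel == CONNECTED:
            g.add_edge(a, b)
    blocks = [set(c) for c in nx.connected_components(g)]
    block_of = {z: i for i, blk in enumerate(blocks) for z in blk}
    violations = [
        pair
        for pair, rel in relations.items()
        if rel == BARRIER and len({block_of[z] for z in pair}) == 1
    ]
    return CompartmentMap(
        zones=list(zones),
        relations=dict(relations),
        merged_blocks=blocks,
        violations=sorted(violations, key=sorted),
        evidence=dict(evidence) if evidence else {},
    )


def _partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


class TooManyZonesError(ValueError):
    """Exact search refused; ``lower_bound`` is still reported."""

    def __init__(self, n_zones: int, lower_bound: int):
        self.lower_bound = lower_bound
        super().__init__(
            f"exact partition search refused for {n_zones} zones (>10); "
            f"lower bound from merged blocks and violations: {lower_bound}"
        )


def count_distinct_compartments(cmap: CompartmentMap) -> int:
    """Minimum number of compartments consistent with the evidence.

    Exhaustive search over set partitions of the zones: a block may not
    contain a barrier pair, and a block of size > 1 must be internally
    connected through connected-evidence edges.  Dynamic pairs contribute to
    neither constraint.  Exact for up to 10 zones; beyond that the search is
    refused and a lower bound (merged blocks plus violations) is raised with
    the error.
    """
    zones = list(cmap.zones)
    if len(zones) > 10:
        raise TooManyZonesError(
            len(zones), len(cmap.merged_blocks) + len(cmap.violations)
        )
    barriers = {p for p, r in cmap.relations.items() if r == BARRIER}
    conn = nx.Graph()
    conn.add_nodes_from(zones)
    for pair, rel in cmap.relations.items():
        if rel == CONNECTED:
            a, b = sorted(pair)
            conn.add_edge(a, b)

    def feasible(block: list[str]) -> bool:
        if len(block) == 1:
            return True
        for a, b in combinations(block, 2):
            if frozenset((a, b)) in barriers:
                return False
        return nx.is_connected(conn.subgraph(block))

    best = len(zones)
    for part in _partitions(zones):
        if len(part) >= best:
            continue
        if all(feasible(blk) for blk in part):
            best = len(part)
    return best


# --------------------------------------------------------------------------
# worked example: the published five-zone fused-unit map
# --------------------------------------------------------------------------

#: printed %FL observations of the five-zone worked example: each entry is
#: (experiment id, bleached zone, channel, observed zone, %FL as a fraction).
EXAMPLE_OBSERVATIONS = (
    ("bleach_GFP_zone", "GFP", "green", "H_GFP", 0.47),
    ("bleach_H_GFP_red", "H_GFP", "red", "mCherry1", 0.13),
    ("bleach_H_GFP_red", "H_GFP", "red", "L_GFP", 0.004),
    ("bleach_L_GFP_red", "L_GFP", "red", "mCherry2", 0.22),
    ("bleach_L_GFP_red", "L_GFP", "red", "H_GFP", 0.08),
    ("bleach_L_GFP_green", "L_GFP", "green", "GFP", 0.31),
    ("bleach_L_GFP_green", "L_GFP", "green", "H_GFP", 0.09),
)

#: per-fluorophore significance thresholds of the worked example (fractions)
EXAMPLE_THRESHOLDS = {"green": 0.191, "red": 0.208}

#: zone pairs sharing a border in the worked example
EXAMPLE_ADJACENCY = frozenset(
    frozenset(p)
    for p in [
        ("GFP", "H_GFP"),
        ("GFP", "L_GFP"),
        ("H_GFP", "L_GFP"),
        ("H_GFP", "mCherry1"),
        ("L_GFP", "mCherry2"),
    ]
)

EXAMPLE_ZONES = ("GFP", "H_GFP", "L_GFP", "mCherry1", "mCherry2")


def example_fusion_evidence() -> tuple[list[EvidenceRecord], frozenset]:
    """Evidence records for the five-zone worked example (printed %FL values
    against the 19.1% / 20.8% per-fluorophore thresholds)."""
    records = []
    for exp, bleached, channel, observed, pfl in EXAMPLE_OBSERVATIONS:
        thr = EXAMPLE_THRESHOLDS[channel]
        call = SignificanceCall(
            roi_id=observed,
            channel=channel,
            percent_loss=pfl,
            threshold=thr,
            significant=pfl > thr,
        )
        records.append(
            EvidenceRecord(
                bleached_zone=bleached,
                bleached_channel=channel,
                observed_zone=observed,
                call=call,
                experiment_id=exp,
            )
        )
    return records, EXAMPLE_ADJACENCY


# --------------------------------------------------------------------------
# simulated bleach surveys (ground-truth-driven pipeline)
# --------------------------------------------------------------------------


def run_bleach_survey(
    graph,
    bleach_species: str = "green",
    null_species: str = "red",
    noise_sd: float = 0.0,
    seed: int = 0,
    adjacency: Optional[Iterable[frozenset]] = None,
    pre_frames: int = 5,
    event_frames: int = 150,
    frame_interval: float = 2.0,
    event_rate: float = 1.0,
    imaging_decay: float = 0.0005,
    n_squares: int = 10_000,
    confidence: float = 0.95,
    gain: float = 100.0,
    background: float = 10.0,
) -> list[EvidenceRecord]:
    """Bleach every zone of ``graph`` in turn, measure %FL in all other zones
    and return the resulting evidence records.

    The movie is rendered from tiled zone geometry; the Monte-Carlo null is
    sampled from the unbleached (``null_species``) channel of each movie, as
    in the experimental procedure.  ``noise_sd`` is the Gaussian noise SD as
    a fraction of the full signal (gain).
    """
    from .compartment_model import (
        PhotoProtocol,
        _tile_geometry,
        integrate_dynamics,
        render_movie,
    )
    from .flip_analysis import (
        measure_zone_trace,
        monte_carlo_null,
        percent_fluorescence_loss,
        zone_roi,
    )

    geometry = _tile_geometry(graph.node_ids)
    records: list[EvidenceRecord] = []
    for i, bleached in enumerate(graph.node_ids):
        protocol = PhotoProtocol(
            pre_frames=pre_frames,
            event_frames=event_frames,
            post_frames=1,
            frame_interval=frame_interval,
            event_kind="bleach",
            target_node=bleached,
            event_rate=event_rate,
            species=bleach_species,
            imaging_decay=imaging_decay,
        )
        series = integrate_dynamics(graph, protocol)
        movie = render_movie(
            series,
            geometry,
            gain=gain,
            background=background,
            noise=(noise_sd * gain, False),
            seed=seed * 1009 + i,
            frame_interval=frame_interval,
            truth_graph=graph,
            truth_protocol=protocol,
        )
        null = monte_carlo_null(
            movie,
            null_species,
            n_squares=n_squares,
            confidence=confidence,
            seed=seed * 2003 + i,
        )
        # the test statistic is measured in the bleached channel, against the
        # null of the unbleached channel at the same confidence level
        for observed in graph.node_ids:
            if observed == bleached:
                continue
            trace = measure_zone_trace(movie, zone_roi(movie, observed), bleach_species)
            meas = percent_fluorescence_loss(trace, t_start=(0, pre_frames))
            call = SignificanceCall(
                roi_id=observed,
                channel=bleach_species,
                percent_loss=meas.percent_loss,
                threshold=null.threshold,
                significant=meas.percent_loss > null.threshold,
            )
            records.append(
                EvidenceRecord(
                    bleached_zone=bleached,
                    bleached_channel=bleach_species,
                    observed_zone=observed,
                    call=call,
                    experiment_id=f"bleach_{bleached}",
                )
            )
    return records


def infer_map_from_graph(
    graph,
    noise_sd: float = 0.0,
    seed: int = 0,
    adjacency: Optional[Iterable[frozenset]] = None,
    **survey_kwargs,
) -> CompartmentMap:
    """End-to-end: simulate a bleach survey on ``graph`` and build the map."""
    records = run_bleach_survey(graph, noise_sd=noise_sd, seed=seed, **survey_kwargs)
    relations, by_pair = accumulate_evidence(records, adjacency=adjacency)
    return build_map(graph.node_ids, relations, evidence=by_pair)
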