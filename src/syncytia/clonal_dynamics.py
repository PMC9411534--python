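"""Stochastic simulator of glial clonal growth with four-colour labelling.

Cortex-glia (CG) units grow from mononucleated founders through two
proliferative routes — endoreplication (genome replication without nuclear
division, which multiplies the copies of a single-insertion labelling
transgene carried per nucleus) and acytokinetic mitosis (nuclear division
without abscission, which adds nuclei to the unit) — and neighbouring units
can fuse.  A four-colour single-copy labelling construct is induced at an
arbitrary time: every transgene copy present at induction independently
recombines with a given efficiency and, if it does, locks in one of four
colours uniformly at random; copies created later by endoreplication or
mitosis inherit the colour of the copy they were replicated from.

The simulation runs in discrete 1-hour steps.  A per-nucleus event with
continuous rate r (1/h) fires in a step with probability e^r - 1 (capped at
1), so the expected per-step multiplication factor is exactly e^r and a
mitosis-only window of width w yields an expected unit size of e^(r*w).

Copy lineage is tracked explicitly (each copy knows its parent copy and birth
time), so label induction can be applied retroactively at any time point of
an already simulated population: the colour of a final copy is the colour
drawn by its ancestor copy alive at the induction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "NucleusState",
    "CGUnitState",
    "EventSchedule",
    "Population",
    "LabelledPopulation",
    "CloneRecord",
    "PopulationStats",
    "FusionOverlap",
    "simulate_population",
    "induce_labels",
    "compute_clone_stats",
    "classify_induction_case",
    "count_overlap_events",
    "canonical_schedule",
]

N_COLOURS = 4


@dataclass
class NucleusState:
    id: int
    copies: list[int]  # copy ids (>= 1 entries)


@dataclass
class CGUnitState:
    id: int
    nuclei: list[NucleusState]
    founder: int
    fused_with: set[int] = field(default_factory=set)


@dataclass(frozen=True)
class EventSchedule:
    """Event windows (h ALH, half-open [t0, t1)) and per-hour rates."""

    horizon: int = 96
    endo_window: tuple[int, int] = (16, 48)
    endo_rate: float = 0.05
    mitosis_window: tuple[int, int] = (48, 80)
    mitosis_rate: float = 0.04
    fusion_rate: float = 0.0
    n_units: int = 16

    def __post_init__(self) -> None:
        for w in (self.endo_window, self.mitosis_window):
            if not (0 <= w[0] <= w[1] <= self.horizon):
                raise ValueError(f"window {w} outside [0, {self.horizon}]")
        if min(self.endo_rate, self.mitosis_rate, self.fusion_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.n_units < 1:
            raise ValueError("need at least one founder unit")

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "endo_window": list(self.endo_window),
            "endo_rate": self.endo_rate,
            "mitosis_window": list(self.mitosis_window),
            "mitosis_rate": self.mitosis_rate,
            "fusion_rate": self.fusion_rate,
            "n_units": self.n_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSchedule":
        d = dict(d)
        d["endo_window"] = tuple(d["endo_window"])
        d["mitosis_window"] = tuple(d["mitosis_window"])
        return cls(**d)


@dataclass(frozen=True)
class Event:
    time: int
    kind: str  # {"endoreplication", "mitosis", "fusion"}
    unit: int
    nucleus: Optional[int] = None
    partner_unit: Optional[int] = None
    copies_a: tuple[int, ...] = ()  # copy snapshot of `unit` at the event (fusion)
    copies_b: tuple[int, ...] = ()  # copy snapshot of the partner (fusion)


@dataclass
class Population:
    """Simulated population with full copy lineage and event log."""

    units: list[CGUnitState]
    copy_parent: dict[int, Optional[int]]
    copy_birth: dict[int, int]
    events: list[Event]
    schedule: Optional[EventSchedule]
    adjacency: dict[int, set[int]]
    seed: Optional[int] = None

    @property
    def n_nuclei(self) -> int:
        return sum(len(u.nuclei) for u in self.units)

    @classmethod
    def from_copy_counts(cls, copy_counts: Sequence[int]) -> "Population":
        """One single-nucleus unit per entry, carrying that many transgene
        copies already present at t = 0 (handy for combinatorics checks)."""
        units, parent, birth = [], {}, {}
        cid = 0
        for i, m in enumerate(copy_counts):
            if m < 1:
                raise ValueError("copy counts must be >= 1")
            copies = list(range(cid, cid + m))
            for c in copies:
                parent[c] = None
                birth[c] = 0
            cid += m
            units.append(CGUnitState(id=i, nuclei=[NucleusState(id=i, copies=copies)], founder=i))
        return cls(
            units=units,
            copy_parent=parent,
            copy_birth=birth,
            events=[],
            schedule=None,
            adjacency={u.id: set() for u in units},
        )


def _step_probability(rate: float) -> float:
    """Per-step event probability giving an exact e^rate per-step mean."""
    return min(1.0, float(np.expm1(rate)))


def simulate_population(schedule: EventSchedule, seed: int = 0) -> Population:
    """Discrete-time (1 h) stochastic simulation of unit growth and fusion.

    Endoreplication doubles a nucleus's transgene copies; acytokinetic
    mitosis duplicates a nucleus within its unit (every copy is replicated
    and each daughter receives one replica, conserving copy number and
    colours); fusion merges two adjacent units (union of nuclei) and is
    logged with per-partner copy snapshots so detectability can be assessed
    after label induction.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    units: list[CGUnitState] = []
    copy_parent: dict[int, Optional[int]] = {}
    copy_birth: dict[int, int] = {}
    next_copy = 0
    next_nucleus = 0
    for i in range(schedule.n_units):
        copy_parent[next_copy] = None
        copy_birth[next_copy] = 0
        units.append(
            CGUnitState(
                id=i,
                nuclei=[NucleusState(id=next_nucleus, copies=[next_copy])],
                founder=i,
            )
        )
        next_copy += 1
        next_nucleus += 1

    # fixed random geometric neighbour graph over founder positions
    pos = rng.random((schedule.n_units, 2))
    radius = np.sqrt(4.0 / (np.pi * max(schedule.n_units - 1, 1)))
    adjacency: dict[int, set[int]] = {u.id: set() for u in units}
    for i in range(schedule.n_units):
        for j in range(i + 1, schedule.n_units):
            if np.hypot(*(pos[i] - pos[j])) <= radius:
                adjacency[i].add(j)
                adjacency[j].add(i)

    alive: dict[int, CGUnitState] = {u.id: u for u in units}
    events: list[Event] = []
    p_endo = _step_probability(schedule.endo_rate)
    p_mito = _step_probability(schedule.mitosis_rate)
    p_fuse = _step_probability(schedule.fusion_rate)

    for t in range(schedule.horizon):
        if schedule.endo_window[0] <= t < schedule.endo_window[1] and p_endo > 0:
            for u in list(alive.values()):
                for nuc in u.nuclei:
                    if rng.random() < p_endo:
                        new = []
                        for c in nuc.copies:
                            copy_parent[next_copy] = c
                            copy_birth[next_copy] = t
                            new.append(next_copy)
                            next_copy += 1
                        nuc.copies.extend(new)
                        events.append(Event(time=t, kind="endoreplication", unit=u.id, nucleus=nuc.id))
        if schedule.mitosis_window[0] <= t < schedule.mitosis_window[1] and p_mito > 0:
            for u in list(alive.values()):
                daughters = []
                for nuc in u.nuclei:
                    if rng.random() < p_mito:
                        new = []
                        for c in nuc.copies:
                            copy_parent[next_copy] = c
                            copy_birth[next_copy] = t
                            new.append(next_copy)
                            next_copy += 1
                        daughters.append(NucleusState(id=next_nucleus, copies=new))
                        next_nucleus += 1
                        events.append(Event(time=t, kind="mitosis", unit=u.id, nucleus=nuc.id))
                u.nuclei.extend(daughters)
        if p_fuse > 0:
            pairs = sorted(
                {tuple(sorted((a, b))) for a, nbrs in adjacency.items() for b in nbrs if a in alive and b in alive}
            )
            for a, b in pairs:
                if a not in alive or b not in alive:
                    continue
                if rng.random() < p_fuse:
                    ua, ub = alive[a], alive[b]
                    events.append(
                        Event(
                            time=t,
                            kind="fusion",
                            unit=a,
                            partner_unit=b,
                            copies_a=tuple(c for n in ua.nuclei for c in n.copies),
                            copies_b=tuple(c for n in ub.nuclei for c in n.copies),
                        )
                    )
                    ua.nuclei.extend(ub.nuclei)
                    ua.fused_with.add(b)
                    ua.fused_with.update(ub.fused_with)
                    adjacency[a] = (adjacency[a] | adjacency[b]) - {a, b}
                    for nbr in adjacency[b]:
                        adjacency[nbr].discard(b)
                        if nbr != a:
                            adjacency[nbr].add(a)
                    del alive[b]
                    del adjacency[b]

    return Population(
        units=sorted(alive.values(), key=lambda u: u.id),
        copy_parent=copy_parent,
        copy_birth=copy_birth,
        events=events,
        schedule=schedule,
        adjacency=adjacency,
        seed=seed,
    )


@dataclass
class LabelledPopulation:
    """A population plus one colour assignment from a label induction."""

    population: Population
    colour_of: dict[int, Optional[int]]  # copy id -> colour 1..4 or None
    induction_time: int
    mode: str  # {"CAAX", "NLS"}
    efficiency: float

    def nucleus_colours(self, nucleus: NucleusState) -> frozenset:
        return frozenset(
            c for c in (self.colour_of[cp] for cp in nucleus.copies) if c is not None
        )

    def copies_colours(self, copies: Iterable[int]) -> frozenset:
        return frozenset(
            c for c in (self.colour_of[cp] for cp in copies) if c is not None
        )


def _ancestor_at(pop: Population, copy: int, time: int) -> int:
    while pop.copy_birth[copy] > time:
        parent = pop.copy_parent[copy]
        if parent is None:  # pragma: no cover - roots are born at 0
            break
        copy = parent
    return copy


def induce_labels(
    population: Population,
    time: int,
    mode: Literal["CAAX", "NLS"] = "NLS",
    efficiency: float = 1.0,
    seed: int = 0,
) -> LabelledPopulation:
    """Apply four-colour single-copy label induction at ``time`` (h ALH).

    Each transgene copy present at the induction time independently
    recombines with probability ``efficiency`` and, if it does, draws one of
    the four colours uniformly; all its later replicas inherit that colour.
    """
    if mode not in ("CAAX", "NLS"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    horizon = population.schedule.horizon if population.schedule else time
    if time > horizon:
        raise ValueError("induction after the simulation horizon")
    rng = np.random.default_rng(seed)
    all_copies = sorted(population.copy_birth)
    ancestors = {c: _ancestor_at(population, c, time) for c in all_copies}
    root_colour: dict[int, Optional[int]] = {}
    for root in sorted(set(ancestors.values())):
        if efficiency > 0 and rng.random() < efficiency:
            root_colour[root] = int(rng.integers(1, N_COLOURS + 1))
        else:
            root_colour[root] = None
    colour_of = {c: root_colour[ancestors[c]] for c in all_copies}
    return LabelledPopulation(
        population=population,
        colour_of=colour_of,
        induction_time=time,
        mode=mode,
        efficiency=efficiency,
    )


@dataclass(frozen=True)
class CloneRecord:
    clone_id: int
    nuclei_count: int
    colour_set: frozenset
    member_units: tuple[int, ...]
    founder: int
    multicopy: bool  # any member nucleus carries more than one transgene copy


@dataclass
class PopulationStats:
    n_clones: int
    clone_sizes: np.ndarray  # nuclei per clone
    colours_per_clone: np.ndarray  # number of colours per clone (1..4)
    multicoloured_fraction: float
    fusion_events: int
    events_per_clone: float
    clones: list[CloneRecord]
    n_unlabelled_nuclei: int
    #: among single-coloured clones, how many contain a multi-copy nucleus
    #: (same-colour multi-copy recombination) vs only single-copy nuclei
    #: (non-endoreplicated route) — the two routes to late single colours
    single_colour_multicopy: int
    single_colour_singlecopy: int

    @property
    def mean_clone_size(self) -> float:
        return float(self.clone_sizes.mean()) if self.n_clones else 0.0


def compute_clone_stats(labelled: LabelledPopulation) -> PopulationStats:
    """Clone statistics of a labelled population.

    A clone is a maximal group of labelled nuclei within one unit that share
    an identical colour combination — the in-tissue observable is colour plus
    contiguity, and distinct units are spatially separate territories.
    Unlabelled nuclei (no recombined copy) are invisible and counted apart.
    """
    pop = labelled.population
    clones: list[CloneRecord] = []
    unlabelled = 0
    cid = 0
    for unit in pop.units:
        groups: dict[frozenset, list[NucleusState]] = {}
        for nuc in unit.nuclei:
            combo = labelled.nucleus_colours(nuc)
            if not combo:
                unlabelled += 1
                continue
            groups.setdefault(combo, []).append(nuc)
        for combo in sorted(groups, key=sorted):
            members = groups[combo]
            clones.append(
                CloneRecord(
                    clone_id=cid,
                    nuclei_count=len(members),
                    colour_set=combo,
                    member_units=(unit.id,),
                    founder=unit.founder,
                    multicopy=any(len(n.copies) > 1 for n in members),
                )
            )
            cid += 1
    if not clones:
        raise ValueError("no labelled clones: induce labels first")
    sizes = np.array([c.nuclei_count for c in clones])
    ncol = np.array([len(c.colour_set) for c in clones])
    fusions = sum(1 for e in pop.events if e.kind == "fusion")
    single = [c for c in clones if len(c.colour_set) == 1]
    return PopulationStats(
        n_clones=len(clones),
        clone_sizes=sizes,
        colours_per_clone=ncol,
        multicoloured_fraction=float(np.mean(ncol >= 2)),
        fusion_events=fusions,
        events_per_clone=fusions / len(clones),
        clones=clones,
        n_unlabelled_nuclei=unlabelled,
        single_colour_multicopy=sum(1 for c in single if c.multicopy),
        single_colour_singlecopy=sum(1 for c in single if not c.multicopy),
    )


def classify_induction_case(
    stats: PopulationStats,
    baseline: PopulationStats,
    multicolour_threshold: float = 0.2,
    band: float = 0.2,
) -> int:
    """Classify an induction outcome against the t = 0 baseline.

    Case 1: mostly single-coloured, clone number and size like baseline
    (induction before any proliferative event).  Case 2: multicoloured but
    number/size like baseline (induction after endoreplication, before
    mitosis).  Case 3: single-coloured but more, smaller clones (mitosis
    before endoreplication).  Case 4: multicoloured and more, smaller clones
    (induction after both).  Thresholds: multicoloured fraction >=
    ``multicolour_threshold``; "more clones" means n_clones > (1 + band) x
    baseline.
    """
    if baseline.n_clones == 0:
        raise ValueError("baseline has no clones")
    multi = stats.multicoloured_fraction >= multicolour_threshold
    more_clones = stats.n_clones > (1.0 + band) * baseline.n_clones
    if multi:
        return 4 if more_clones else 2
    return 3 if more_clones else 1


@dataclass(frozen=True)
class FusionOverlap:
    """Colour-overlap counts from logged fusion events."""

    detectable: int  # partners had different colour combinations
    undetectable: int  # same-colour fusions, invisible as overlaps

    @property
    def total(self) -> int:
        return self.detectable + self.undetectable


def count_overlap_events(
    labelled: LabelledPopulation, mode: str = "CAAX"
) -> FusionOverlap:
    """Count fusion events detectable as membrane-colour overlaps.

    A fusion is detectable iff the two partners carried different colour
    combinations when they fused (same-colour fusions leave no overlap).
    Only meaningful for membrane-targeted labelling.
    """
    if mode != "CAAX":
        raise ValueError("overlap events are defined on membranes (CAAX mode)")
    if labelled.mode != "CAAX":
        raise ValueError("population was labelled in NLS mode; overlaps need CAAX")
    detectable = undetectable = 0
    for e in labelled.population.events:
        if e.kind != "fusion":
            continue
        ca = labelled.copies_colours(e.copies_a)
        cb = labelled.copies_colours(e.copies_b)
        if ca != cb:
            detectable += 1
        else:
            undetectable += 1
    return FusionOverlap(detectable=detectable, undetectable=undetectable)


def canonical_schedule(fusion_rate: float = 0.0, n_units: int = 16) -> EventSchedule:
    """The documented default growth schedule: endoreplication in [16, 48) h
    at 0.05/h per nucleus, acytokinetic mitosis in [48, 80) h at 0.04/h, over
    a 96 h horizon — endoreplication precedes mitosis at the population
    level.  Fusion defaults to off for clone-dynamics work; pass a rate to
    study overlap counting."""
    return EventSchedule(fusion_rate=fusion_rate, n_units=n_units)
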