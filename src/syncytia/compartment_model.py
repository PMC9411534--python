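"""Compartment-graph fluorescence dynamics and synthetic movie rendering.

A piece of syncytial tissue is modelled as a graph of well-mixed fluorescent
compartments coupled by exchange bridges (ring canals / fusion pores).  Each
node carries one concentration per fluorescent species; an open edge (a, b)
with exchange rate ``k`` (1/s) moves fluorophore down the concentration
gradient with flux ``k * (C_b - C_a)`` applied symmetrically to both nodes.
Photomanipulation protocols (continuous bleaching, pulsed photoconversion)
act on a single target node, and every acquisition additionally bleaches the
whole field by a per-frame imaging-decay factor.

Because bleaching, conversion and exchange are all linear in the
concentrations, the dynamics between two acquisitions is a constant linear
map.  The integrator is an explicit fixed-step RK4 scheme; for speed the
one-step RK4 propagator (a matrix polynomial in the system matrix) is raised
to the number of sub-steps per frame, which reproduces the RK4 iterates
exactly in exact arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Node",
    "Edge",
    "CompartmentGraph",
    "PhotoProtocol",
    "ConcentrationSeries",
    "FieldGeometry",
    "SyntheticMovie",
    "integrate_dynamics",
    "closed_form_two_compartment",
    "render_movie",
    "make_fixture",
    "make_null_movie",
    "make_conversion_movie",
    "fused_units_graph",
    "FIXTURE_NAMES",
]

KAEDE_NATIVE = "kaede_native"
KAEDE_CONVERTED = "kaede_converted"


@dataclass(frozen=True)
class Node:
    """A well-mixed fluorescent compartment.

    ``init`` maps species name to initial concentration (a.u., >= 0);
    ``nuclei_count`` is the number of nuclei residing in the compartment
    (used by connected-nuclei counting downstream).
    """

    id: str
    init: Mapping[str, float]
    volume: float = 1.0
    nuclei_count: int = 0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"node {self.id!r}: volume must be > 0")
        if self.nuclei_count < 0:
            raise ValueError(f"node {self.id!r}: nuclei_count must be >= 0")
        for sp, c in self.init.items():
            if c < 0:
                raise ValueError(f"node {self.id!r}: negative concentration for {sp!r}")


@dataclass(frozen=True)
class Edge:
    """An exchange bridge between two compartments (undirected)."""

    a: str
    b: str
    rate: float  # 1/s
    open: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("exchange rate must be >= 0")


@dataclass
class CompartmentGraph:
    nodes: list[Node]
    edges: list[Edge]
    species: list[str]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique")
        known = set(ids)
        for e in self.edges:
            if e.a not in known or e.b not in known:
                raise ValueError(f"edge ({e.a!r}, {e.b!r}) references unknown node")

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node_index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node {node_id!r}") from None

    def initial_state(self) -> np.ndarray:
        """Concentrations as an (n_nodes, n_species) array."""
        c0 = np.zeros((len(self.nodes), len(self.species)))
        for i, n in enumerate(self.nodes):
            for sp, v in n.init.items():
                if sp not in self.species:
                    raise ValueError(f"node {n.id!r} initialises unknown species {sp!r}")
                c0[i, self.species.index(sp)] = v
        return c0

    def connected_components(self) -> list[set[str]]:
        """Ground-truth reachability through open bridges."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((e.a, e.b) for e in self.edges if e.open and e.rate > 0)
        return [set(c) for c in nx.connected_components(g)]

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "nodes": [
                {
                    "id": n.id,
                    "init": dict(n.init),
                    "volume": n.volume,
                    "nuclei_count": n.nuclei_count,
                }
                for n in self.nodes
            ],
            "edges": [
                {"a": e.a, "b": e.b, "rate": e.rate, "open": e.open} for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentGraph":
        return cls(
            nodes=[
                Node(
                    id=n["id"],
                    init=n["init"],
                    volume=n.get("volume", 1.0),
                    nuclei_count=n.get("nuclei_count", 0),
                )
                for n in d["nodes"]
            ],
            edges=[
                Edge(a=e["a"], b=e["b"], rate=e["rate"], open=e.get("open", True))
                for e in d["edges"]
            ],
            species=list(d["species"]),
        )


@dataclass
class PhotoProtocol:
    """Acquisition and photomanipulation schedule.

    Frames are 0-based; the event (bleach or convert) is active during the
    half-open frame range [pre_frames, pre_frames + event_frames).  ``species``
    names the bleached species (ignored for conversion, which always acts on
    the native -> converted Kaede pair).  ``imaging_decay`` is the fraction of
    signal lost per acquired frame, either one value for all species or a
    mapping per species.
    """

    pre_frames: int = 0
    event_frames: int = 0
    post_frames: int = 0
    frame_interval: float = 2.0  # s
    event_kind: str = "none"  # {"bleach", "convert", "none"}
    target_node: Optional[str] = None
    event_rate: float = 0.0  # s^-1 (beta for bleach, gamma for convert)
    species: Optional[str] = None
    imaging_decay: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if self.event_kind not in ("bleach", "convert", "none"):
            raise ValueError(f"unknown event_kind {self.event_kind!r}")
        if min(self.pre_frames, self.event_frames, self.post_frames) < 0:
            raise ValueError("frame counts must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.event_kind != "none" and self.target_node is None:
            raise ValueError("target_node required when event_kind != 'none'")

    @property
    def n_frames(self) -> int:
        return self.pre_frames + self.event_frames + self.post_frames

    def decay_for(self, species: str) -> float:
        if isinstance(self.imaging_decay, Mapping):
            a = float(self.imaging_decay.get(species, 0.0))
        else:
            a = float(self.imaging_decay)
        if not 0.0 <= a < 1.0:
            raise ValueError("imaging_decay must lie in [0, 1)")
        return a

    def event_active(self, frame: int) -> bool:
        return self.pre_frames <= frame < self.pre_frames + self.event_frames

    def to_dict(self) -> dict:
        d = {
            "pre_frames": self.pre_frames,
            "event_frames": self.event_frames,
            "post_frames": self.post_frames,
            "frame_interval": self.frame_interval,
            "event_kind": self.event_kind,
            "target_node": self.target_node,
            "event_rate": self.event_rate,
            "species": self.species,
        }
        d["imaging_decay"] = (
            dict(self.imaging_decay)
            if isinstance(self.imaging_decay, Mapping)
            else self.imaging_decay
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhotoProtocol":
        return cls(**d)


@dataclass
class ConcentrationSeries:
    """Per-node, per-species concentrations at every acquired frame."""

    times: np.ndarray  # (T,), seconds
    values: np.ndarray  # (n_nodes, n_species, T)
    node_ids: list[str]
    species: list[str]

    def trace(self, node_id: str, species: str) -> np.ndarray:
        return self.values[self.node_ids.index(node_id), self.species.index(species)]


@dataclass
class FieldGeometry:
    """Pixel-to-compartment assignment: label 0 is background."""

    label_image: np.ndarray  # (Z, Y, X) integer labels
    pixel_size: float  # um / pixel
    label_of_node: Mapping[str, int]  # node id -> label value

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 3:
            raise ValueError("label_image must be (Z, Y, X)")


@dataclass
class SyntheticMovie:
    """A rendered time-lapse with known ground truth.

    ``data`` has axes (T, Z, Y, X, C); physical metadata mirror what a
    microscope would record (pixel size in um, frame interval in s).
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float  # um
    frame_interval: float  # s
    geometry: Optional[FieldGeometry] = None
    truth_graph: Optional[CompartmentGraph] = None
    truth_protocol: Optional[PhotoProtocol] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("movie data must be 5-D (T, Z, Y, X, C)")
        if self.data.shape[-1] != len(self.channel_names):
            raise ValueError("channel_names length must match C axis")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("physical metadata must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _system_matrix(
    graph: CompartmentGraph, protocol: PhotoProtocol, with_event: bool
) -> np.ndarray:
    """Linear generator M of dx/dt = M x on the stacked (node, species) state."""
    n, s = len(graph.nodes), len(graph.species)
    m = np.zeros((n * s, n * s))

    def ix(node_i: int, sp_i: int) -> int:
        return node_i * s + sp_i

    for e in graph.edges:
        if not e.open or e.rate == 0:
            continue
        ia, ib = graph.node_index(e.a), graph.node_index(e.b)
        for sp in range(s):
            a, b = ix(ia, sp), ix(ib, sp)
            m[a, a] -= e.rate
            m[a, b] += e.rate
            m[b, b] -= e.rate
            m[b, a] += e.rate

    if with_event and protocol.event_kind != "none":
        it = graph.node_index(protocol.target_node)
        if protocol.event_kind == "bleach":
            sp = protocol.species
            if sp is None:
                raise ValueError("bleach protocol must name the bleached species")
            if sp not in graph.species:
                raise ValueError(f"unknown species {sp!r} in protocol")
            j = ix(it, graph.species.index(sp))
            m[j, j] -= protocol.event_rate
        else:  # convert
            for required in (KAEDE_NATIVE, KAEDE_CONVERTED):
                if required not in graph.species:
                    raise ValueError(
                        f"conversion requires species {required!r} in the graph"
                    )
            jn = ix(it, graph.species.index(KAEDE_NATIVE))
            jc = ix(it, graph.species.index(KAEDE_CONVERTED))
            m[jn, jn] -= protocol.event_rate
            m[jc, jn] += protocol.event_rate
    return m


def _rk4_propagator(m: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """(I + A + A^2/2 + A^3/6 + A^4/24)^n_steps with A = M*dt — the exact
    linear map of n_steps explicit RK4 steps on a linear system."""
    a = m * dt
    eye = np.eye(m.shape[0])
    step = eye + a + a @ a / 2.0 + a @ a @ a / 6.0 + a @ a @ a @ a / 24.0
    return np.linalg.matrix_power(step, n_steps)


def integrate_dynamics(
    graph: CompartmentGraph,
    protocol: PhotoProtocol,
    solver_dt: Optional[float] = None,
) -> ConcentrationSeries:
    """Integrate compartment dynamics; returns concentrations at each frame.

    Acquisition order per frame: the state is recorded, then the imaging-decay
    multiplier (1 - alpha) is applied once per species, then the continuous
    dynamics (exchange plus any active bleach/convert term) run for one frame
    interval.  ``solver_dt`` defaults to frame_interval / 100 and must not
    exceed frame_interval / 10.
    """
    if solver_dt is None:
        solver_dt = protocol.frame_interval / 100.0
    if solver_dt <= 0 or solver_dt > protocol.frame_interval / 10.0 + 1e-12:
        raise ValueError("solver_dt must be in (0, frame_interval / 10]")
    n_steps = max(1, int(round(protocol.frame_interval / solver_dt)))
    dt = protocol.frame_interval / n_steps

    n, s = len(graph.nodes), len(graph.species)
    t_total = protocol.n_frames
    if t_total == 0:
        raise ValueError("protocol schedules zero frames")

    phi_quiet = _rk4_propagator(_system_matrix(graph, protocol, False), dt, n_steps)
    phi_event = (
        _rk4_propagator(_system_matrix(graph, protocol, True), dt, n_steps)
        if protocol.event_kind != "none" and protocol.event_frames > 0
        else phi_quiet
    )
    decay = np.array([1.0 - protocol.decay_for(sp) for sp in graph.species])
    decay_vec = np.tile(decay, n)

    x = graph.initial_state().reshape(-1)
    values = np.empty((n, s, t_total))
    for f in range(t_total):
        values[:, :, f] = x.reshape(n, s)
        if f == t_total - 1:
            break
        x = x * decay_vec
        phi = phi_event if protocol.event_active(f) else phi_quiet
        x = phi @ x
    times = np.arange(t_total) * protocol.frame_interval
    return ConcentrationSeries(
        times=times, values=values, node_ids=graph.node_ids, species=list(graph.species)
    )


def closed_form_two_compartment(k: float, beta: float, t):
    """Analytic solution of the bleached two-compartment system.

    dC1/dt = k (C2 - C1) - beta C1,  dC2/dt = k (C1 - C2),  C1(0) = C2(0) = 1,
    solved by eigen-decomposition of the 2x2 generator.  ``t`` may be a scalar
    or an array of times (s); returns (C1, C2) with matching shape.
    """
    if k < 0 or beta < 0:
        raise ValueError("k and beta must be >= 0")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if k == 0.0 and beta == 0.0:
        c1, c2 = np.ones_like(t), np.ones_like(t)
    else:
        a = np.array([[-(k + beta), k], [k, -k]])
        lam, v = np.linalg.eig(a)
        coef = np.linalg.solve(v, np.ones(2))
        sol = (v @ (coef[:, None] * np.exp(np.outer(lam, t)))).real
        c1, c2 = sol[0], sol[1]
    if scalar:
        return float(c1[0]), float(c2[0])
    return c1, c2


def render_movie(
    series: ConcentrationSeries,
    geometry: FieldGeometry,
    gain: float = 1.0,
    background: float = 0.0,
    noise: tuple[float, bool] = (0.0, False),
    seed: int = 0,
    frame_interval: Optional[float] = None,
    truth_graph: Optional[CompartmentGraph] = None,
    truth_protocol: Optional[PhotoProtocol] = None,
    dtype=np.float32,
) -> SyntheticMovie:
    """Render a concentration series into a noisy intensity movie.

    Pixel value = gain * C_node(t) + background (+ noise); background pixels
    get background (+ noise) only.  ``noise`` is (gaussian_sd, poisson).
    Deterministic given ``seed``.  Negative values after Gaussian noise are
    clipped to zero, so fixtures should carry enough background offset that
    clipping is negligible.
    """
    gaussian_sd, poisson = noise
    labels = geometry.label_image
    n_nodes = len(series.node_ids)
    lut = np.full(int(labels.max()) + 1, -1, dtype=np.int64)
    for node_id, lab in geometry.label_of_node.items():
        if node_id not in series.node_ids:
            raise ValueError(f"geometry references unknown node {node_id!r}")
        if lab <= 0:
            raise ValueError("node labels must be positive integers")
        lut[lab] = series.node_ids.index(node_id)
    present = np.unique(labels)
    for lab in present[present > 0]:
        if lab >= lut.size or lut[lab] < 0:
            raise ValueError(f"label {int(lab)} has no corresponding graph node")

    t_total = series.values.shape[2]
    z, y, x = labels.shape
    c = len(series.species)
    rng = np.random.default_rng(seed)
    idx = lut[labels]  # (Z, Y, X), -1 for background
    fg = idx >= 0
    data = np.empty((t_total, z, y, x, c), dtype=np.float64)
    for f in range(t_total):
        conc = series.values[:, :, f]  # (n_nodes, n_species)
        frame = np.full((z, y, x, c), background, dtype=np.float64)
        frame[fg] += gain * conc[idx[fg]]
        data[f] = frame
    if poisson:
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float64)
    if gaussian_sd > 0:
        data += rng.normal(0.0, gaussian_sd, size=data.shape)
    np.clip(data, 0, None, out=data)
    return SyntheticMovie(
        data=data.astype(dtype),
        channel_names=list(series.species),
        pixel_size=geometry.pixel_size,
        frame_interval=(
            frame_interval
            if frame_interval is not None
            else float(series.times[1] - series.times[0]) if t_total > 1 else 1.0
        ),
        geometry=geometry,
        truth_graph=truth_graph,
        truth_protocol=truth_protocol,
    )


# --------------------------------------------------------------------------
# documented fixtures
# --------------------------------------------------------------------------

FIXTURE_NAMES = ("two_open", "two_closed", "chain3", "fused_units")

#: shared fixture rendering parameters (a.u. / um / s)
_FIX_GAIN = 100.0
_FIX_BACKGROUND = 10.0
_FIX_NOISE_SD = 2.0  # 2% of full signal
_FIX_PIXEL = 0.5
_FIX_INTERVAL = 2.0
_FIX_DECAY = 0.001
_FIX_K = 0.05
_FIX_BETA = 0.5
_TILE = 40  # px per compartment tile


def _tile_geometry(node_ids: Sequence[str], tile: int = _TILE) -> FieldGeometry:
    """One Z plane; compartments are side-by-side square tiles.

    Zones tile the field completely (no background margin) so that randomly
    placed null squares sample the same decay-plus-noise population as the
    zones themselves.
    """
    labels = np.zeros((1, tile, tile * len(node_ids)), dtype=np.int32)
    label_of = {}
    for i, node in enumerate(node_ids):
        labels[0, :, i * tile : (i + 1) * tile] = i + 1
        label_of[node] = i + 1
    return FieldGeometry(label_image=labels, pixel_size=_FIX_PIXEL, label_of_node=label_of)


def _render_fixture(graph, protocol, seed):
    series = integrate_dynamics(graph, protocol)
    geometry = _tile_geometry(graph.node_ids)
    return render_movie(
        series,
        geometry,
        gain=_FIX_GAIN,
        background=_FIX_BACKGROUND,
        noise=(_FIX_NOISE_SD, False),
        seed=seed,
        frame_interval=protocol.frame_interval,
        truth_graph=graph,
        truth_protocol=protocol,
    )


def make_fixture(name: str, seed: int = 0) -> SyntheticMovie:
    """Seeded synthetic movies with embedded ground truth.

    ``two_open``    two compartments joined by an open bridge; continuous
                    green bleach in node ``n1``.
    ``two_closed``  same layout, bridge closed — a full diffusion barrier.
    ``chain3``      three compartments in a chain, both bridges open, bleach
                    at one end; nuclei counts 3/2/2.
    ``fused_units`` five zones reproducing a partially fused pair of units:
                    a GFP-only zone in continuity with two fused subzones
                    (H_GFP, L_GFP) that are mutually separated by a barrier,
                    one red zone connected to L_GFP and one untouched red
                    neighbour.  Default protocol bleaches green in the GFP
                    zone.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name in ("two_open", "two_closed"):
        open_bridge = name == "two_open"
        graph = CompartmentGraph(
            nodes=[
                Node("n1", {"green": 1.0, "red": 1.0}, nuclei_count=2),
                Node("n2", {"green": 1.0, "red": 1.0}, nuclei_count=3),
            ],
            edges=[Edge("n1", "n2", _FIX_K, open=open_bridge)],
            species=["green", "red"],
        )
        protocol = PhotoProtocol(
            pre_frames=5,
            event_frames=100,
            post_frames=1,
            frame_interval=_FIX_INTERVAL,
            event_kind="bleach",
            target_node="n1",
            event_rate=_FIX_BETA,
            species="green",
            imaging_decay=_FIX_DECAY,
        )
        return _render_fixture(graph, protocol, seed)
    if name == "chain3":
        graph = CompartmentGraph(
            nodes=[
                Node("n1", {"green": 1.0, "red": 1.0}, nuclei_count=3),
                Node("n2", {"green": 1.0, "red": 1.0}, nuclei_count=2),
                Node("n3", {"green": 1.0, "red": 1.0}, nuclei_count=2),
            ],
            edges=[Edge("n1", "n2", _FIX_K), Edge("n2", "n3", _FIX_K)],
            species=["green", "red"],
        )
        protocol = PhotoProtocol(
            pre_frames=5,
            event_frames=150,
            post_frames=1,
            frame_interval=_FIX_INTERVAL,
            event_kind="bleach",
            target_node="n1",
            event_rate=_FIX_BETA,
            species="green",
            imaging_decay=_FIX_DECAY,
        )
        return _render_fixture(graph, protocol, seed)
    # fused_units
    graph = fused_units_graph()
    protocol = PhotoProtocol(
        pre_frames=5,
        event_frames=150,
        post_frames=1,
        frame_interval=_FIX_INTERVAL,
        event_kind="bleach",
        target_node="GFP",
        event_rate=_FIX_BETA,
        species="green",
        imaging_decay=_FIX_DECAY,
    )
    return _render_fixture(graph, protocol, seed)


def make_null_movie(
    shape: tuple[int, int] = (512, 512),
    n_frames: int = 100,
    imaging_decay: float = 0.002,
    noise_sd_frac: float = 0.03,
    pixel_size: float = 0.2,
    frame_interval: float = 2.0,
    gain: float = 1000.0,
    seed: int = 0,
) -> SyntheticMovie:
    """A no-FLIP movie: a uniform fluorescent field undergoing only
    per-acquisition imaging decay and additive Gaussian noise (SD given as a
    fraction of the full signal).  The null-distribution and false-positive
    properties of the Monte-Carlo threshold are calibrated on such movies."""
    graph = CompartmentGraph(
        nodes=[Node("field", {"green": 1.0})], edges=[], species=["green"]
    )
    protocol = PhotoProtocol(
        pre_frames=n_frames,
        event_frames=0,
        post_frames=0,
        frame_interval=frame_interval,
        event_kind="none",
        imaging_decay=imaging_decay,
    )
    series = integrate_dynamics(graph, protocol)
    geometry = FieldGeometry(
        label_image=np.ones((1, *shape), dtype=np.int32),
        pixel_size=pixel_size,
        label_of_node={"field": 1},
    )
    return render_movie(
        series,
        geometry,
        gain=gain,
        background=0.0,
        noise=(noise_sd_frac * gain, False),
        seed=seed,
        frame_interval=frame_interval,
        truth_graph=graph,
        truth_protocol=protocol,
    )


def make_conversion_movie(
    k: float = 0.05,
    open_bridge: bool = True,
    pre_frames: int = 10,
    pulses: int = 20,
    post_frames: int = 40,
    frame_interval: float = 2.0,
    conversion_rate: float = 0.2,
    noise_sd_frac: float = 0.02,
    gain: float = 1000.0,
    background: float = 50.0,
    seed: int = 0,
) -> SyntheticMovie:
    """A pulsed Kaede photoconversion trial on a two-compartment graph.

    The native form fills both compartments; conversion pulses act on the
    ``proximal`` node and the converted form may reach the ``distal`` node
    through the bridge (open or closed).  Gaussian noise SD is a fraction of
    the full signal."""
    graph = CompartmentGraph(
        nodes=[
            Node("proximal", {KAEDE_NATIVE: 1.0, KAEDE_CONVERTED: 0.0}),
            Node("distal", {KAEDE_NATIVE: 1.0, KAEDE_CONVERTED: 0.0}),
        ],
        edges=[Edge("proximal", "distal", k, open=open_bridge)],
        species=[KAEDE_NATIVE, KAEDE_CONVERTED],
    )
    protocol = PhotoProtocol(
        pre_frames=pre_frames,
        event_frames=pulses,
        post_frames=post_frames,
        frame_interval=frame_interval,
        event_kind="convert",
        target_node="proximal",
        event_rate=conversion_rate,
    )
    series = integrate_dynamics(graph, protocol)
    geometry = _tile_geometry(graph.node_ids)
    return render_movie(
        series,
        geometry,
        gain=gain,
        background=background,
        noise=(noise_sd_frac * gain, False),
        seed=seed,
        frame_interval=frame_interval,
        truth_graph=graph,
        truth_protocol=protocol,
    )


def fused_units_graph() -> CompartmentGraph:
    """Ground-truth graph of the five-zone partially fused configuration."""
    return CompartmentGraph(
        nodes=[
            Node("GFP", {"green": 1.0, "red": 0.0}, nuclei_count=3),
            Node("H_GFP", {"green": 1.0, "red": 0.7}, nuclei_count=2),
            Node("L_GFP", {"green": 0.4, "red": 0.7}, nuclei_count=2),
            Node("mCherry1", {"green": 0.0, "red": 1.0}, nuclei_count=2),
            Node("mCherry2", {"green": 0.0, "red": 1.0}, nuclei_count=2),
        ],
        edges=[
            Edge("GFP", "H_GFP", _FIX_K, open=True),
            Edge("GFP", "L_GFP", _FIX_K, open=True),
            Edge("L_GFP", "mCherry2", _FIX_K, open=True),
            Edge("H_GFP", "L_GFP", 0.0, open=False),
            Edge("H_GFP", "mCherry1", 0.0, open=False),
        ],
        species=["green", "red"],
    )
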