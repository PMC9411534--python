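"""Readers/writers: TIFF movies with a JSON ground-truth sidecar, ROI files,
CSV tables and run manifests.

Movies are multi-page TIFF with axes (T, Z, Y, X, C); physical metadata
(pixel size in um, frame interval in s) and any embedded ground truth live in
a structured JSON sidecar next to the image (``<image>.json``), so a movie
round-trips bit-identically.  ROIs, evidence, maps and manifests are JSON;
every tabular result is CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .compartment_model import (
    CompartmentGraph,
    FieldGeometry,
    PhotoProtocol,
    SyntheticMovie,
)
from .flip_analysis import ROI, IntensityTrace, SignificanceCall

__all__ = [
    "save_movie",
    "load_movie",
    "save_rois",
    "load_rois",
    "traces_to_csv",
    "calls_to_csv",
    "write_report",
    "load_manifest",
    "load_config",
]

log = logging.getLogger("syncytia")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_movie(movie: SyntheticMovie, path) -> Path:
    """Write the movie as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, metadata={"axes": "TZYXC"})
    meta = {
        "axes": "TZYXC",
        "shape": list(movie.data.shape),
        "dtype": str(movie.data.dtype),
        "channel_names": list(movie.channel_names),
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
    }
    if movie.geometry is not None:
        meta["geometry"] = {
            "pixel_size": movie.geometry.pixel_size,
            "label_of_node": dict(movie.geometry.label_of_node),
            "label_image": np.asarray(movie.geometry.label_image).tolist(),
        }
    if movie.truth_graph is not None:
        meta["truth_graph"] = movie.truth_graph.to_dict()
    if movie.truth_protocol is not None:
        meta["truth_protocol"] = movie.truth_protocol.to_dict()
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def load_movie(
    path,
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
    channel_names: Optional[Sequence[str]] = None,
    channel_map: Optional[Sequence[str]] = None,
) -> SyntheticMovie:
    """Read a TIFF/OME-TIFF movie; metadata come from the sidecar unless
    overridden.  Missing pixel size or frame interval raises an error naming
    the field.  ``channel_map`` reorders channels by name on load."""
    path = Path(path)
    data = tifffile.imread(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if "shape" in meta:
        data = np.asarray(data).reshape(meta["shape"])
    elif data.ndim != 5:
        raise ValueError(
            f"cannot infer TZYXC axes from a {data.ndim}-D TIFF without a sidecar"
        )
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    names = list(channel_names or meta.get("channel_names") or [])
    if px is None:
        raise ValueError("missing physical metadata: pixel_size_um (supply an override)")
    if dt is None:
        raise ValueError(
            "missing physical metadata: frame_interval_s (supply an override)"
        )
    if not names:
        names = [f"ch{i}" for i in range(data.shape[-1])]
    geometry = None
    if "geometry" in meta:
        g = meta["geometry"]
        geometry = FieldGeometry(
            label_image=np.asarray(g["label_image"]),
            pixel_size=g["pixel_size"],
            label_of_node=g["label_of_node"],
        )
    movie = SyntheticMovie(
        data=data,
        channel_names=names,
        pixel_size=float(px),
        frame_interval=float(dt),
        geometry=geometry,
        truth_graph=(
            CompartmentGraph.from_dict(meta["truth_graph"])
            if "truth_graph" in meta
            else None
        ),
        truth_protocol=(
            PhotoProtocol.from_dict(meta["truth_protocol"])
            if "truth_protocol" in meta
            else None
        ),
    )
    if channel_map:
        order = [movie.channel_index(c) for c in channel_map]
        movie.data = movie.data[..., order]
        movie.channel_names = list(channel_map)
    return movie


def save_rois(rois: Sequence[ROI], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([r.to_dict() for r in rois], indent=1))
    return path


def load_rois(path) -> list[ROI]:
    return [ROI.from_dict(d) for d in json.loads(Path(path).read_text())]


def traces_to_csv(traces: Sequence[IntensityTrace], path) -> Path:
    rows = [
        {
            "roi": t.roi_id,
            "channel": t.channel,
            "frame": i,
            "time_s": t.times[i],
            "I_mean": t.values[i],
        }
        for t in traces
        for i in range(len(t.values))
    ]
    df = pd.DataFrame(rows, columns=["roi", "channel", "frame", "time_s", "I_mean"])
    df.to_csv(path, index=False)
    return Path(path)


def calls_to_csv(calls: Sequence[SignificanceCall], path) -> Path:
    df = pd.DataFrame(
        [
            {
                "roi": c.roi_id,
                "channel": c.channel,
                "pFL": c.percent_loss,
                "threshold": c.threshold,
                "significant": c.significant,
            }
            for c in calls
        ],
        columns=["roi", "channel", "pFL", "threshold", "significant"],
    )
    df.to_csv(path, index=False)
    return Path(path)


def write_report(
    tables: Mapping[str, pd.DataFrame], outdir, manifest: Mapping
) -> Path:
    """Write CSV tables plus a structured manifest (inputs, seeds, parameters,
    tool version) sufficient to re-run bit-identically."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    man = dict(manifest)
    man["tool_version"] = __version__
    (outdir / "manifest.json").write_text(json.dumps(man, indent=1, sort_keys=True))
    return outdir


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Flat YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg
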