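"""Fixture plumbing: tab-delimited readers/writers and the fixture bundle.

All tabular fixtures are UTF-8 tab-delimited text with a one-line header;
times are seconds, lengths and coordinates µm. Floats are written with
Python's shortest round-tripping representation, so
``reader(writer(x)) == x`` holds bit-exactly. Masks are single-channel
16-bit TIFF. The manifest (JSON) records the seed, per-file row counts and
column documentation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import (
    SimConfig,
    simulate_bundle_field,
    simulate_dwell_events,
    simulate_filament_population,
    simulate_photobleach_traces,
    simulate_spot_sets,
)
from .types import DwellRecord, EndStateEvent, FilamentTrack, IntensityTrace, SpotSet

_TRACK_COLS = ["filament_id", "fov_id", "time_s", "length_um", "condition"]
_EVENT_COLS = ["filament_id", "state", "start_s", "end_s"]
_DWELL_COLS = ["molecule_id", "species", "bind_time_s", "release_time_s", "censored"]
_TRACE_COLS = ["molecule_id", "time_s", "intensity", "true_step_count"]
_SPOT_COLS = ["fov_id", "channel", "x_um", "y_um"]


def tracks_to_frame(tracks: list[FilamentTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t, length in zip(tr.times, tr.lengths):
            rows.append((tr.filament_id, tr.fov_id, t, length, tr.condition))
    return pd.DataFrame(rows, columns=_TRACK_COLS)


def frame_to_tracks(df: pd.DataFrame) -> list[FilamentTrack]:
    tracks = []
    for (fid, fov), grp in df.groupby(["filament_id", "fov_id"], sort=True):
        grp = grp.sort_values("time_s")
        cond = grp["condition"].iloc[0]
        tracks.append(
            FilamentTrack(
                filament_id=int(fid),
                fov_id=int(fov),
                times=grp["time_s"].to_numpy(),
                lengths=grp["length_um"].to_numpy(),
                condition="" if pd.isna(cond) else str(cond),
            )
        )
    return tracks


def write_tracks(path, tracks: list[FilamentTrack]) -> int:
    df = tracks_to_frame(tracks)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_tracks(path) -> list[FilamentTrack]:
    return frame_to_tracks(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_events(path, events: list[EndStateEvent]) -> int:
    df = pd.DataFrame(
        [(e.filament_id, e.state, e.start, e.end) for e in events],
        columns=_EVENT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_events(path) -> list[EndStateEvent]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        EndStateEvent(int(r.filament_id), str(r.state), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]


def write_dwells(path, records: list[DwellRecord]) -> int:
    df = pd.DataFrame(
        [(r.molecule_id, r.species, r.bind_time, r.release_time, r.censored) for r in records],
        columns=_DWELL_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_dwells(path) -> list[DwellRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        DwellRecord(
            int(r.molecule_id), str(r.species), float(r.bind_time_s),
            float(r.release_time_s), bool(r.censored),
        )
        for r in df.itertuples()
    ]


def write_traces(path, traces: list[IntensityTrace]) -> int:
    rows = []
    for tr in traces:
        k = -1 if tr.true_step_count is None else tr.true_step_count
        for t, y in zip(tr.times, tr.intensities):
            rows.append((tr.molecule_id, t, y, k))
    df = pd.DataFrame(rows, columns=_TRACE_COLS)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_traces(path) -> list[IntensityTrace]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    traces = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("time_s")
        k = int(grp["true_step_count"].iloc[0])
        traces.append(
            IntensityTrace(
                molecule_id=int(mid),
                times=grp["time_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                true_step_count=None if k < 0 else k,
            )
        )
    return traces


def write_spots(path, spots: SpotSet) -> int:
    df = pd.DataFrame(
        [(spots.fov_id, spots.channel, x, y) for x, y in spots.points],
        columns=_SPOT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_spots(path, fov_extent) -> SpotSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if len(df):
        fov = int(df["fov_id"].iloc[0])
        channel = str(df["channel"].iloc[0])
        points = df[["x_um", "y_um"]].to_numpy()
    else:
        fov, channel, points = 0, "", np.empty((0, 2))
    return SpotSet(fov_id=fov, channel=channel, points=points, fov_extent=tuple(fov_extent))


def read_durations(path) -> np.ndarray:
    """One-column duration table (header ``duration_s``)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")["duration_s"].to_numpy(dtype=float)


def write_durations(path, durations) -> int:
    df = pd.DataFrame({"duration_s": np.asarray(durations, dtype=float)})
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def _demo_mask(size: int = 64, radius: int = 20) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    disk = (xx - size / 2) ** 2 + (yy - size / 2) ** 2 <= radius**2
    return (disk * np.uint16(1000)).astype(np.uint16)


def write_fixture_bundle(
    output_dir,
    config: SimConfig,
    *,
    n_filaments: int = 25,
    n_dwell_molecules: int = 60,
    n_photobleach_molecules: int = 40,
) -> dict:
    """Write a complete synthetic fixture set and return its manifest.

    Produces filament tracks with their ground-truth state ledger,
    photobleaching traces, dwell records, two spot channels, a bundle
    pixel sample, a small disk mask (TIFF) and a JSON manifest; the same
    config and seed reproduce byte-identical delimited files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    tracks, events = simulate_filament_population(config, n_filaments)
    dwells = simulate_dwell_events(
        {"IQGAP1": 25.0, "mDia1": 300.0, "CP": 500.0},
        displacement_hazard=0.0,
        movie_duration=config.movie_duration,
        n_molecules=n_dwell_molecules,
        seed=seed + 1,
    )
    traces = simulate_photobleach_traces(
        n_oligomer=2, p_label=0.7, n_molecules=n_photobleach_molecules,
        bleach_rate=0.1, noise_sd=0.15, seed=seed + 2,
    )
    spots_a, spots_b = simulate_spot_sets(
        0.05, coloc_fraction=0.5, jitter_sd=0.05, fov_extent=(80.0, 80.0),
        seed=seed + 3,
    )
    bundle = simulate_bundle_field(
        2000, bundle_fraction=0.2, bundle_multiplier=4.0, noise_sd=0.2,
        seed=seed + 4,
    )

    pd.DataFrame({"intensity": bundle}).to_csv(
        out / "bundle_pixels.tsv", sep="\t", index=False
    )
    files = {
        "tracks.tsv": write_tracks(out / "tracks.tsv", tracks),
        "end_states.tsv": write_events(out / "end_states.tsv", events),
        "dwells.tsv": write_dwells(out / "dwells.tsv", dwells),
        "traces.tsv": write_traces(out / "traces.tsv", traces),
        "spots_a.tsv": write_spots(out / "spots_a.tsv", spots_a),
        "spots_b.tsv": write_spots(out / "spots_b.tsv", spots_b),
        "bundle_pixels.tsv": int(len(bundle)),
    }
    tifffile.imwrite(out / "mask.tif", _demo_mask())
    files["mask.tif"] = int(_demo_mask().size)

    manifest = {
        "seed": seed,
        "config": {
            "frame_interval": config.frame_interval,
            "movie_duration": config.movie_duration,
            "actin_conc": config.actin_conc,
            "pixel_size": config.pixel_size,
            "length_noise_sd": config.length_noise_sd,
            "pause_duration_mean": config.pause_duration_mean,
            "pause_duration_sd": config.pause_duration_sd,
        },
        "spot_fov_extent_um": [80.0, 80.0],
        "files": files,
        "columns": {
            "tracks.tsv": _TRACK_COLS,
            "end_states.tsv": _EVENT_COLS,
            "dwells.tsv": _DWELL_COLS,
            "traces.tsv": _TRACE_COLS,
            "spots_a.tsv": _SPOT_COLS,
            "spots_b.tsv": _SPOT_COLS,
            "bundle_pixels.tsv": ["intensity"],
        },
        "units": {"time": "s", "length": "um", "intensity": "a.u."},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
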