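"""On-disk session-directory format.

A session directory holds::

    photometry.h5   /f465, /f405, /t  (attrs: rate, mouse_id, phase, oblom_id,
                    session_id, schema_version)
    pose.csv        frame, neck_x, neck_y, nose_x, nose_y   [cm]
    ethogram.csv    frame + one 0/1 column per behavior
    objects.json    object centers per phase
    truth.h5        latent activity + components (synthetic sessions only)
    config.yaml     generator configuration (synthetic sessions only)

Round-trips are lossless for the arrays (float64 end to end).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from cholinepipe.behavior import BEHAVIORS, Ethogram, Trajectory, compute_speed
from cholinepipe.photometry import PhotometrySession, SessionMeta

SCHEMA_VERSION = 1


@dataclass
class SessionData:
    """Everything read back from a session directory."""

    photometry: PhotometrySession
    traj: Trajectory
    etho: Ethogram
    objects: dict
    truth: "object | None" = None  # GroundTruth when the session is synthetic
    config: dict | None = None


def write_session(session, directory: str | Path) -> Path:
    """Write a :class:`~cholinepipe.synth.SyntheticSession` (or equivalent bundle)."""
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"parent directory {directory.parent} does not exist")
    directory.mkdir(exist_ok=True)

    phot = session.photometry
    with h5py.File(directory / "photometry.h5", "w") as f:
        f.create_dataset("f465", data=phot.f465)
        f.create_dataset("f405", data=phot.f405)
        f.create_dataset("t", data=phot.t)
        f.attrs["rate"] = phot.rate
        f.attrs["mouse_id"] = phot.meta.mouse_id
        f.attrs["phase"] = phot.meta.phase
        f.attrs["oblom_id"] = phot.meta.oblom_id
        f.attrs["session_id"] = phot.meta.session_id
        f.attrs["schema_version"] = SCHEMA_VERSION

    traj = session.traj
    pose = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "neck_x": traj.neck_xy[:, 0],
            "neck_y": traj.neck_xy[:, 1],
            "nose_x": traj.nose_xy[:, 0],
            "nose_y": traj.nose_xy[:, 1],
        }
    )
    pose.to_csv(directory / "pose.csv", index=False, float_format="%.17g")

    etho = session.etho
    edf = pd.DataFrame({"frame": np.arange(etho.n_frames)})
    for name in BEHAVIORS:
        edf[name] = etho.flags[name].astype(int)
    edf.to_csv(directory / "ethogram.csv", index=False)

    cfg = getattr(session, "cfg", None)
    objects = cfg.object_centers if cfg is not None else getattr(session, "objects", {})
    with open(directory / "objects.json", "w") as f:
        json.dump({"video_rate": traj.rate, "centers": objects}, f, indent=1)

    truth = getattr(session, "truth", None)
    if truth is not None:
        with h5py.File(directory / "truth.h5", "w") as f:
            f.create_dataset("t", data=truth.t)
            f.create_dataset("z_true", data=truth.z_true)
            grp = f.create_group("components")
            for name, arr in truth.components.items():
                grp.create_dataset(name, data=arr)
            f.attrs["rate"] = truth.rate

    if cfg is not None:
        with open(directory / "config.yaml", "w") as f:
            yaml.safe_dump(_config_to_dict(cfg), f)
    return directory


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    # tuples -> lists for YAML round-trip cleanliness
    return json.loads(json.dumps(d))


def read_session(directory: str | Path) -> SessionData:
    """Read a session directory back into in-memory containers."""
    directory = Path(directory)
    with h5py.File(directory / "photometry.h5", "r") as f:
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version in {directory}")
        meta = SessionMeta(
            mouse_id=str(f.attrs["mouse_id"]),
            phase=str(f.attrs["phase"]),
            oblom_id=int(f.attrs["oblom_id"]),
            session_id=str(f.attrs["session_id"]),
        )
        phot = PhotometrySession(
            f465=f["f465"][:], f405=f["f405"][:], t=f["t"][:], rate=float(f.attrs["rate"]), meta=meta
        )

    with open(directory / "objects.json") as f:
        obj_doc = json.load(f)
    video_rate = float(obj_doc["video_rate"])
    centers = {
        phase: {k: tuple(v) for k, v in objs.items()}
        for phase, objs in obj_doc["centers"].items()
    }

    pose = pd.read_csv(directory / "pose.csv", float_precision="round_trip")
    n = len(pose)
    traj = Trajectory(
        t=np.arange(n) / video_rate,
        neck_xy=pose[["neck_x", "neck_y"]].to_numpy(),
        nose_xy=pose[["nose_x", "nose_y"]].to_numpy(),
        rate=video_rate,
    )
    traj.speed = compute_speed(traj)

    edf = pd.read_csv(directory / "ethogram.csv")
    etho = Ethogram(
        t=traj.t,
        rate=video_rate,
        flags={name: edf[name].to_numpy().astype(bool) for name in BEHAVIORS if name in edf},
    )

    truth = None
    if (directory / "truth.h5").exists():
        from cholinepipe.synth import GroundTruth

        with h5py.File(directory / "truth.h5", "r") as f:
            truth = GroundTruth(
                t=f["t"][:],
                rate=float(f.attrs["rate"]),
                z_true=f["z_true"][:],
                components={k: f["components"][k][:] for k in f["components"]},
            )

    config = None
    if (directory / "config.yaml").exists():
        with open(directory / "config.yaml") as f:
            config = yaml.safe_load(f)

    return SessionData(
        photometry=phot, traj=traj, etho=etho, objects=centers, truth=truth, config=config
    )


def write_dff(series, path: str | Path) -> None:
    """Write a processed ΔF/F series (dff.h5: /dff, /t, attrs stage_tags, rate)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=series.values)
        f.create_dataset("t", data=series.t)
        f.attrs["rate"] = series.rate
        f.attrs["stage_tags"] = ",".join(series.stage_tags)


def read_dff(path: str | Path):
    from cholinepipe.photometry import DffSeries

    with h5py.File(path, "r") as f:
        return DffSeries(
            values=f["dff"][:],
            t=f["t"][:],
            rate=float(f.attrs["rate"]),
            stage_tags=[s for s in str(f.attrs["stage_tags"]).split(",") if s],
        )
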