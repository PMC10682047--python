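"""File formats: columnar text and HDF5 recordings, HDF5 datasets, checkpoints.

Text recordings are for inspection/interchange (lossless to the printed
decimal precision); the HDF5 container round-trips recordings and datasets
losslessly and carries annotations, subject profile, seed and the config hash
of the producing run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .model import ModelConfig, SFENetwork, build_model
from .preprocess import Dataset, SequenceWindow
from .synth import EventSpec, Recording, SubjectProfile

TEXT_HEADER = ("t", "ax", "ay", "az", "semg")
TEXT_PRECISION = 9


class RecordingParseError(ValueError):
    pass


def config_hash(obj) -> str:
    """Stable sha256 of a config mapping (canonical YAML form)."""
    canon = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# -- columnar text ----------------------------------------------------------

def write_recording_text(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs!r} seed={rec.seed!r}\n")
        if rec.subject is not None:
            fh.write(f"# subject={json.dumps(asdict(rec.subject))}\n")
        for ev in rec.annotations:
            fh.write(f"# annotation={json.dumps(asdict(ev))}\n")
        fh.write("\t".join(TEXT_HEADER) + "\n")
        t = rec.t
        mat = rec.channel_matrix()
        for i in range(rec.n_samples):
            row = [f"{t[i]:.{TEXT_PRECISION}g}"] + [
                f"{mat[c, i]:.{TEXT_PRECISION}g}" for c in range(4)
            ]
            fh.write("\t".join(row) + "\n")


def read_recording_text(path: str | Path) -> Recording:
    path = Path(path)
    fs, seed, subject = None, None, None
    annotations: list[EventSpec] = []
    rows: list[list[float]] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs="):
                    parts = dict(p.split("=", 1) for p in body.split(" "))
                    fs = float(parts["fs"])
                    seed = None if parts.get("seed") in (None, "None") else int(
                        parts["seed"])
                elif body.startswith("subject="):
                    subject = SubjectProfile(**json.loads(body[len("subject="):]))
                elif body.startswith("annotation="):
                    annotations.append(
                        EventSpec(**json.loads(body[len("annotation="):]))
                    )
                continue
            cols = line.split("\t")
            if not header_seen:
                if tuple(cols) != TEXT_HEADER:
                    extra = set(cols) - set(TEXT_HEADER)
                    raise RecordingParseError(
                        f"line {lineno}: unexpected column(s) "
                        f"{sorted(extra) or cols}; expected header "
                        f"{' '.join(TEXT_HEADER)}"
                    )
                header_seen = True
                continue
            if len(cols) != len(TEXT_HEADER):
                raise RecordingParseError(
                    f"line {lineno}: expected {len(TEXT_HEADER)} columns, "
                    f"got {len(cols)}"
                )
            try:
                rows.append([float(c) for c in cols])
            except ValueError as exc:
                raise RecordingParseError(f"line {lineno}: {exc}") from exc
    if fs is None:
        raise RecordingParseError("missing '# fs=' metadata line")
    if not header_seen or not rows:
        raise RecordingParseError("missing header or data rows (truncated file?)")
    arr = np.array(rows)
    return Recording(
        fs=fs, ax=arr[:, 1], ay=arr[:, 2], az=arr[:, 3], semg=arr[:, 4],
        annotations=annotations, subject=subject, seed=seed,
    )


# -- HDF5 container ---------------------------------------------------------

_ANNOT_DTYPE = np.dtype(
    [("kind", "S16"), ("onset", "f8"), ("duration", "f8"), ("intensity", "f8")]
)


def write_recording_h5(rec: Recording, path: str | Path, meta: dict | None = None
                       ) -> None:
    with h5py.File(path, "w") as f:
        for name in Recording.CHANNEL_NAMES:
            f.create_dataset(name, data=getattr(rec, name))
        ann = np.array(
            [(ev.kind.encode(), ev.onset, ev.duration, ev.intensity)
             for ev in rec.annotations],
            dtype=_ANNOT_DTYPE,
        )
        f.create_dataset("annotations", data=ann)
        f.attrs["fs"] = rec.fs
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed
        if rec.subject is not None:
            f.attrs["subject"] = json.dumps(asdict(rec.subject))
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def read_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        channels = {name: f[name][:] for name in Recording.CHANNEL_NAMES}
        ann = [
            EventSpec(
                kind=row["kind"].decode(),
                onset=float(row["onset"]),
                duration=float(row["duration"]),
                intensity=float(row["intensity"]),
            )
            for row in f["annotations"][:]
        ]
        subject = None
        if "subject" in f.attrs:
            subject = SubjectProfile(**json.loads(f.attrs["subject"]))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return Recording(fs=float(f.attrs["fs"]), annotations=ann, subject=subject,
                         seed=seed, **channels)


def write_dataset_h5(ds: Dataset, path: str | Path, meta: dict | None = None) -> None:
    X = np.stack([w.values for w in ds.windows])
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=X, compression="gzip")
        f.create_dataset("labels", data=np.array([w.label for w in ds.windows]))
        f.create_dataset(
            "subject_ids",
            data=np.array([w.subject_id.encode() for w in ds.windows]),
        )
        f.create_dataset(
            "roles", data=np.array([w.role.encode() for w in ds.windows])
        )
        f.create_dataset(
            "offsets", data=np.array([w.source_offset for w in ds.windows])
        )
        f.attrs["n_classes"] = ds.n_classes
        f.attrs["class_names"] = json.dumps(ds.class_names)
        f.attrs["split"] = json.dumps(ds.split)
        f.attrs["params"] = json.dumps(ds.params)
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def read_dataset_h5(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        X = f["windows"][:]
        labels = f["labels"][:]
        subj = [s.decode() for s in f["subject_ids"][:]]
        roles = [r.decode() for r in f["roles"][:]]
        offs = f["offsets"][:]
        windows = [
            SequenceWindow(
                values=X[i], label=int(labels[i]), subject_id=subj[i],
                source_offset=int(offs[i]), role=roles[i],
            )
            for i in range(len(X))
        ]
        return Dataset(
            windows=windows,
            n_classes=int(f.attrs["n_classes"]),
            class_names=json.loads(f.attrs["class_names"]),
            split=json.loads(f.attrs["split"]),
            params=json.loads(f.attrs["params"]),
        )


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(network: SFENetwork, path: str | Path,
                    meta: dict | None = None) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(network.state_arrays())}
    header = {
        "config": asdict(network.config),
        "seed": network.seed,
        "census": network.layer_census(),
        "meta": meta or {},
    }
    np.savez(path, __header__=np.bytes_(json.dumps(header).encode()), **arrays)


def load_checkpoint(path: str | Path) -> SFENetwork:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    try:
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(bytes(data["__header__"].item()).decode())
            cfg_dict = header["config"]
            for key in ("block_convs", "channels_per_block"):
                cfg_dict[key] = tuple(cfg_dict[key])
            net = build_model(ModelConfig(**cfg_dict), seed=header["seed"])
            n_arrays = len(net.all_params) + len(net.all_buffers)
            arrays = [data[f"p{i}"] for i in range(n_arrays)]
            net.load_state_arrays(arrays)
            return net
    except (KeyError, ValueError, OSError) as exc:
        raise ValueError(f"incompatible or corrupt checkpoint {path}: {exc}") from exc


# -- manifests --------------------------------------------------------------

def write_manifest(path: str | Path, payload: dict) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
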