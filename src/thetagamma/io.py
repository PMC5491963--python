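"""Session-bundle persistence.

A session is stored as a directory ("bundle") of open formats:

* ``metadata.json`` — ids, genotype, sampling rate, channel and unit lists;
* ``lfp_<channel>.f32`` (flat little-endian 32-bit float, with shape in the
  metadata) or ``lfp_<channel>.csv`` (one µV value per line);
* ``spikes.csv`` — columns ``unit_id,time_s``;
* ``waveforms.csv`` — columns ``unit_id,sample_index,uv``;
* ``manifest.json`` — file list with SHA-256 checksums.

Binary mode round-trips bit-exactly at the stored precision; CSV mode is
accurate to 1e-6 µV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LfpTrace, PipelineError, Session, SpikeUnit

__all__ = ["write_bundle", "read_bundle"]

_FORMATS = ("binary", "csv")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(session: Session, path: str | Path, lfp_format: str = "binary") -> dict:
    """Write a session to a bundle directory; returns the manifest."""
    if lfp_format not in _FORMATS:
        raise PipelineError(f"lfp_format must be one of {_FORMATS}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    channels = []
    for trace in session.lfp:
        if lfp_format == "binary":
            fname = f"lfp_{trace.channel_id}.f32"
            trace.samples.astype("<f4").tofile(path / fname)
        else:
            fname = f"lfp_{trace.channel_id}.csv"
            np.savetxt(path / fname, trace.samples, fmt="%.6f")
        channels.append(
            {"channel_id": trace.channel_id, "file": fname,
             "n_samples": int(trace.samples.size)}
        )
        files.append(path / fname)

    spikes = pd.DataFrame(
        [
            {"unit_id": u.unit_id, "time_s": t}
            for u in session.units
            for t in u.spike_times
        ],
        columns=["unit_id", "time_s"],
    )
    spikes.to_csv(path / "spikes.csv", index=False, float_format="%.9f")
    files.append(path / "spikes.csv")

    wf_rows = []
    for u in session.units:
        if u.mean_waveform is None:
            continue
        for i, v in enumerate(u.mean_waveform):
            wf_rows.append({"unit_id": u.unit_id, "sample_index": i, "uv": v})
    pd.DataFrame(wf_rows, columns=["unit_id", "sample_index", "uv"]).to_csv(
        path / "waveforms.csv", index=False, float_format="%.9g"
    )
    files.append(path / "waveforms.csv")

    meta = {
        "session_id": session.session_id,
        "animal_id": session.animal_id,
        "genotype": session.genotype,
        "fs": session.fs,
        "lfp_format": lfp_format,
        "channels": channels,
        "units": [
            {
                "unit_id": u.unit_id,
                "waveform_fs": u.waveform_fs,
                "layer": u.layer,
                "cell_class": u.cell_class,
            }
            for u in session.units
        ],
    }
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    files.append(path / "metadata.json")

    manifest = {
        "files": {f.name: _sha256(f) for f in files},
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"bundle is missing {path.name} (expected at {path})")
    return path


def read_bundle(path: str | Path) -> Session:
    """Read a bundle directory back into a Session."""
    path = Path(path)
    with open(_require(path / "metadata.json")) as fh:
        meta = json.load(fh)

    traces = []
    for ch in meta["channels"]:
        f = _require(path / ch["file"])
        if meta["lfp_format"] == "binary":
            samples = np.fromfile(f, dtype="<f4").astype(float)
        else:
            samples = np.loadtxt(f, ndmin=1)
        if samples.size != ch["n_samples"]:
            raise PipelineError(
                f"{f.name}: expected {ch['n_samples']} samples, found {samples.size}"
            )
        traces.append(
            LfpTrace(samples=samples, fs=meta["fs"], channel_id=ch["channel_id"],
                     session_id=meta["session_id"])
        )

    spikes = pd.read_csv(_require(path / "spikes.csv"))
    wfs = pd.read_csv(_require(path / "waveforms.csv"))
    units = []
    for u in meta["units"]:
        uid = u["unit_id"]
        times = spikes.loc[spikes["unit_id"] == uid, "time_s"].to_numpy()
        wf_rows = wfs[wfs["unit_id"] == uid].sort_values("sample_index")
        wf = wf_rows["uv"].to_numpy() if len(wf_rows) else None
        units.append(
            SpikeUnit(
                unit_id=uid,
                spike_times=np.sort(times),
                mean_waveform=wf,
                waveform_fs=u["waveform_fs"],
                layer=u.get("layer", "unknown"),
                cell_class=u.get("cell_class", "unclassified"),
            )
        )
    return Session(
        lfp=traces,
        units=units,
        animal_id=meta["animal_id"],
        genotype=meta["genotype"],
        session_id=meta["session_id"],
    )
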