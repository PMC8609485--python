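"""File I/O: BrainVision/EDF recordings, TSV tables, JSON reports.

Recordings are written in BrainVision format (.vhdr/.vmrk text headers plus
an IEEE float32 multiplexed .eeg stream) and read back through mne, which
also handles EDF input.  Tables go to TSV, structured results to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .montage import build_montage
from .preprocessing import Event, Recording

_VHDR = """Brain Vision Data Exchange Header File Version 1.0
; generated by l2brain

[Common Infos]
Codepage=UTF-8
DataFile={name}.eeg
MarkerFile={name}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_VMRK = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={name}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,00000000000000000000
{markers}
"""


def write_brainvision(rec: Recording, basepath: str | Path) -> Path:
    """Write a recording as a BrainVision triplet; returns the .vhdr path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    channels = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(rec.labels)
    )
    (base.with_suffix(".vhdr")).write_text(
        _VHDR.format(
            name=name,
            n_channels=rec.n_channels,
            sampling_interval=f"{1e6 / rec.fs:g}",
            channels=channels,
        ),
        encoding="utf-8",
    )
    markers = "\n".join(
        f"Mk{i + 2}=Stimulus,{ev.kind},{ev.sample + 1},1,0"
        for i, ev in enumerate(sorted(rec.events, key=lambda e: e.sample))
    )
    (base.with_suffix(".vmrk")).write_text(
        _VMRK.format(name=name, markers=markers), encoding="utf-8"
    )
    np.asarray(rec.data, np.float32).T.tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def read_recording(path: str | Path, positions: np.ndarray | None = None) -> Recording:
    """Read BrainVision (.vhdr) or EDF (.edf) via mne into µV."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    data = (raw.get_data() * 1e6).astype(np.float32)  # volts -> µV
    labels = tuple(raw.ch_names)
    if positions is None:
        try:
            positions = build_montage(len(labels)).positions
        except Exception:
            positions = np.zeros((len(labels), 3))
    events = []
    for ann in raw.annotations:
        kind = ann["description"]
        if "/" in kind:
            kind = kind.split("/", 1)[1]
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= sample < data.shape[1]:
            events.append(Event(sample, kind))
    return Recording(data, float(raw.info["sfreq"]), labels, positions, events)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_tsv(df, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
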