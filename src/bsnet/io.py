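"""EDF recording I/O and annotation sidecars.

Recordings are written as plain EDF (16-bit, one data record per second)
with a tab-separated annotation sidecar (onset, duration, label); reading
goes through MNE's EDF reader so the two paths cross-check each other.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording

__all__ = ["read_recording", "write_recording", "read_annotations", "write_annotations"]

log = logging.getLogger(__name__)

_DIGITAL_MAX = 32767


def write_annotations(annotations, path: str | Path) -> None:
    df = pd.DataFrame(annotations, columns=["onset", "duration", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.onset), float(r.duration), str(r.label)) for r in df.itertuples()]


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write an EDF file plus a ``<name>_annotations.tsv`` sidecar.

    Samples are quantized to 16 bits over a symmetric physical range just
    covering the data; the final data record is zero-padded to a whole
    second.  Output bytes are deterministic for identical input.
    """
    path = Path(path)
    data = np.asarray(recording.data, dtype=float)
    if data.size == 0:
        raise ValueError("refusing to write an empty recording")
    fs = recording.fs
    if not np.isclose(fs, round(fs)):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / fs))
    phys = float(np.max(np.abs(data)))
    phys = max(phys * 1.001, 1e-6)
    if phys >= 10_000_000:
        raise ValueError(f"amplitude {phys:.3g} uV overflows the EDF physical range field")
    # the scaling must use exactly the (8-char) value written to the header
    while True:
        phys_str = f"{phys:.5g}"[:7]
        phys = float(phys_str)
        if phys >= np.max(np.abs(data)):
            break
        phys *= 1.01

    labels = [str(l)[:16] for l in recording.labels]
    hdr = bytearray()
    hdr += b"0" + b" " * 7  # version
    hdr += b" " * 80  # patient id (anonymous)
    hdr += b" " * 80  # recording id
    hdr += b"01.01.00"  # fixed start date: deterministic bytes
    hdr += b"00.00.00"
    hdr += f"{256 * (1 + n_ch):<8d}".encode()
    hdr += b" " * 44
    hdr += f"{n_rec:<8d}".encode()
    hdr += f"{1:<8d}".encode()  # record duration, s
    hdr += f"{n_ch:<4d}".encode()

    def field(values, width):
        out = b""
        for v in values:
            s = f"{v:<{width}}".encode()
            if len(s) > width:
                raise ValueError(f"EDF header field too long: {v!r}")
            out += s
        return out

    hdr += field(labels, 16)
    hdr += field(["" for _ in labels], 80)  # transducer
    hdr += field(["uV" for _ in labels], 8)
    hdr += field([f"-{phys_str}"[:8] for _ in labels], 8)
    hdr += field([phys_str for _ in labels], 8)
    hdr += field([str(-_DIGITAL_MAX) for _ in labels], 8)
    hdr += field([str(_DIGITAL_MAX) for _ in labels], 8)
    hdr += field(["" for _ in labels], 80)  # prefiltering
    hdr += field([str(fs) for _ in labels], 8)
    hdr += field(["" for _ in labels], 32)  # reserved

    scale = _DIGITAL_MAX / phys
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = data
    dig = np.clip(np.round(padded * scale), -_DIGITAL_MAX, _DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(bytes(hdr))
        for rec_i in range(n_rec):
            block = dig[:, rec_i * fs:(rec_i + 1) * fs]
            f.write(block.tobytes())  # channel-major within the record
    write_annotations(recording.annotations,
                      path.with_name(path.stem + "_annotations.tsv"))
    return path


def read_recording(edf_path: str | Path, annotations_path: str | Path | None = None,
                   ) -> Recording:
    """Read an EDF file (via MNE) and its annotation sidecar into a Recording."""
    import mne

    edf_path = Path(edf_path)
    _validate_edf_header(edf_path)
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    fs = float(raw.info["sfreq"])
    labels = tuple(raw.ch_names)

    if annotations_path is None:
        annotations_path = edf_path.with_name(edf_path.stem + "_annotations.tsv")
    annotations_path = Path(annotations_path)
    if annotations_path.exists():
        annotations = read_annotations(annotations_path)
    else:
        log.warning("no annotation sidecar at %s: recording loads unannotated",
                    annotations_path)
        annotations = []
    return Recording(data=data, fs=fs, labels=labels, annotations=annotations)


def _validate_edf_header(path: Path) -> None:
    with open(path, "rb") as f:
        head = f.read(256)
    if len(head) < 256:
        raise ValueError(f"corrupt EDF header: file shorter than 256 bytes ({path})")
    if not head[:8].strip() == b"0":
        raise ValueError(f"corrupt EDF header: bad version field {head[:8]!r}")
    try:
        n_ch = int(head[252:256].decode().strip())
        n_rec = int(head[236:244].decode().strip())
    except ValueError as err:
        raise ValueError("corrupt EDF header: non-numeric signal/record count") from err
    if n_ch <= 0 or n_rec <= 0:
        raise ValueError("corrupt EDF header: non-positive signal or record count")
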