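"""File I/O: EDF recordings, SFP/ELC montages, ground-truth sidecars.

Reading EDF/BDF goes through MNE.  Writing uses a small self-contained EDF
writer (fixed-layout 256-byte header plus 16-bit little-endian data records,
one-second records, physical units microvolts).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import Recording


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as EDF (16-bit, physical units uV, 1-s records)."""
    path = Path(path)
    x = recording.data
    n_ch, n_samp = x.shape
    srate = recording.srate
    spr = int(round(srate))  # samples per 1-s record
    if abs(srate - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record")
    x = x[:, :n_rec * spr]

    phys_min = np.floor(x.min(axis=1))
    phys_max = np.ceil(x.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)           # patient id (anonymous)
    header += _edf_field("Startdate X X X X", 80)  # recording id
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)                     # record duration (s)
    header += _edf_field(n_ch, 4)

    def per_signal(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += per_signal(recording.channel_labels, 16)
    header += per_signal(["EEG"] * n_ch, 80)
    header += per_signal(["uV"] * n_ch, 8)
    header += per_signal([f"{v:g}" for v in phys_min], 8)
    header += per_signal([f"{v:g}" for v in phys_max], 8)
    header += per_signal([-32768] * n_ch, 8)
    header += per_signal([32767] * n_ch, 8)
    header += per_signal([""] * n_ch, 80)
    header += per_signal([spr] * n_ch, 8)
    header += per_signal([""] * n_ch, 32)

    gain = (phys_max - phys_min) / (32767.0 - (-32768.0))
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            seg = x[:, r * spr:(r + 1) * spr]
            dig = np.round((seg - phys_min[:, None]) / gain[:, None]
                           + (-32768.0)).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path) -> Recording:
    """Read an EDF/BDF recording into microvolts via MNE."""
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" \
        else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = list(raw.ch_names)
    pos = np.zeros((len(labels), 3))
    return Recording(data=data, srate=float(raw.info["sfreq"]),
                     channel_labels=labels, sensor_positions=pos)


def write_sfp(labels, positions, path) -> None:
    """Write an SFP montage: one 'label x y z' line per sensor (mm)."""
    positions = np.asarray(positions, float)
    with open(path, "w") as fh:
        for lb, p in zip(labels, positions):
            fh.write(f"{lb}\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\n")


def read_montage(path) -> tuple[list, np.ndarray]:
    """Read sensor positions from SFP (label x y z) or ELC text files (mm)."""
    path = Path(path)
    labels, pos = [], []
    if path.suffix.lower() == ".elc":
        lines = path.read_text().splitlines()
        in_pos = False
        plist = []
        for ln in lines:
            t = ln.strip()
            if t.lower().startswith("positions"):
                in_pos = True
                continue
            if t.lower().startswith("labels"):
                in_pos = False
                continue
            if in_pos and t:
                parts = t.replace(":", " ").split()
                if len(parts) >= 4:
                    labels.append(parts[0])
                    plist.append([float(v) for v in parts[-3:]])
                elif len(parts) == 3:
                    labels.append(f"E{len(labels)+1}")
                    plist.append([float(v) for v in parts])
            elif not in_pos and t and not any(c.isdigit() for c in t):
                pass
        pos = plist
    else:
        for i, ln in enumerate(Path(path).read_text().splitlines()):
            t = ln.strip()
            if not t or t.startswith("#"):
                continue
            parts = t.split()
            if len(parts) < 4:
                raise ValueError(f"malformed SFP line {i + 1}: {ln!r}")
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
    return labels, np.asarray(pos, float)


def write_ground_truth(gt, path) -> None:
    """JSON sidecar with the generator's ground truth for one subject."""
    sc = gt.scenario
    payload = {
        "positions_mm": sc.positions.tolist(),
        "orientations": sc.orientations.tolist(),
        "mvar_order": int(sc.order),
        "mvar_coeffs": sc.mvar_coeffs.tolist(),
        "innovation_cov": sc.innovation_cov.tolist(),
        "band_profiles": [list(b) if b is not None else None
                          for b in sc.band_profiles],
        "snr_db": sc.snr_db,
        "seed": int(gt.subject_seed),
        "true_adjacency": np.asarray(gt.true_adjacency, bool).tolist(),
        "score_coeffs": gt.score_coeffs,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
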