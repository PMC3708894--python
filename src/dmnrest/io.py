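"""File I/O: EDF and CSV recordings, metadata tables, ground-truth JSON.

EDF writing is a minimal, deterministic implementation of the European
Data Format (16-bit signed samples, one-second data records, physical
units microvolts, fixed start date so that byte-identical files result
from byte-identical data).  Reading goes through :func:`mne.io.read_raw_edf`,
which doubles as an independent check on the writer.

CSV layout: header row of channel labels, one row per sample, values in
microvolts; the sampling rate is stored in a leading ``# fs=...`` comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

_EDF_DIG_MAX = 32767


def write_edf(path: str | Path, data: np.ndarray, labels: list[str] | tuple[str, ...],
              fs: float) -> None:
    """Write (channels, samples) microvolt data as 16-bit EDF.

    The recording is truncated to a whole number of one-second records.
    Quantization error is bounded by (physical range) / 2^16 per channel.
    """
    data = np.asarray(data, dtype=float)
    n_ch = data.shape[0]
    if len(labels) != n_ch:
        raise ValueError("labels must match data rows")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = data.shape[1] // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")
    data = data[:, :n_rec * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    scale = _EDF_DIG_MAX / phys_max
    digital = np.clip(np.round(data * scale[:, None]), -_EDF_DIG_MAX,
                      _EDF_DIG_MAX).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2000 X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(str(256 * (n_ch + 1)), 8),
        f("", 44), f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    sig = b"".join(f(lab, 16) for lab in labels)
    sig += b"".join(f("", 80) for _ in range(n_ch))
    sig += b"".join(f("uV", 8) for _ in range(n_ch))
    sig += b"".join(f(f"{-pm:.6g}"[:8], 8) for pm in phys_max)
    sig += b"".join(f(f"{pm:.6g}"[:8], 8) for pm in phys_max)
    sig += b"".join(f(str(-_EDF_DIG_MAX), 8) for _ in range(n_ch))
    sig += b"".join(f(str(_EDF_DIG_MAX), 8) for _ in range(n_ch))
    sig += b"".join(f("", 80) for _ in range(n_ch))
    sig += b"".join(f(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(f("", 32) for _ in range(n_ch))

    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (data in microvolts, labels, fs)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return data, list(raw.ch_names), float(raw.info["sfreq"])


def write_csv(path: str | Path, data: np.ndarray,
              labels: list[str] | tuple[str, ...], fs: float) -> None:
    """Write a recording as CSV (header of labels, one row per sample)."""
    data = np.asarray(data, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        fh.write(",".join(labels) + "\n")
        np.savetxt(fh, data.T, delimiter=",", fmt="%.10g")


def read_csv(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read a CSV recording written by :func:`write_csv`."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError("CSV recording must start with a '# fs=' line")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    return df.to_numpy(dtype=float).T, [str(c) for c in df.columns], fs


def write_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(path: str | Path, records: list[dict]) -> None:
    """Serialize per-subject ground-truth parameters as JSON (lossless for
    floats via repr round-tripping)."""
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_ground_truth(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
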