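"""File I/O: EDF sessions, tidy TSV tables, JSON reports.

Continuous sessions are written as EDF+C (16-bit European Data Format with
an annotations channel carrying trial onsets) by a small writer implemented
here, and read back through MNE's native EDF reader — writer and reader are
independent code paths, so a write/read round trip is a real format check.
Voltages are microvolts on both sides; EDF quantizes each channel to 16 bits
over its physical range, so round trips agree to within one quantization
step.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording

__all__ = [
    "write_edf",
    "read_edf_session",
    "write_spectra_tsv",
    "write_tests_tsv",
    "write_behavior_tsv",
    "write_json",
]

_ANNOT_SAMPLES_PER_RECORD = 64  # 128 bytes of TAL capacity per 1-s record


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> Path:
    """Write one session as EDF+C with trial-onset annotations.

    One-second data records; requires an integer sampling rate. Each trial
    onset becomes an annotation ``trial`` (or ``trial/outlier`` for flagged
    trials) at its onset time. The recording is zero-padded to a whole
    number of records.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    # symmetric integer physical limits: exact in the 8-char ascii header
    phys_max = np.ceil(np.maximum(np.abs(padded).max(axis=1) * 1.01, 1.0))
    dig_max, dig_min = 32767, -32768
    gain = 2.0 * phys_max / (dig_max - dig_min)  # uV per digital unit
    digital = np.clip(
        np.round((padded + phys_max[:, None]) / gain[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    ns = n_ch + 1  # + annotations channel
    header = b"".join([
        _ascii("0", 8),
        _ascii(rec.subject_id, 80),
        _ascii(f"Startdate 01-JAN-2000 condition={rec.condition}", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("EDF+C", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ])

    labels = [f"EEG {i:03d}" for i in range(n_ch)] + ["EDF Annotations"]
    transducer = ["AgAgCl electrode"] * n_ch + [""]
    phys_dim = ["uV"] * n_ch + [""]
    p_min = [str(int(-m)) for m in phys_max] + ["-1"]
    p_max = [str(int(m)) for m in phys_max] + ["1"]
    d_min = [str(dig_min)] * n_ch + [str(dig_min)]
    d_max = [str(dig_max)] * n_ch + [str(dig_max)]
    prefilter = [""] * ns
    n_samp = [str(fs)] * n_ch + [str(_ANNOT_SAMPLES_PER_RECORD)]

    for values, width in [
        (labels, 16), (transducer, 80), (phys_dim, 8), (p_min, 8), (p_max, 8),
        (d_min, 8), (d_max, 8), (prefilter, 80), (n_samp, 8),
        ([""] * ns, 32),
    ]:
        header += b"".join(_ascii(v, width) for v in values)

    # trial-onset annotations, assigned to the record containing each onset
    outliers = set(rec.outlier_trials.tolist())
    per_record: dict[int, list[bytes]] = {}
    for i, onset in enumerate(rec.trial_onsets):
        desc = "trial/outlier" if i in outliers else "trial"
        tal = f"+{onset:.4f}\x14{desc}\x14\x00".encode("ascii")
        per_record.setdefault(int(onset), []).append(tal)

    annot_bytes = 2 * _ANNOT_SAMPLES_PER_RECORD
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes(order="C"))
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            tal += b"".join(per_record.get(r, []))
            if len(tal) > annot_bytes:
                raise ValueError(f"too many annotations in record {r}")
            fh.write(tal.ljust(annot_bytes, b"\x00"))
    return path


def read_edf_session(
    path: str | Path,
    layout: np.ndarray,
    subject_id: str | None = None,
    condition: str | None = None,
) -> EEGRecording:
    """Read a continuous EDF session with trial-onset annotations.

    Voltages are returned in microvolts; onsets come from annotations whose
    description starts with ``trial`` (``trial/outlier`` marks outlier
    trials). Subject and condition default to the EDF header fields written
    by :func:`write_edf`. The channel count must match ``layout``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    n_ch = len(raw.ch_names)
    if n_ch != layout.shape[0]:
        raise ValueError(
            f"EDF has {n_ch} channels but layout has {layout.shape[0]}"
        )
    data_uv = raw.get_data() * 1e6  # MNE stores EEG in volts

    onsets, outlier_idx = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("trial"):
            if "outlier" in desc:
                outlier_idx.append(len(onsets))
            onsets.append(float(onset))
    if not onsets:
        raise ValueError(f"{path}: no trial annotations found")

    if subject_id is None:
        info = raw.info["subject_info"] or {}
        subject_id = info.get("his_id") or info.get("last_name") \
            or path.stem.split("_")[0]
    if condition is None:
        meas = raw.info.get("description") or ""
        m = re.search(r"condition=(\w+)", meas)
        if m:
            condition = m.group(1)
        else:
            m = re.search(r"(sentence|control)", path.stem)
            condition = m.group(1) if m else "sentence"

    return EEGRecording(
        subject_id=subject_id,
        condition=condition,
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        layout=np.asarray(layout, dtype=float),
        trial_onsets=np.array(onsets),
        outlier_trials=np.array(outlier_idx, dtype=int),
        reference="vertex",
    )


def write_spectra_tsv(path: str | Path, rows: list[dict]) -> Path:
    """Tidy spectra table: subject, condition, channel|avg, freq_bin,
    freq_hz, E, R, I, En."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_tests_tsv(path: str | Path, results: list) -> Path:
    """One row per :class:`~freqtag.inference.TestResult`."""
    rows = []
    for r in results:
        rows.append({
            "method": r.method,
            "target": r.target,
            "scope": r.scope,
            "statistic": r.statistic,
            "dof": str(r.dof),
            "p": r.p,
            "q": r.q,
            **{f"extra_{k}": v for k, v in r.extra.items()},
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_behavior_tsv(
    path: str | Path, subjects: list[str], condition: str, scores: np.ndarray
) -> Path:
    path = Path(path)
    pd.DataFrame({
        "subject": subjects,
        "condition": condition,
        "percent_correct": np.asarray(scores, dtype=float),
    }).to_csv(path, sep="\t", index=False)
    return path


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default))
    return path
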