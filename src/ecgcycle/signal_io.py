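"""Record I/O, lead derivation, segmentation and per-lead normalisation.

Records are stored as delimited text: a comment header carrying the sampling
rate, a header row of lead names, then one row per sample (comma separator,
'.' decimal, UTF-8).  A dataset directory additionally holds a labels table
(record id -> 34 indicator bits) and a manifest listing clean/noisy pairs.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ecgsynth import (
    LEADS_8,
    LEADS_12,
    N_CLASSES,
    EcgRecord,
    LabelSet,
    ParameterError,
)


class FormatError(ValueError):
    """Malformed record or dataset file."""


@dataclass
class SegmentationConfig:
    window_samples: int
    hop_samples: int
    pad_policy: str = "drop_tail"

    def __post_init__(self):
        if self.window_samples <= 0 or self.hop_samples <= 0:
            raise ParameterError("window and hop must be positive")
        if self.hop_samples > self.window_samples:
            raise ParameterError("hop must not exceed window")
        if self.pad_policy not in ("drop_tail", "zero_pad"):
            raise ParameterError(f"unknown pad policy {self.pad_policy!r}")


# -- record round trip -------------------------------------------------------------


def write_record(record: EcgRecord, path) -> None:
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# fs={record.fs!r}\n")
    buf.write(",".join(record.lead_names) + "\n")
    np.savetxt(buf, record.signal.T, delimiter=",", fmt="%.8g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_record(path) -> EcgRecord:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty record file")
    if not lines[0].startswith("# fs="):
        raise FormatError(f"{path}: missing '# fs=' header on line 1")
    try:
        fs = float(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise FormatError(f"{path}: unreadable sampling rate: {exc}") from exc
    if len(lines) < 3:
        raise FormatError(f"{path}: no sample rows")
    lead_names = tuple(name.strip() for name in lines[1].split(","))
    if lead_names not in (LEADS_8, LEADS_12):
        raise FormatError(
            f"{path}: lead header must be the canonical 8- or 12-lead set, "
            f"got {len(lead_names)} columns {lead_names}"
        )
    n_cols = len(lead_names)
    rows = np.empty((len(lines) - 2, n_cols))
    for i, line in enumerate(lines[2:], start=3):
        parts = line.split(",")
        if len(parts) != n_cols:
            raise FormatError(
                f"{path}: row {i} has {len(parts)} fields, expected {n_cols}"
            )
        try:
            rows[i - 3] = [float(p) for p in parts]
        except ValueError:
            raise FormatError(f"{path}: non-numeric cell on row {i}") from None
    if not np.isfinite(rows).all():
        bad = int(np.argwhere(~np.isfinite(rows))[0, 0]) + 3
        raise FormatError(f"{path}: non-finite value on row {bad}")
    return EcgRecord(signal=rows.T, fs=fs, lead_names=lead_names,
                     meta={"path": str(path)})


# -- 12-lead derivation -------------------------------------------------------------


def derive_12_lead(record: EcgRecord) -> EcgRecord:
    """Append the four linearly dependent limb leads (Einthoven/Goldberger).

    III = II - I;  aVR = -(I + II)/2;  aVL = I - II/2;  aVF = II - I/2.
    """
    names = record.lead_names
    if "I" not in names or "II" not in names:
        raise ParameterError("lead derivation requires leads I and II")
    if any(lead in names for lead in ("III", "aVR", "aVL", "aVF")):
        raise ParameterError("record already carries derived leads")
    lead_i = record.signal[names.index("I")]
    lead_ii = record.signal[names.index("II")]
    derived = np.vstack(
        [
            lead_ii - lead_i,
            -(lead_i + lead_ii) / 2.0,
            lead_i - lead_ii / 2.0,
            lead_ii - lead_i / 2.0,
        ]
    )
    return EcgRecord(
        signal=np.vstack([record.signal, derived]),
        fs=record.fs,
        lead_names=names + ("III", "aVR", "aVL", "aVF"),
        meta=dict(record.meta),
    )


# -- segmentation -------------------------------------------------------------------


def segment(record: EcgRecord, cfg: SegmentationConfig) -> list[EcgRecord]:
    """Half-open windows [start, start+window) advanced by `hop` samples."""
    window, hop = cfg.window_samples, cfg.hop_samples
    n = record.n_samples
    if cfg.pad_policy == "drop_tail":
        count = (n - window) // hop + 1 if n >= window else 0
        sig = record.signal
    else:  # zero_pad
        count = max(1, -(-(n - window) // hop) + 1)
        needed = (count - 1) * hop + window
        sig = np.pad(record.signal, ((0, 0), (0, needed - n)))
    out = []
    for j in range(count):
        start = j * hop
        out.append(
            EcgRecord(
                signal=sig[:, start : start + window].copy(),
                fs=record.fs,
                lead_names=record.lead_names,
                meta={**record.meta, "segment_start": start},
            )
        )
    return out


# -- normalisation -------------------------------------------------------------------


def normalize_array(x: np.ndarray, mode: str = "zscore") -> np.ndarray:
    """Per-row normalisation of a (leads x samples) matrix."""
    x = np.asarray(x, dtype=float)
    if mode == "zscore":
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        return np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if mode == "minmax":
        lo = x.min(axis=-1, keepdims=True)
        hi = x.max(axis=-1, keepdims=True)
        span = hi - lo
        return np.where(span > 0, 2.0 * (x - lo) / np.where(span > 0, span, 1.0) - 1.0, 0.0)
    raise ParameterError(f"unknown normalisation mode {mode!r}")


def normalize(record: EcgRecord, mode: str = "zscore") -> EcgRecord:
    return record.copy(signal=normalize_array(record.signal, mode), normalized=mode)


# -- dataset persistence ---------------------------------------------------------------


def save_dataset(directory, triples, seed: int | None = None, spec: dict | None = None) -> None:
    """One CSV per record plus labels table and clean/noisy manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows, label_rows = [], []
    for i, (clean, noisy, labels) in enumerate(triples):
        rid = f"rec_{i:05d}"
        clean_path = directory / f"{rid}_clean.csv"
        noisy_path = directory / f"{rid}_noisy.csv"
        write_record(clean, clean_path)
        write_record(noisy, noisy_path)
        manifest_rows.append(
            {"record_id": rid, "clean": clean_path.name, "noisy": noisy_path.name}
        )
        label_rows.append({"record_id": rid,
                           **{f"c{j}": int(b) for j, b in enumerate(labels.vector)}})
    pd.DataFrame(manifest_rows).to_csv(directory / "manifest.csv", index=False)
    pd.DataFrame(label_rows).to_csv(directory / "labels.csv", index=False)
    meta = {"n_records": len(manifest_rows)}
    if seed is not None:
        meta["seed"] = seed
    if spec:
        meta.update(spec)
    pd.Series(meta).to_csv(directory / "meta.csv", header=False)


def load_dataset(directory) -> list[tuple[EcgRecord, EcgRecord, LabelSet]]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    labels = pd.read_csv(directory / "labels.csv").set_index("record_id")
    triples = []
    for row in manifest.itertuples():
        vec = labels.loc[row.record_id, [f"c{j}" for j in range(N_CLASSES)]].to_numpy()
        triples.append(
            (
                read_record(directory / row.clean),
                read_record(directory / row.noisy),
                LabelSet(vec),
            )
        )
    return triples
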