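"""On-disk representations: EDF/CSV recordings, PSQI tables, result bundles.

EDF (European Data Format) is the interchange format for the signals;
reading goes through MNE's EDF reader, writing through a minimal 16-bit
EDF writer (one-second data records, physical units µV). A long-format
CSV representation is provided as a plain-text fallback. Tables are
CSV/TSV with a stable column order; result bundles are written as CSVs
plus a JSON manifest with checksums so two runs of the same seed can be
diffed byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CONDITIONS, PREFRONTAL_CHANNELS, PSQIRecord, Recording

logger = logging.getLogger(__name__)

PSQI_COLUMNS = ["participant", "month"] + [f"psqi_c{i}" for i in range(1, 8)] + [
    "psqi_total"
]


def recording_filename(rec: Recording, fmt: str = "edf") -> str:
    return f"{rec.participant_id}_m{rec.month}_{rec.condition}.{fmt}"


def parse_recording_filename(path: str | Path) -> tuple[str, int, str]:
    stem = Path(path).stem
    try:
        pid, month_s, condition = stem.rsplit("_", 2)
        month = int(month_s.lstrip("m"))
    except ValueError as exc:
        raise ValueError(
            f"cannot parse participant/month/condition from {Path(path).name!r}; "
            "expected '<participant>_m<month>_<condition>.<ext>'"
        ) from exc
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r} in {Path(path).name!r}")
    return pid, month, condition


# ---------------------------------------------------------------------------
# EDF writing (16-bit, 1-second data records)


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path,
                        phys_range_uv: float | None = None) -> Path:
    """Write a Recording as a 16-bit EDF file.

    The physical range defaults to the recording's absolute maximum
    (rounded up); samples exceeding an explicitly supplied range raise —
    silent clipping would corrupt the spectra downstream.
    """
    path = Path(path)
    n_per_record = int(round(rec.fs))
    if abs(n_per_record - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate; use CSV")
    n_records = rec.n_samples // n_per_record
    if n_records * n_per_record != rec.n_samples:
        raise ValueError(
            "EDF writer requires a whole number of 1-second records; use CSV"
        )
    absmax = float(np.abs(rec.samples).max())
    if phys_range_uv is None:
        phys_range_uv = max(np.ceil(absmax * 1.01), 1.0)
    elif absmax > phys_range_uv:
        raise ValueError(
            f"samples reach {absmax:.1f} µV, outside the physical range "
            f"±{phys_range_uv:g} µV; clipping is refused"
        )
    n_sig = len(rec.channels)
    header = b"".join([
        _edf_field(0, 8),
        _edf_field("X X X X", 80),
        _edf_field(f"Startdate X {rec.participant_id} m{rec.month} {rec.condition}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_sig, 4),
    ])
    pmin, pmax = -phys_range_uv, phys_range_uv
    dmin, dmax = -32768, 32767
    sig_fields = [
        [_edf_field(ch, 16) for ch in rec.channels],
        [_edf_field("AgAgCl electrode", 80)] * n_sig,
        [_edf_field("uV", 8)] * n_sig,
        [_edf_field(f"{pmin:g}", 8)] * n_sig,
        [_edf_field(f"{pmax:g}", 8)] * n_sig,
        [_edf_field(dmin, 8)] * n_sig,
        [_edf_field(dmax, 8)] * n_sig,
        [_edf_field("BP:0.5-30Hz", 80)] * n_sig,
        [_edf_field(n_per_record, 8)] * n_sig,
        [_edf_field("", 32)] * n_sig,
    ]
    header += b"".join(b"".join(f) for f in sig_fields)
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((rec.samples - pmin) * gain + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = digital[:, r * n_per_record: (r + 1) * n_per_record]
            fh.write(chunk.tobytes())
    return path


def read_recording_edf(path: str | Path, participant_id: str | None = None,
                       month: int | None = None,
                       condition: str | None = None) -> Recording:
    """Read an EDF recording via MNE; physical units are enforced to µV."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [ch for ch in PREFRONTAL_CHANNELS if ch not in raw.ch_names]
    if missing:
        raise ValueError(
            f"{path.name}: missing channel(s) {missing}; found {raw.ch_names}"
        )
    order = [raw.ch_names.index(ch) for ch in PREFRONTAL_CHANNELS]
    data_v = raw.get_data()[order]  # MNE converts EDF 'uV' to volts
    if participant_id is None or month is None or condition is None:
        pid, m, cond = parse_recording_filename(path)
        participant_id = participant_id or pid
        month = month or m
        condition = condition or cond
    return Recording(
        participant_id=participant_id, month=month, condition=condition,
        fs=float(raw.info["sfreq"]), samples=data_v * 1e6,
        channels=PREFRONTAL_CHANNELS,
    )


# ---------------------------------------------------------------------------
# CSV recordings (long format)


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    n = rec.n_samples
    frames = []
    for ci, ch in enumerate(rec.channels):
        frames.append(pd.DataFrame({
            "participant": rec.participant_id, "month": rec.month,
            "condition": rec.condition, "channel": ch,
            "sample_index": np.arange(n), "microvolts": rec.samples[ci],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")
    return path


def read_recording_csv(path: str | Path, fs: float = 512.0) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"participant", "month", "condition", "channel",
                "sample_index", "microvolts"}
    if not required <= set(df.columns):
        raise ValueError(f"{path.name}: missing columns {required - set(df.columns)}")
    pid = str(df["participant"].iloc[0])
    month = int(df["month"].iloc[0])
    condition = str(df["condition"].iloc[0])
    chans = []
    lengths = set()
    for ch in PREFRONTAL_CHANNELS:
        sub = df[df["channel"] == ch].sort_values("sample_index")
        if sub.empty:
            raise ValueError(f"{path.name}: no rows for channel {ch}")
        chans.append(sub["microvolts"].to_numpy())
        lengths.add(len(sub))
    if len(lengths) != 1:
        raise ValueError(f"{path.name}: channels have mismatched lengths {lengths}")
    return Recording(participant_id=pid, month=month, condition=condition,
                     fs=fs, samples=np.stack(chans))


def write_recording(rec: Recording, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return write_recording_edf(rec, path)
    if fmt == "csv":
        return write_recording_csv(rec, path)
    raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, fmt: str | None = None, **kwargs) -> Recording:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return read_recording_edf(path, **kwargs)
    if fmt == "csv":
        return read_recording_csv(path, **kwargs)
    raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# PSQI tables


def write_psqi_table(records: list[PSQIRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        dict(participant=r.participant_id, month=r.month,
             **{f"psqi_c{i + 1}": c for i, c in enumerate(r.components)},
             psqi_total=r.total)
        for r in sorted(records, key=lambda r: (r.participant_id, r.month))
    ]
    pd.DataFrame(rows, columns=PSQI_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_psqi_table(path: str | Path) -> list[PSQIRecord]:
    """Read and validate a PSQI table (TSV or CSV; totals are re-checked)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        logger.warning("PSQI table %s is empty", path)
        return []
    missing = set(PSQI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        comps = tuple(int(row[f"psqi_c{i}"]) for i in range(1, 8))
        total = int(row["psqi_total"])
        if total != sum(comps):
            raise ValueError(
                f"{path.name} row {idx} ({row['participant']} month "
                f"{row['month']}): total {total} != component sum {sum(comps)}"
            )
        try:
            records.append(PSQIRecord(str(row["participant"]), int(row["month"]),
                                      comps, total))
        except ValueError as exc:
            raise ValueError(f"{path.name} row {idx}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# result bundles


@dataclass
class ResultBundle:
    """All tables one pipeline run produces, plus run metadata."""

    band_power: pd.DataFrame
    band_correlations: pd.DataFrame
    correlation_spectrum: pd.DataFrame
    paired_tests: pd.DataFrame
    crossmonth_tests: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "band_power": self.band_power,
            "band_correlations": self.band_correlations,
            "correlation_spectrum": self.correlation_spectrum,
            "paired_tests": self.paired_tests,
            "crossmonth_tests": self.crossmonth_tests,
        }

    def validate(self) -> None:
        for name, df in self.tables().items():
            for col in ("p", "p_adj"):
                if col in df.columns and len(df) and not (
                    df[col].dropna().between(0, 1).all()
                ):
                    raise ValueError(f"{name}: {col} outside [0, 1]")
            if "r" in df.columns and len(df) and not (
                df["r"].dropna().between(-1, 1).all()
            ):
                raise ValueError(f"{name}: r outside [-1, 1]")


_SORT_KEYS = {
    "band_power": ["participant", "month", "condition", "band", "component"],
    "band_correlations": ["subset", "condition", "band", "component", "grouping"],
    "correlation_spectrum": ["condition", "grouping", "freq_hz"],
    "paired_tests": ["month", "band", "component"],
    "crossmonth_tests": ["condition", "band", "months"],
}


def write_results(bundle: ResultBundle, out_dir: str | Path) -> dict:
    """Write all tables as CSV plus a JSON manifest with checksums.

    Row order and float formatting are fixed, so identical bundles
    produce byte-identical files.
    """
    bundle.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"metadata": bundle.metadata, "files": {}}
    for name, df in bundle.tables().items():
        if df is None or df.empty:
            continue
        keys = [k for k in _SORT_KEYS.get(name, []) if k in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
        fname = f"{name}.csv"
        fpath = out_dir / fname
        df.to_csv(fpath, index=False, float_format="%.10g")
        manifest["files"][fname] = hashlib.sha256(fpath.read_bytes()).hexdigest()
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True,
                                    default=str))
    manifest["files"]["run_metadata.json"] = hashlib.sha256(
        meta_path.read_bytes()
    ).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
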