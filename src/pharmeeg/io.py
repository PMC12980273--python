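"""Reading and writing of recordings and tabular artefacts.

The canonical interchange format is delimited text (comma separated,
UTF-8, ``.`` decimal): recordings are one file per 60-s sample with a
channel-per-column layout, and feature/score/posterior matrices are flat
tables with a small number of metadata columns in front.  EDF is
supported read-only for real acquisitions (via :mod:`mne`, optional
dependency).  Published score tables mix minus signs, en-dashes and in
places decimal commas, so the score-table reader normalises those
dialects instead of rejecting them.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

#: Canonical montage: frontal, parietal and occipital electrode pairs.
CHANNELS: tuple[str, ...] = ("FP1", "FP2", "C3", "C4", "O1", "O2")

#: Channel-region grouping used by drug signatures.
REGIONS: dict[str, tuple[str, str]] = {
    "frontal": ("FP1", "FP2"),
    "parietal": ("C3", "C4"),
    "occipital": ("O1", "O2"),
}

REGION_OF: dict[str, str] = {ch: reg for reg, chs in REGIONS.items() for ch in chs}

#: Metadata columns carried alongside feature/score values in tables.
META_COLUMNS: tuple[str, ...] = ("record_id", "animal_id", "group")

RECORDING_SCHEMA = "pharmeeg-recording v1"
EFFECT_SCHEMA = "pharmeeg-effect-matrix v1"

_DEFAULT_FS = 500.0
_MIN_DURATION_S = 5.0


@dataclass
class EcogRecording:
    """One fixed-rate multi-channel ECoG sample.

    Parameters
    ----------
    samples
        Channel x time array in microvolts, channels in canonical order.
    fs
        Sampling rate in Hz (500 by default).
    phase
        ``"pre"`` (immediately before injection) or ``"post"``
        (20 minutes after injection).
    """

    samples: np.ndarray
    fs: float = _DEFAULT_FS
    channels: tuple[str, ...] = CHANNELS
    phase: str = "pre"
    animal_id: str = ""
    group: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channels = tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[-1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> "EcogRecording":
        if self.samples.ndim != 2 or self.samples.shape[0] != len(CHANNELS):
            raise FormatError(
                f"recording {self.record_id!r}: expected {len(CHANNELS)} channel rows, "
                f"got array of shape {self.samples.shape}"
            )
        if self.channels != CHANNELS:
            raise FormatError(
                f"recording {self.record_id!r}: channels must be in canonical order "
                f"{CHANNELS}, got {self.channels}"
            )
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples).all(axis=0))[0])
            raise FormatError(
                f"recording {self.record_id!r}: non-finite sample at index {bad}"
            )
        if self.fs <= 0:
            raise FormatError(f"recording {self.record_id!r}: fs must be > 0, got {self.fs}")
        if self.duration_s < _MIN_DURATION_S:
            raise FormatError(
                f"recording {self.record_id!r}: duration {self.duration_s:.3f} s is "
                f"shorter than the minimum {_MIN_DURATION_S} s"
            )
        if self.phase not in ("pre", "post"):
            raise FormatError(
                f"recording {self.record_id!r}: phase must be 'pre' or 'post', got {self.phase!r}"
            )
        return self


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: EcogRecording, path: str | Path) -> Path:
    """Write a recording as delimited text with a commented metadata header."""
    rec.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {RECORDING_SCHEMA}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# phase={rec.phase}\n")
        fh.write(f"# animal_id={rec.animal_id}\n")
        fh.write(f"# group={rec.group}\n")
        fh.write(f"# record_id={rec.record_id}\n")
        df = pd.DataFrame(rec.samples.T, columns=list(rec.channels))
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    return path


def _parse_header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    *,
    expected_fs: float | None = None,
) -> EcogRecording:
    """Read a recording from delimited text or EDF.

    The channel labels in the file are mapped onto the canonical montage;
    a missing canonical channel is an error naming the missing label.
    ``expected_fs`` cross-checks the sampling rate declared by the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "text":
        rec = _read_text_recording(path)
    else:
        raise FormatError(f"{path}: unknown recording format {fmt!r}")
    if expected_fs is not None and abs(rec.fs - expected_fs) > 1e-9:
        raise FormatError(
            f"{path}: sampling rate {rec.fs} Hz does not match expected {expected_fs} Hz"
        )
    return rec.validate()


def _read_text_recording(path: Path) -> EcogRecording:
    meta = _parse_header_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse delimited recording: {exc}") from None
    cols = {c.strip().upper(): c for c in df.columns}
    for label in CHANNELS:
        if label not in cols:
            raise FormatError(f"{path}: missing channel {label!r} in header {list(df.columns)}")
    samples = np.column_stack([df[cols[label]].to_numpy(float) for label in CHANNELS]).T
    if not np.all(np.isfinite(samples)):
        row = int(np.flatnonzero(~np.isfinite(samples).all(axis=0))[0])
        raise FormatError(f"{path}: non-finite sample value at data row {row}")
    fs = float(meta.get("fs", _DEFAULT_FS))
    return EcogRecording(
        samples,
        fs=fs,
        phase=meta.get("phase", "pre"),
        animal_id=meta.get("animal_id", ""),
        group=meta.get("group", ""),
        record_id=meta.get("record_id", ""),
    )


def _read_edf(path: Path) -> EcogRecording:
    try:
        import mne
    except ImportError:
        raise FormatError(
            f"{path}: reading EDF requires the optional 'mne' dependency "
            "(pip install pharmeeg[edf])"
        ) from None
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = {name.strip().upper(): name for name in raw.ch_names}
    for label in CHANNELS:
        if label not in labels:
            raise FormatError(f"{path}: missing channel {label!r} in EDF montage {raw.ch_names}")
    data = raw.get_data(picks=[labels[label] for label in CHANNELS]) * 1e6  # V -> uV
    return EcogRecording(np.asarray(data, float), fs=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# effect matrices


def write_effect_matrix(effects: pd.DataFrame, path: str | Path) -> Path:
    """Write an effect matrix (one row per paired administration).

    The frame must carry the metadata columns ``record_id``, ``animal_id``
    and ``group`` followed by the named ratio features (schema
    ``channel|entity|metric``, e.g. ``FP1|delta|mean_power``).
    """
    _check_meta_columns(effects, "effect matrix")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {EFFECT_SCHEMA}\n")
        effects.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_effect_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"effect matrix not found: {path}")
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise FormatError(f"{path}: effect matrix is empty")
    _check_meta_columns(df, str(path))
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    values = df[feature_cols]
    if not np.all(np.isfinite(values.to_numpy(float))):
        bad = values.columns[~np.isfinite(values.to_numpy(float)).all(axis=0)][0]
        raise FormatError(f"{path}: non-finite value in feature column {bad!r}")
    return df


def _check_meta_columns(df: pd.DataFrame, what: str) -> None:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing metadata column(s) {missing}")


# ---------------------------------------------------------------------------
# score tables

_DASHES = {
    "−": "-",  # minus sign
    "–": "-",  # en dash
    "—": "-",  # em dash
    " ": " ",  # no-break space
}

_PC_PATTERN = re.compile(r"^PC\s*0*(\d+)", re.IGNORECASE)


def _normalise_text(text: str) -> str:
    for src, dst in _DASHES.items():
        text = text.replace(src, dst)
    return text


def _to_float(cell: object, *, row: int, column: str, path: str) -> float:
    if isinstance(cell, (int, float, np.integer, np.floating)):
        return float(cell)
    s = _normalise_text(str(cell)).strip()
    if "," in s and "." not in s:
        s = s.replace(",", ".")  # decimal-comma locale
    s = s.replace(" ", "")
    try:
        return float(s)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric score cell {cell!r} at row {row}, column {column!r}"
        ) from None


def read_score_table(
    path: str | Path,
    *,
    sep: str | None = None,
    group_col: str | None = None,
    record_col: str | None = None,
    animal_col: str | None = None,
) -> pd.DataFrame:
    """Read a PC-score table into the canonical layout.

    Returns a frame with columns ``record_id``, ``animal_id``, ``group``
    and ``PC1..PCk``.  Number parsing is locale tolerant (decimal commas,
    Unicode minus signs and en-dashes are accepted); the column mapping is
    configurable because published layouts vary.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"score table not found: {path}")
    text = path.read_text(encoding="utf-8")
    # strip full-line comments only: cell values such as animal id "#63"
    # legitimately contain the hash character
    text = "\n".join(ln for ln in text.splitlines() if not ln.lstrip().startswith("#"))
    try:
        if sep is None:
            df = pd.read_csv(_stdio.StringIO(text), sep=None, engine="python")
        else:
            df = pd.read_csv(_stdio.StringIO(text), sep=sep)
    except Exception as exc:
        raise FormatError(f"{path}: could not parse score table: {exc}") from None
    if df.empty:
        raise FormatError(f"{path}: score table is empty")
    df.columns = [str(c).strip() for c in df.columns]

    pc_cols: dict[int, str] = {}
    for col in df.columns:
        m = _PC_PATTERN.match(_normalise_text(col))
        if m:
            pc_cols[int(m.group(1))] = col
    if not pc_cols:
        raise FormatError(f"{path}: no PC columns found in header {list(df.columns)}")
    ks = sorted(pc_cols)
    if ks != list(range(1, len(ks) + 1)):
        raise FormatError(f"{path}: PC columns are not contiguous from PC1: {ks}")

    def pick(explicit: str | None, candidates: Sequence[str]) -> str | None:
        if explicit is not None:
            if explicit not in df.columns:
                raise FormatError(f"{path}: column {explicit!r} not present")
            return explicit
        lowered = {c.lower(): c for c in df.columns}
        for cand in candidates:
            if cand in lowered:
                return lowered[cand]
        return None

    rec = pick(record_col, ("record_id", "record", "record number", "id"))
    grp = pick(group_col, ("group", "class", "agent"))
    ani = pick(animal_col, ("animal_id", "animal", "rat"))

    out = pd.DataFrame()
    out["record_id"] = (
        df[rec].astype(str).str.strip() if rec is not None else [f"r{i}" for i in range(len(df))]
    )
    out["animal_id"] = df[ani].astype(str).str.strip() if ani is not None else ""
    out["group"] = df[grp].astype(str).str.strip() if grp is not None else ""
    for k in ks:
        col = pc_cols[k]
        out[f"PC{k}"] = [
            _to_float(v, row=i, column=col, path=str(path))
            for i, v in enumerate(df[col].tolist())
        ]
    if out["record_id"].duplicated().any():
        dup = out.loc[out["record_id"].duplicated(), "record_id"].iloc[0]
        raise FormatError(f"{path}: duplicate record id {dup!r}")
    return out


def write_score_table(scores: pd.DataFrame, path: str | Path) -> Path:
    _check_meta_columns(scores, "score table")
    path = Path(path)
    scores.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# posterior tables


def write_posterior_table(posteriors: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    posteriors.to_csv(path, index=False, lineterminator="\n")
    return path


def read_posterior_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"posterior table not found: {path}")
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise FormatError(f"{path}: posterior table is empty")
    class_cols = [c for c in df.columns if c not in META_COLUMNS]
    rows = df[class_cols].to_numpy(float)
    if np.any(rows < -1e-12) or np.any(rows > 1 + 1e-12):
        raise FormatError(f"{path}: posterior entries outside [0, 1]")
    sums = rows.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise FormatError(f"{path}: posterior row {bad} sums to {sums[bad]:.6f}, not 1")
    return df


def write_mps_table(mps: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    mps.to_csv(path, lineterminator="\n")
    return path


def read_mps_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"MPS table not found: {path}")
    return pd.read_csv(path, comment="#", index_col=0)
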