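"""Shared data model and file I/O.

Event-level cytometry data travel as :class:`EventTable` objects holding an
events x channels matrix on the analysis scale: fluorescence channels are
asinh-transformed (``asinh(x / cofactor)``, cofactor 150 by default) while the
scatter channels FSC-A, FSC-H and SSC-A stay linear. FCS files are assumed to
hold raw (linear, compensated) intensities and are transformed on read /
inverse-transformed on write; CSV event tables are the package's own fixture
format and store the analysis scale directly.

Per-sample clinical covariates travel as a plain pandas DataFrame (one row per
sample) validated by :func:`read_cohort_metadata`; the column dictionary is
documented in ``docs/methods.md``.
"""

from __future__ import annotations

import io as _stdlib_io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import FCSFormatError, read_fcs, write_fcs

__all__ = [
    "ScaleTransform",
    "EventTable",
    "QCReport",
    "REQUIRED_GATING_CHANNELS",
    "DIAGNOSIS_GROUPS",
    "read_event_table",
    "write_event_table",
    "read_cohort_metadata",
    "validate_sample",
]

#: Channels the gating tree consumes; PLP1 is optional (second tissue marker).
REQUIRED_GATING_CHANNELS = (
    "FSC-A", "FSC-H", "SSC-A", "CD45", "HLA-DR", "CD300e", "CD14", "CD16", "GFAP",
)

DIAGNOSIS_GROUPS = (
    "WHO-I", "diffuse-astrocytoma", "oligodendroglioma", "GBM", "metastasis",
    "other-tumour", "healthy", "AIS",
)

DEFAULT_MIN_EVENTS = 20_000


@dataclass(frozen=True)
class ScaleTransform:
    """asinh transform for fluorescence; scatter channels stay linear."""

    cofactor: float = 150.0
    linear_channels: tuple[str, ...] = ("FSC-A", "FSC-H", "SSC-A")

    def apply(self, channels: list[str], values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=np.float64, copy=True)
        for j, name in enumerate(channels):
            if name not in self.linear_channels:
                out[:, j] = np.arcsinh(out[:, j] / self.cofactor)
        return out

    def invert(self, channels: list[str], values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=np.float64, copy=True)
        for j, name in enumerate(channels):
            if name not in self.linear_channels:
                out[:, j] = np.sinh(out[:, j]) * self.cofactor
        return out


DEFAULT_TRANSFORM = ScaleTransform()


@dataclass
class EventTable:
    """One sample's events x channels intensity matrix (analysis scale)."""

    sample_id: str
    channels: list[str]
    values: np.ndarray
    truth_labels: np.ndarray | None = None  # simulator only
    truth_gfap: np.ndarray | None = None
    truth_plp1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[0] < 1:
            raise ValueError("EventTable needs at least one event")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel list does not match value columns")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all event values must be finite")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"missing channel {name}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]


@dataclass
class QCReport:
    """Named quality flags for one sample; usable iff no flags."""

    sample_id: str
    n_events: int
    n_events_after_cleanup: int
    flags: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return not self.flags


def read_event_table(
    path: str | Path,
    format: str | None = None,
    transform: ScaleTransform = DEFAULT_TRANSFORM,
    sample_id: str | None = None,
) -> EventTable:
    """Read an event table from an FCS 3.0/3.1 or CSV file.

    FCS values are transformed onto the analysis scale; CSV files already hold
    it. Missing gating channels are not an error here (validated later).
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if not path.exists():
        raise FileNotFoundError(path)
    sid = sample_id or path.stem
    if format == "fcs":
        channels, values, kw = read_fcs(path)
        values = transform.apply(channels, values)
        return EventTable(kw.get("TIMASCAN_SAMPLE_ID", sid), channels, values)
    if format == "csv":
        if path.stat().st_size == 0:
            raise FCSFormatError("CSV: empty file")
        df = pd.read_csv(path)
        if df.shape[0] < 1:
            raise FCSFormatError("CSV: no event rows")
        truth = None
        if "truth_label" in df.columns:
            truth = df.pop("truth_label").to_numpy(dtype=object)
        tg = df.pop("truth_gfap").to_numpy(bool) if "truth_gfap" in df.columns else None
        tp = df.pop("truth_plp1").to_numpy(bool) if "truth_plp1" in df.columns else None
        return EventTable(sid, list(df.columns), df.to_numpy(dtype=np.float64),
                          truth_labels=truth, truth_gfap=tg, truth_plp1=tp)
    raise ValueError(f"unknown format {format!r}")


def write_event_table(
    table: EventTable,
    path: str | Path,
    format: str | None = None,
    transform: ScaleTransform = DEFAULT_TRANSFORM,
) -> Path:
    """Write an event table; round-trips with :func:`read_event_table`."""
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    sid = table.sample_id or path.stem
    if format == "fcs":
        raw = transform.invert(table.channels, table.values)
        return write_fcs(path, table.channels, raw,
                         extra_keywords={"TIMASCAN_SAMPLE_ID": sid})
    if format == "csv":
        df = pd.DataFrame(table.values, columns=table.channels)
        if table.truth_labels is not None:
            df["truth_label"] = table.truth_labels
        if table.truth_gfap is not None:
            df["truth_gfap"] = table.truth_gfap.astype(int)
        if table.truth_plp1 is not None:
            df["truth_plp1"] = table.truth_plp1.astype(int)
        df.to_csv(path, index=False)
        return path
    raise ValueError(f"unknown format {format!r}")


_NUMERIC_COLUMNS = {
    "age": float, "kps": float, "dexamethasone_dose": float,
    "tumour_diameter_1": float, "tumour_diameter_2": float, "tumour_diameter_3": float,
    "tumour_size": float, "wbc_count": float, "plasma_gfap": float,
    "os_months": float, "pfs_months": float,
    "hours_since_onset": float, "infarct_volume": float,
}


def read_cohort_metadata(path: str | Path | _stdlib_io.IOBase) -> pd.DataFrame:
    """Read and validate the per-sample clinical metadata CSV.

    Derives ``tumour_size`` as the arithmetic mean of the three recorded
    broadest tumour diameters when they are present.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "diagnosis_group" not in df.columns:
        raise ValueError("metadata must contain sample_id and diagnosis_group columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup}")
    unknown = set(df["diagnosis_group"].dropna()) - set(DIAGNOSIS_GROUPS)
    if unknown:
        raise ValueError(f"unknown diagnosis group(s): {sorted(unknown)}")
    if "patient_id" not in df.columns:
        df["patient_id"] = df["sample_id"]
    for col, typ in _NUMERIC_COLUMNS.items():
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(typ)
    for col in ("os_event", "pfs_event", "dexamethasone_use"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    for col in ("os_months", "pfs_months"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"negative survival time in {col}")
    diam = [f"tumour_diameter_{i}" for i in (1, 2, 3)]
    if all(c in df.columns for c in diam):
        have = df[diam].notna().all(axis=1)
        derived = df.loc[have, diam].mean(axis=1)
        if "tumour_size" not in df.columns:
            df["tumour_size"] = np.nan
        df.loc[have, "tumour_size"] = derived
    return df


def validate_sample(
    table: EventTable,
    min_events: int = DEFAULT_MIN_EVENTS,
    required_channels: tuple[str, ...] = REQUIRED_GATING_CHANNELS,
) -> QCReport:
    """Report (never raise) per-sample QC flags, in deterministic order."""
    flags: list[str] = []
    for ch in required_channels:
        if ch not in table.channels:
            flags.append(f"missing channel {ch}")
    if table.n_events < min_events:
        flags.append("too few events")
    return QCReport(table.sample_id, table.n_events, table.n_events, flags)
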