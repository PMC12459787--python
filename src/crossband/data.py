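"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import RegionAtlas


class InvalidDataError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ParcellatedRun:
    """TRs x regions matrix of parcel-mean BOLD for one run."""

    data: np.ndarray  # (n_tr, n_regions)
    region_labels: list[str]
    tr_seconds: float
    subject_id: str
    run_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise InvalidDataError("parcellated data must be a TRs x regions matrix with >= 1 row")
        if self.data.shape[1] != len(self.region_labels):
            raise InvalidDataError("column count does not match region_labels")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise InvalidDataError("region_labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise InvalidDataError("parcellated data contains non-finite values")
        if self.tr_seconds <= 0:
            raise InvalidDataError("tr_seconds must be positive")

    @property
    def n_tr(self) -> int:
        return self.data.shape[0]


@dataclass
class MotionTrace:
    """Per-TR framewise displacement in millimetres."""

    displacement_mm: np.ndarray

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.displacement_mm.ndim != 1:
            raise InvalidDataError("motion trace must be one-dimensional")
        if not np.all(np.isfinite(self.displacement_mm)):
            raise InvalidDataError("motion trace contains non-finite values")
        if np.any(self.displacement_mm < 0):
            raise InvalidDataError("motion trace must be nonnegative")

    def __len__(self) -> int:
        return len(self.displacement_mm)


@dataclass
class RawEEG:
    """Raw EEG channel vectors on a common sampling grid."""

    channels: dict[str, np.ndarray]
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidDataError("EEG sampling rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise InvalidDataError("all EEG channels must have equal length")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class RunRecord:
    """One simultaneous EEG-fMRI run: parcels + motion + raw EEG."""

    parcels: ParcellatedRun
    motion: MotionTrace
    eeg: RawEEG

    def __post_init__(self) -> None:
        if len(self.motion) != self.parcels.n_tr:
            raise InvalidDataError("motion trace length must equal run TR count")

    @property
    def subject_id(self) -> str:
        return self.parcels.subject_id

    @property
    def run_id(self) -> str:
        return self.parcels.run_id


@dataclass
class Dataset:
    """A multi-subject collection of runs sharing one atlas and TR."""

    runs: list[RunRecord]
    atlas: RegionAtlas
    has_alpha: dict[str, bool] = field(default_factory=dict)
    dataset_id: str = "A"

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for run in self.runs:
            if run.subject_id not in seen:
                seen.append(run.subject_id)
        return seen

    def runs_for(self, subject_id: str) -> list[RunRecord]:
        return [r for r in self.runs if r.subject_id == subject_id]

    @property
    def tr_seconds(self) -> float:
        return self.runs[0].parcels.tr_seconds
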