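"""Center-aligned sliding-window design matrices.

Each EEG point is predicted from 60 consecutive TRs of every region,
with the EEG target at the window's 30th TR (1-based): adjacent windows
overlap by 59 TRs, so a segment of T TRs yields T - 59 windows and the
first 29 / last 30 EEG points of the segment are never targets. Columns
are region-major, time-minor: column r*60 + tau is region r at window
offset tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data import InvalidDataError
from .qc import PreparedDataset, Segment

__all__ = ["WindowDataset", "build_windows", "assemble_design"]


@dataclass
class WindowDataset:
    """Stacked predictor windows with center-aligned EEG targets."""

    X: np.ndarray                 # (n_windows, n_regions * window_len)
    y: np.ndarray                 # targets in [0, 1]
    groups: np.ndarray            # subject id per window
    region_subset: list[str]
    window_len: int = 60
    center_pos: int = 30          # 1-based position of the predicted EEG point
    segment_ids: np.ndarray = field(default=None)  # provenance per window
    band: str = ""

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.region_subset) * self.window_len:
            raise InvalidDataError("column count must be window_len * n_regions")
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise InvalidDataError("X, y and groups must align")
        if self.segment_ids is None:
            self.segment_ids = np.zeros(len(self.y), dtype=int)

    @property
    def n_windows(self) -> int:
        return len(self.y)

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def region_columns(self, region: str) -> np.ndarray:
        """Column indices of one region's 60-TR block."""
        r = self.region_subset.index(region)
        return np.arange(r * self.window_len, (r + 1) * self.window_len)

    def columns_for(self, regions: list[str]) -> np.ndarray:
        return np.concatenate([self.region_columns(r) for r in regions])

    def subset(self, regions: list[str]) -> "WindowDataset":
        cols = self.columns_for(regions)
        return WindowDataset(
            X=self.X[:, cols], y=self.y, groups=self.groups,
            region_subset=list(regions), window_len=self.window_len,
            center_pos=self.center_pos, segment_ids=self.segment_ids,
            band=self.band)


def build_windows(segment: Segment, band: str, window_len: int = 60,
                  center_pos: int = 30,
                  region_indices: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Windows and targets for one segment: T - (window_len - 1) rows."""
    T = segment.n_tr
    if T < window_len:
        raise InvalidDataError(
            f"segment of {T} TRs is shorter than the {window_len}-TR window")
    fmri = segment.fmri if region_indices is None else segment.fmri[:, region_indices]
    # (n_windows, n_regions, window_len): row i covers TRs [i, i + window_len)
    wins = sliding_window_view(fmri, window_len, axis=0)
    n = wins.shape[0]
    X = np.ascontiguousarray(wins).reshape(n, -1)
    y = segment.targets[band][center_pos - 1: center_pos - 1 + n]
    return X, y


def assemble_design(prepared: PreparedDataset, region_subset: list[str] | None,
                    band: str, window_len: int = 60, center_pos: int = 30
                    ) -> WindowDataset:
    """Stack windows across all segments, runs and subjects.

    For the alpha band, subjects without a clear eyes-closed alpha rhythm
    (``has_alpha`` false) are excluded from the design entirely.
    """
    if region_subset is None:
        region_subset = list(prepared.region_labels)
    if not region_subset:
        raise InvalidDataError("region subset must be nonempty")
    label_pos = {name: i for i, name in enumerate(prepared.region_labels)}
    try:
        region_idx = np.array([label_pos[r] for r in region_subset])
    except KeyError as exc:
        raise InvalidDataError(f"region {exc.args[0]!r} not in dataset") from None

    X_parts, y_parts, g_parts, s_parts = [], [], [], []
    for si, seg in enumerate(prepared.segments):
        if band == "alpha" and not prepared.has_alpha.get(seg.subject_id, True):
            continue
        if seg.n_tr < window_len:
            continue
        X, y = build_windows(seg, band, window_len, center_pos, region_idx)
        X_parts.append(X)
        y_parts.append(y)
        g_parts.append(np.full(len(y), seg.subject_id, dtype=object))
        s_parts.append(np.full(len(y), si, dtype=int))
    if not X_parts:
        raise InvalidDataError(f"no usable segments for band {band!r}")
    return WindowDataset(
        X=np.vstack(X_parts), y=np.concatenate(y_parts),
        groups=np.concatenate(g_parts), region_subset=list(region_subset),
        window_len=window_len, center_pos=center_pos,
        segment_ids=np.concatenate(s_parts), band=band)
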