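"""TR-level quality control, segmentation and per-subject normalization.

Three criteria mark TRs unusable: framewise motion above 0.3 mm,
z-scored 40-52 Hz EEG power above 1 (broadband MR/muscle artifact), and
local outliers farther than 6 scaled MADs from the running median in a
1000-TR window (applied to delta and artifact-band power, not to alpha,
whose fast natural fluctuations would be flagged spuriously). The first
20 TRs of each run are always discarded. Retained data is split into
contiguous segments (>= 60 TRs, the window length) so that no predictor
window spans a masked gap; fMRI is then z-scored and the EEG target
rescaled to 0-1, both within subject so held-out subjects never touch
training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bandpower import BANDS, PowerSeries, run_band_power
from .data import Dataset, InvalidDataError, MotionTrace, RunRecord
from .atlas import RegionAtlas

__all__ = [
    "QCConfig", "QCMask", "Segment", "PreparedDataset",
    "mask_motion", "mask_hf_power", "mask_mad_outliers", "mask_missing",
    "combine_masks", "apply_masks_and_segment", "zscore_regions",
    "rescale_eeg", "prepare_dataset",
]

MAD_SCALE = 1.4826  # scaled MAD: consistent estimator of the SD under normality


@dataclass
class QCConfig:
    motion_threshold_mm: float = 0.3
    hf_z_threshold: float = 1.0
    hf_z_overrides: dict[str, float] = field(default_factory=dict)  # run_id -> threshold
    mad_window_tr: int = 1000
    mad_n: float = 6.0
    min_segment_len: int = 60
    initial_discard: int = 20
    zscore_scope: str = "subject"  # or "run"


@dataclass
class QCMask:
    """Per-TR bad flags with one boolean vector per reason code."""

    bad: np.ndarray
    reasons: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bad = np.asarray(self.bad, dtype=bool)
        for name, vec in self.reasons.items():
            vec = np.asarray(vec, dtype=bool)
            if len(vec) != len(self.bad):
                raise InvalidDataError(f"reason {name!r} length mismatch")
            if np.any(vec & ~self.bad):
                raise InvalidDataError(f"reason {name!r} set on a good TR")
            self.reasons[name] = vec

    def __len__(self) -> int:
        return len(self.bad)


@dataclass
class Segment:
    """A contiguous artifact-free stretch of one run."""

    subject_id: str
    run_id: str
    start: int                      # TR index within the run
    fmri: np.ndarray                # (n_tr, n_regions)
    targets: dict[str, np.ndarray]  # band -> per-TR EEG power

    @property
    def n_tr(self) -> int:
        return self.fmri.shape[0]

    @property
    def stop(self) -> int:
        return self.start + self.n_tr


@dataclass
class PreparedDataset:
    """Cleaned, segmented, normalized data ready for window assembly."""

    segments: list[Segment]
    atlas: RegionAtlas
    region_labels: list[str]
    tr_seconds: float
    has_alpha: dict[str, bool]
    dataset_id: str = "A"

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for seg in self.segments:
            if seg.subject_id not in seen:
                seen.append(seg.subject_id)
        return seen

    def segments_for(self, subject_id: str) -> list[Segment]:
        return [s for s in self.segments if s.subject_id == subject_id]


# ---------------------------------------------------------------------------
# individual criteria

def mask_motion(motion: MotionTrace, threshold_mm: float = 0.3) -> QCMask:
    """Criterion 1: displacement strictly above the threshold."""
    if threshold_mm < 0:
        raise InvalidDataError("motion threshold must be nonnegative")
    bad = motion.displacement_mm > threshold_mm
    return QCMask(bad=bad, reasons={"motion": bad})


def mask_hf_power(artifact_series: np.ndarray, z_threshold: float = 1.0) -> QCMask:
    """Criterion 2: z-scored 40-52 Hz power above the threshold (within run)."""
    x = np.asarray(artifact_series, dtype=float)
    valid = np.isfinite(x)
    sd = np.nanstd(x[valid], ddof=1) if valid.sum() > 1 else 0.0
    if sd == 0:
        warnings.warn("artifact-band power has zero variance; nothing masked")
        bad = np.zeros(len(x), dtype=bool)
    else:
        z = (x - np.nanmean(x[valid])) / sd
        bad = np.zeros(len(x), dtype=bool)
        bad[valid] = z[valid] > z_threshold
    return QCMask(bad=bad, reasons={"hf_power": bad})


def _rolling_median_mad(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered running median and scaled MAD, window truncated at edges."""
    n = len(x)
    med = np.empty(n)
    mad = np.empty(n)
    half = window // 2
    lo_edge = min(half, n)
    hi_edge = max(n - (window - half) + 1, lo_edge)
    if n >= window:
        segs = sliding_window_view(x, window)  # rows i -> x[i : i + window]
        interior_med = np.nanmedian(segs, axis=1)
        interior_mad = MAD_SCALE * np.nanmedian(
            np.abs(segs - interior_med[:, None]), axis=1)
        # window centered at i covers [i - half, i - half + window)
        med[half: half + len(interior_med)] = interior_med
        mad[half: half + len(interior_mad)] = interior_mad
    edge_idx = [i for i in range(n) if i < half or i - half >= max(n - window + 1, 0)]
    for i in edge_idx:
        w = x[max(i - half, 0): min(i - half + window, n)]
        m = np.nanmedian(w)
        med[i] = m
        mad[i] = MAD_SCALE * np.nanmedian(np.abs(w - m))
    return med, mad


def mask_mad_outliers(series: np.ndarray, window_tr: int = 1000,
                      n_mad: float = 6.0) -> QCMask:
    """Criterion 3: |x - local median| > n_mad * local scaled MAD.

    Windows are centered and truncated at the run edges. If the local MAD
    is zero (constant window) nothing is masked there.
    """
    if window_tr < 3:
        raise InvalidDataError("MAD window must be >= 3 TRs")
    x = np.asarray(series, dtype=float)
    med, mad = _rolling_median_mad(x, min(window_tr, max(len(x), 3)))
    with np.errstate(invalid="ignore"):
        bad = (np.abs(x - med) > n_mad * mad) & (mad > 0)
    bad &= np.isfinite(x)
    return QCMask(bad=bad, reasons={"mad_outlier": bad})


def mask_missing(*series: np.ndarray) -> QCMask:
    """TRs where any required power series is undefined (outside EEG support)."""
    bad = np.zeros(len(series[0]), dtype=bool)
    for s in series:
        bad |= ~np.isfinite(np.asarray(s, dtype=float))
    return QCMask(bad=bad, reasons={"missing": bad})


def combine_masks(masks: list[QCMask], initial_discard: int = 20) -> QCMask:
    n = len(masks[0])
    bad = np.zeros(n, dtype=bool)
    reasons: dict[str, np.ndarray] = {}
    init = np.zeros(n, dtype=bool)
    init[: min(initial_discard, n)] = True
    bad |= init
    reasons["initial_discard"] = init
    for m in masks:
        if len(m) != n:
            raise InvalidDataError("masks must have equal length")
        bad |= m.bad
        for name, vec in m.reasons.items():
            reasons[name] = reasons.get(name, np.zeros(n, dtype=bool)) | vec
    return QCMask(bad=bad, reasons=reasons)


# ---------------------------------------------------------------------------
# segmentation and normalization

def apply_masks_and_segment(run: RunRecord, mask: QCMask,
                            band_targets: dict[str, np.ndarray],
                            min_len: int = 60) -> list[Segment]:
    """Split the retained TRs into maximal contiguous clean segments.

    Segments shorter than ``min_len`` (the predictor window length) are
    discarded; keeping them would create windows spanning masked gaps.
    """
    n = run.parcels.n_tr
    if len(mask) != n:
        raise InvalidDataError("mask length must equal run TR count")
    good = ~mask.bad
    segments: list[Segment] = []
    i = 0
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        while j < n and good[j]:
            j += 1
        if j - i >= min_len:
            segments.append(Segment(
                subject_id=run.subject_id, run_id=run.run_id, start=i,
                fmri=run.parcels.data[i:j].copy(),
                targets={b: np.asarray(v[i:j], dtype=float)
                         for b, v in band_targets.items()},
            ))
        i = j
    return segments


def zscore_regions(segments: list[Segment], scope: str = "subject") -> list[Segment]:
    """Z-score each region over the retained TRs, within subject (or run).

    Uses the sample (n-1) SD. Zero-variance regions are left at zero with
    a warning rather than producing NaNs.
    """
    if scope not in ("subject", "run"):
        raise InvalidDataError("scope must be 'subject' or 'run'")
    key = (lambda s: s.subject_id) if scope == "subject" else (lambda s: (s.subject_id, s.run_id))
    groups: dict[object, list[Segment]] = {}
    for seg in segments:
        groups.setdefault(key(seg), []).append(seg)
    out: list[Segment] = []
    for segs in groups.values():
        stacked = np.vstack([s.fmri for s in segs])
        if stacked.shape[0] < 2:
            raise InvalidDataError("need >= 2 retained TRs to z-score")
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0, ddof=1)
        zero = sd == 0
        if np.any(zero):
            warnings.warn(f"{int(zero.sum())} zero-variance regions left at 0")
            sd = np.where(zero, 1.0, sd)
        for s in segs:
            z = (s.fmri - mean) / sd
            z[:, zero] = 0.0
            out.append(Segment(s.subject_id, s.run_id, s.start, z, dict(s.targets)))
    by_key = {(s.subject_id, s.run_id, s.start): s for s in out}
    return [by_key[(s.subject_id, s.run_id, s.start)] for s in segments]


def rescale_eeg(segments: list[Segment], band: str) -> list[Segment]:
    """Min-max rescale the band target to [0, 1] per subject, across all
    retained segments of that subject."""
    groups: dict[str, list[Segment]] = {}
    for seg in segments:
        groups.setdefault(seg.subject_id, []).append(seg)
    for segs in groups.values():
        allvals = np.concatenate([s.targets[band] for s in segs])
        lo, hi = np.min(allvals), np.max(allvals)
        if hi == lo:
            raise InvalidDataError(
                f"constant {band} target for subject {segs[0].subject_id}")
        for s in segs:
            s.targets[band] = (s.targets[band] - lo) / (hi - lo)
    return segments


# ---------------------------------------------------------------------------
# full preparation

def prepare_dataset(dataset: Dataset, qc: QCConfig | None = None,
                    bands: dict[str, tuple[float, float]] | None = None,
                    power_cache: dict | None = None) -> PreparedDataset:
    """Band power -> masks -> segments -> normalization, for a whole dataset.

    ``power_cache`` maps (subject_id, run_id) to a precomputed band-power
    dict, letting callers skip the spectrogram stage on repeated runs.
    """
    qc = qc or QCConfig()
    bands = bands or BANDS
    raw_segments: list[Segment] = []
    for run in dataset.runs:
        n = run.parcels.n_tr
        tr_times = np.arange(n) * run.parcels.tr_seconds
        key = (run.subject_id, run.run_id)
        if power_cache is not None and key in power_cache:
            power = power_cache[key]
        else:
            power = run_band_power(run.eeg, tr_times, bands=bands)
            if power_cache is not None:
                power_cache[key] = power
        art = power["artifact"].values
        hf_thresh = qc.hf_z_overrides.get(run.run_id, qc.hf_z_threshold)
        masks = [
            mask_motion(run.motion, qc.motion_threshold_mm),
            mask_hf_power(art, hf_thresh),
            mask_mad_outliers(power["delta"].values, qc.mad_window_tr, qc.mad_n),
            mask_mad_outliers(art, qc.mad_window_tr, qc.mad_n),
            mask_missing(*(power[b].values for b in bands)),
        ]
        mask = combine_masks(masks, qc.initial_discard)
        band_targets = {b: power[b].values for b in bands if b != "artifact"}
        raw_segments.extend(apply_masks_and_segment(run, mask, band_targets,
                                                    qc.min_segment_len))
    segments = zscore_regions(raw_segments, scope=qc.zscore_scope)
    for band in (b for b in bands if b != "artifact"):
        segments = rescale_eeg(segments, band)
    return PreparedDataset(
        segments=segments, atlas=dataset.atlas,
        region_labels=list(dataset.runs[0].parcels.region_labels),
        tr_seconds=dataset.tr_seconds, has_alpha=dict(dataset.has_alpha),
        dataset_id=dataset.dataset_id,
    )
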