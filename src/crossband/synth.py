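"""Synthetic coupled EEG-fMRI data with planted network structure.

The generator emulates the statistical structure the decoding pipeline
assumes: slow latent vigilance processes (AR(1), time constants of
seconds to tens of seconds) drive both occipital EEG band power and
HRF-convolved regional BOLD. Alpha power is driven by two separable
latents (an arousal-like one expressed in subcortical parcels and a
visual-like one expressed in occipital cortex); delta power is driven by
a systemic latent expressed diffusely in cortex and mirrored in
non-gray-matter parcels. Subject-specific gains, region noise, motion
spikes and 45 Hz EEG bursts provide realistic nuisance structure, and
the ground truth (latents, memberships, artifact locations) is returned
so every downstream stage can be validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps
from scipy import stats

from .atlas import RegionAtlas, default_atlas, synthetic_atlas
from .data import Dataset, InvalidDataError, MotionTrace, ParcellatedRun, RawEEG, RunRecord

__all__ = [
    "LatentSpec", "NetworkSpec", "NoiseSpec", "ArtifactSpec", "SimConfig",
    "SyntheticGroundTruth", "canonical_hrf", "simulate_latents",
    "generate_run", "generate_dataset", "default_config", "scaled_config",
    "alpha_network_config", "delta_diffuse_config", "pruning_config",
]


@dataclass
class LatentSpec:
    """AR(1) latent: time constant in seconds and stationary variance."""

    tau_s: float
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise InvalidDataError("latent time constant must be positive")
        if self.variance < 0:
            raise InvalidDataError("latent variance must be nonnegative")


@dataclass
class NetworkSpec:
    """A named set of regions coupled to one latent with a common gain."""

    regions: list[str]
    latent: str
    gain: float = 1.0


@dataclass
class NoiseSpec:
    region_noise_sd: float = 1.0
    eeg_broadband_sd: float = 1.0


@dataclass
class ArtifactSpec:
    """Rates (per minute) and magnitudes of planted artifacts."""

    motion_rate_per_min: float = 1.0
    motion_magnitude_mm: float = 0.5  # exceeds the 0.3 mm mask threshold
    eeg_burst_rate_per_min: float = 0.5
    eeg_burst_amplitude: float = 8.0
    eeg_burst_duration_s: float = 1.0


@dataclass
class SimConfig:
    n_subjects: int = 10
    runs_per_subject: int = 1
    run_length_tr: int = 3000
    tr_seconds: float = 0.378
    eeg_fs: float = 250.0
    n_regions_per_class: dict[str, int] = field(
        default_factory=lambda: {"cortical": 62, "subcortical": 14, "nongray": 8})
    network_spec: dict[str, NetworkSpec] = field(default_factory=dict)
    latent_params: dict[str, LatentSpec] = field(default_factory=dict)
    alpha_weights: dict[str, float] = field(default_factory=dict)
    delta_weights: dict[str, float] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subject_gain_sd: float = 0.2
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    alpha_power_base: float = 3.0
    delta_power_base: float = 3.0
    power_floor: float = 0.2
    # EEG-side variability invisible to fMRI (sets the decoding ceiling)
    eeg_power_private_sd: float = 0.6
    eeg_power_private_tau_s: float = 6.0
    hrf_extra_lag_s: float = 0.0  # EEG->BOLD lag beyond the canonical HRF
    p_no_alpha: float = 0.0
    seed: int = 0
    atlas: RegionAtlas | None = None

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.runs_per_subject) < 1:
            raise InvalidDataError("subject and run counts must be >= 1")
        if self.run_length_tr < 120:
            raise InvalidDataError("run_length_tr must be >= 120")
        if self.tr_seconds <= 0:
            raise InvalidDataError("tr_seconds must be positive")
        if self.eeg_fs < 4 * 52.0:
            raise InvalidDataError("eeg_fs must be >= 208 Hz to resolve the 40-52 Hz band")
        if self.noise.region_noise_sd < 0 or self.noise.eeg_broadband_sd < 0:
            raise InvalidDataError("noise SDs must be nonnegative")
        if self.atlas is None:
            self.atlas = synthetic_atlas(
                self.n_regions_per_class.get("cortical", 0),
                self.n_regions_per_class.get("subcortical", 0),
                self.n_regions_per_class.get("nongray", 0),
            )
        names = set(self.atlas.names)
        for net_name, net in self.network_spec.items():
            unknown = set(net.regions) - names
            if unknown:
                raise InvalidDataError(
                    f"network {net_name!r} references unknown regions: {sorted(unknown)}")
            if net.latent not in self.latent_params:
                raise InvalidDataError(
                    f"network {net_name!r} references unknown latent {net.latent!r}")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    latents: dict[str, np.ndarray]          # (subject, run) key -> TRs x n_latents
    latent_names: list[str]
    memberships: dict[str, str]             # region -> network label
    subject_gains: dict[str, dict[str, float]]
    alpha_weights: dict[str, float]
    delta_weights: dict[str, float]
    artifact_tr_indices: dict[str, list[int]]
    has_alpha: dict[str, bool]

    def run_key(self, subject_id: str, run_id: str) -> str:
        return f"{subject_id}/{run_id}"

    def latent_mix(self, subject_id: str, run_id: str, band: str) -> np.ndarray:
        """The planted band-power drive (before clipping) for one run."""
        weights = self.alpha_weights if band == "alpha" else self.delta_weights
        gains = self.subject_gains[subject_id]
        lat = self.latents[self.run_key(subject_id, run_id)]
        mix = np.zeros(lat.shape[0])
        for name, w in weights.items():
            mix += w * gains[name] * lat[:, self.latent_names.index(name)]
        return mix


# ---------------------------------------------------------------------------
# primitives

def canonical_hrf(tr_seconds: float, duration_seconds: float = 30.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at TR spacing.

    Standard parameterization: response peak ~5 s (gamma shape 6, scale 1),
    undershoot ~15 s (shape 16, scale 1), undershoot ratio 1/6. Normalized
    to unit sum of absolute values so convolution preserves scale.
    """
    if tr_seconds <= 0:
        raise InvalidDataError("tr_seconds must be positive")
    if duration_seconds < tr_seconds:
        raise InvalidDataError("duration must be >= one TR")
    n = math.ceil(duration_seconds / tr_seconds)
    t = np.arange(n) * tr_seconds
    h = stats.gamma.pdf(t, a=6, scale=1.0) - stats.gamma.pdf(t, a=16, scale=1.0) / 6.0
    denom = np.sum(np.abs(h))
    if denom == 0:  # single-sample kernel at t=0
        h = np.zeros(n)
        h[0] = 1.0
        return h
    return h / denom


def simulate_latents(n_tr: int, tr_seconds: float,
                     latent_params: dict[str, LatentSpec],
                     rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) latents, one column per latent, unit-variance expectation."""
    if n_tr < 1:
        raise InvalidDataError("n_tr must be >= 1")
    out = np.empty((n_tr, len(latent_params)))
    for j, spec in enumerate(latent_params.values()):
        phi = math.exp(-tr_seconds / spec.tau_s)
        if spec.variance == 0:
            out[:, j] = 0.0
            continue
        sd = math.sqrt(spec.variance)
        innov = rng.standard_normal(n_tr) * sd * math.sqrt(1 - phi * phi)
        innov[0] = rng.standard_normal() * sd  # draw x0 from the stationary law
        out[:, j] = sps.lfilter([1.0], [1.0, -phi], innov)
    return out


def _clipped_power(base: float, mix: np.ndarray, floor: float) -> np.ndarray:
    return np.maximum(base + mix, floor)


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_run(config: SimConfig, subject_id: str, run_id: str,
                 subject_gains: dict[str, float], alpha_on: bool,
                 rng: np.random.Generator):
    """Simulate one run; returns (RunRecord, latents, artifact TR indices)."""
    n_tr = config.run_length_tr
    tr = config.tr_seconds
    atlas = config.atlas
    names = atlas.names
    latents = simulate_latents(n_tr, tr, config.latent_params, rng)
    latent_names = list(config.latent_params)

    # --- regional BOLD: HRF (x) sum of gain-weighted latents + noise -------
    neural = np.zeros((n_tr, len(names)))
    idx = {n: i for i, n in enumerate(names)}
    for net in config.network_spec.values():
        j = latent_names.index(net.latent)
        drive = net.gain * subject_gains[net.latent] * latents[:, j]
        for r in net.regions:
            neural[:, idx[r]] += drive
    hrf = canonical_hrf(tr)
    bold = sps.fftconvolve(neural, hrf[:, None], mode="full", axes=0)[:n_tr]
    lag_tr = int(round(config.hrf_extra_lag_s / tr))
    if lag_tr > 0:
        bold = np.vstack([np.zeros((lag_tr, bold.shape[1])), bold[:-lag_tr]])
    bold = bold + rng.standard_normal(bold.shape) * config.noise.region_noise_sd

    # --- motion trace with Poisson-placed spikes ---------------------------
    art = config.artifact_spec
    motion = np.abs(rng.standard_normal(n_tr) * 0.05)
    run_minutes = n_tr * tr / 60.0
    n_spikes = rng.poisson(art.motion_rate_per_min * run_minutes)
    spike_idx = np.sort(rng.choice(n_tr, size=min(n_spikes, n_tr), replace=False)) \
        if n_spikes else np.array([], dtype=int)
    motion[spike_idx] = art.motion_magnitude_mm

    # --- raw EEG -----------------------------------------------------------
    fs = config.eeg_fs
    n_samp = int(round(n_tr * tr * fs))
    t_eeg = np.arange(n_samp) / fs
    t_tr = np.arange(n_tr) * tr
    gains = subject_gains

    def mix_for(weights: dict[str, float]) -> np.ndarray:
        m = np.zeros(n_tr)
        for name, w in weights.items():
            m += w * gains[name] * latents[:, latent_names.index(name)]
        return m

    private = simulate_latents(
        n_tr, tr, {"pa": LatentSpec(config.eeg_power_private_tau_s),
                   "pd": LatentSpec(config.eeg_power_private_tau_s)}, rng
    ) * config.eeg_power_private_sd
    p_alpha = _clipped_power(config.alpha_power_base,
                             mix_for(config.alpha_weights) + private[:, 0],
                             config.power_floor)
    p_delta = _clipped_power(config.delta_power_base,
                             mix_for(config.delta_weights) + private[:, 1],
                             config.power_floor)
    amp_alpha = np.interp(t_eeg, t_tr, np.sqrt(p_alpha))
    amp_delta = np.interp(t_eeg, t_tr, np.sqrt(p_delta))
    if not alpha_on:
        amp_alpha = np.zeros_like(amp_alpha)

    phase = rng.uniform(0, 2 * np.pi)
    alpha_carrier = np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t_eeg + phase)
    delta_carrier = _bandlimited_noise(n_samp, fs, 1.1, 4.0, rng)

    n_bursts = rng.poisson(art.eeg_burst_rate_per_min * run_minutes)
    burst_tr_idx = np.sort(rng.choice(n_tr, size=min(n_bursts, n_tr), replace=False)) \
        if n_bursts else np.array([], dtype=int)
    burst = np.zeros(n_samp)
    blen = max(int(art.eeg_burst_duration_s * fs), 1)
    win = sps.windows.hann(blen)
    for k in burst_tr_idx:
        s0 = int(k * tr * fs)
        s1 = min(s0 + blen, n_samp)
        burst[s0:s1] += art.eeg_burst_amplitude * win[: s1 - s0] * np.sin(
            2 * np.pi * 45.0 * t_eeg[s0:s1])

    channels = {}
    for ch in ("O1", "O2", "Oz"):
        broadband = rng.standard_normal(n_samp) * config.noise.eeg_broadband_sd
        channels[ch] = (amp_alpha * alpha_carrier + amp_delta * delta_carrier
                        + broadband + burst)
    eeg = RawEEG(channels=channels, fs=fs, start_time=0.0)

    record = RunRecord(
        parcels=ParcellatedRun(bold, list(names), tr, subject_id, run_id),
        motion=MotionTrace(motion),
        eeg=eeg,
    )
    artifact_idx = sorted(set(spike_idx.tolist()) | set(burst_tr_idx.tolist()))
    return record, latents, artifact_idx


def generate_dataset(config: SimConfig) -> tuple[Dataset, SyntheticGroundTruth]:
    """Simulate the full multi-subject dataset; reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    latent_names = list(config.latent_params)
    memberships: dict[str, str] = {}
    for r in config.atlas.gray_regions:
        memberships[r] = "uninformative"
    for net_name, net in config.network_spec.items():
        for r in net.regions:
            if config.atlas.class_of(r) != "nongray":
                memberships[r] = net_name

    runs: list[RunRecord] = []
    truth = SyntheticGroundTruth(
        latents={}, latent_names=latent_names, memberships=memberships,
        subject_gains={}, alpha_weights=dict(config.alpha_weights),
        delta_weights=dict(config.delta_weights), artifact_tr_indices={},
        has_alpha={},
    )
    for s in range(config.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        gains = {name: max(0.1, 1.0 + rng.standard_normal() * config.subject_gain_sd)
                 for name in latent_names}
        if config.subject_gain_sd == 0:
            gains = {name: 1.0 for name in latent_names}
        truth.subject_gains[subject_id] = gains
        alpha_on = bool(rng.uniform() >= config.p_no_alpha)
        truth.has_alpha[subject_id] = alpha_on
        for r in range(config.runs_per_subject):
            run_id = f"run-{r + 1:02d}"
            record, latents, artifacts = generate_run(
                config, subject_id, run_id, gains, alpha_on, rng)
            runs.append(record)
            key = truth.run_key(subject_id, run_id)
            truth.latents[key] = latents
            truth.artifact_tr_indices[key] = artifacts
    dataset = Dataset(runs=runs, atlas=config.atlas, has_alpha=dict(truth.has_alpha))
    return dataset, truth


# ---------------------------------------------------------------------------
# configuration presets

_DEFAULT_LATENTS = {
    "arousal": LatentSpec(tau_s=8.0),
    "visual": LatentSpec(tau_s=12.0),
    "systemic": LatentSpec(tau_s=20.0),
}

# default planted structure on the 84-region atlas: a focal arousal-like
# alpha network in subcortex, a focal visual-like alpha network in occipital
# cortex, diffuse cortical delta loading and a systemic component mirrored
# in all non-gray parcels.
_AROUSAL_LABELS = ["thalamus", "caudate", "putamen", "pallidum"]
_VISUAL_LABELS = ["pericalcarine", "lateraloccipital", "cuneus", "lingual",
                  "fusiform", "precuneus"]
_DELTA_LABELS = ["superiorfrontal", "rostralmiddlefrontal", "caudalmiddlefrontal",
                 "precentral", "postcentral", "superiorparietal", "inferiorparietal",
                 "supramarginal", "superiortemporal", "middletemporal",
                 "inferiortemporal", "lateralorbitofrontal", "medialorbitofrontal",
                 "posteriorcingulate", "paracentral"]


def default_config(**overrides) -> SimConfig:
    """The full-scale default: 84 regions, 10 subjects, 3000 TRs."""
    atlas = default_atlas()
    networks = {
        "arousal": NetworkSpec(
            regions=[f"{h}h-{lab}" for lab in _AROUSAL_LABELS for h in ("l", "r")],
            latent="arousal", gain=1.5),
        "visual": NetworkSpec(
            regions=[f"ctx-{h}h-{lab}" for lab in _VISUAL_LABELS for h in ("l", "r")],
            latent="visual", gain=1.5),
        "delta_diffuse": NetworkSpec(
            regions=[f"ctx-{h}h-{lab}" for lab in _DELTA_LABELS for h in ("l", "r")],
            latent="systemic", gain=0.8),
        "systemic": NetworkSpec(
            regions=list(atlas.nongray_regions), latent="systemic", gain=1.2),
    }
    cfg = dict(
        atlas=atlas,
        n_regions_per_class={"cortical": 62, "subcortical": 14, "nongray": 8},
        network_spec=networks,
        latent_params=dict(_DEFAULT_LATENTS),
        alpha_weights={"arousal": 1.0, "visual": 0.8},
        delta_weights={"systemic": 1.0},
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def scaled_config(n_cortical: int = 10, n_subcortical: int = 4, n_nongray: int = 2,
                  n_visual: int = 6, **overrides) -> SimConfig:
    """Reduced-region analogue of the default structure for fast runs.

    All subcortical regions form the arousal-like network, the first
    ``n_visual`` cortical regions form the visual-like network, remaining
    cortical regions are uninformative; the systemic latent loads on half
    the uninformative cortex (diffusely, delta-style) and on all non-gray
    regions.
    """
    atlas = synthetic_atlas(n_cortical, n_subcortical, n_nongray)
    cortical = atlas.regions_of_class("cortical")
    subcortical = atlas.regions_of_class("subcortical")
    nongray = atlas.regions_of_class("nongray")
    visual = cortical[:n_visual]
    rest = cortical[n_visual:]
    delta_regions = rest[: max(len(rest) // 2, 1)]
    networks = {
        "arousal": NetworkSpec(regions=subcortical, latent="arousal", gain=1.5),
        "visual": NetworkSpec(regions=visual, latent="visual", gain=1.5),
        "delta_diffuse": NetworkSpec(regions=delta_regions, latent="systemic", gain=0.8),
    }
    if nongray:
        networks["systemic"] = NetworkSpec(regions=nongray, latent="systemic", gain=1.2)
    cfg = dict(
        atlas=atlas,
        n_regions_per_class={"cortical": n_cortical, "subcortical": n_subcortical,
                             "nongray": n_nongray},
        network_spec=networks,
        latent_params=dict(_DEFAULT_LATENTS),
        alpha_weights={"arousal": 1.0, "visual": 0.8},
        delta_weights={"systemic": 1.0},
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def alpha_network_config(n_arousal: int = 9, n_visual: int = 9,
                         n_uninformative: int = 2, bilateral: bool = False,
                         **overrides) -> SimConfig:
    """Planted two-network alpha structure for the network-recovery analysis.

    Arousal and visual latents each load on a focal set of regions; the
    remaining regions are uninformative. Clustering of pairwise
    performance benefits should recover the three groups. By default each
    region is its own analysis unit (midline singleton); pass
    ``bilateral=True`` for L/R-paired layouts.
    """
    n_cort = n_visual + n_uninformative
    n_sub = n_arousal
    atlas = synthetic_atlas(n_cort, n_sub, 0, bilateral=bilateral)
    cortical = atlas.regions_of_class("cortical")
    subcortical = atlas.regions_of_class("subcortical")
    visual = cortical[:n_visual]
    networks = {
        "arousal": NetworkSpec(regions=subcortical, latent="arousal", gain=1.5),
        "visual": NetworkSpec(regions=visual, latent="visual", gain=1.5),
    }
    cfg = dict(
        atlas=atlas,
        n_regions_per_class={"cortical": n_cort, "subcortical": n_sub, "nongray": 0},
        network_spec=networks,
        latent_params={"arousal": LatentSpec(8.0), "visual": LatentSpec(12.0)},
        alpha_weights={"arousal": 1.0, "visual": 1.0},
        delta_weights={},
        delta_power_base=3.0,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def delta_diffuse_config(n_gray: int = 20, n_nongray: int = 2,
                         bilateral: bool = False, **overrides) -> SimConfig:
    """One diffuse systemic latent loading on many regions (no subnetworks)."""
    n_cort = n_gray
    atlas = synthetic_atlas(n_cort, 0, n_nongray, bilateral=bilateral)
    cortical = atlas.regions_of_class("cortical")
    networks = {
        "delta_diffuse": NetworkSpec(regions=cortical, latent="systemic", gain=1.0),
    }
    if n_nongray:
        networks["systemic"] = NetworkSpec(
            regions=atlas.regions_of_class("nongray"), latent="systemic", gain=1.2)
    cfg = dict(
        atlas=atlas,
        n_regions_per_class={"cortical": n_cort, "subcortical": 0, "nongray": n_nongray},
        network_spec=networks,
        latent_params={"systemic": LatentSpec(20.0)},
        alpha_weights={},
        delta_weights={"systemic": 1.0},
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def pruning_config(n_informative: int = 10, n_noise: int = 74, **overrides) -> SimConfig:
    """A few informative regions in a sea of noise regions (spatial-scale test).

    Each informative region carries its own latent (all of them feeding the
    alpha target), so every informative region contributes unique
    predictive information and removing any one of them costs performance.
    """
    n_total = n_informative + n_noise
    atlas = synthetic_atlas(n_total, 0, 0, bilateral=False)
    cortical = atlas.regions_of_class("cortical")
    w = 1.0 / math.sqrt(n_informative)
    # one shared time constant: the HRF low-pass passes slower latents more
    # strongly, so mixed time constants would make regions unevenly decodable
    latents = {f"inf{i:02d}": LatentSpec(10.0) for i in range(n_informative)}
    networks = {
        f"net{i:02d}": NetworkSpec(regions=[cortical[i]], latent=f"inf{i:02d}",
                                   gain=2.0)
        for i in range(n_informative)
    }
    cfg = dict(
        atlas=atlas,
        n_regions_per_class={"cortical": n_total, "subcortical": 0, "nongray": 0},
        network_spec=networks,
        latent_params=latents,
        alpha_weights={name: w for name in latents},
        delta_weights={},
        # homogeneous informativeness: the retention analysis assumes every
        # informative region is distinctly informative in all subjects, and
        # an EEG target fully explained by the planted latents
        subject_gain_sd=0.1,
        eeg_power_private_sd=0.0,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
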