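"""Synthetic three-group paired-click ERP cohorts with known ground truth.

Emulates the study conditions of a P50 sensory-gating experiment on
first-episode schizophrenia (FESZ), ultra-high-risk (UHR) and healthy
control (HC) groups: 25/23/19 subjects, 80 click pairs per subject sampled
at 1000 Hz, epochs spanning -200...+1000 ms around the first click, the
second click at +500 ms.  Every downstream stage is testable against the
planted truth:

* P50-like bursts (Gaussian-windowed, peak ~50 ms after each click) are
  injected into designated "auditory" sources with per-group S1/S2
  amplitude distributions taken from published group means/SDs;
* cross-region coupling is planted by mixing shared trial-locked latent
  signals into both regions of each planted edge during the 30-90 ms
  post-click analysis windows, with per-group coupling strength;
* sensor data are ``lead_field @ sources`` plus white sensor noise; the
  trial-locked background of every source is 1/f-shaped so the averaged
  ERP retains realistic autocorrelation for the MI estimator;
* demographic and cognitive covariates are drawn from per-group normal
  distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .erp import EpochSet
from .inverse import LeadField

__all__ = [
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "generate_feature_covariates",
    "generate_lead_field",
    "generate_atlas",
    "connectivity_only_config",
    "default_planted_edges",
    "burst_template",
    "GROUPS",
]

GROUPS = ("FESZ", "UHR", "HC")

#: per-group (mean, SD) of the P50 amplitudes in microvolts
S1_AMP_DEFAULT = {"FESZ": (1.24, 0.58), "UHR": (1.13, 0.73), "HC": (1.30, 0.90)}
S2_AMP_DEFAULT = {"FESZ": (0.99, 0.61), "UHR": (0.67, 0.43), "HC": (0.74, 0.56)}

#: per-group (mean, SD) of demographics and the eight MCCB domain scores
COVARIATE_DEFAULT: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"FESZ": (25.09, 6.44), "UHR": (22.67, 5.38), "HC": (25.45, 2.90)},
    "education": {"FESZ": (12.74, 3.08), "UHR": (13.37, 3.12), "HC": (14.38, 3.14)},
    "SOPV": {"FESZ": (33.28, 9.22), "UHR": (36.96, 7.21), "HC": (41.68, 6.38)},
    "AVV": {"FESZ": (31.91, 10.63), "UHR": (39.53, 9.04), "HC": (47.79, 8.80)},
    "WMV": {"FESZ": (37.24, 10.01), "UHR": (40.70, 9.35), "HC": (44.84, 8.07)},
    "VBLV": {"FESZ": (39.12, 9.83), "UHR": (42.74, 10.08), "HC": (46.58, 9.34)},
    "VSLV": {"FESZ": (40.96, 13.77), "UHR": (44.04, 10.22), "HC": (43.89, 10.07)},
    "RPSV": {"FESZ": (34.32, 11.87), "UHR": (37.74, 9.21), "HC": (40.37, 10.16)},
    "SCV": {"FESZ": (30.80, 11.79), "UHR": (38.55, 7.90), "HC": (37.00, 11.06)},
    "OCV": {"FESZ": (35.22, 7.08), "UHR": (39.83, 6.02), "HC": (42.88, 6.40)},
}

#: male rate per group (MCCB subsample: 12/25, 11/23, 11/19)
GENDER_MALE_RATE_DEFAULT = {"FESZ": 12 / 25, "UHR": 11 / 23, "HC": 11 / 19}

#: default per-group coupling of auto-selected planted edges: patient groups
#: share elevated coupling relative to HC, so patient-vs-HC comparisons carry
#: signal while FESZ-vs-UHR does not.
PLANTED_STRENGTHS_DEFAULT = {"FESZ": 0.8, "UHR": 0.8, "HC": 0.1}
N_PLANTED_EDGES_DEFAULT = 5

# 40 cortical region base names (AAL-style), mirrored over hemispheres
_ROI_BASE_NAMES = [
    "Precentral gyrus", "Superior frontal gyrus", "Superior frontal gyrus, orbital part",
    "Middle frontal gyrus", "Middle frontal gyrus, orbital part",
    "Inferior frontal gyrus, triangular part", "Inferior frontal operculum",
    "Rolandic operculum", "Supplementary motor area", "Olfactory cortex",
    "Superior frontal gyrus, medial part", "Media orbitofrontal cortex",
    "Gyrus rectus", "Insula", "Anterior cingulate cortex", "Middle cingulate cortex",
    "Posterior cingulate cortex", "Hippocampus", "Parahippocampal gyrus", "Amygdala",
    "Calcarine cortex", "Cuneus", "Lingual gyrus", "Superior occipital gyrus",
    "Middle occipital gyrus", "Inferior occipital gyrus", "Fusiform gyrus",
    "Postcentral gyrus", "Superior parietal lobule", "Inferior parietal lobule",
    "Supramarginal gyrus", "Angular gyrus", "Precuneus", "Paracentral lobule",
    "Heschl gyrus", "Superior temporal gyrus", "Temporal pole, superior temporal gyrus",
    "Middle temporal gyrus", "Temporal pole, middle temporal gyrus",
    "Inferior temporal gyrus",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort (defaults = study conditions)."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"FESZ": 25, "UHR": 23, "HC": 19}
    )
    n_trials: int = 80
    fs: float = 1000.0
    n_sensors: int = 32
    n_rois: int = 80
    sources_per_roi: int = 1
    s1_amp_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(S1_AMP_DEFAULT)
    )
    s2_amp_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(S2_AMP_DEFAULT)
    )
    planted_edges: list[tuple[int, int, dict[str, float]]] | None = None
    # None selects N_PLANTED_EDGES_DEFAULT interhemispheric pairs among the
    # regions with the weakest vertex projection (see default_planted_edges),
    # keeping the connectivity manipulation spatially orthogonal to the
    # vertex-measured P50 amplitudes; [] plants nothing.
    noise_sd: float = 0.3          # trial-locked 1/f background per source
    latent_sd: float = 3.0         # scale of planted shared latents
    trial_noise_sd: float = 0.3    # per-trial white noise per source
    sensor_noise_sd: float = 1.0   # per-trial white noise per sensor (uV)
    burst_peak_ms: float = 50.0
    burst_sigma_ms: float = 8.0
    epoch_span_ms: tuple[float, float] = (-200.0, 1000.0)
    s2_offset_ms: float = 500.0
    auditory_rois: tuple[int, ...] | None = None  # None: nearest-to-vertex per hemisphere
    lead_field_kind: str = "spherical"            # or "gaussian"
    artifact_fraction: float = 0.0                # trials given a 500 uV spike
    covariate_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in COVARIATE_DEFAULT.items()}
    )
    gender_male_rate: dict[str, float] = field(
        default_factory=lambda: dict(GENDER_MALE_RATE_DEFAULT)
    )
    seed: int = 0

    @property
    def n_sources(self) -> int:
        return self.n_rois * self.sources_per_roi

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if self.n_trials <= 0 or self.n_sensors <= 0 or self.n_rois <= 0:
            raise ValueError("counts must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_rois % 2:
            raise ValueError("n_rois must be even (half per hemisphere)")
        if self.sources_per_roi < 1:
            raise ValueError("sources_per_roi must be >= 1")
        for i, j, strengths in self.planted_edges or []:
            if i >= self.n_rois or j >= self.n_rois or i < 0 or j < 0 or i == j:
                raise ValueError(f"planted edge ({i}, {j}) references invalid regions")
            for g, c in strengths.items():
                if g not in GROUPS:
                    raise ValueError(f"unknown group {g!r} in planted edge")
                if not 0 <= c <= 1:
                    raise ValueError("coupling strengths must lie in [0, 1]")
        if self.lead_field_kind not in ("spherical", "gaussian"):
            raise ValueError("lead_field_kind must be 'spherical' or 'gaussian'")


@dataclass
class SynthCohort:
    """Generated cohort: epochs, forward model, atlas, labels and truth."""

    epochs: list[EpochSet]
    lead_field: LeadField
    atlas: pd.DataFrame
    labels: list[str]
    covariates: pd.DataFrame
    truth: dict
    config: SynthConfig

    @property
    def subjects(self) -> list[str]:
        return [e.subject for e in self.epochs]

    @property
    def vertex_channels(self) -> list[int]:
        return list(self.truth["vertex_channels"])


def connectivity_only_config(seed: int = 0, **overrides) -> SynthConfig:
    """Cohort whose *only* group differences are the planted couplings.

    Every group draws amplitudes and covariates from the HC distributions,
    so demographic, cognitive and ERP features carry no group signal; the
    planted edges (patients coupled, HC not) remain the sole ground-truth
    difference.  Used to test that network features add discriminative
    information when connectivity genuinely differs.
    """
    cfg = SynthConfig(seed=seed, **overrides)
    cfg.s1_amp_mean_sd = {g: S1_AMP_DEFAULT["HC"] for g in GROUPS}
    cfg.s2_amp_mean_sd = {g: S2_AMP_DEFAULT["HC"] for g in GROUPS}
    cfg.covariate_params = {
        k: {g: v["HC"] for g in GROUPS} for k, v in COVARIATE_DEFAULT.items()
    }
    cfg.gender_male_rate = {g: GENDER_MALE_RATE_DEFAULT["HC"] for g in GROUPS}
    return cfg


def burst_template(t_ms: np.ndarray, peak_ms: float, sigma_ms: float) -> np.ndarray:
    """Unit-amplitude Gaussian burst centred ``peak_ms`` on a ms time axis."""
    t_ms = np.asarray(t_ms, dtype=np.float64)
    return np.exp(-0.5 * ((t_ms - peak_ms) / sigma_ms) ** 2)


def powerlaw_noise(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit SD per row."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _fibonacci_points(n: int, hemisphere_only: bool = False) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (upper half if requested)."""
    i = np.arange(n) + 0.5
    golden = (1 + 5**0.5) / 2
    z = 1 - i / n if hemisphere_only else 1 - 2 * i / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_atlas(n_rois: int = 80, sources_per_roi: int = 1) -> pd.DataFrame:
    """Region table: name, hemisphere, centroid source index, roi index."""
    half = n_rois // 2
    names, hemis = [], []
    for hemi in ("Left", "Right"):
        for r in range(half):
            base = (
                _ROI_BASE_NAMES[r]
                if n_rois == 80
                else f"Region {r + 1:03d}"
            )
            names.append(base)
            hemis.append(hemi)
    centroid = np.arange(n_rois) * sources_per_roi  # first source of each ROI
    return pd.DataFrame(
        {
            "roi": np.arange(n_rois),
            "name": names,
            "hemisphere": hemis,
            "centroid_source": centroid,
        }
    )


def generate_lead_field(config: SynthConfig, rng: np.random.Generator) -> LeadField:
    """Forward model with unit-norm columns.

    ``spherical``: sensors on the upper unit hemisphere, fixed-orientation
    dipoles on an inner shell (radius 0.8), homogeneous-medium dipole
    potentials — columns of neighbouring sources are correlated, as on a
    head.  ``gaussian``: i.i.d. random columns, for unit tests.
    """
    n_sen, n_src = config.n_sensors, config.n_sources
    if config.lead_field_kind == "gaussian":
        gain = rng.standard_normal((n_sen, n_src))
    else:
        sensors = _fibonacci_points(n_sen, hemisphere_only=True)
        # cortical shell under the sensor cap: radius 0.85, z in [0, 0.95]
        pts = _fibonacci_points(n_src, hemisphere_only=False)
        z = (pts[:, 2] + 1.0) / 2.0 * 0.95
        rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        src_pos = 0.85 * np.column_stack(
            [rho * np.cos(theta), rho * np.sin(theta), z]
        )
        moments = rng.standard_normal((n_src, 3))
        moments /= np.linalg.norm(moments, axis=1, keepdims=True)
        diff = sensors[:, None, :] - src_pos[None, :, :]  # sen x src x 3
        dist3 = np.linalg.norm(diff, axis=2) ** 3
        gain = (diff * moments[None, :, :]).sum(axis=2) / dist3
    gain = gain / np.linalg.norm(gain, axis=0, keepdims=True)
    names = [f"EEG{i:03d}" for i in range(n_sen)]
    return LeadField(gain=gain, sensor_names=names)


def _vertex_channels(config: SynthConfig, n_pick: int = 3) -> list[int]:
    """Indices of the channels nearest the vertex (highest z)."""
    if config.lead_field_kind == "gaussian":
        return list(range(min(n_pick, config.n_sensors)))
    sensors = _fibonacci_points(config.n_sensors, hemisphere_only=True)
    return [int(i) for i in np.argsort(-sensors[:, 2])[:n_pick]]


def _pick_auditory_rois(
    config: SynthConfig, gain_centered: np.ndarray, vertex: list[int], atlas: pd.DataFrame
) -> tuple[int, ...]:
    """One region per hemisphere whose centroid projects strongest to the vertex."""
    score = gain_centered[vertex].mean(axis=0)  # per source
    half = config.n_rois // 2
    chosen = []
    for lo, hi in ((0, half), (half, config.n_rois)):
        cols = atlas["centroid_source"].to_numpy()[lo:hi]
        chosen.append(int(lo + np.argmax(score[cols])))
    return tuple(chosen)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, lower: float
) -> np.ndarray:
    """Normal draws with values below ``lower`` clipped up (scores >= 0 etc.)."""
    return np.maximum(rng.normal(mean, sd, size), lower)


def generate_feature_covariates(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Demographics, gender flag and the eight MCCB scores per subject."""
    config.validate()
    for fld in ("age", "education"):
        if fld not in config.covariate_params:
            raise ValueError(f"covariate_params missing {fld!r}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FA]))
    rows = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        for key in config.covariate_params.values():
            if group not in key:
                raise ValueError(f"covariate_params missing group {group!r}")
        cols = {
            name: _truncated_normal(rng, *params[group], n, lower=0.0)
            for name, params in config.covariate_params.items()
        }
        gender = (rng.random(n) < config.gender_male_rate[group]).astype(int)
        for k in range(n):
            rows.append(
                {
                    "subject": f"{group}{k:03d}",
                    "group": group,
                    "gender": int(gender[k]),
                    **{name: float(col[k]) for name, col in cols.items()},
                }
            )
    return pd.DataFrame(rows)


def default_planted_edges(
    config: SynthConfig,
    gain_centered: np.ndarray,
    vertex: list[int],
    atlas: pd.DataFrame,
    n_edges: int = N_PLANTED_EDGES_DEFAULT,
    strengths: dict[str, float] | None = None,
) -> list[tuple[int, int, dict[str, float]]]:
    """Interhemispheric edges among the regions least visible at the vertex.

    Pairing the left- and right-hemisphere regions with the weakest
    vertex-channel projection keeps the planted connectivity manipulation
    spatially orthogonal to the vertex-measured P50 amplitudes.
    """
    if strengths is None:
        strengths = dict(PLANTED_STRENGTHS_DEFAULT)
    centroids = atlas["centroid_source"].to_numpy()
    score = np.abs(gain_centered[vertex].mean(axis=0))[centroids]
    half = config.n_rois // 2
    left = np.argsort(score[:half], kind="stable")[:n_edges]
    right = half + np.argsort(score[half:], kind="stable")[:n_edges]
    return [(int(l), int(r), dict(strengths)) for l, r in zip(left, right)]


def _subject_sources(
    config: SynthConfig,
    rng: np.random.Generator,
    group: str,
    amp_scale: float,
    t_ms: np.ndarray,
    auditory: tuple[int, ...],
    atlas: pd.DataFrame,
    planted_edges: list[tuple[int, int, dict[str, float]]],
) -> tuple[np.ndarray, float, float]:
    """Trial-locked source activity (sources x samples) for one subject."""
    n_src, n_samp = config.n_sources, t_ms.size
    sources = (
        config.noise_sd * powerlaw_noise(rng, (n_src, n_samp))
        if config.noise_sd > 0
        else np.zeros((n_src, n_samp))
    )

    m1, s1 = config.s1_amp_mean_sd[group]
    m2, s2 = config.s2_amp_mean_sd[group]
    a1 = float(max(rng.normal(m1, s1), 0.05)) if s1 > 0 else m1
    a2 = float(max(rng.normal(m2, s2), 0.02)) if s2 > 0 else m2
    burst = a1 * burst_template(t_ms, config.burst_peak_ms, config.burst_sigma_ms)
    burst = burst + a2 * burst_template(
        t_ms, config.s2_offset_ms + config.burst_peak_ms, config.burst_sigma_ms
    )
    centroids = atlas["centroid_source"].to_numpy()
    for roi in auditory:
        sources[centroids[roi]] += amp_scale * burst

    if planted_edges:
        windows = []
        for onset in (0.0, config.s2_offset_ms):
            mask = (t_ms >= onset + 30.0) & (t_ms <= onset + 90.0)
            idx = np.flatnonzero(mask)
            taper = np.hanning(idx.size)
            windows.append((idx, taper))
        for i, j, strengths in planted_edges:
            c = strengths.get(group, 0.0)
            if c <= 0:
                continue
            for idx, taper in windows:
                z = config.latent_sd * powerlaw_noise(rng, (idx.size,))
                for roi in (i, j):
                    sources[centroids[roi], idx] += c * z * taper
    return sources, a1, a2


def generate_cohort(config: SynthConfig | None = None) -> SynthCohort:
    """Generate a full synthetic cohort under the configured conditions.

    Same seed gives a bit-identical cohort.  The returned ``truth`` record
    stores everything planted: per-subject amplitudes, the planted edge
    list, the auditory regions, the amplitude calibration factor and the
    lead-field condition number.
    """
    if config is None:
        config = SynthConfig()
    config.validate()

    ss = np.random.SeedSequence(config.seed)
    ss_structure, ss_cov, ss_subjects = ss.spawn(3)
    rng_structure = np.random.default_rng(ss_structure)
    rng_cov = np.random.default_rng(ss_cov)

    atlas = generate_atlas(config.n_rois, config.sources_per_roi)
    lead_field = generate_lead_field(config, rng_structure)
    gain = lead_field.gain
    gain_centered = gain - gain.mean(axis=0, keepdims=True)

    vertex = _vertex_channels(config)
    planted_edges = (
        config.planted_edges
        if config.planted_edges is not None
        else default_planted_edges(config, gain_centered, vertex, atlas)
    )
    auditory = (
        config.auditory_rois
        if config.auditory_rois is not None
        else _pick_auditory_rois(config, gain_centered, vertex, atlas)
    )
    for roi in auditory:
        if not 0 <= roi < config.n_rois:
            raise ValueError(f"auditory region {roi} out of range")

    # calibrate so a unit source burst in the auditory regions appears as
    # ~1 uV on the average-referenced vertex-channel mean
    centroids = atlas["centroid_source"].to_numpy()
    combined = gain_centered[:, centroids[list(auditory)]].sum(axis=1)
    c = float(combined[vertex].mean())
    if abs(c) < 1e-9:
        raise ValueError("degenerate geometry: auditory sources invisible at vertex")
    amp_scale = 1.0 / c

    span0, span1 = config.epoch_span_ms
    n_samp = int(round((span1 - span0) * config.fs / 1000.0)) + 1
    t_ms = span0 + np.arange(n_samp) * 1000.0 / config.fs
    t0_idx = int(round(-span0 * config.fs / 1000.0))

    labels: list[str] = []
    epochs: list[EpochSet] = []
    s1_true, s2_true = [], []
    subject_rngs = iter(
        np.random.default_rng(s)
        for s in ss_subjects.spawn(sum(config.n_per_group.values()))
    )
    for group in GROUPS:
        for k in range(config.n_per_group.get(group, 0)):
            rng = next(subject_rngs)
            sources, a1, a2 = _subject_sources(
                config, rng, group, amp_scale, t_ms, auditory, atlas, planted_edges
            )
            clean = gain @ sources  # sensors x samples
            data = np.broadcast_to(
                clean, (config.n_trials, *clean.shape)
            ).astype(np.float32).copy()
            if config.trial_noise_sd > 0:
                trial_src = config.trial_noise_sd * rng.standard_normal(
                    (config.n_trials, config.n_sources, n_samp)
                )
                data += np.einsum("cs,tsn->tcn", gain, trial_src).astype(np.float32)
            if config.sensor_noise_sd > 0:
                data += (
                    config.sensor_noise_sd
                    * rng.standard_normal(data.shape)
                ).astype(np.float32)
            if config.artifact_fraction > 0:
                n_bad = int(round(config.artifact_fraction * config.n_trials))
                bad = rng.choice(config.n_trials, size=n_bad, replace=False)
                data[bad, 0, t0_idx + 300] += 500.0
            epochs.append(
                EpochSet(
                    data=data,
                    fs=config.fs,
                    t0_idx=t0_idx,
                    s2_offset_ms=config.s2_offset_ms,
                    ch_names=list(lead_field.sensor_names),
                    subject=f"{group}{k:03d}",
                )
            )
            labels.append(group)
            s1_true.append(a1)
            s2_true.append(a2)

    covariates = generate_feature_covariates(config, rng_cov)
    truth = {
        "s1_amp_true": np.array(s1_true),
        "s2_amp_true": np.array(s2_true),
        "planted_edges": list(planted_edges),
        "auditory_rois": tuple(auditory),
        "vertex_channels": vertex,
        "amp_scale": amp_scale,
        "lead_field_condition": lead_field.condition_number(),
    }
    return SynthCohort(
        epochs=epochs,
        lead_field=lead_field,
        atlas=atlas,
        labels=labels,
        covariates=covariates,
        truth=truth,
        config=config,
    )
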