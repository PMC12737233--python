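"""Synthetic GSTRIDE-like cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not foot biomechanics: four latent gait phenotypes with distinct
cadence/speed/stride-shape archetypes, correlated gait and clinical
features, and phenotype-specific fall-label mechanisms (a single planted
driver feature per phenotype acting through a logistic model whose
intercept is calibrated to the phenotype's target fall prevalence).

Stride waveforms are sums of event-locked Gaussian bumps positioned by the
gait-cycle phase fractions (heel-strike impact in vertical acceleration,
push-off peak in progression acceleration, swing lobe in sagittal angular
velocity), scaled by walking speed and foot clearance, with additive white
noise and per-stride timing jitter.  A scalar ``separation`` multiplier
scales every between-archetype mean difference; at 0 the archetypes
coincide, at high values downstream clustering recovers them cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import SignalConfig
from .types import FEATURE_COLUMNS, META_COLUMNS, CohortDataset, StrideWaveform

PHASE_NAMES = ("load", "foot_flat", "push", "swing")

#: Clinical score names drawn directly from archetype means (the remaining
#: features are derived from the generated strides).
CLINICAL_SCORES = ("gds", "frailty", "short_fes_i", "sppb", "gait_speed_4m", "tug_s")


@dataclass
class PhenotypeArchetype:
    """Parameters of one latent gait phenotype."""

    name: str
    cadence_mean: float  # strides/min
    step_speed_mean: float  # m/s
    stride_length_mean: float  # m
    clearance_mean: float  # m
    phase_fractions: tuple  # (load, foot_flat, push, swing), sum 1
    clinical_means: dict  # score name -> mean
    within_phenotype_sd: dict  # feature -> SD
    fall_driver: str
    driver_coefficient: float  # logistic slope per SD of the driver
    base_prevalence: float
    age_mean: float = 82.6
    height_mean: float = 1.60
    toe_off_angle_mean: float = -32.0  # deg
    heel_strike_angle_mean: float = 18.0  # deg
    stride_time_std_mean: float = 0.06  # s, subject-level timing variability
    width_factor: float = 1.0  # archetype bump-width signature
    amp_factor: float = 1.0  # archetype amplitude signature

    def __post_init__(self) -> None:
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: phase fractions must sum to 1")
        if any(v < 0 for v in self.within_phenotype_sd.values()):
            raise ValueError(f"{self.name}: SDs must be nonnegative")
        if not 0.0 <= self.base_prevalence <= 1.0:
            raise ValueError(f"{self.name}: base_prevalence must be in [0, 1]")


_DEFAULT_SD = {
    "cadence": 4.8,
    "step_speed": 0.16,
    "stride_length": 0.13,
    "clearance": 0.02,
    "phase": 0.015,
    "age": 6.0,
    "height": 0.07,
    "toe_off_angle": 4.0,
    "heel_strike_angle": 3.5,
    "stride_time_std": 0.022,
    "gds": 1.1,
    "frailty": 1.0,
    "short_fes_i": 4.2,
    "sppb": 1.9,
    "gait_speed_4m": 0.16,
    "tug_s": 4.0,
}


def _base_archetypes() -> list[PhenotypeArchetype]:
    """Archetype means anchored to the published cohort profiles of the four
    phenotypes (cadence/speed/stride length/SPPB/TUG/FES-I)."""
    sd = dict(_DEFAULT_SD)
    common = dict(within_phenotype_sd=sd)
    return [
        PhenotypeArchetype(
            name="high_cadence",
            cadence_mean=53.7,
            step_speed_mean=0.84,
            stride_length_mean=0.87,
            clearance_mean=0.11,
            phase_fractions=(0.12, 0.42, 0.14, 0.32),
            clinical_means={
                "gds": 3.8, "frailty": 2.2, "short_fes_i": 11.2,
                "sppb": 8.49, "gait_speed_4m": 0.84, "tug_s": 15.9,
            },
            fall_driver="short_fes_i",
            driver_coefficient=2.0,
            base_prevalence=0.56,
            age_mean=82.5,
            height_mean=1.59,
            toe_off_angle_mean=-31.0,
            heel_strike_angle_mean=17.0,
            stride_time_std_mean=0.055,
            width_factor=0.80,
            amp_factor=1.00,
            **common,
        ),
        PhenotypeArchetype(
            name="cautious",
            cadence_mean=46.5,
            step_speed_mean=0.67,
            stride_length_mean=0.78,
            clearance_mean=0.09,
            phase_fractions=(0.16, 0.46, 0.10, 0.28),
            clinical_means={
                "gds": 4.5, "frailty": 3.2, "short_fes_i": 11.4,
                "sppb": 7.00, "gait_speed_4m": 0.67, "tug_s": 19.8,
            },
            fall_driver="gait_speed_4m",
            driver_coefficient=-2.0,
            base_prevalence=0.68,
            age_mean=85.0,
            height_mean=1.56,
            toe_off_angle_mean=-25.0,
            heel_strike_angle_mean=13.0,
            stride_time_std_mean=0.090,
            width_factor=1.35,
            amp_factor=0.75,
            **common,
        ),
        PhenotypeArchetype(
            name="intermediate",
            cadence_mean=48.3,
            step_speed_mean=0.85,
            stride_length_mean=0.95,
            clearance_mean=0.13,
            phase_fractions=(0.11, 0.45, 0.12, 0.32),
            clinical_means={
                "gds": 3.5, "frailty": 2.0, "short_fes_i": 9.86,
                "sppb": 9.15, "gait_speed_4m": 0.87, "tug_s": 13.0,
            },
            fall_driver="push_pct",
            driver_coefficient=-2.0,
            base_prevalence=0.48,
            age_mean=82.0,
            height_mean=1.60,
            toe_off_angle_mean=-33.0,
            heel_strike_angle_mean=19.0,
            stride_time_std_mean=0.065,
            width_factor=1.10,
            amp_factor=0.90,
            **common,
        ),
        PhenotypeArchetype(
            name="robust",
            cadence_mean=51.9,
            step_speed_mean=1.10,
            stride_length_mean=1.14,
            clearance_mean=0.15,
            phase_fractions=(0.10, 0.40, 0.16, 0.34),
            clinical_means={
                "gds": 3.0, "frailty": 1.2, "short_fes_i": 9.58,
                "sppb": 10.1, "gait_speed_4m": 1.05, "tug_s": 11.1,
            },
            fall_driver="stride_time_std",
            driver_coefficient=2.0,
            base_prevalence=0.27,
            age_mean=80.5,
            height_mean=1.63,
            toe_off_angle_mean=-38.0,
            heel_strike_angle_mean=22.0,
            stride_time_std_mean=0.040,
            width_factor=1.00,
            amp_factor=1.15,
            **common,
        ),
    ]


def default_archetypes(separation: float = 1.0) -> list[PhenotypeArchetype]:
    """The four default archetypes with every between-archetype mean
    difference scaled by ``separation`` about the grand (unweighted) mean.

    separation 0 collapses all archetypes onto the grand mean (downstream
    clustering can only perform at chance); values above 1 stretch the
    archetypes apart.  Fall mechanisms (driver, slope, prevalence) are not
    part of the dial.
    """
    base = _base_archetypes()

    def blend(vals: list[float]) -> list[float]:
        g = float(np.mean(vals))
        return [g + separation * (v - g) for v in vals]

    scalar_fields = [
        "cadence_mean", "step_speed_mean", "stride_length_mean", "clearance_mean",
        "age_mean", "height_mean", "toe_off_angle_mean", "heel_strike_angle_mean",
        "stride_time_std_mean", "width_factor", "amp_factor",
    ]
    out = [dict() for _ in base]
    for f in scalar_fields:
        for d, v in zip(out, blend([getattr(a, f) for a in base])):
            d[f] = max(v, 1e-3) if f in ("stride_time_std_mean", "clearance_mean") else v
    # phase fractions: blend each component then renormalize
    phases = np.array([a.phase_fractions for a in base])
    g = phases.mean(axis=0)
    scaled = np.clip(g + separation * (phases - g), 0.02, None)
    scaled /= scaled.sum(axis=1, keepdims=True)
    # clinical means
    clin = []
    for key in CLINICAL_SCORES:
        clin.append(blend([a.clinical_means[key] for a in base]))
    result = []
    for i, a in enumerate(base):
        cm = {key: clin[j][i] for j, key in enumerate(CLINICAL_SCORES)}
        result.append(
            replace(a, phase_fractions=tuple(scaled[i]), clinical_means=cm, **out[i])
        )
    return result


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def generate_subject_strides(
    archetype: PhenotypeArchetype,
    subject_effects: dict,
    n_strides: int,
    signal: SignalConfig,
    rng: np.random.Generator,
    subject_id: str = "",
    noise_sd: tuple = (0.30, 0.30, 6.0),
    timing_jitter_rel: float | None = None,
    scalar_jitter: tuple = (0.06, 0.08),
    record: dict | None = None,
) -> list[StrideWaveform]:
    """Synthesize ``n_strides`` event-locked 3-channel strides for one subject.

    ``subject_effects`` holds additive offsets from the archetype means for
    the gait latents ("cadence", "step_speed", "stride_length", "clearance",
    the four phase names, "stride_time_std").  Stride durations differ
    across strides (timing jitter), so stride sample counts vary.  If a
    ``record`` dict is supplied, the per-stride scalars actually realized
    (lengths, clearances, phase fractions) are stored in it so derived gait
    parameters can be computed for exactly these strides.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    eff = subject_effects
    cadence = archetype.cadence_mean + eff.get("cadence", 0.0)
    if cadence <= 0:
        raise ValueError(f"cadence must be positive, got {cadence}")
    speed = max(archetype.step_speed_mean + eff.get("step_speed", 0.0), 0.05)
    length = max(archetype.stride_length_mean + eff.get("stride_length", 0.0), 0.10)
    clearance = max(archetype.clearance_mean + eff.get("clearance", 0.0), 0.01)
    phases = np.clip(
        [archetype.phase_fractions[i] + eff.get(p, 0.0) for i, p in enumerate(PHASE_NAMES)],
        0.02, None,
    )
    phases = phases / phases.sum()
    p1, p2, p3 = np.cumsum(phases)[:3]  # load end, foot-flat end, push end

    stride_time = 60.0 / cadence
    if timing_jitter_rel is None:
        st_std = max(archetype.stride_time_std_mean + eff.get("stride_time_std", 0.0), 0.0)
        timing_jitter_rel = st_std / stride_time
    wmod = archetype.width_factor * (1.0 + eff.get("shape_width", 0.0))
    amod = archetype.amp_factor * (1.0 + eff.get("shape_amp", 0.0))

    fs = signal.sampling_rate_hz
    strides = []
    if record is not None:
        record.update({"lengths": [], "clearances": [], "phases": []})
    for _ in range(n_strides):
        dur = stride_time * max(1.0 + rng.normal(0.0, timing_jitter_rel), 0.3)
        len_i = length * max(1.0 + rng.normal(0.0, scalar_jitter[0]), 0.2)
        clr_i = clearance * max(1.0 + rng.normal(0.0, scalar_jitter[1]), 0.2)
        if record is not None:
            record["lengths"].append(len_i)
            record["clearances"].append(clr_i)
            record["phases"].append(phases.copy())
        spd_i = len_i / dur
        n = max(int(round(dur * fs)), 8)
        t = np.arange(n) / n  # normalized gait-cycle time [0, 1)

        c_load = p1 / 2.0
        c_push = (p2 + p3) / 2.0
        c_swing = (p3 + 1.0) / 2.0
        w_ev = 0.050 * wmod  # event bumps; wide enough to survive the 4 Hz low-pass
        w_sw = (1.0 - p3) / 4.5 * wmod

        acc_y = amod * (
            (1.5 + 3.5 * spd_i) * _bump(t, c_push, w_ev)
            - (1.0 + 2.0 * spd_i) * _bump(t, c_load, w_ev)
        )
        acc_z = amod * (
            (2.0 + 3.0 * spd_i) * _bump(t, c_load, 0.8 * w_ev)
            + 22.0 * clr_i * _bump(t, c_swing, w_sw)
            - (0.8 + 1.2 * spd_i) * _bump(t, c_push, w_ev)
        )
        gyro_x = amod * (
            (120.0 + 160.0 * spd_i + 700.0 * clr_i) * _bump(t, c_swing, w_sw)
            - (30.0 + 60.0 * spd_i) * _bump(t, c_load, w_ev)
            - (20.0 + 50.0 * spd_i) * _bump(t, c_push, w_ev)
        )
        if any(s > 0 for s in noise_sd):
            acc_y = acc_y + rng.normal(0.0, noise_sd[0], n)
            acc_z = acc_z + rng.normal(0.0, noise_sd[1], n)
            gyro_x = gyro_x + rng.normal(0.0, noise_sd[2], n)
        strides.append(StrideWaveform(subject_id, acc_y, acc_z, gyro_x))
    return strides


def _derive_features(
    strides: list[StrideWaveform],
    per_stride: dict,
    signal: SignalConfig,
) -> dict:
    """Standard gait parameters (means, SDs, totals, paths) computed from the generated strides."""
    fs = signal.sampling_rate_hz
    durations = np.array([s.n_samples / fs for s in strides])
    lengths = np.asarray(per_stride["lengths"])
    clearances = np.asarray(per_stride["clearances"])
    phases = np.asarray(per_stride["phases"])  # (k, 4)
    ddof = 1 if len(strides) > 1 else 0
    path_2d = 1.04 * lengths
    path_3d = path_2d + 2.0 * clearances
    return {
        "cadence": 60.0 / durations.mean(),
        "step_speed": float(np.mean(lengths / durations)),
        "stride_length": float(lengths.mean()),
        "clearance": float(clearances.mean()),
        "total_distance": float(lengths.sum()),
        "total_time": float(durations.sum()),
        "total_strides": float(len(strides)),
        "swing_pct": float(phases[:, 3].mean() * 100.0),
        "load_pct": float(phases[:, 0].mean() * 100.0),
        "foot_flat_pct": float(phases[:, 1].mean() * 100.0),
        "push_pct": float(phases[:, 2].mean() * 100.0),
        "stride_time": float(durations.mean()),
        "stride_time_std": float(durations.std(ddof=ddof)),
        "stride_length_std": float(lengths.std(ddof=ddof)),
        "clearance_std": float(clearances.std(ddof=ddof)),
        "path_3d": float(path_3d.mean()),
        "path_2d": float(path_2d.mean()),
    }


def generate_cohort(
    archetypes: list[PhenotypeArchetype],
    n_subjects: int,
    signal: SignalConfig | None = None,
    seed: int = 0,
    n_strides_range: tuple = (20, 60),
    missing_rate: float = 0.0,
) -> CohortDataset:
    """Generate a full cohort: subjects split near-equally across archetypes,
    per-subject gait/clinical features drawn from archetype means + SDs,
    stride waveforms synthesized per subject, standard gait parameters
    derived from those strides, and fall labels planted by each archetype's
    driver mechanism.  Identical (inputs, seed) give an identical cohort.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if not archetypes:
        raise ValueError("archetype list must not be empty")
    if n_subjects < 4 * len(archetypes):
        raise ValueError("need at least 4 subjects per archetype")
    signal = signal or SignalConfig()
    rng = np.random.default_rng(seed)

    rows, strides_map, truth = [], {}, {}
    for i in range(n_subjects):
        arch = archetypes[i % len(archetypes)]
        sd = arch.within_phenotype_sd
        sid = f"S{i:04d}"
        truth[sid] = arch.name

        eff = {
            "cadence": rng.normal(0.0, sd["cadence"]),
            "step_speed": rng.normal(0.0, sd["step_speed"]),
            "stride_length": rng.normal(0.0, sd["stride_length"]),
            "clearance": rng.normal(0.0, sd["clearance"]),
            "stride_time_std": rng.normal(0.0, sd["stride_time_std"]),
            "shape_width": rng.normal(0.0, 0.05),
            "shape_amp": rng.normal(0.0, 0.05),
        }
        for p in PHASE_NAMES:
            eff[p] = rng.normal(0.0, sd["phase"])

        if arch.cadence_mean + eff["cadence"] <= 5.0:
            eff["cadence"] = 5.0 - arch.cadence_mean  # floor implausibly slow draws
        n_str = int(rng.integers(n_strides_range[0], n_strides_range[1] + 1))
        per_stride: dict = {}
        strides = generate_subject_strides(
            arch, eff, n_str, signal, rng, subject_id=sid, record=per_stride
        )
        # small measurement jitter on the recorded per-stride phase fractions
        per_stride["phases"] = [
            p + rng.normal(0.0, 0.004, 4) for p in per_stride["phases"]
        ]
        strides_map[sid] = strides
        feats = _derive_features(strides, per_stride, signal)
        feats["toe_off_angle"] = arch.toe_off_angle_mean + rng.normal(0.0, sd["toe_off_angle"])
        feats["heel_strike_angle"] = arch.heel_strike_angle_mean + rng.normal(
            0.0, sd["heel_strike_angle"]
        )
        feats["gds"] = float(np.clip(round(arch.clinical_means["gds"] + rng.normal(0, sd["gds"])), 1, 7))
        feats["frailty"] = float(
            np.clip(round(arch.clinical_means["frailty"] + rng.normal(0, sd["frailty"])), 0, 5)
        )
        feats["short_fes_i"] = float(
            np.clip(round(arch.clinical_means["short_fes_i"] + rng.normal(0, sd["short_fes_i"])), 7, 28)
        )
        feats["sppb"] = float(
            np.clip(round(arch.clinical_means["sppb"] + rng.normal(0, sd["sppb"])), 0, 12)
        )
        feats["gait_speed_4m"] = max(
            arch.clinical_means["gait_speed_4m"] + rng.normal(0, sd["gait_speed_4m"]), 0.05
        )
        feats["tug_s"] = max(
            arch.clinical_means["tug_s"] + rng.normal(0, sd["tug_s"]), 3.0
        )
        feats["age"] = arch.age_mean + rng.normal(0, sd["age"])
        feats["height"] = arch.height_mean + rng.normal(0, sd["height"])
        feats["fell"] = 0  # assigned below
        rows.append(pd.Series(feats, name=sid))

    features = pd.DataFrame(rows)[FEATURE_COLUMNS + META_COLUMNS]
    features.index.name = "subject_id"
    cohort = CohortDataset(
        features=features,
        strides=strides_map,
        true_phenotype=pd.Series(truth, name="phenotype"),
        seed=seed,
    )
    cohort = assign_fall_labels(cohort, archetypes, rng)
    if missing_rate > 0:
        mask_cols = list(CLINICAL_SCORES)
        m = rng.random((len(features), len(mask_cols))) < missing_rate
        vals = cohort.features[mask_cols].to_numpy()
        vals[m] = np.nan
        cohort.features[mask_cols] = vals
    return cohort


def _calibrate_intercept(z: np.ndarray, coef: float, target: float) -> float:
    """Intercept b with mean(expit(b + coef*z)) == target."""
    if target <= 0.0:
        return -30.0
    if target >= 1.0:
        return 30.0

    def f(b: float) -> float:
        return float(np.mean(expit(b + coef * z))) - target

    return brentq(f, -40.0, 40.0, xtol=1e-10)


def assign_fall_labels(
    cohort: CohortDataset,
    archetypes: list[PhenotypeArchetype],
    rng: np.random.Generator,
) -> CohortDataset:
    """Draw 12-month fall labels per subject.

    Within each phenotype, fall probability is logistic in the phenotype's
    standardized driver feature; the intercept is calibrated so the expected
    prevalence equals the archetype's ``base_prevalence``.
    """
    if cohort.true_phenotype is None:
        raise ValueError("assign_fall_labels needs planted phenotype labels")
    by_name = {a.name: a for a in archetypes}
    fell = pd.Series(0, index=cohort.features.index, dtype=int)
    for name, arch in by_name.items():
        ids = cohort.true_phenotype[cohort.true_phenotype == name].index
        if len(ids) == 0:
            continue
        if arch.fall_driver not in cohort.features.columns:
            raise ValueError(f"unknown driver feature {arch.fall_driver!r}")
        x = cohort.features.loc[ids, arch.fall_driver].to_numpy(dtype=float)
        s = x.std(ddof=0)
        z = (x - x.mean()) / s if s > 0 else np.zeros_like(x)
        b = _calibrate_intercept(z, arch.driver_coefficient, arch.base_prevalence)
        p = expit(b + arch.driver_coefficient * z)
        fell.loc[ids] = (rng.random(len(ids)) < p).astype(int)
    cohort.features["fell"] = fell
    return cohort
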