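"""Core in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical subject-feature columns (the 25 gait/clinical variables fed to
#: the faller models), in fixed order.  Units follow the field conventions:
#: cadence strides/min, speeds m/s, lengths m, phases % of gait-cycle time,
#: times s, angles deg; GDS/frailty/FES-I/SPPB are questionnaire scores.
FEATURE_COLUMNS = [
    "cadence",
    "step_speed",
    "stride_length",
    "clearance",
    "total_distance",
    "total_time",
    "total_strides",
    "swing_pct",
    "load_pct",
    "foot_flat_pct",
    "push_pct",
    "stride_time",
    "toe_off_angle",
    "heel_strike_angle",
    "stride_time_std",
    "stride_length_std",
    "clearance_std",
    "path_3d",
    "path_2d",
    "gds",
    "frailty",
    "short_fes_i",
    "sppb",
    "gait_speed_4m",
    "tug_s",
]

#: Extra per-subject columns carried alongside the model features.
META_COLUMNS = ["age", "height", "fell"]


@dataclass
class StrideWaveform:
    """One stride's 3-channel IMU samples.

    acc_y: progression-direction acceleration [m/s^2]
    acc_z: vertical acceleration [m/s^2]
    gyro_x: sagittal-plane angular velocity [deg/s]
    """

    subject_id: str
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyro_x: np.ndarray

    def __post_init__(self) -> None:
        self.acc_y = np.asarray(self.acc_y, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)
        self.gyro_x = np.asarray(self.gyro_x, dtype=float)
        n = len(self.acc_y)
        if len(self.acc_z) != n or len(self.gyro_x) != n:
            raise ValueError("stride channels must have equal length")
        if n < 2:
            raise ValueError("stride must have at least 2 samples")
        if not (
            np.all(np.isfinite(self.acc_y))
            and np.all(np.isfinite(self.acc_z))
            and np.all(np.isfinite(self.gyro_x))
        ):
            raise ValueError("stride contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.acc_y)

    def channels(self) -> np.ndarray:
        """(n_samples, 3) array in (acc_y, acc_z, gyro_x) order."""
        return np.column_stack([self.acc_y, self.acc_z, self.gyro_x])


@dataclass
class RepresentativeGait:
    """Per-subject mean stride: 3 channels x L time-normalized samples."""

    subject_id: str
    curves: np.ndarray  # shape (3, L)
    n_strides_used: int

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2 or self.curves.shape[0] != 3:
            raise ValueError("curves must have shape (3, L)")
        if self.n_strides_used < 1:
            raise ValueError("n_strides_used must be >= 1")


@dataclass
class SubjectRecord:
    """Validated single-subject row: demographics, the 25 gait/clinical
    features, and the 12-month fall-history label."""

    id: str
    age: float
    height: float
    features: dict
    fell: int

    def __post_init__(self) -> None:
        if self.fell not in (0, 1):
            raise ValueError(f"fall label must be 0/1, got {self.fell}")
        f = self.features
        if f.get("tug_s", 1.0) <= 0:
            raise ValueError(f"subject {self.id}: TUG must be positive")
        if not 0 <= f.get("sppb", 0.0) <= 12:
            raise ValueError(f"subject {self.id}: SPPB out of [0, 12]")
        if not 7 <= f.get("short_fes_i", 7.0) <= 28:
            raise ValueError(f"subject {self.id}: Short FES-I out of [7, 28]")
        if not 0 <= f.get("frailty", 0.0) <= 5:
            raise ValueError(f"subject {self.id}: frailty count out of [0, 5]")


@dataclass
class CohortDataset:
    """A cohort: wide feature table, per-subject strides, and (for synthetic
    cohorts) the planted phenotype of every subject."""

    features: pd.DataFrame  # index subject id; FEATURE_COLUMNS + META_COLUMNS
    strides: dict = field(default_factory=dict)  # subject id -> [StrideWaveform]
    true_phenotype: pd.Series | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_phenotype is not None:
            if set(self.true_phenotype.index) != set(self.features.index):
                raise ValueError("true_phenotype keys must equal subject ids")
        if self.strides:
            for sid, slist in self.strides.items():
                if len(slist) < 1:
                    raise ValueError(f"subject {sid} has no strides")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def n_subjects(self) -> int:
        return len(self.features)


@dataclass
class DissimilarityMatrix:
    """Symmetric inter-subject distances.

    mode "waveform_only": raw multivariate-DTW distances between
    representative strides.  mode "waveform_plus_basic": max-min rescaled
    DTW block plus ``fusion_weight`` times a rescaled Euclidean block on
    cohort-standardized age and height.
    """

    D: np.ndarray
    subject_ids: list
    mode: str = "waveform_only"
    fusion_weight: float = 0.0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = self.D.shape[0]
        if self.D.shape != (n, n):
            raise ValueError("D must be square")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("D must have zero diagonal")
        if np.any(self.D < -1e-12):
            raise ValueError("D must be nonnegative")
        self.D = np.maximum((self.D + self.D.T) / 2.0, 0.0)
        np.fill_diagonal(self.D, 0.0)

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class Embedding:
    """MDS coordinates of a dissimilarity matrix plus the final stress."""

    coordinates: np.ndarray  # (n, d)
    stress: float
    subject_ids: list

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")
        if self.stress < 0:
            raise ValueError("stress must be nonnegative")

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]
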