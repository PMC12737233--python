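"""Cohort readers and writers in the GSTRIDE-like layout.

A cohort directory holds one wide ``subjects.csv`` (or spreadsheet,
accepted read-only) with the canonical gait/clinical column names, one raw CSV per
subject with columns time_s, acc_y, acc_z, gyro_x, and one stride-event
CSV per subject (stride_start_idx, foot_flat_idx).  Parsing is name-based,
row-level validation errors are collected and reported together, and the
writer/reader pair round-trips a synthetic cohort losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import segment_strides
from .types import FEATURE_COLUMNS, META_COLUMNS, CohortDataset, RepresentativeGait, SubjectRecord

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = FEATURE_COLUMNS + META_COLUMNS


def write_cohort(cohort: CohortDataset, path: str | Path) -> None:
    """Write subjects.csv, per-subject raw/<id>.csv and events/<id>.csv, and
    (for synthetic cohorts) truth.csv with the planted phenotypes."""
    path = Path(path)
    (path / "raw").mkdir(parents=True, exist_ok=True)
    (path / "events").mkdir(parents=True, exist_ok=True)
    feats = cohort.features.copy()
    feats.index.name = "subject_id"
    feats.to_csv(path / "subjects.csv")
    if cohort.true_phenotype is not None:
        tp = cohort.true_phenotype.rename("phenotype").to_frame()
        tp.index.name = "subject_id"
        tp.to_csv(path / "truth.csv")
    fs = 104.0
    for sid, strides in cohort.strides.items():
        chunks, starts, flats = [], [], []
        pos = 0
        for s in strides:
            starts.append(pos)
            # Foot Flat onset approximated at the end of the load phase
            flats.append(pos + max(int(round(0.12 * s.n_samples)), 1))
            chunks.append(s.channels())
            pos += s.n_samples
        rec = np.vstack(chunks)
        starts.append(pos)  # final event closes the last stride
        t = np.arange(rec.shape[0]) / fs
        pd.DataFrame(
            {"time_s": t, "acc_y": rec[:, 0], "acc_z": rec[:, 1], "gyro_x": rec[:, 2]}
        ).to_csv(path / "raw" / f"{sid}.csv", index=False)
        pd.DataFrame(
            {"stride_start_idx": starts, "foot_flat_idx": flats + [pos]}
        ).to_csv(path / "events" / f"{sid}.csv", index=False)


def _unit_sanity(feats: pd.DataFrame) -> None:
    tug = feats["tug_s"].dropna()
    if len(tug) and tug.median() < 1.0:
        log.warning("TUG column median < 1 s; values may be in minutes")
    spd = feats["gait_speed_4m"].dropna()
    if len(spd) and (spd.median() > 5.0 or spd.median() < 0.05):
        log.warning("4 m gait speed outside plausible m/s range")


def read_cohort_tables(path: str | Path, load_strides: bool = True) -> CohortDataset:
    """Read and validate a cohort directory.

    Raises a single error listing every invalid row rather than dropping
    rows silently.  Column order is irrelevant (name-based parsing).
    """
    path = Path(path)
    table = path / "subjects.csv"
    if table.exists():
        feats = pd.read_csv(table, index_col="subject_id")
    else:
        xlsx = list(path.glob("subjects.xls*"))
        if not xlsx:
            raise FileNotFoundError(f"no subjects table under {path}")
        feats = pd.read_excel(xlsx[0], index_col=0)
    missing = [c for c in MANDATORY_COLUMNS if c not in feats.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    if feats.index.duplicated().any():
        dups = feats.index[feats.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    feats = feats[MANDATORY_COLUMNS]
    feats.index = feats.index.astype(str)
    _unit_sanity(feats)

    errors = []
    for sid, row in feats.iterrows():
        try:
            f = {c: row[c] for c in FEATURE_COLUMNS}
            if not np.isfinite(row["fell"]):
                raise ValueError(f"subject {sid}: missing fall label")
            SubjectRecord(
                id=str(sid), age=row["age"], height=row["height"],
                features={k: v for k, v in f.items() if np.isfinite(v)},
                fell=int(row["fell"]),
            )
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("cohort validation failed:\n" + "\n".join(errors))

    truth = None
    tfile = path / "truth.csv"
    if tfile.exists():
        truth = pd.read_csv(tfile, index_col="subject_id")["phenotype"]
        truth.index = truth.index.astype(str)

    strides = {}
    if load_strides and (path / "raw").is_dir():
        for sid in feats.index:
            rawf = path / "raw" / f"{sid}.csv"
            evf = path / "events" / f"{sid}.csv"
            if not rawf.exists():
                continue
            raw = pd.read_csv(rawf)
            rec = raw[["acc_y", "acc_z", "gyro_x"]].to_numpy()
            events = pd.read_csv(evf)["stride_start_idx"].to_numpy()
            strides[sid] = segment_strides(rec, events, subject_id=str(sid))
    return CohortDataset(features=feats, strides=strides, true_phenotype=truth)


def write_representative(reps: list[RepresentativeGait], path: str | Path) -> None:
    """Wide CSV: one row per subject, 3*L curve values plus stride count."""
    L = reps[0].curves.shape[1]
    cols = [f"{ch}_{i}" for ch in ("acc_y", "acc_z", "gyro_x") for i in range(L)]
    data = {r.subject_id: np.concatenate([r.curves[c] for c in range(3)]) for r in reps}
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df["n_strides_used"] = [r.n_strides_used for r in reps]
    df.index.name = "subject_id"
    df.to_csv(path)


def read_representative(path: str | Path) -> list[RepresentativeGait]:
    df = pd.read_csv(path, index_col="subject_id")
    n_used = df.pop("n_strides_used")
    L = df.shape[1] // 3
    out = []
    for sid, row in df.iterrows():
        curves = row.to_numpy(dtype=float).reshape(3, L)
        out.append(RepresentativeGait(str(sid), curves, int(n_used[sid])))
    return out


def write_matrix(D: np.ndarray, subject_ids: list, path: str | Path) -> None:
    """Square distance matrix with subject-id header row and column."""
    df = pd.DataFrame(D, index=subject_ids, columns=subject_ids)
    df.index.name = "subject_id"
    df.to_csv(path)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, index_col="subject_id")
    return df.to_numpy(dtype=float), [str(s) for s in df.index]
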