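"""Core dataset containers, delimited-text I/O, and patient-disjoint CV folds.

A cohort is a sample x metabolite concentration table plus right-censored
survival labels: an event indicator (1 = deceased, 0 = censored), a
nonnegative time-to-event in days, an optional binary malignancy label
(1 = aggressive pathology) and an optional patient identifier used to keep
repeat samples from one patient inside a single cross-validation fold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

logger = logging.getLogger("pathsurv")

LABEL_COLUMNS = ("event", "duration_days")
OPTIONAL_LABEL_COLUMNS = ("malignancy", "patient_id")


@dataclass
class SurvivalDataset:
    """Feature matrix with survival labels.

    Parameters
    ----------
    features : (N, P) float array of nonnegative metabolite concentrations.
    metabolite_names : P unique column names.
    events : (N,) array in {0, 1}; 1 = deceased, 0 = censored.
    durations : (N,) nonnegative times in days.
    malignancy : optional (N,) array in {0, 1}; 1 = aggressive.
    patient_ids : N identifiers; defaults to the sample ids.
    sample_ids : N unique identifiers.
    """

    features: np.ndarray
    metabolite_names: list[str]
    events: np.ndarray
    durations: np.ndarray
    malignancy: np.ndarray | None = None
    patient_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        n = self.features.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.patient_ids:
            self.patient_ids = list(self.sample_ids)
        if self.malignancy is not None:
            self.malignancy = np.asarray(self.malignancy, dtype=int)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.features.shape
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if len(self.metabolite_names) != p:
            raise ValueError(
                f"{len(self.metabolite_names)} metabolite names for {p} columns"
            )
        if len(set(self.metabolite_names)) != p:
            raise ValueError("metabolite names are not unique")
        for name, vec in (("events", self.events), ("durations", self.durations)):
            if len(vec) != n:
                raise ValueError(f"{name} has length {len(vec)}, expected {n}")
        if self.malignancy is not None and len(self.malignancy) != n:
            raise ValueError("malignancy length mismatch")
        if len(self.patient_ids) != n or len(self.sample_ids) != n:
            raise ValueError("id vectors must have one entry per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        bad = ~np.isin(self.events, (0, 1))
        if bad.any():
            raise ValueError(f"events must be 0/1; offending values {self.events[bad][:5]}")
        if (self.durations < 0).any():
            i = int(np.argmax(self.durations < 0))
            raise ValueError(
                f"negative duration {self.durations[i]} for sample {self.sample_ids[i]}"
            )
        if self.malignancy is not None and (~np.isin(self.malignancy, (0, 1))).any():
            raise ValueError("malignancy labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        index = np.asarray(index)
        return SurvivalDataset(
            features=self.features[index],
            metabolite_names=list(self.metabolite_names),
            events=self.events[index],
            durations=self.durations[index],
            malignancy=None if self.malignancy is None else self.malignancy[index],
            patient_ids=[self.patient_ids[i] for i in index],
            sample_ids=[self.sample_ids[i] for i in index],
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    # comma vs tab auto-detection, documented contract
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_dataset(features_path: str | Path, labels_path: str | Path) -> SurvivalDataset:
    """Read a cohort from two delimited text files joined on sample id.

    The features file has a header of metabolite names and sample ids in the
    first column. The labels file has columns ``sample_id``, ``event``,
    ``duration_days`` and optionally ``malignancy`` and ``patient_id``.
    The join is by id, so row order of the labels file does not matter; the
    features file's row order is preserved.
    """
    features_path, labels_path = Path(features_path), Path(labels_path)
    feats = pd.read_csv(features_path, sep=_sniff_delimiter(features_path), index_col=0)
    labels = pd.read_csv(labels_path, sep=_sniff_delimiter(labels_path))
    if "sample_id" not in labels.columns:
        raise ValueError("labels file must contain a 'sample_id' column")
    labels["sample_id"] = labels["sample_id"].astype(str)
    feats.index = feats.index.astype(str)
    dup = labels["sample_id"][labels["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id in labels: {dup.iloc[0]}")
    if feats.index.duplicated().any():
        raise ValueError(
            f"duplicate sample id in features: {feats.index[feats.index.duplicated()][0]}"
        )
    for col in LABEL_COLUMNS:
        if col not in labels.columns:
            raise ValueError(f"labels file lacks required column '{col}'")
    labels = labels.set_index("sample_id")
    missing = feats.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"sample id missing from labels: {missing[0]}")
    labels = labels.loc[feats.index]
    return SurvivalDataset(
        features=feats.to_numpy(dtype=float),
        metabolite_names=[str(c) for c in feats.columns],
        events=labels["event"].to_numpy(),
        durations=labels["duration_days"].to_numpy(dtype=float),
        malignancy=labels["malignancy"].to_numpy() if "malignancy" in labels else None,
        patient_ids=[str(x) for x in labels["patient_id"]]
        if "patient_id" in labels
        else list(feats.index),
        sample_ids=list(feats.index),
    )


def write_dataset(
    ds: SurvivalDataset,
    features_path: str | Path,
    labels_path: str | Path,
    sep: str = ",",
) -> None:
    """Write a cohort back to the two-file delimited layout read_dataset expects."""
    feats = pd.DataFrame(ds.features, index=ds.sample_ids, columns=ds.metabolite_names)
    feats.index.name = "sample_id"
    feats.to_csv(features_path, sep=sep)
    cols = {
        "sample_id": ds.sample_ids,
        "event": ds.events,
        "duration_days": ds.durations,
        "patient_id": ds.patient_ids,
    }
    if ds.malignancy is not None:
        cols["malignancy"] = ds.malignancy
    pd.DataFrame(cols).to_csv(labels_path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)


# -- cross-validation folds ---------------------------------------------


@dataclass
class FoldAssignment:
    """One CV iteration: test fold i, validation fold (i+1) mod k, train = rest."""

    fold_index: np.ndarray  # per-sample fold in [0, k)
    k: int
    repeat: int
    iteration: int  # test-fold index within the repeat
    seed: int

    @property
    def test_fold(self) -> int:
        return self.iteration

    @property
    def val_fold(self) -> int:
        return (self.iteration + 1) % self.k

    def roles(self) -> np.ndarray:
        out = np.full(len(self.fold_index), "train", dtype=object)
        out[self.fold_index == self.test_fold] = "test"
        out[self.fold_index == self.val_fold] = "val"
        return out

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles() == role)


def make_folds(
    ds: SurvivalDataset, k: int = 5, repeats: int = 3, seed: int = 0
) -> list[FoldAssignment]:
    """Patient-disjoint k-fold assignments, repeated with derived seeds.

    Patients (all samples sharing a patient id) are shuffled and dealt
    round-robin into k near-equal folds; every (repeat, test-fold) pair yields
    one :class:`FoldAssignment`, so the list has ``repeats * k`` entries.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    patients = list(dict.fromkeys(ds.patient_ids))
    if len(patients) < k:
        raise ValueError(f"only {len(patients)} patients for k={k} folds")
    assignments: list[FoldAssignment] = []
    for rep in range(repeats):
        rep_seed = (seed + 9973 * rep) % (2**31)
        rng = np.random.default_rng(rep_seed)
        order = list(rng.permutation(len(patients)))
        patient_fold = {patients[j]: i % k for i, j in enumerate(order)}
        fold_index = np.array([patient_fold[p] for p in ds.patient_ids])
        for it in range(k):
            assignments.append(
                FoldAssignment(fold_index=fold_index, k=k, repeat=rep, iteration=it, seed=rep_seed)
            )
    return assignments
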