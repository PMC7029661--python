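"""Synthetic two-cohort ROI time-series generator.

Resting-state fMRI studies of functional hypernetworks start from a matrix of
ROI-averaged BOLD time series per subject (here 90 ROIs x 238 retained
volumes by default).  Real cohorts of that kind are access-restricted, so this
module emulates their one property the downstream method actually consumes:
linear dependence structure among ROI rows, organised in blocks ("group
structure" among brain regions).  Each subject is a zero-mean multivariate
Gaussian time series, i.i.d. over time, whose ROI covariance is block-constant
exchangeable: correlation ``within_r`` inside a block, ``between_r`` across
blocks.  Cohort B re-draws a configurable subset of blocks with a different
within-block correlation, which is the planted group-level effect the
pipeline should recover.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SubjectTimeSeries",
    "make_block_covariance",
    "simulate_subject",
    "simulate_cohort",
    "write_timeseries",
    "read_timeseries",
]

COHORT_LABELS = ("A", "B")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a two-cohort block-structured Gaussian simulation.

    ``group_sizes`` must sum to ``n_rois``.  ``perturbed_blocks`` are indices
    (0-based) into ``group_sizes`` whose within-block correlation is replaced
    by ``perturbed_within_r`` in cohort B only.
    """

    n_rois: int = 90
    n_timepoints: int = 238
    n_subjects_a: int = 15
    n_subjects_b: int = 15
    group_sizes: tuple[int, ...] = (15, 15, 15, 15, 15, 15)
    within_r: float = 0.6
    between_r: float = 0.05
    perturbed_blocks: frozenset[int] = frozenset({0})
    perturbed_within_r: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(self.group_sizes))
        object.__setattr__(self, "perturbed_blocks", frozenset(self.perturbed_blocks))
        if self.n_rois <= 0 or self.n_timepoints <= 0:
            raise ValueError("n_rois and n_timepoints must be positive")
        if self.n_subjects_a <= 0 or self.n_subjects_b <= 0:
            raise ValueError("cohort sizes must be positive")
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if sum(self.group_sizes) != self.n_rois:
            raise ValueError(
                f"group_sizes sum to {sum(self.group_sizes)}, expected n_rois={self.n_rois}"
            )
        if not 0.0 <= self.within_r < 1.0:
            raise ValueError("within_r must lie in [0, 1)")
        if not 0.0 <= self.perturbed_within_r < 1.0:
            raise ValueError("perturbed_within_r must lie in [0, 1)")
        if not 0.0 <= self.between_r < 1.0 or self.between_r >= max(
            self.within_r, 1e-300
        ):
            if not (self.within_r == 0.0 and self.between_r == 0.0):
                raise ValueError("between_r must lie in [0, within_r)")
        bad = [b for b in self.perturbed_blocks if not 0 <= b < len(self.group_sizes)]
        if bad:
            raise ValueError(f"perturbed block indices out of range: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_a + self.n_subjects_b

    def block_of(self) -> np.ndarray:
        """Block index of every ROI, shape (n_rois,)."""
        return np.repeat(np.arange(len(self.group_sizes)), self.group_sizes)


@dataclass
class SubjectTimeSeries:
    """One subject's ROI x timepoint matrix with its cohort label."""

    subject_id: str
    cohort: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.cohort not in COHORT_LABELS:
            raise ValueError(f"cohort must be one of {COHORT_LABELS}, got {self.cohort!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois, n_timepoints) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in data")
        if np.any(self.data.var(axis=1) <= 0):
            bad = int(np.flatnonzero(self.data.var(axis=1) <= 0)[0])
            raise ValueError(f"subject {self.subject_id}: ROI {bad} has zero variance")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def make_block_covariance(config: CohortConfig, cohort: str = "A") -> np.ndarray:
    """Block-constant exchangeable correlation matrix for one cohort.

    Unit diagonal; ``within_r`` inside each block (``perturbed_within_r`` for
    perturbed blocks when ``cohort == "B"``), ``between_r`` elsewhere.  Raises
    if the resulting matrix is not positive definite, naming the first block
    whose parameters break positive definiteness.
    """
    if cohort not in COHORT_LABELS:
        raise ValueError(f"cohort must be one of {COHORT_LABELS}")
    block = config.block_of()
    same = block[:, None] == block[None, :]
    cov = np.where(same, config.within_r, config.between_r)
    if cohort == "B":
        for b in config.perturbed_blocks:
            idx = np.flatnonzero(block == b)
            cov[np.ix_(idx, idx)] = config.perturbed_within_r
    np.fill_diagonal(cov, 1.0)
    smallest = float(np.linalg.eigvalsh(cov)[0])
    if smallest <= 1e-10:
        # Identify a block whose exchangeable sub-matrix is itself degenerate,
        # otherwise blame the between-block coupling.
        for b, g in enumerate(config.group_sizes):
            r = (
                config.perturbed_within_r
                if cohort == "B" and b in config.perturbed_blocks
                else config.within_r
            )
            if 1.0 + (g - 1) * r <= 1e-10 or 1.0 - r <= 1e-10:
                raise ValueError(
                    f"covariance not positive definite (smallest eigenvalue "
                    f"{smallest:.3e}); block {b} with size {g} and correlation {r} "
                    "is degenerate"
                )
        raise ValueError(
            f"covariance not positive definite (smallest eigenvalue {smallest:.3e}); "
            "between-block correlation too large for the block structure"
        )
    return cov


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    rng_seed: int,
    subject_id: str = "subject",
    cohort: str = "A",
) -> SubjectTimeSeries:
    """Draw one subject: columns are i.i.d. N(0, cov) samples over time."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be square")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError("cov must be symmetric")
    if np.linalg.eigvalsh(cov)[0] <= 0:
        raise ValueError("cov must be positive definite")
    rng = np.random.default_rng(rng_seed)
    chol = np.linalg.cholesky(cov)
    data = chol @ rng.standard_normal((cov.shape[0], n_timepoints))
    return SubjectTimeSeries(subject_id=subject_id, cohort=cohort, data=data)


def _subject_seed(config_seed: int, index: int) -> int:
    """Deterministic per-subject seed, independent across subjects."""
    return int(
        np.random.SeedSequence(entropy=config_seed, spawn_key=(index,)).generate_state(1)[0]
    )


def simulate_cohort(config: CohortConfig) -> list[SubjectTimeSeries]:
    """Simulate both cohorts; cohort B uses the perturbed covariance.

    Returns n_subjects_a subjects labelled ``A`` followed by n_subjects_b
    labelled ``B``.  The whole cohort is a pure function of ``config``.
    """
    cov_a = make_block_covariance(config, "A")
    cov_b = make_block_covariance(config, "B")
    subjects: list[SubjectTimeSeries] = []
    for i in range(config.n_subjects):
        cohort = "A" if i < config.n_subjects_a else "B"
        cov = cov_a if cohort == "A" else cov_b
        subjects.append(
            simulate_subject(
                cov,
                config.n_timepoints,
                rng_seed=_subject_seed(config.seed, i),
                subject_id=f"sub-{i:03d}",
                cohort=cohort,
            )
        )
    return subjects


def cohort_labels(subjects: Sequence[SubjectTimeSeries]) -> np.ndarray:
    return np.array([s.cohort for s in subjects])


def write_timeseries(subjects: Sequence[SubjectTimeSeries], directory: str) -> str:
    """Write one TSV matrix per subject plus a manifest; returns manifest path.

    Matrices are tab-delimited, rows = ROIs, columns = timepoints, no header,
    full repr precision so that a read/write round trip is exact.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []
    for s in subjects:
        fname = f"{s.subject_id}.tsv"
        path = os.path.join(directory, fname)
        with open(path, "w") as fh:
            for row in s.data:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")
        rows.append((s.subject_id, s.cohort, fname))
    manifest = os.path.join(directory, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("subject_id\tlabel\tpath\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return manifest


def read_timeseries(manifest_path: str) -> list[SubjectTimeSeries]:
    """Read a cohort back from a manifest written by :func:`write_timeseries`."""
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "label", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    subjects: list[SubjectTimeSeries] = []
    shape = None
    for _, rec in manifest.iterrows():
        label = rec["label"]
        if label not in COHORT_LABELS:
            raise ValueError(
                f"subject {rec['subject_id']}: unknown label {label!r} "
                f"(expected one of {COHORT_LABELS})"
            )
        path = os.path.join(base, rec["path"])
        data = _read_matrix(path)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"subject {rec['subject_id']}: matrix shape {data.shape} differs "
                f"from previous subjects' {shape}"
            )
        subjects.append(
            SubjectTimeSeries(subject_id=rec["subject_id"], cohort=label, data=data)
        )
    return subjects


def _read_matrix(path: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            cells = line.rstrip("\n").split("\t")
            row = []
            for j, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                    ) from None
            rows.append(row)
    if not rows or any(len(r) != len(rows[0]) for r in rows):
        raise ValueError(f"{path}: ragged or empty matrix")
    return np.array(rows, dtype=float)
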