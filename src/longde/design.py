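"""Two-group repeated-measures study layouts and their fixed-effect design matrices.

The design throughout the package is a two-arm longitudinal layout: each
subject belongs to one group (control or treatment) and is observed at a
fixed set of timepoints.  The fixed-effect mean model uses reference coding
with the control group and the first timepoint as references::

    log mu = b0 + b1*GRP + b2*T2 + b3*T3 + b4*T4
                + b5*GRP*T2 + b6*GRP*T3 + b7*GRP*T4

so with four timepoints there are eight coefficients: an intercept, a
baseline group difference, three time effects in the control group, and
three group-by-time interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StudyDesign", "design_parts"]


def design_parts(design):
    """Extract (design matrix, subject index) from a StudyDesign or a
    ``(X, subject_index)`` tuple — the latter supports free-form layouts
    such as intercept-only or paired toys."""
    if isinstance(design, tuple):
        X, subj = design
        return np.asarray(X, dtype=float), np.asarray(subj)
    return design.design_matrix(), design.subject_index


@dataclass(frozen=True)
class StudyDesign:
    """Maps samples to subjects, groups and timepoints.

    Parameters
    ----------
    subject_ids : array of str/int, one per sample
    group : int array, 0 = control, 1 = treatment, one per sample
    time : int array, timepoints coded 1..T, one per sample
    sample_ids : optional sample labels (generated when omitted)
    """

    subject_ids: np.ndarray
    group: np.ndarray
    time: np.ndarray
    sample_ids: np.ndarray | None = None
    # filled in __post_init__
    subject_index: np.ndarray = field(init=False, repr=False)
    subject_labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        subj = np.asarray(self.subject_ids)
        group = np.asarray(self.group, dtype=int)
        time = np.asarray(self.time, dtype=int)
        if not (len(subj) == len(group) == len(time)):
            raise ValueError("subject_ids, group and time must have equal length")
        if self.sample_ids is None:
            object.__setattr__(
                self, "sample_ids", np.array([f"sample_{i + 1}" for i in range(len(subj))])
            )
        labels, index = np.unique(subj, return_inverse=True)
        # a subject may not span two groups
        for lab in labels:
            g = np.unique(group[subj == lab])
            if g.size > 1:
                raise ValueError(f"subject {lab!r} appears in more than one group")
        object.__setattr__(self, "subject_ids", subj)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "subject_index", index)
        object.__setattr__(self, "subject_labels", labels)

    # ------------------------------------------------------------------
    @classmethod
    def balanced(cls, n_per_group: int, n_timepoints: int = 4) -> "StudyDesign":
        """Balanced layout: ``n_per_group`` subjects per arm, each observed at
        timepoints 1..n_timepoints."""
        if n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        n_subj = 2 * n_per_group
        subjects = np.repeat([f"subj_{i + 1:03d}" for i in range(n_subj)], n_timepoints)
        group = np.repeat(np.arange(n_subj) >= n_per_group, n_timepoints).astype(int)
        time = np.tile(np.arange(1, n_timepoints + 1), n_subj)
        return cls(subjects, group, time)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_labels)

    @property
    def n_timepoints(self) -> int:
        return int(self.time.max())

    @property
    def n_coef(self) -> int:
        return 2 * self.n_timepoints

    def design_matrix(self) -> np.ndarray:
        """Fixed-effect design matrix, reference-coded.

        Columns: intercept, group, time-2..T indicators, group x time-2..T
        interactions (8 columns for the default 4 timepoints).
        """
        T = self.n_timepoints
        n = self.n_samples
        X = np.zeros((n, 2 * T))
        X[:, 0] = 1.0
        X[:, 1] = self.group
        for t in range(2, T + 1):
            ind = (self.time == t).astype(float)
            X[:, t] = ind
            X[:, T + t - 1] = ind * self.group
        return X

    def design_row(self, group: int, time: int) -> np.ndarray:
        """Single design row for a (group, timepoint) cell."""
        T = self.n_timepoints
        row = np.zeros(2 * T)
        row[0] = 1.0
        row[1] = group
        if time > 1:
            row[time] = 1.0
            row[T + time - 1] = float(group)
        return row

    def validate_full_rank(self) -> None:
        X = self.design_matrix()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient for this layout")
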