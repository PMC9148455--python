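"""Readers, writers and run configuration for the pipeline.

Counts come as TSV/CSV (gene-id first column, one column per sample) or as
MatrixMarket triplets with companion row/column name files; sample metadata
as a TSV with columns sample, subject, group, time.  Reference coding is
documented and fixed: the alphabetically first group is the control, the
smallest timepoint is the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign
from .simulate import CountMatrix


class ConfigError(ValueError):
    """Invalid configuration (exit code 2)."""


class DataError(ValueError):
    """Invalid input data (exit code 3)."""


def read_counts(path) -> CountMatrix:
    """Load a gene-by-sample count matrix from TSV/CSV or MatrixMarket.

    MTX input expects ``<stem>.rows`` / ``<stem>.cols`` name files next to
    the matrix.  Counts must be non-negative integers; duplicate gene ids
    are rejected.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        genes = np.loadtxt(path.with_suffix(".rows"), dtype=str)
        samples = np.loadtxt(path.with_suffix(".cols"), dtype=str)
        df = pd.DataFrame(mat, index=np.atleast_1d(genes), columns=np.atleast_1d(samples))
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate gene id {dup!r}")
    vals = df.to_numpy()
    bad = np.argwhere(vals != np.floor(vals))
    if bad.size:
        g, s = bad[0]
        raise DataError(f"non-integer count at gene {df.index[g]!r}, sample "
                        f"{df.columns[s]!r}")
    if (vals < 0).any():
        g, s = np.argwhere(vals < 0)[0]
        raise DataError(f"negative count at gene {df.index[g]!r}, sample "
                        f"{df.columns[s]!r}")
    return CountMatrix(vals.astype(np.int64), df.index.to_numpy(), df.columns.to_numpy())


def write_counts(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_metadata(path, counts: CountMatrix | None = None) -> StudyDesign:
    """Build a StudyDesign from a sample-metadata TSV.

    Columns: sample, subject, group, time.  Groups are coded with the
    alphabetically first level as control; timepoints are mapped to 1..T in
    sorted order.  When ``counts`` is given, rows are aligned to its sample
    order and mismatches raise.
    """
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "subject", "group", "time"}
    if not required.issubset(meta.columns):
        raise DataError(f"metadata needs columns {sorted(required)}")
    if counts is not None:
        missing = set(counts.sample_ids) - set(meta["sample"])
        if missing:
            raise DataError(f"metadata missing samples: {sorted(missing)[:5]}")
        extra = set(meta["sample"]) - set(counts.sample_ids)
        if extra:
            raise DataError(f"metadata lists unknown samples: {sorted(extra)[:5]}")
        meta = meta.set_index("sample").loc[counts.sample_ids].reset_index()
    groups = np.sort(meta["group"].astype(str).unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups, found {list(groups)}")
    group = (meta["group"].astype(str) == groups[1]).astype(int).to_numpy()
    times = np.sort(meta["time"].unique())
    tmap = {t: i + 1 for i, t in enumerate(times)}
    time = meta["time"].map(tmap).to_numpy()
    return StudyDesign(
        subject_ids=meta["subject"].to_numpy(),
        group=group,
        time=time,
        sample_ids=meta["sample"].to_numpy(),
    )


def write_metadata(design: StudyDesign, path, group_labels=("control", "treatment")):
    pd.DataFrame(
        {
            "sample": design.sample_ids,
            "subject": design.subject_ids,
            "group": [group_labels[g] for g in design.group],
            "time": design.time,
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Full-pipeline configuration (YAML-loadable, CLI-overridable)."""

    seed: int = 0
    n_genes: int = 2000
    n_per_group: list = field(default_factory=lambda: [10])
    n_datasets: int = 3
    prop_de: float = 0.2
    methods: list = field(default_factory=lambda: ["lmm"])
    tests: list = field(default_factory=lambda: ["between", "within", "interaction", "global"])
    alpha: float = 0.05
    transform: str = "vst"
    gee_cov: str = "wang-long"
    n_nodes: int = 11
    threads: int = 1
    out_dir: str = "longde_out"
    params_tsv: str | None = None

    def __post_init__(self):
        from .contrasts import TEST_NAMES
        from .pipeline import METHODS

        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        for m in self.methods:
            if m not in METHODS:
                raise ConfigError(f"unknown method {m!r}")
        for t in self.tests:
            if t not in TEST_NAMES:
                raise ConfigError(f"unknown test {t!r}")
        if self.transform not in ("vst", "log2"):
            raise ConfigError("transform must be 'vst' or 'log2'")
        if self.gee_cov not in ("naive", "robust", "wang-long"):
            raise ConfigError("gee_cov must be naive, robust or wang-long")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
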