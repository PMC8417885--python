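"""Core containers and plain-text I/O for abundance tables and result tables.

The central object is :class:`AbundanceMatrix`: one subject's longitudinal
species-by-time-point count table, treated as one metacommunity whose local
communities are the individual time points.  Everything downstream (the
multi-site neutral fit, the niche-neutral hybrid fit, the reports) consumes
this container, and all per-sample depths are the column sums of its counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Host-status group labels used by the study-shaped cohort generator; the
#: metadata reader accepts arbitrary labels so new cohorts are not blocked.
DEFAULT_GROUPS = ("ABV", "SBV", "HEA-1", "HEA-2", "PREG")

MSN_COLUMNS = [
    "subject_id", "L_0", "theta", "M_value",
    "L_M", "N_M", "N", "P_M", "L_L", "N_L", "P_L",
]
NNH_COLUMNS = [
    "subject_id", "J", "S", "theta", "m", "x", "gamma",
    "R2", "chi2", "P", "N_pass", "pct_pass",
]


@dataclasses.dataclass
class AbundanceMatrix:
    """Species x local-community (time point) read counts for one subject.

    Parameters
    ----------
    counts : ndarray of shape (S_obs, T), non-negative integers
        Read counts; rows are species observed at least once, columns are
        local communities (time points) with depth >= 1.
    species_ids, sample_ids : sequences of labels matching the two axes.
    subject_id : label for the subject / metacommunity.
    """

    counts: np.ndarray
    species_ids: list[str]
    sample_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D species x sample matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if self.counts.size == 0:
            raise ValueError("empty abundance matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every species row must have a positive entry")
        if (self.counts.sum(axis=0) < 1).any():
            raise ValueError("every sample must contain at least one read")
        self.species_ids = [str(s) for s in self.species_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.species_ids) != self.counts.shape[0]:
            raise ValueError("species_ids length mismatch")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        """Number of local communities T (niches in the hybrid mapping)."""
        return self.counts.shape[1]

    @property
    def sample_sizes(self) -> np.ndarray:
        """Per-sample depths N_i — the single source of truth downstream."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.species_ids,
                            columns=self.sample_ids)


@dataclasses.dataclass
class SubjectMetadata:
    subject_id: str
    group: str
    sample_times: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        times = list(self.sample_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times must be strictly increasing")
        self.sample_times = times


@dataclasses.dataclass
class ResultRowMSN:
    """One subject's multi-site neutral summary (TS1-style schema)."""

    subject_id: str
    L_0: float
    theta: float
    M_value: float
    L_M: float
    N_M: int
    N: int
    P_M: float
    L_L: float
    N_L: int
    P_L: float

    def __post_init__(self) -> None:
        for name in ("P_M", "P_L"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.N_M > self.N or self.N_L > self.N:
            raise ValueError("pass counts cannot exceed the simulation count")


@dataclasses.dataclass
class ResultRowNNH:
    """One subject's niche-neutral hybrid summary (TS2-style schema)."""

    subject_id: str
    J: float
    S: float
    theta: float
    m: float
    x: float
    gamma: float
    R2: float
    chi2: float
    P: float
    N_pass: int
    pct_pass: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0 and not np.isnan(self.P):
            raise ValueError(f"P={self.P} outside [0, 1]")
        if not 0.0 <= self.pct_pass <= 100.0:
            raise ValueError("pct_pass outside [0, 100]")


def read_abundance_table(path: str | Path, orientation: str = "species_rows",
                         subject_id: str | None = None,
                         sep: str = "\t") -> AbundanceMatrix:
    """Read a TSV/CSV count table into a validated :class:`AbundanceMatrix`.

    ``orientation="species_rows"`` (the taxa-as-rows convention) expects
    species as rows; ``"samples_rows"`` transposes.  All-zero species rows
    are dropped with a warning; non-integer or negative entries raise a
    :class:`ValueError` naming the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.size == 0:
        raise ValueError(f"{path}: empty abundance table")
    if orientation == "samples_rows":
        df = df.T
    elif orientation != "species_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy()
    rounded = np.rint(np.asarray(values, dtype=float))
    bad = ~np.isfinite(rounded) | (np.asarray(values, dtype=float) != rounded) \
        | (rounded < 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: entry {values[r, c]!r} at species {df.index[r]!r}, "
            f"sample {df.columns[c]!r} is not a non-negative integer")
    counts = rounded.astype(np.int64)
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        dropped = [str(s) for s in df.index[~keep]]
        logger.warning("%s: dropping %d all-zero species rows: %s",
                       path, len(dropped), ", ".join(dropped[:5]))
    counts = counts[keep]
    if counts.size == 0:
        raise ValueError(f"{path}: no species with positive counts")
    return AbundanceMatrix(
        counts=counts,
        species_ids=[str(s) for s in df.index[keep]],
        sample_ids=[str(c) for c in df.columns],
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_abundance_table(data: AbundanceMatrix, path: str | Path) -> None:
    data.to_frame().to_csv(path, sep="\t")


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample-metadata TSV (subject_id, sample_id, group, time_index)."""
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "sample_id", "group", "time_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def subject_metadata(df: pd.DataFrame) -> dict[str, SubjectMetadata]:
    out: dict[str, SubjectMetadata] = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("time_index")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {sid} has multiple group labels")
        out[str(sid)] = SubjectMetadata(str(sid), str(groups[0]),
                                        [int(t) for t in sub["time_index"]])
    return out


def _fmt(value: float, nd: int = 3) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "nan"
    return f"{value:.{nd}f}"


def write_result_tables(rows: Sequence[ResultRowMSN | ResultRowNNH],
                        path: str | Path, schema: str | None = None) -> None:
    """Write MSN or NNH result rows as a TSV matching the report schemas.

    Reals and log-likelihoods are rendered to 3 decimals, percentages to 1
    decimal, counts as integers.  ``schema`` ("msn" or "nnh") is inferred
    from the first row and only needed for an empty row list.
    """
    if rows:
        schema = "msn" if isinstance(rows[0], ResultRowMSN) else "nnh"
    elif schema is None:
        raise ValueError("schema required to write an empty table")
    columns = MSN_COLUMNS if schema == "msn" else NNH_COLUMNS
    lines = ["\t".join(columns)]
    for row in rows:
        if schema == "msn":
            assert isinstance(row, ResultRowMSN)
            lines.append("\t".join([
                row.subject_id, _fmt(row.L_0), _fmt(row.theta),
                _fmt(row.M_value), _fmt(row.L_M), str(int(row.N_M)),
                str(int(row.N)), _fmt(row.P_M), _fmt(row.L_L),
                str(int(row.N_L)), _fmt(row.P_L),
            ]))
        else:
            assert isinstance(row, ResultRowNNH)
            lines.append("\t".join([
                row.subject_id, _fmt(row.J), _fmt(row.S), _fmt(row.theta),
                _fmt(row.m), _fmt(row.x), _fmt(row.gamma), _fmt(row.R2),
                _fmt(row.chi2), _fmt(row.P), str(int(row.N_pass)),
                _fmt(row.pct_pass, 1),
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_result_table(path: str | Path) -> list[ResultRowMSN | ResultRowNNH]:
    """Read back a result TSV written by :func:`write_result_tables`."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    rows: list[ResultRowMSN | ResultRowNNH] = []
    if cols == MSN_COLUMNS:
        for rec in df.itertuples(index=False):
            rows.append(ResultRowMSN(str(rec.subject_id), rec.L_0, rec.theta,
                                     rec.M_value, rec.L_M, int(rec.N_M),
                                     int(rec.N), rec.P_M, rec.L_L,
                                     int(rec.N_L), rec.P_L))
    elif cols == NNH_COLUMNS:
        for rec in df.itertuples(index=False):
            rows.append(ResultRowNNH(str(rec.subject_id), rec.J, rec.S,
                                     rec.theta, rec.m, rec.x, rec.gamma,
                                     rec.R2, rec.chi2, rec.P,
                                     int(rec.N_pass), rec.pct_pass))
    else:
        raise ValueError(f"{path}: unrecognized result schema {cols}")
    return rows


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (seed, iterations, thresholds, version)."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(entries, indent=2, default=_default,
                                     sort_keys=True) + "\n")
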