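"""Expression and clinical-survival table I/O, probe collapsing, alignment.

Expression matrices are pandas DataFrames with one row per feature (probe or
gene symbol) and one column per sample.  The pipeline expects an
already-normalized matrix; the only preprocessing offered here is an optional
log2 transform and per-gene z-scoring (sample sd, ddof=1), which puts Cox
hazard ratios on a per-standard-deviation scale.

Survival data are carried as a small validated container: per-sample
follow-up time in months and an event indicator (1 = death observed,
0 = right-censored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up for a sample cohort.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, in a fixed order.
    time : numpy.ndarray
        Positive follow-up time in months, one per sample.
    event : numpy.ndarray
        1 if death was observed at ``time``, 0 if censored.
    """

    sample_ids: tuple[str, ...]
    time: np.ndarray = field(repr=False)
    event: np.ndarray = field(repr=False)

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids in survival data")
        if not (len(self.sample_ids) == len(time) == len(event)):
            raise ValueError("sample_ids, time and event lengths differ")
        bad = np.flatnonzero(~(time > 0))
        if bad.size:
            raise ValueError(
                f"non-positive survival time for sample {self.sample_ids[bad[0]]!r}"
            )
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: list[str]) -> "SurvivalData":
        """Restrict to ``sample_ids``, in the given order."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        pos = [idx[s] for s in sample_ids]
        return SurvivalData(tuple(sample_ids), self.time[pos], self.event[pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.time, "event": self.event},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def load_expression(path: str | Path, missing: str = "drop") -> pd.DataFrame:
    """Read a feature x sample expression TSV.

    The first column holds feature identifiers (probes or gene symbols), the
    header row holds sample identifiers.  Lines starting with ``!`` (GEO
    series-matrix metadata) are skipped, so a series-matrix table body loads
    directly.

    Parameters
    ----------
    missing
        ``"drop"``: remove rows containing any non-numeric/missing cell
        (count logged).  ``"mean"``: impute missing cells with the row mean.

    Raises
    ------
    ValueError
        On duplicate sample ids, duplicate handling of missing policy, or a
        table that is empty after parsing.
    """
    if missing not in ("drop", "mean"):
        raise ValueError(f"unknown missing-value policy: {missing!r}")
    # pandas mangles duplicate header names, so check the raw header first
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("!"):
                header = [c.strip() for c in line.rstrip("\n").split("\t")[1:]]
                break
        else:
            raise ValueError(f"{path}: empty expression table")
    dups = {c for c in header if header.count(c) > 1}
    if dups:
        raise ValueError(f"{path}: duplicate sample id {sorted(dups)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="!")
    if df.empty:
        raise ValueError(f"{path}: empty expression table")
    df = df.apply(pd.to_numeric, errors="coerce")
    na_rows = df.isna().any(axis=1)
    if na_rows.any():
        if missing == "drop":
            logger.warning(
                "dropping %d rows with missing values", int(na_rows.sum())
            )
            df = df.loc[~na_rows]
        else:
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    if df.empty:
        raise ValueError(f"{path}: no numeric rows left after missing-value policy")
    df.index = df.index.astype(str).str.strip().str.upper()
    df.index.name = "feature_id"
    return df.astype(float)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Collapse probe-level rows to gene symbols by arithmetic mean.

    A gene assayed by several probes gets, in each sample, the mean of those
    probes' intensities in that sample.  Probes without a mapping are dropped
    (count logged).
    """
    mapping = pd.Series(dict(probe_to_gene) if not isinstance(probe_to_gene, pd.Series) else probe_to_gene)
    mapping.index = mapping.index.astype(str).str.strip().str.upper()
    mapping = mapping.astype(str).str.strip().str.upper()
    mapped = probe_matrix.index.intersection(mapping.index)
    if mapped.empty:
        raise ValueError("no probes in the matrix have a gene mapping")
    n_drop = len(probe_matrix) - len(mapped)
    if n_drop:
        logger.info("dropping %d unmapped probes", n_drop)
    sub = probe_matrix.loc[mapped]
    collapsed = sub.groupby(mapping.loc[mapped].values).mean()
    collapsed.index.name = "gene"
    return collapsed


def standardize(m: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scoring: each row to mean 0, sample sd 1 (ddof=1).

    Zero-variance rows carry no information for a proportional-hazards fit
    and are dropped with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("standardize needs >=2 samples")
    sd = m.std(axis=1, ddof=1)
    dead = sd <= 0
    if dead.any():
        logger.warning("dropping %d zero-variance rows", int(dead.sum()))
        m = m.loc[~dead]
        sd = sd.loc[~dead]
    if m.empty:
        raise ValueError("all rows have zero variance")
    return m.sub(m.mean(axis=1), axis=0).div(sd, axis=0)


def load_survival(path: str | Path) -> SurvivalData:
    """Read a 3-column survival TSV: sample_id, time_months, event."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (sample_id, time_months, event)")
    sample_ids = df.iloc[:, 0].astype(str).str.strip()
    time = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    event = pd.to_numeric(df.iloc[:, 2], errors="raise").to_numpy()
    return SurvivalData(tuple(sample_ids), time, event)


def align_samples(
    m: pd.DataFrame, s: SurvivalData
) -> tuple[pd.DataFrame, SurvivalData]:
    """Restrict expression and survival to their shared samples.

    Both outputs use a single canonical order (expression column order
    filtered to the intersection).  Requires >=2 shared samples.
    """
    shared = [c for c in m.columns if c in set(s.sample_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared samples between expression and survival"
        )
    n_drop_m = m.shape[1] - len(shared)
    n_drop_s = s.n_samples - len(shared)
    if n_drop_m or n_drop_s:
        logger.info(
            "align: dropped %d expression-only and %d survival-only samples",
            n_drop_m,
            n_drop_s,
        )
    return m[shared], s.subset(shared)
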