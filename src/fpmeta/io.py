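"""Reading and writing long-format individual participant data.

The on-disk schema is one row per participant in a delimited text file
with a header: a study identifier, follow-up time, 0/1 event indicator,
the continuous exposure, optional entry time, and any number of
confounder columns.  Column names are configurable through
:class:`ColumnMap`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import winsorize
from .errors import SchemaError
from .study import StudyData

logger = logging.getLogger("fpmeta")


@dataclass
class ColumnMap:
    """Mapping from schema roles to column names in the data file."""

    study: str = "study"
    time: str = "time"
    event: str = "event"
    exposure: str = "exposure"
    entry: str | None = None
    confounders: tuple[str, ...] = ()


def _numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()]
    if len(bad):
        raise SchemaError(
            f"column {col!r}: non-numeric value {df.loc[bad[0], col]!r} "
            f"at row {int(bad[0])}"
        )
    missing = vals.index[vals.isna()]
    if len(missing):
        raise SchemaError(f"column {col!r}: missing value at row {int(missing[0])}")
    return vals.to_numpy(dtype=float)


def read_ipd(
    path,
    columns: ColumnMap | None = None,
    sep: str = ",",
    winsor: tuple[float, float] | None = (0.01, 0.99),
) -> list[StudyData]:
    """Load per-study containers from a delimited text file.

    The exposure is winsorized at the given centiles computed on the
    pooled (all-study) vector before any FP work (pass ``winsor=None``
    to skip).  Studies with zero events are loaded with a warning — a
    fit error occurs only if such a study is actually fitted.
    """
    cmap = columns or ColumnMap()
    df = pd.read_csv(path, sep=sep)
    required = [cmap.study, cmap.time, cmap.event, cmap.exposure]
    required += list(cmap.confounders)
    if cmap.entry:
        required.append(cmap.entry)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    time = _numeric(df, cmap.time)
    event = _numeric(df, cmap.event)
    exposure = _numeric(df, cmap.exposure)
    conf = (
        np.column_stack([_numeric(df, c) for c in cmap.confounders])
        if cmap.confounders else None
    )
    entry = _numeric(df, cmap.entry) if cmap.entry else None
    if not np.isin(event, (0.0, 1.0)).all():
        bad = int(np.where(~np.isin(event, (0.0, 1.0)))[0][0])
        raise SchemaError(f"column {cmap.event!r}: non-binary value at row {bad}")

    if winsor is not None:
        exposure = winsorize(exposure, *winsor)
    nonpos = np.where(exposure <= 0)[0]
    if nonpos.size:
        raise SchemaError(
            f"column {cmap.exposure!r}: non-positive exposure after "
            f"winsorization at row {int(nonpos[0])}"
        )

    studies = []
    for sid, idx in df.groupby(cmap.study, sort=True).groups.items():
        idx = np.asarray(idx)
        study = StudyData(
            study_id=str(sid),
            time=time[idx],
            event=event[idx].astype(int),
            exposure=exposure[idx],
            confounders=None if conf is None else conf[idx],
            confounder_names=tuple(cmap.confounders) or None,
            entry=None if entry is None else entry[idx],
        )
        logger.info("loaded study %s: n=%d, events=%d", sid, study.n,
                    study.n_events)
        if study.n_events == 0:
            logger.warning("study %s has zero events", sid)
        studies.append(study)
    if not studies:
        raise SchemaError("no studies found in input file")
    return studies


def write_ipd(
    studies: list[StudyData],
    path,
    columns: ColumnMap | None = None,
    sep: str = ",",
) -> Path:
    """Write studies back to the long-format delimited schema."""
    cmap = columns or ColumnMap()
    frames = []
    for study in studies:
        data = {
            cmap.study: study.study_id,
            cmap.time: study.time,
            cmap.event: study.event,
            cmap.exposure: study.exposure,
        }
        names = study.confounder_names or tuple(
            f"c{k + 1}" for k in range(study.confounders.shape[1])
        )
        for k, name in enumerate(names):
            data[name] = study.confounders[:, k]
        if study.entry is not None:
            data[cmap.entry or "entry"] = study.entry
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, sep=sep, index=False)
    return path
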