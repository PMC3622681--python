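"""Session container I/O.

A session is stored as one HDF5 file with a group per trial holding
``spikes`` (uint8 neurons x bins), ``kinematics`` (float bins x 6),
and metadata attributes.  Datasets are written without modification
times so that re-serializing the same records is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .task import TrialOutcome, TrialRecord

__all__ = ["write_session", "read_session", "outcomes_to_csv"]

_SCHEMA = "ofcbmi.session/1"


def write_session(records: Sequence[TrialRecord], path) -> None:
    """Write trial records to an HDF5 session container."""
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["schema"] = _SCHEMA
        f.attrs["n_trials"] = len(records)
        for i, rec in enumerate(records):
            g = f.create_group(f"trials/{i:05d}")
            g.create_dataset("spikes", data=rec.spikes, track_times=False)
            g.create_dataset("kinematics", data=rec.kinematics,
                             track_times=False)
            g.attrs["cued_target"] = rec.cued_target
            g.attrs["epoch_marks"] = np.asarray(rec.epoch_marks)
            if rec.intended_duration_bins is not None:
                g.attrs["intended_duration_bins"] = rec.intended_duration_bins
            if rec.outcome is not None:
                g.attrs["outcome_success"] = rec.outcome.success
                g.attrs["outcome_cause"] = rec.outcome.cause
                if rec.outcome.first_target_hit is not None:
                    g.attrs["outcome_first_hit"] = rec.outcome.first_target_hit
                if rec.outcome.acquisition_time_ms is not None:
                    g.attrs["outcome_acq_ms"] = rec.outcome.acquisition_time_ms


def read_session(path) -> list[TrialRecord]:
    """Read a session container; raises on corrupt or partial files."""
    path = Path(path)
    records: list[TrialRecord] = []
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != _SCHEMA:
            raise IOError(f"{path} is not an ofcbmi session file")
        n = int(f.attrs["n_trials"])
        trials = f.get("trials", {})
        for i in range(n):
            key = f"{i:05d}"
            if key not in trials:
                raise IOError(f"session file {path} missing trial {key}")
            g = trials[key]
            try:
                outcome = None
                if "outcome_cause" in g.attrs:
                    cause = str(g.attrs["outcome_cause"])
                    hit = g.attrs.get("outcome_first_hit")
                    acq = g.attrs.get("outcome_acq_ms")
                    outcome = TrialOutcome(
                        success=bool(g.attrs["outcome_success"]),
                        first_target_hit=None if hit is None else int(hit),
                        cause=cause,
                        acquisition_time_ms=None if acq is None else float(acq),
                    )
                dur = g.attrs.get("intended_duration_bins")
                records.append(TrialRecord(
                    cued_target=int(g.attrs["cued_target"]),
                    spikes=g["spikes"][()],
                    kinematics=g["kinematics"][()],
                    epoch_marks=tuple(int(x) for x in g.attrs["epoch_marks"]),
                    outcome=outcome,
                    intended_duration_bins=None if dur is None else int(dur),
                ))
            except (KeyError, ValueError) as exc:
                raise IOError(f"corrupt trial {key} in {path}: {exc}") from exc
    return records


def outcomes_to_csv(records: Sequence[TrialRecord], path) -> None:
    """Export per-trial outcomes as CSV."""
    rows = []
    for i, rec in enumerate(records):
        o = rec.outcome
        rows.append({
            "trial": i,
            "cued_target": rec.cued_target,
            "success": None if o is None else o.success,
            "cause": None if o is None else o.cause,
            "first_target_hit": None if o is None else o.first_target_hit,
            "acquisition_time_ms": None if o is None else o.acquisition_time_ms,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
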