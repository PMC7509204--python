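"""Reading and writing the pipeline's file formats.

RR files are the Kubios-compatible plain-text dialect: one interbeat
interval in milliseconds per line, one file per recording segment, named
``<subject>_<segment>.txt``.  Trial and covariate tables are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, SubjectSession
from .hrv import IBISeries

__all__ = ["SEGMENT_NAMES", "write_rr_file", "read_rr_file",
           "write_cohort", "read_cohort"]

#: The nine segment labels of one session.
SEGMENT_NAMES = ("rest_baseline",) + tuple(
    f"{c}_{part}" for c in CONDITIONS for part in ("baseline", "task"))


def write_rr_file(path, series: IBISeries) -> None:
    """One interval (ms) per line, fixed 2-decimal format for reproducibility."""
    Path(path).write_text(
        "\n".join(f"{v:.2f}" for v in series.intervals) + "\n")


def read_rr_file(path, label: str = "", subject: str = "") -> IBISeries:
    vals = np.loadtxt(path, dtype=float, ndmin=1)
    return IBISeries(vals, label=label, subject=subject)


def write_cohort(sessions, outdir, ground_truth=None) -> None:
    """Write RR files, trials.csv and covariates.csv (and optional truth)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cov_rows = []
    trial_frames = []
    for s in sessions:
        for name, series in s.segments.items():
            write_rr_file(out / f"{s.subject}_{name}.txt", series)
        cov_rows.append(dict(subject=s.subject, age=s.age, sex=s.sex, bmi=s.bmi))
        trial_frames.append(s.trials)
    pd.DataFrame(cov_rows).to_csv(out / "covariates.csv", index=False,
                                  float_format="%.2f")
    trials = pd.concat(trial_frames, ignore_index=True)
    trials.to_csv(out / "trials.csv", index=False, float_format="%.3f")
    if ground_truth is not None:
        ground_truth.latents.to_csv(out / "ground_truth_latents.csv",
                                    index=False, float_format="%.6f")
        ground_truth.reactivity_shifts.to_csv(
            out / "ground_truth_reactivity.csv", index=False, float_format="%.4f")
        ground_truth.interference_true.to_csv(
            out / "ground_truth_interference.csv", index=False, float_format="%.4f")


def read_cohort(indir) -> list[SubjectSession]:
    """Rebuild sessions from a directory written by :func:`write_cohort`."""
    d = Path(indir)
    cov = pd.read_csv(d / "covariates.csv", dtype={"subject": str})
    trials = pd.read_csv(d / "trials.csv", dtype={"subject": str})
    sessions = []
    for row in cov.itertuples():
        segments = {}
        for name in SEGMENT_NAMES:
            f = d / f"{row.subject}_{name}.txt"
            if not f.exists():
                raise FileNotFoundError(f"missing segment file {f}")
            segments[name] = read_rr_file(f, label=name, subject=row.subject)
        sessions.append(SubjectSession(
            subject=row.subject, age=float(row.age), sex=int(row.sex),
            bmi=float(row.bmi),
            segments=segments,
            trials=trials[trials["subject"] == row.subject].reset_index(drop=True),
            condition_order=(),
        ))
    return sessions
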