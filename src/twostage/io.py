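"""Trial-table file format, preprocessing/exclusion rules and fixtures.

The on-disk format is a UTF-8 comma-delimited table with one row per trial
and the exact header::

    subject_id,timepoint,block,trial,choice1,transition,state2,choice2,reward,rt1_s,rt2_s

RTs are stored in seconds; missing RTs (choice-only data) are empty fields.
A mapping hook (``column_map``) lets externally produced tables with other
column names be ingested.

Preprocessing follows the standard exclusion rules for this task: subjects
pressing the same first-stage key on more than 95% of trials or with
implausibly fast RTs (< 150 ms) on more than 10% of trials are excluded;
for the remaining subjects each block's first trial and any trial with an
implausible RT are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import SessionData, TaskConfig, validate_transitions

__all__ = [
    "SCHEMA_COLUMNS", "ExclusionReport", "read_trials", "write_trials",
    "apply_exclusions", "make_fixtures",
    "SAME_KEY_THRESHOLD", "FAST_RT_THRESHOLD", "MIN_RT_S",
]

SCHEMA_COLUMNS = ["subject_id", "timepoint", "block", "trial", "choice1",
                  "transition", "state2", "choice2", "reward", "rt1_s",
                  "rt2_s"]

SAME_KEY_THRESHOLD = 0.95   # subject excluded above this same-key fraction
FAST_RT_THRESHOLD = 0.10    # subject excluded above this fast-RT fraction
MIN_RT_S = 0.150            # implausibly fast RT bound (seconds)


@dataclass
class ExclusionReport:
    """Exclusion bookkeeping.

    ``subjects`` has one row per session (same-key and fast-RT fractions,
    excluded flag and reason); ``trials`` has one row per dropped trial of
    every retained session (reason: ``block_first`` or ``fast_rt``).
    """

    subjects: pd.DataFrame
    trials: pd.DataFrame
    n_trials_dropped: int
    n_subjects_excluded: int


def write_trials(sessions: Sequence[SessionData], path) -> None:
    """Serialise sessions to the trial CSV (full float precision)."""
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df.insert(0, "subject_id", s.subject_id)
        df.insert(1, "timepoint", s.timepoint)
        df = df.rename(columns={"rt1": "rt1_s", "rt2": "rt2_s"})
        frames.append(df[SCHEMA_COLUMNS])
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")


def read_trials(path, config: Optional[TaskConfig] = None,
                column_map: Optional[dict] = None) -> list[SessionData]:
    """Parse a trial CSV into sessions (one per subject x timepoint).

    Validates the header, the categorical fields and the consistency of
    every transition label with (choice1, state2); errors cite the
    offending line.  ``column_map`` renames external columns onto the
    schema before validation.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[SCHEMA_COLUMNS]

    def _bad(mask, what):
        if mask.any():
            line = int(np.nonzero(mask.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"{path}:{line}: {what}")

    _bad(~df["choice1"].isin([1, 2]), "choice1 must be 1 or 2")
    _bad(~df["choice2"].isin([1, 2]), "choice2 must be 1 or 2")
    _bad(~df["state2"].isin([2, 3]), "state2 must be 2 or 3")
    _bad(~df["transition"].isin(["common", "rare"]), "bad transition label")
    _bad(~df["reward"].isin([0, 1]), "reward must be 0 or 1")
    for c in ("rt1_s", "rt2_s"):
        _bad(df[c].notna() & ~(df[c] > 0), f"{c} must be positive when present")

    sessions = []
    for (sid, tp), grp in df.groupby(["subject_id", "timepoint"], sort=False):
        trials = grp.drop(columns=["subject_id", "timepoint"]).rename(
            columns={"rt1_s": "rt1", "rt2_s": "rt2"}).reset_index(drop=True)
        try:
            validate_transitions(trials)
        except ValueError as e:
            raise ValueError(f"{path}: subject {sid}/{tp}: {e}") from None
        cfg = config or TaskConfig(
            n_trials=max(len(trials), 2),
            n_blocks=max(int(trials["block"].nunique()), 1))
        sessions.append(SessionData(str(sid), str(tp), cfg, trials))
    return sessions


def apply_exclusions(sessions: Sequence[SessionData],
                     same_key_threshold: float = SAME_KEY_THRESHOLD,
                     fast_rt_threshold: float = FAST_RT_THRESHOLD,
                     min_rt_s: float = MIN_RT_S,
                     ) -> tuple[list[SessionData], ExclusionReport]:
    """Apply the subject- and trial-level exclusion rules.

    The same-key rule looks at stage-1 responses; the fast-RT rules look at
    both stages' RTs.  RT-based rules are skipped (fractions NaN) for
    choice-only sessions.  Retained sessions keep their original trial
    indices so downstream stay-pair logic can detect the gaps.
    """
    kept, rows, trial_rows = [], [], []
    n_dropped = 0
    for s in sessions:
        t = s.trials
        c1 = t["choice1"].to_numpy()
        same_key = max((c1 == 1).mean(), (c1 == 2).mean()) if len(t) else np.nan
        rts = t[["rt1", "rt2"]].to_numpy(dtype=float)
        has_rt = np.isfinite(rts).any()
        fast = np.zeros(len(t), dtype=bool)
        if has_rt:
            with np.errstate(invalid="ignore"):
                fast = np.nanmin(rts, axis=1) < min_rt_s
            fast_frac = float(fast.mean())
        else:
            fast_frac = np.nan
        excluded = bool(same_key > same_key_threshold) or bool(
            has_rt and fast_frac > fast_rt_threshold)
        reason = ("same_key" if same_key > same_key_threshold else
                  "fast_rt" if excluded else "")
        rows.append({"subject_id": s.subject_id, "timepoint": s.timepoint,
                     "same_key_fraction": float(same_key),
                     "fast_rt_fraction": fast_frac,
                     "excluded": excluded, "reason": reason})
        if excluded:
            continue
        first = t["block"].ne(t["block"].shift()).to_numpy()
        drop = first | fast
        n_dropped += int(drop.sum())
        for idx in np.nonzero(drop)[0]:
            trial_rows.append({
                "subject_id": s.subject_id, "timepoint": s.timepoint,
                "trial": int(t["trial"].iloc[idx]),
                "reason": "fast_rt" if fast[idx] else "block_first"})
        kept.append(SessionData(s.subject_id, s.timepoint, s.config,
                                t.loc[~drop].reset_index(drop=True)))
    report = ExclusionReport(
        pd.DataFrame(rows),
        pd.DataFrame(trial_rows,
                     columns=["subject_id", "timepoint", "trial", "reason"]),
        n_dropped, int(sum(r["excluded"] for r in rows)))
    return kept, report


def make_fixtures(seed: int = 20240, n_subjects: int = 6, n_trials: int = 50,
                  ) -> list[SessionData]:
    """Deterministic small cohorts for tests and docs.

    ``n_subjects`` agents at two timepoints: diffusion agents (with RTs) at
    both.  Parameters are drawn uniformly from the canonical ranges except
    that non-decision times start at 200 ms and the stage-1 drift scaling
    and perseveration are kept moderate, so that no fixture subject trips
    the same-key or fast-RT exclusion rules.
    """
    from .psychometrics import simulate_cohort
    ranges = {"tau1": (0.2, 0.5), "tau2": (0.2, 0.5),
              "b1": (1.0, 3.0), "p": (0.0, 0.2)}
    out = []
    for i, tp in enumerate(("baseline", "followup")):
        out.extend(simulate_cohort("ddm11", n_subjects, n_trials,
                                   seed + 1000 * i, ranges=ranges,
                                   timepoint=tp))
    return out
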