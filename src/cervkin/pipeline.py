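"""Cohort-level orchestration: raw recordings → subject metric table →
statistical inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_analysis import FeatureTable
from .kinematics import compute_signals
from .metrics import METRIC_NAMES, aggregate_subject, process_trial
from .reliability import PairedMeasurements
from .trial_io import CohortDataset

__all__ = ["process_cohort", "feature_table", "paired_measurements"]


def process_cohort(
    ds: CohortDataset, sid_denominator: str = "mean"
) -> pd.DataFrame:
    """Run the per-trial pipeline over every non-practice trial and average
    valid trials per subject and session (left/right pooled).

    Returns one row per subject × session with the six kinematic variables,
    ``n_valid_trials``, and the subject metadata; subjects with no valid
    trial in a session are reported with NaN metrics.
    """
    rows = []
    seen = set()
    for subj in ds.subjects:
        key = (subj.subject_id, subj.session)
        if key in seen:
            continue
        seen.add(key)
        trials = ds.trials_for(subj.subject_id, subj.session)
        metrics = [
            process_trial(compute_signals(rec), sid_denominator=sid_denominator)
            for rec in trials
        ]
        row = {
            "subject_id": subj.subject_id,
            "session": subj.session,
            "group": subj.group,
            "age": subj.age_years,
            "low_back_pain": subj.low_back_pain,
            "n_trials": len(trials),
        }
        try:
            agg = aggregate_subject(metrics, session=subj.session)
            row.update({name: agg.means[name] for name in METRIC_NAMES})
            row["n_valid_trials"] = agg.n_valid_trials
        except ValueError:
            row.update({name: np.nan for name in METRIC_NAMES})
            row["n_valid_trials"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def feature_table(metrics_df: pd.DataFrame, session: str = "test1") -> FeatureTable:
    """Subject-level feature table for group analysis from one session."""
    df = metrics_df[metrics_df["session"] == session].copy()
    df = df[df["n_valid_trials"] >= 1]
    return FeatureTable(frame=df.reset_index(drop=True))


def paired_measurements(
    metrics_df: pd.DataFrame, variable: str, group: str
) -> PairedMeasurements:
    """Test-retest pairs for one variable in one group, dropping subjects
    without both sessions or with an undefined value in either."""
    df = metrics_df[metrics_df["group"] == group]
    t1 = df[df["session"] == "test1"].set_index("subject_id")[variable]
    t2 = df[df["session"] == "test2"].set_index("subject_id")[variable]
    common = t1.index.intersection(t2.index)
    a, b = t1.loc[common], t2.loc[common]
    keep = a.notna() & b.notna()
    return PairedMeasurements(
        subject_ids=list(common[keep]),
        test1=a[keep].to_numpy(float),
        test2=b[keep].to_numpy(float),
        variable_name=variable,
        group=group,
    )
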