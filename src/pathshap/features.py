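"""Event-level feature extraction from IC time courses.

One fMRI volume is selected per event — by default the third volume
acquired after stimulus onset, which under the default onset-to-scanner
alignment falls 6.5 s post onset, near the hemodynamic peak.  The value of
each of the 125 IC time courses at that volume becomes one feature, giving
one 125-dimensional instance per event, labeled with the event's category.
Instances are partitioned into train/test by *subject* (never by event),
and standardization defaults to training-set statistics applied to both
splits so no test information leaks into the features.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .synthetic import Cohort, EventSchedule, ICTimeSeries

IC_PREFIX = "IC"


def feature_columns(n_ics: int = 125) -> list[str]:
    return [f"{IC_PREFIX}{i + 1}" for i in range(n_ics)]


def select_volume(
    onset_seconds: float,
    tr_seconds: float,
    volume_offset: int = 3,
    n_volumes: int | None = None,
) -> int:
    """Index (0-based) of the ``volume_offset``-th volume after an onset.

    Volumes are acquired at times ``k * tr_seconds``; the count starts at
    the first volume acquired strictly after the onset.  With onsets placed
    1.0 s after an acquisition (the default schedule alignment) the
    post-onset samples fall at +1.5, +4.0 and +6.5 s, so the default
    ``volume_offset=3`` selects the sample 6.5 s after onset.
    """
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    if volume_offset < 1:
        raise ValueError(f"volume_offset must be >= 1, got {volume_offset}")
    if onset_seconds < 0:
        raise ValueError(f"onset_seconds must be >= 0, got {onset_seconds}")
    # tolerance so onsets sitting exactly on the grid are not shifted by
    # floating-point jitter; "strictly after" is kept for on-grid onsets
    first_after = math.floor(onset_seconds / tr_seconds + 1e-9) + 1
    idx = first_after + volume_offset - 1
    if n_volumes is not None and idx >= n_volumes:
        raise ValueError(
            f"selected volume {idx} for onset {onset_seconds} s is past the "
            f"end of the scan ({n_volumes} volumes)"
        )
    return idx


def build_instances(cohort: Cohort, volume_offset: int = 3) -> pd.DataFrame:
    """One instance per event: IC values at the selected volume.

    Returns a DataFrame with columns ``subject, split, category, valence,
    onset_s, IC1..ICn`` — unstandardized.
    """
    rows = []
    for subj in cohort.subjects:
        ts = subj.timeseries
        for ev in subj.schedule.events:
            idx = select_volume(
                ev.onset_seconds,
                ts.tr_seconds,
                volume_offset=volume_offset,
                n_volumes=ts.n_volumes,
            )
            rows.append(
                (subj.subject_id, subj.split, ev.category, ev.valence,
                 ev.onset_seconds, ts.data[idx])
            )
    n_ics = cohort.subjects[0].timeseries.n_ics if cohort.subjects else 0
    meta = pd.DataFrame(
        [r[:5] for r in rows],
        columns=["subject", "split", "category", "valence", "onset_s"],
    )
    feats = pd.DataFrame(
        np.array([r[5] for r in rows]).reshape(len(rows), n_ics),
        columns=feature_columns(n_ics),
    )
    return pd.concat([meta, feats], axis=1)


def split_instances(
    instances: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition an instance table into (train, test) by its split tag."""
    train = instances[instances["split"] == "train"].reset_index(drop=True)
    test = instances[instances["split"] == "test"].reset_index(drop=True)
    assert_no_leakage(train, test)
    return train, test


def assert_no_leakage(train: pd.DataFrame, test: pd.DataFrame) -> None:
    """Raise if any subject contributes instances to both splits."""
    shared = set(train["subject"]) & set(test["subject"])
    if shared:
        raise ValueError(
            f"subject-level leakage: {sorted(shared)} appear in both splits"
        )


def standardize(
    train: pd.DataFrame,
    test: pd.DataFrame,
    mode: str = "train_stats",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score the IC feature columns of both splits.

    ``train_stats`` (default, leakage-safe): both splits are scaled with
    the training set's per-feature mean and SD.  ``independent``: each
    split is scaled with its own statistics.  Population (ddof=0) SDs.
    A zero-variance feature raises, naming the feature.
    """
    if mode not in ("train_stats", "independent"):
        raise ValueError(f"unknown standardization mode: {mode!r}")
    cols = [c for c in train.columns if c.startswith(IC_PREFIX)]

    def _zscore(df: pd.DataFrame, stats_df: pd.DataFrame) -> pd.DataFrame:
        mu = stats_df[cols].mean(axis=0)
        sd = stats_df[cols].std(axis=0, ddof=0)
        dead = sd.index[sd == 0.0]
        if len(dead):
            raise ValueError(
                f"zero-variance feature(s): {', '.join(dead)}"
            )
        out = df.copy()
        out[cols] = (df[cols] - mu) / sd
        return out

    if mode == "train_stats":
        return _zscore(train, train), _zscore(test, train)
    return _zscore(train, train), _zscore(test, test)


def as_xy(instances: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (features, category labels) arrays from an instance table."""
    cols = [c for c in instances.columns if c.startswith(IC_PREFIX)]
    return instances[cols].to_numpy(dtype=float), instances["category"].to_numpy()
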