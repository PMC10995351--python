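"""Plain-text persistence for cohorts and ground truth.

Per subject: ``<id>_timeseries.csv`` (volumes x ICs, header ``IC1..``),
``<id>_events.csv`` (``onset_s,category,valence``) and a ``<id>.json``
sidecar (subject id, TR, split).  Ground truth goes to ``truth.json``.
All formats are round-trip exact up to CSV float printing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    Cohort,
    Event,
    EventSchedule,
    GroundTruth,
    ICTimeSeries,
    Subject,
)


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "informative": {c: list(ics) for c, ics in truth.informative.items()},
        "effect_size": [
            {"category": c, "ic": ic, "effect": e}
            for (c, ic), e in truth.effect_size.items()
        ],
        "noise_sd": truth.noise_sd,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        informative={c: tuple(ics) for c, ics in d["informative"].items()},
        effect_size={
            (e["category"], e["ic"]): e["effect"] for e in d["effect_size"]
        },
        noise_sd=d["noise_sd"],
    )


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_truth(cohort.truth, out / "truth.json")
    for s in cohort.subjects:
        s.timeseries.to_frame().to_csv(
            out / f"{s.subject_id}_timeseries.csv", index=False
        )
        s.schedule.to_frame().to_csv(out / f"{s.subject_id}_events.csv", index=False)
        (out / f"{s.subject_id}.json").write_text(
            json.dumps(
                {
                    "subject_id": s.subject_id,
                    "tr_seconds": s.timeseries.tr_seconds,
                    "split": s.split,
                }
            )
        )


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    truth = load_truth(src / "truth.json")
    subjects = []
    for sidecar in sorted(src.glob("sub-*.json")):
        meta = json.loads(sidecar.read_text())
        sid = meta["subject_id"]
        ts = pd.read_csv(src / f"{sid}_timeseries.csv")
        ev = pd.read_csv(src / f"{sid}_events.csv")
        events = tuple(
            Event(onset_seconds=float(r.onset_s), category=r.category,
                  valence=r.valence)
            for r in ev.itertuples()
        )
        subjects.append(
            Subject(
                subject_id=sid,
                split=meta["split"],
                schedule=EventSchedule(subject_id=sid, events=events),
                timeseries=ICTimeSeries(
                    subject_id=sid,
                    data=ts.to_numpy(dtype=float),
                    tr_seconds=meta["tr_seconds"],
                ),
            )
        )
    return Cohort(subjects=tuple(subjects), truth=truth)
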