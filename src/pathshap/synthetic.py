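"""Synthetic cohorts for the event-related brand-perception paradigm.

Real acquisitions for this kind of study are rarely redistributable, so the
package ships a generator that emulates the measurement chain downstream of
ICA: per-subject independent-component (IC) time courses sampled every TR,
in which a small, known subset of ICs carries category-specific signal —
each event convolved with a hemodynamic response peaking 5-7 s post onset —
on top of i.i.d. Gaussian noise.  Because the informative ICs are known
(:class:`GroundTruth`), every downstream stage (feature extraction, network
training, pruning, Shapley attribution) can be checked for parameter
recovery, not just for running without error.

The paradigm is a rapid event-related design: four stimulus categories
(BP = preferred brands, BI = indifferent brands, O = objects, P = people),
40 events per category per subject, each event 4.0 s of stimulus followed
by a 3.5 s fixation cross, acquired with TR = 2.5 s over 485 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES: tuple[str, ...] = ("BP", "BI", "O", "P")
VALENCES: tuple[str, ...] = ("+", "-")

#: default acquisition geometry
TR_SECONDS = 2.5
N_VOLUMES = 485
N_ICS = 125

#: event timing: 4.0 s stimulus + 3.5 s fixation
EVENT_DURATION_S = 7.5
#: default lead-in rest; places onsets 1.0 s after a volume acquisition so
#: the post-onset samples fall at +1.5, +4.0, +6.5 s (third sample = 6.5 s)
DEFAULT_FIRST_ONSET_S = 6.0


class ScheduleError(ValueError):
    """An event schedule does not fit the scan it is paired with."""


# --------------------------------------------------------------------------
# Hemodynamic response
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HRF:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    The response is the difference of two gamma densities: a positive lobe
    whose mode sits at ``peak_delay`` seconds and a later, smaller negative
    lobe (the undershoot) at ``undershoot_delay``.  Shapes are
    mode-parameterized: the gamma shape is ``delay / dispersion + 1`` with
    scale ``dispersion``, so the stated delays are exact lobe modes.

    Parameters are configurable; the defaults put the overall peak at
    ~6 s, inside the 5-7 s window BOLD responses are observed to peak in.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def _raw(self, t: np.ndarray) -> np.ndarray:
        pos = stats.gamma.pdf(
            t,
            self.peak_delay / self.peak_dispersion + 1.0,
            scale=self.peak_dispersion,
        )
        neg = stats.gamma.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion + 1.0,
            scale=self.undershoot_dispersion,
        )
        return pos - self.undershoot_ratio * neg

    @property
    def _amplitude(self) -> float:
        # raw peak height, used to normalize the kernel maximum to 1
        tt = np.arange(0.0, self.undershoot_delay + 16.0, 0.001)
        return float(self._raw(tt).max())

    def __call__(self, t) -> np.ndarray:
        """Evaluate the peak-normalized response at time(s) ``t`` (seconds).

        Zero for ``t < 0`` (causality).
        """
        t = np.asarray(t, dtype=float)
        out = np.where(t >= 0.0, self._raw(np.clip(t, 0.0, None)), 0.0)
        return out / self._amplitude

    def integral(self, duration_seconds: float) -> float:
        """Analytic integral of the normalized kernel over [0, duration].

        Uses the gamma CDF, so it is exact up to the peak-height
        normalization; tests check it against independent quadrature.
        """
        pos = stats.gamma.cdf(
            duration_seconds,
            self.peak_delay / self.peak_dispersion + 1.0,
            scale=self.peak_dispersion,
        )
        neg = stats.gamma.cdf(
            duration_seconds,
            self.undershoot_delay / self.undershoot_dispersion + 1.0,
            scale=self.undershoot_dispersion,
        )
        return float(pos - self.undershoot_ratio * neg) / self._amplitude


@dataclass(frozen=True)
class SampledHRF:
    """An :class:`HRF` sampled on a regular time grid."""

    times: np.ndarray
    values: np.ndarray
    tr_seconds: float
    #: analytic integral of the continuous kernel over the sampled window
    normalization: float
    hrf: HRF

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.values))])


def gen_hrf(
    tr_seconds: float = TR_SECONDS,
    duration_seconds: float = 32.5,
    hrf: HRF | None = None,
) -> SampledHRF:
    """Sample a hemodynamic response kernel on the acquisition grid.

    Parameters
    ----------
    tr_seconds
        Sampling interval (the scanner TR); must be positive.
    duration_seconds
        Length of the sampled window; must cover the response peak.
    hrf
        Continuous response to sample; default canonical double gamma.
    """
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    hrf = hrf or HRF()
    if duration_seconds < hrf.peak_delay:
        raise ValueError(
            f"duration_seconds={duration_seconds} does not cover the "
            f"response peak at ~{hrf.peak_delay} s"
        )
    times = np.arange(0.0, duration_seconds + 1e-9, tr_seconds)
    return SampledHRF(
        times=times,
        values=hrf(times),
        tr_seconds=tr_seconds,
        normalization=hrf.integral(duration_seconds),
        hrf=hrf,
    )


# --------------------------------------------------------------------------
# Behavioral ratings
# --------------------------------------------------------------------------


def gen_ratings(
    n_stimuli: int = 200,
    seed: int = 0,
    class_probs: tuple[float, float, float] = (0.35, 0.35, 0.30),
) -> pd.DataFrame:
    """Simulate per-stimulus pleasure/arousal ratings for brand screening.

    Each stimulus gets one (pleasure, arousal) pair, pleasure on the
    five-point -2..+2 scale and arousal on 1..5.  To guarantee that the
    screening classes are well populated by default, the generator first
    draws the screening class (preferred / indifferent / discarded) from
    ``class_probs`` and then a rating pair uniformly inside that class's
    region of the rating grid; with the defaults and 200 stimuli each
    retained class holds ~70 stimuli, comfortably above the 40 the
    selection step needs.

    Returns a DataFrame with columns ``stimulus_id, pleasure, arousal``.
    """
    if n_stimuli < 1:
        raise ValueError(f"n_stimuli must be >= 1, got {n_stimuli}")
    probs = np.asarray(class_probs, dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_probs must be non-negative and sum to 1")

    # rating-grid cells per screening class
    preferred = [(p, a) for p in (1, 2) for a in (3, 4, 5)]
    indifferent = [(0, a) for a in (1, 2, 3)]
    all_cells = [(p, a) for p in range(-2, 3) for a in range(1, 6)]
    discarded = [c for c in all_cells if c not in preferred and c not in indifferent]
    regions = (preferred, indifferent, discarded)

    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=n_stimuli, p=probs)
    pleasure = np.empty(n_stimuli, dtype=int)
    arousal = np.empty(n_stimuli, dtype=int)
    for i, c in enumerate(classes):
        cells = regions[c]
        p, a = cells[rng.integers(len(cells))]
        pleasure[i] = p
        arousal[i] = a
    return pd.DataFrame(
        {
            "stimulus_id": np.arange(1, n_stimuli + 1),
            "pleasure": pleasure,
            "arousal": arousal,
        }
    )


# --------------------------------------------------------------------------
# Event schedules and ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    onset_seconds: float
    category: str
    valence: str


@dataclass(frozen=True)
class EventSchedule:
    subject_id: str
    events: tuple[Event, ...]

    @property
    def end_seconds(self) -> float:
        if not self.events:
            return 0.0
        return max(e.onset_seconds for e in self.events) + EVENT_DURATION_S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_seconds for e in self.events],
                "category": [e.category for e in self.events],
                "valence": [e.valence for e in self.events],
            }
        )


@dataclass(frozen=True)
class GroundTruth:
    """Which ICs carry which category's signal, and how strongly.

    ``informative`` maps category -> IC indices (0-based); ``effect_size``
    maps (category, ic) -> response amplitude in noise-SD-free units.
    Non-informative ICs are pure noise.
    """

    informative: dict[str, tuple[int, ...]]
    effect_size: dict[tuple[str, int], float]
    noise_sd: float = 0.5

    @classmethod
    def default(
        cls, effect_size: float = 1.0, noise_sd: float = 0.5
    ) -> "GroundTruth":
        """Two informative ICs per category, disjoint across categories."""
        informative = {
            "BP": (3, 17),
            "BI": (9, 42),
            "O": (54, 71),
            "P": (88, 103),
        }
        effects = {
            (cat, ic): effect_size
            for cat, ics in informative.items()
            for ic in ics
        }
        return cls(informative=informative, effect_size=effects, noise_sd=noise_sd)

    @property
    def all_informative(self) -> set[int]:
        return {ic for ics in self.informative.values() for ic in ics}


def gen_schedule(
    subject_id: str,
    seed: int,
    n_per_category: int = 40,
    first_onset_seconds: float = DEFAULT_FIRST_ONSET_S,
    drop_events: list[int] | None = None,
) -> EventSchedule:
    """Generate one subject's randomized event schedule.

    Events are back-to-back 7.5 s slots (4.0 s stimulus + 3.5 s fixation)
    starting at ``first_onset_seconds``; the category/valence order is a
    seeded permutation of the balanced deck (``n_per_category`` events per
    category, half of each valence).  ``drop_events`` removes events by
    position after scheduling, leaving a gap — useful for emulating
    discarded acquisitions.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    half = n_per_category // 2
    deck = [
        (cat, val)
        for cat in CATEGORIES
        for val, count in zip(VALENCES, (half, n_per_category - half))
        for _ in range(count)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(deck))
    events = [
        Event(
            onset_seconds=first_onset_seconds + i * EVENT_DURATION_S,
            category=deck[j][0],
            valence=deck[j][1],
        )
        for i, j in enumerate(order)
    ]
    if drop_events:
        keep = [e for i, e in enumerate(events) if i not in set(drop_events)]
        events = keep
    return EventSchedule(subject_id=subject_id, events=tuple(events))


def gen_ic_timecourses(
    schedule: EventSchedule,
    truth: GroundTruth,
    hrf: HRF | None = None,
    seed: int = 0,
    n_volumes: int = N_VOLUMES,
    n_ics: int = N_ICS,
    tr_seconds: float = TR_SECONDS,
) -> "ICTimeSeries":
    """Simulate one subject's IC time-course matrix (volumes x ICs).

    An informative IC's course is the sum, over its categories' events, of
    ``effect_size * HRF(t - onset)``, plus Gaussian noise with SD
    ``truth.noise_sd``; non-informative ICs are pure noise (exactly zero
    when ``noise_sd == 0``).
    """
    hrf = hrf or HRF()
    scan_s = n_volumes * tr_seconds
    if schedule.events and schedule.end_seconds > scan_s:
        raise ScheduleError(
            f"schedule for {schedule.subject_id} ends at "
            f"{schedule.end_seconds:.1f} s but the scan lasts {scan_s:.1f} s"
        )
    rng = np.random.default_rng(seed)
    t_vol = np.arange(n_volumes) * tr_seconds
    data = np.zeros((n_volumes, n_ics))
    # per-category regressor: sum of shifted HRFs over that category's onsets
    for cat in CATEGORIES:
        onsets = np.array(
            [e.onset_seconds for e in schedule.events if e.category == cat]
        )
        if onsets.size == 0:
            continue
        regressor = hrf(t_vol[:, None] - onsets[None, :]).sum(axis=1)
        for ic in truth.informative.get(cat, ()):
            data[:, ic] += truth.effect_size[(cat, ic)] * regressor
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd, size=data.shape)
    return ICTimeSeries(
        subject_id=schedule.subject_id,
        data=data,
        tr_seconds=tr_seconds,
    )


@dataclass(frozen=True)
class ICTimeSeries:
    subject_id: str
    data: np.ndarray  # n_volumes x n_ics
    tr_seconds: float = TR_SECONDS

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_ics(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"IC{i + 1}" for i in range(self.n_ics)]
        return pd.DataFrame(self.data, columns=cols)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Subject:
    subject_id: str
    split: str  # "train" | "test"
    schedule: EventSchedule
    timeseries: ICTimeSeries


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]
    truth: GroundTruth

    def split(self, which: str) -> list[Subject]:
        return [s for s in self.subjects if s.split == which]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def gen_cohort(
    truth: GroundTruth | None = None,
    n_train: int = 15,
    n_test: int = 7,
    seed: int = 0,
    hrf: HRF | None = None,
    n_per_category: int = 40,
    n_volumes: int = N_VOLUMES,
    n_ics: int = N_ICS,
    tr_seconds: float = TR_SECONDS,
    drop_events: dict[str, list[int]] | None = None,
) -> Cohort:
    """Generate a cohort with a subject-level train/test split.

    Each subject gets an independent event order and independent noise
    (child seeds spawned from ``seed``); the split is by subject, so no
    subject contributes instances to both sides.  Defaults mirror the
    study design: 22 subjects, 15 train / 7 test, 160 events each.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must each be >= 1")
    truth = truth or GroundTruth.default()
    hrf = hrf or HRF()
    drop_events = drop_events or {}
    ss = np.random.SeedSequence(seed)
    subjects = []
    n_total = n_train + n_test
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_total)]
    for i in range(n_total):
        split = "train" if i < n_train else "test"
        sid = f"sub-{i + 1:02d}"
        sched = gen_schedule(
            sid,
            seed=child_seeds[2 * i],
            n_per_category=n_per_category,
            drop_events=drop_events.get(sid),
        )
        ts = gen_ic_timecourses(
            sched,
            truth,
            hrf=hrf,
            seed=child_seeds[2 * i + 1],
            n_volumes=n_volumes,
            n_ics=n_ics,
            tr_seconds=tr_seconds,
        )
        subjects.append(
            Subject(subject_id=sid, split=split, schedule=sched, timeseries=ts)
        )
    return Cohort(subjects=tuple(subjects), truth=truth)
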