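"""Behavioral screening of brand stimuli from pleasure/arousal ratings.

Stimuli are rated on five-point pleasure (-2..+2) and arousal (1..5)
scales (dominance is deliberately ignored).  A stimulus is *preferred*
when pleasure is +1 or +2 and arousal >= 3, *indifferent* when pleasure
is 0 and arousal <= 3, and *discarded* otherwise; 40 stimuli per retained
class are then drawn at random for the scanning session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PREFERRED = "preferred"
INDIFFERENT = "indifferent"
DISCARDED = "discarded"
LABELS = (PREFERRED, INDIFFERENT, DISCARDED)


class ShortageError(ValueError):
    """A screening class holds fewer stimuli than the selection needs."""

    def __init__(self, label: str, available: int, needed: int):
        self.label = label
        self.available = available
        self.needed = needed
        super().__init__(
            f"screening class '{label}' has only {available} stimuli, "
            f"{needed} required"
        )


def classify_stimulus(pleasure: int, arousal: int) -> str:
    """Assign one screening label from a (pleasure, arousal) rating pair."""
    if pleasure not in (-2, -1, 0, 1, 2):
        raise ValueError(f"pleasure must be in -2..+2, got {pleasure}")
    if arousal not in (1, 2, 3, 4, 5):
        raise ValueError(f"arousal must be in 1..5, got {arousal}")
    if pleasure >= 1 and arousal >= 3:
        return PREFERRED
    if pleasure == 0 and arousal <= 3:
        return INDIFFERENT
    return DISCARDED


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Label every stimulus in a rating table.

    Returns a copy of ``table`` with a ``label`` column appended.
    """
    labels = [
        classify_stimulus(int(p), int(a))
        for p, a in zip(table["pleasure"], table["arousal"])
    ]
    out = table.copy()
    out["label"] = labels
    return out


def screen_and_select(
    table: pd.DataFrame, n_per_group: int = 40, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Screen a rating table and draw ``n_per_group`` stimuli per class.

    Sampling is without replacement with a seeded generator.  Returns
    (preferred ids, indifferent ids); raises :class:`ShortageError` naming
    the deficient class if either holds fewer than ``n_per_group``.
    """
    labeled = classify_table(table)
    out: list[list[int]] = []
    rng = np.random.default_rng(seed)
    for label in (PREFERRED, INDIFFERENT):
        ids = labeled.loc[labeled["label"] == label, "stimulus_id"].to_numpy()
        if len(ids) < n_per_group:
            raise ShortageError(label, len(ids), n_per_group)
        chosen = rng.choice(ids, size=n_per_group, replace=False)
        out.append([int(x) for x in chosen])
    return out[0], out[1]
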