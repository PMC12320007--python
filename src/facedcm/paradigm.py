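"""Block design and input regressors.

The experiment presents faces (F) and non-face objects (O) in the left (L),
central (C) or right (R) visual field, in blocks of 15.75 s, each followed
by a fixation baseline of half that length (7.875 s).  With the default 8
blocks per condition this yields 48 stimulus blocks and 48 baseline blocks.

From a schedule we build six boxcar input functions on a microtime grid
(``TR / bins_per_scan`` resolution):

* driving inputs CS, LS, RS — stimulation at a location, faces *and* objects;
* modulatory inputs CF, LF, RF — face blocks only, at the same location.

Blocks are modelled as sustained unit boxcars; the individual images inside
a block are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STIMULUS_CONDITIONS",
    "BLOCK_DURATION_S",
    "BASELINE_DURATION_S",
    "DEFAULT_TR_S",
    "StimulusSchedule",
    "RegressorSet",
    "generate_schedule",
    "build_regressors",
]

STIMULUS_CONDITIONS: tuple[str, ...] = ("FL", "FR", "FC", "OL", "OR", "OC")
BLOCK_DURATION_S: float = 15.75
BASELINE_DURATION_S: float = BLOCK_DURATION_S / 2.0
DEFAULT_TR_S: float = 1.45
DEFAULT_BINS_PER_SCAN: int = 16

_ALL_INPUTS = ("CS", "LS", "RS", "CF", "LF", "RF")


@dataclass
class StimulusSchedule:
    """Ordered block sequence with onsets and durations in seconds."""

    blocks: list[tuple[str, float, float]]  # (condition, onset_s, duration_s)

    @property
    def total_duration(self) -> float:
        if not self.blocks:
            return 0.0
        cond, onset, dur = self.blocks[-1]
        return onset + dur

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cond, _, _ in self.blocks:
            counts[cond] = counts.get(cond, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.blocks, columns=["condition", "onset_s", "duration_s"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StimulusSchedule":
        df = pd.read_csv(path, sep="\t")
        blocks = [
            (str(r.condition), float(r.onset_s), float(r.duration_s))
            for r in df.itertuples()
        ]
        return cls(blocks=blocks)


@dataclass
class RegressorSet:
    """Six input boxcars sampled on the microtime grid.

    ``u`` has shape ``(n_scans * bins_per_scan, 6)`` with columns ordered
    (CS, LS, RS, CF, LF, RF); values are 0 or 1.
    """

    times: np.ndarray
    u: np.ndarray
    tr: float
    bins_per_scan: int
    n_scans: int
    input_names: tuple[str, ...] = _ALL_INPUTS

    @property
    def dt(self) -> float:
        return self.tr / self.bins_per_scan

    @property
    def driving(self) -> np.ndarray:
        """(n_bins, 3) columns CS, LS, RS."""
        return self.u[:, :3]

    @property
    def modulatory(self) -> np.ndarray:
        """(n_bins, 3) columns CF, LF, RF."""
        return self.u[:, 3:]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.u, columns=list(self.input_names))
        df.insert(0, "time_s", self.times)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(
        cls, path: str | Path, tr: float, bins_per_scan: int
    ) -> "RegressorSet":
        df = pd.read_csv(path, sep="\t")
        times = df["time_s"].to_numpy()
        u = df[list(_ALL_INPUTS)].to_numpy(dtype=float)
        n_scans = len(df) // bins_per_scan
        return cls(times=times, u=u, tr=tr, bins_per_scan=bins_per_scan,
                   n_scans=n_scans)


def generate_schedule(
    blocks_per_condition: int = 8, seed: int = 0, max_tries: int = 100_000
) -> StimulusSchedule:
    """Pseudo-randomised block order with no immediate condition repeats.

    Each of the six stimulus conditions occurs ``blocks_per_condition``
    times; every stimulus block is followed by one baseline block.  The
    order is a uniform shuffle, rejected and redrawn until no two
    consecutive stimulus blocks share a condition.  Deterministic for a
    fixed seed.
    """
    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    conditions = np.repeat(STIMULUS_CONDITIONS, blocks_per_condition)
    order = None
    for _ in range(max_tries):
        cand = rng.permutation(conditions)
        if blocks_per_condition == 1 or not np.any(cand[1:] == cand[:-1]):
            order = cand
            break
    if order is None:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not find a repeat-free block order")

    blocks: list[tuple[str, float, float]] = []
    t = 0.0
    for cond in order:
        blocks.append((str(cond), t, BLOCK_DURATION_S))
        t += BLOCK_DURATION_S
        blocks.append(("baseline", t, BASELINE_DURATION_S))
        t += BASELINE_DURATION_S
    return StimulusSchedule(blocks=blocks)


# condition -> (driving input, modulatory input or None)
_CONDITION_INPUTS = {
    "FC": ("CS", "CF"),
    "FL": ("LS", "LF"),
    "FR": ("RS", "RF"),
    "OC": ("CS", None),
    "OL": ("LS", None),
    "OR": ("RS", None),
}


def build_regressors(
    schedule: StimulusSchedule,
    tr: float = DEFAULT_TR_S,
    bins_per_scan: int = DEFAULT_BINS_PER_SCAN,
    n_scans: int = 795,
) -> RegressorSet:
    """Rasterise a schedule onto the microtime grid.

    A microtime bin takes value 1 for an input if the bin midpoint falls
    inside a block driving that input.  Schedule events beyond the scan
    window (``n_scans * tr`` seconds) are silently truncated.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if bins_per_scan < 1:
        raise ValueError("bins_per_scan must be >= 1")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")

    dt = tr / bins_per_scan
    n_bins = n_scans * bins_per_scan
    times = np.arange(n_bins) * dt
    mid = times + dt / 2.0
    u = np.zeros((n_bins, len(_ALL_INPUTS)), dtype=float)
    col = {name: k for k, name in enumerate(_ALL_INPUTS)}

    for cond, onset, duration in schedule.blocks:
        if cond == "baseline":
            continue
        drive, modulate = _CONDITION_INPUTS[cond]
        inside = (mid >= onset) & (mid < onset + duration)
        u[inside, col[drive]] = 1.0
        if modulate is not None:
            u[inside, col[modulate]] = 1.0

    return RegressorSet(times=times, u=u, tr=tr, bins_per_scan=bins_per_scan,
                        n_scans=n_scans)
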