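"""Echo-time (TE) schedules for multi-echo sodium MRI.

A single density-adapted radial acquisition yields 8 echoes; the study
protocol repeats the sequence three times with interleaved echo spacings so
that the merged schedule samples the decay densely from the ultra-short TE
needed for T2*_short up to 100 ms where the long component and the noise
floor dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionSchedule",
    "DEFAULT_RUNS",
    "ALTERNATE_RUNS",
    "make_default_schedule",
    "make_schedule",
]

# Three 8-echo runs of the default 24-TE protocol (ms).
DEFAULT_RUNS: tuple[tuple[float, ...], ...] = (
    (0.3, 6.3, 13.0, 19.0, 25.0, 31.0, 54.0, 89.0),
    (0.8, 7.0, 12.0, 17.0, 23.0, 35.0, 45.0, 80.0),
    (2.3, 9.7, 15.0, 21.0, 28.0, 40.0, 66.0, 100.0),
)

# 23-TE variant used for the first subjects scanned (run 3 has 7 echoes).
ALTERNATE_RUNS: tuple[tuple[float, ...], ...] = (
    (0.3, 6.3, 13.0, 19.0, 25.0, 31.0, 50.0, 100.0),
    (2.0, 7.0, 12.0, 17.0, 23.0, 40.0, 45.0, 80.0),
    (3.0, 9.0, 15.0, 22.0, 28.0, 34.0, 70.0),
)

_NAMED_RUNS = {"default-24": DEFAULT_RUNS, "alternate-23": ALTERNATE_RUNS}


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered echo times with the run each echo was acquired in.

    Parameters
    ----------
    echo_times
        Echo times in milliseconds, in acquisition order (run by run).
    run_labels
        1-based run index per echo; same length as ``echo_times``.
    name
        Optional schedule label.
    """

    echo_times: tuple[float, ...]
    run_labels: tuple[int, ...]
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        if len(self.echo_times) != len(self.run_labels):
            raise ValueError("echo_times and run_labels must have equal length")
        if len(self.echo_times) == 0:
            raise ValueError("schedule must contain at least one echo")
        te = np.asarray(self.echo_times, dtype=float)
        if np.any(te <= 0):
            raise ValueError("echo times must be strictly positive")
        if any(r < 1 for r in self.run_labels):
            raise ValueError("run labels are 1-based")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def n_runs(self) -> int:
        return max(self.run_labels)

    def sorted_echo_times(self) -> np.ndarray:
        """Merged view: all runs' echo times in increasing order (ms)."""
        return np.sort(np.asarray(self.echo_times, dtype=float))

    def run(self, label: int) -> np.ndarray:
        """Echo times belonging to one run, in acquisition order."""
        return np.asarray(
            [t for t, r in zip(self.echo_times, self.run_labels) if r == label],
            dtype=float,
        )

    @classmethod
    def from_runs(
        cls, runs: tuple[tuple[float, ...], ...], name: str = "custom"
    ) -> "AcquisitionSchedule":
        te: list[float] = []
        labels: list[int] = []
        for i, run in enumerate(runs, start=1):
            te.extend(float(t) for t in run)
            labels.extend([i] * len(run))
        return cls(tuple(te), tuple(labels), name=name)


def make_default_schedule() -> AcquisitionSchedule:
    """The default three-run, 24-echo schedule (0.3-100 ms)."""
    return AcquisitionSchedule.from_runs(DEFAULT_RUNS, name="default-24")


def make_schedule(name: str) -> AcquisitionSchedule:
    """Look up a named schedule: ``default-24`` or ``alternate-23``."""
    try:
        runs = _NAMED_RUNS[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule {name!r}; choose from {sorted(_NAMED_RUNS)}"
        ) from None
    return AcquisitionSchedule.from_runs(runs, name=name)
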