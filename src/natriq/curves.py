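"""Decay curves: ROI-mean or reference-tube magnitude signal vs echo time."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["DecayCurve"]


@dataclass
class DecayCurve:
    """Magnitude signal samples at a set of echo times.

    ``echo_times`` (ms) and ``signals`` (arbitrary units) must have equal
    length; magnitude data cannot be negative. ``meta`` carries provenance
    such as the generating (truth) parameters of a simulated curve.
    """

    echo_times: np.ndarray
    signals: np.ndarray
    source_id: str = ""
    run_labels: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.echo_times.ndim != 1 or self.signals.ndim != 1:
            raise ValueError("echo_times and signals must be 1-D")
        if self.echo_times.shape != self.signals.shape:
            raise ValueError("echo_times and signals must have equal length")
        if np.any(self.echo_times < 0):
            raise ValueError("echo times cannot be negative")
        if np.any(self.signals < 0):
            raise ValueError("magnitude signals cannot be negative")
        if self.run_labels is not None:
            self.run_labels = np.asarray(self.run_labels, dtype=int)
            if self.run_labels.shape != self.echo_times.shape:
                raise ValueError("run_labels must match echo_times in length")

    def __len__(self) -> int:
        return self.echo_times.size

    @property
    def n_distinct_echoes(self) -> int:
        return np.unique(self.echo_times).size

    def sorted(self) -> "DecayCurve":
        """Copy with samples ordered by increasing echo time."""
        order = np.argsort(self.echo_times, kind="stable")
        return DecayCurve(
            self.echo_times[order],
            self.signals[order],
            source_id=self.source_id,
            run_labels=None if self.run_labels is None else self.run_labels[order],
            meta=dict(self.meta),
        )
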