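"""Infection-stage windows over the post-infection time axis.

The infection cycle is divided into three stages: early (5-10 min, phage
adsorption/genome entry), middle (10-30 min, biosynthesis) and late
(30-80 min, assembly and lysis). Two related notions are kept apart:

* *peak classing* assigns a phage ORF to the stage whose window contains
  its expression peak; windows are half-open upper-inclusive, with the
  first sampled time (5 min) counted as early;
* *sample windows* select the replicate-level samples used for
  stage-restricted screens; stage boundaries are shared (the 10-min
  samples belong to both the early and the middle window, matching the
  "10-30 min" usage for the middle stage).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STAGES = ("early", "middle", "late")


@dataclass(frozen=True)
class StageWindows:
    """Stage boundaries (minutes); defaults early<=10 < middle<=30 < late<=80."""

    early_end: int = 10
    middle_end: int = 30
    late_end: int = 80

    def __post_init__(self) -> None:
        if not (0 < self.early_end < self.middle_end < self.late_end):
            raise ValueError("stage boundaries must be strictly increasing")

    def class_of_time(self, t: float) -> str:
        """Stage whose peak window contains time ``t`` (minutes, > 0)."""
        if t <= 0:
            raise ValueError("peak time must be post-infection (> 0 min)")
        if t <= self.early_end:
            return "early"
        if t <= self.middle_end:
            return "middle"
        if t <= self.late_end:
            return "late"
        raise ValueError(f"time {t} outside the infection cycle")

    def peak_range(self, stage: str) -> tuple[float, float]:
        """(lower, upper] peak-time interval of a stage."""
        if stage == "early":
            return (0.0, float(self.early_end))
        if stage == "middle":
            return (float(self.early_end), float(self.middle_end))
        if stage == "late":
            return (float(self.middle_end), float(self.late_end))
        raise ValueError(f"unknown stage: {stage!r}")

    def sample_times(self, stage: str, times: Iterable[int]) -> list[int]:
        """Post-infection time points whose samples belong to ``stage``.

        Boundary time points are shared between adjacent stages;
        ``stage='merged'`` selects every post-infection time point.
        """
        post = sorted(t for t in times if t > 0)
        if stage == "merged":
            return post
        if stage == "early":
            lo, hi = 0, self.early_end
        elif stage == "middle":
            lo, hi = self.early_end, self.middle_end
        elif stage == "late":
            lo, hi = self.middle_end, self.late_end
        else:
            raise ValueError(f"unknown stage: {stage!r}")
        return [t for t in post if lo <= t <= hi]
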