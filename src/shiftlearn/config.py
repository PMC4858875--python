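"""Shared run configuration for the learning loop and its components."""
from __future__ import annotations

from dataclasses import dataclass


@dataclass
class LearnerConfig:
    """Knobs of the assignment/prediction loop.

    Parameters
    ----------
    r_min, r_max:
        Smallest and largest sphere radius (in bonds from the proton) used
        for database entries and cascading lookup. Defaults 2 and 4.
    max_iterations:
        Hard cap on training iterations (iteration indices 0 .. cap-1).
    low_match_threshold:
        Predictions based on fewer than this many matches get the wide
        ``fallback_tolerance`` instead of a standard-deviation-derived one.
    fallback_tolerance:
        Shift-matching window, in ppm, for low-match predictions.
    tolerance_floor:
        Lower bound, in ppm, on the shift-matching window so that duplicate
        observations (sample std 0) cannot lock out every assignment.
    solution_cap:
        Enumeration aborts with an overflow status beyond this many
        assignment solutions; nothing is learnt from such a molecule.
    exclude_labile:
        Drop O-H/N-H/S-H protons from assignment scope and learning.
    seed:
        Seed for any sampling in synthetic runs; ``None`` means unseeded.
    """

    r_min: int = 2
    r_max: int = 4
    max_iterations: int = 10
    low_match_threshold: int = 2
    fallback_tolerance: float = 20.0
    tolerance_floor: float = 0.02
    solution_cap: int = 10_000
    exclude_labile: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.r_min <= self.r_max):
            raise ValueError("require 1 <= r_min <= r_max")
        if self.max_iterations < 1 or self.solution_cap < 1:
            raise ValueError("caps must be positive")
        if self.tolerance_floor < 0 or self.fallback_tolerance <= 0:
            raise ValueError("tolerances must be non-negative")


DEFAULT_CONFIG = LearnerConfig()
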