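"""A classic worked assignment example.

Five single-proton signals, all integrals 1: two protons (*a*, *b*) whose
constraints admit only the two upfield peaks, two (*d*, *e*) admitting only
the two downfield peaks, and one proton (*c*) pinned to the mid-spectrum
peak.  Integral balance alone leaves the two pairs interchangeable, so four
complete assignments exist — yet *c*'s signal at 4.16 ppm is common to all
of them and can be learnt despite the ambiguity.
"""
from __future__ import annotations

from .assigner import AssignmentProblem, Peak

PEAK_POSITIONS = (1.30, 2.52, 4.16, 7.47, 8.27)


def five_proton_problem() -> AssignmentProblem:
    """The five-proton, five-peak problem with two interchangeable pairs."""
    peaks = tuple(Peak(position=p, integral=1.0, integer_integral=1)
                  for p in PEAK_POSITIONS)
    upfield, fixed, downfield = frozenset({0, 1}), frozenset({2}), frozenset({3, 4})
    return AssignmentProblem(
        class_sizes=(1, 1, 1, 1, 1),
        peaks=peaks,
        allowed=(upfield, upfield, fixed, downfield, downfield),
        labels=("a", "b", "c", "d", "e"),
    )
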