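"""Integral- and shift-constrained enumeration of spectrum assignments.

An assignment maps proton equivalence classes (not individual protons) to
peaks such that the class sizes mapped to each peak add up exactly to its
integer integral, and — when a prediction is available for a class — the
peak position lies within the prediction's tolerance window.  The search
is a symmetry-constrained branch and bound: branching over classes in
most-constrained-first order, bounding on remaining peak capacity, and
exploring the complete solution space.  Dyads shared by *all* solutions
(the consensus) are the only thing ever learnt from a molecule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem_model import Molecule, ProtonClass, proton_classes
from .config import DEFAULT_CONFIG, LearnerConfig
from .predictor import Prediction, assignment_tolerance


class InfeasibleProblemError(ValueError):
    """Rescaled-rounded integrals cannot balance the proton count."""


class SolutionOverflowError(ValueError):
    """Consensus was requested on an overflowed enumeration."""


@dataclass(frozen=True)
class Peak:
    position: float        # ppm
    integral: float        # raw (arbitrary units)
    integer_integral: int  # after rescaling to the proton count and rounding


@dataclass(frozen=True)
class AssignmentProblem:
    class_sizes: tuple[int, ...]
    peaks: tuple[Peak, ...]
    #: per class, the set of peak indices its shift constraint admits
    allowed: tuple[frozenset[int], ...]
    labels: tuple[str, ...] | None = None
    molecule: Molecule | None = None
    classes: tuple[ProtonClass, ...] | None = None


@dataclass(frozen=True)
class AssignmentSolution:
    """Peak index per class, in class order."""

    class_to_peak: tuple[int, ...]

    def shifts(self, problem: AssignmentProblem) -> tuple[float, ...]:
        return tuple(problem.peaks[j].position for j in self.class_to_peak)


@dataclass
class EnumerationResult:
    solutions: list[AssignmentSolution]
    overflow: bool
    problem: AssignmentProblem


@dataclass(frozen=True)
class ConsensusDyad:
    class_index: int
    delta: float  # ppm, the shared peak's position


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_problem(molecule: Molecule, peaks: Sequence[tuple[float, float]],
                  predictions: Mapping[int, Prediction] | None = None,
                  iteration: int = 0,
                  config: LearnerConfig = DEFAULT_CONFIG,
                  classes: Sequence[ProtonClass] | None = None) -> AssignmentProblem:
    """Normalise a raw peak list against a molecule's proton classes.

    Raw integrals are arbitrary-unit; they are rescaled so their sum equals
    the in-scope proton count, then rounded half-away-from-zero.  A peak
    list that cannot balance after rounding raises
    :class:`InfeasibleProblemError` (the molecule is skipped upstream).
    """
    if not peaks:
        raise ValueError("peak list must be non-empty")
    cls = tuple(classes) if classes is not None \
        else tuple(proton_classes(molecule, config.exclude_labile))
    sizes = tuple(c.size for c in cls)
    n_protons = sum(sizes)
    total_raw = sum(integral for _, integral in peaks)
    if total_raw <= 0:
        raise InfeasibleProblemError(f"{molecule.id}: non-positive total integral")
    scale = n_protons / total_raw
    peak_objs = tuple(
        Peak(position=pos, integral=integral,
             integer_integral=_round_half_away(integral * scale))
        for pos, integral in peaks
    )
    if sum(p.integer_integral for p in peak_objs) != n_protons:
        raise InfeasibleProblemError(
            f"{molecule.id}: integer integrals do not sum to the proton count"
        )
    everything = frozenset(range(len(peak_objs)))
    allowed = []
    for i in range(len(cls)):
        pred = predictions.get(i) if predictions else None
        if pred is not None and pred.ok:
            tol = assignment_tolerance(pred, iteration, config)
            allowed.append(frozenset(
                j for j, p in enumerate(peak_objs)
                if abs(p.position - pred.delta_hat) <= tol
            ))
        else:
            allowed.append(everything)
    return AssignmentProblem(
        class_sizes=sizes, peaks=peak_objs, allowed=tuple(allowed),
        molecule=molecule, classes=cls,
    )


def enumerate_assignments(problem: AssignmentProblem,
                          cap: int = DEFAULT_CONFIG.solution_cap) -> EnumerationResult:
    """All assignments satisfying integral balance and shift windows.

    Solutions are returned in lexicographic order (by class order, then
    peak index).  If more than ``cap`` solutions exist the search aborts
    and the result carries ``overflow=True``.
    """
    sizes = problem.class_sizes
    k = len(sizes)
    remaining = [p.integer_integral for p in problem.peaks]
    if sum(sizes) != sum(remaining):
        return EnumerationResult([], False, problem)
    # fail-first: fewest admissible peaks, then biggest class
    order = sorted(range(k), key=lambda i: (len(problem.allowed[i]), -sizes[i], i))
    assign: list[int] = [-1] * k
    found: list[tuple[int, ...]] = []
    overflow = False

    def dfs(pos: int) -> None:
        nonlocal overflow
        if overflow:
            return
        if pos == k:
            if len(found) >= cap:
                overflow = True
                return
            found.append(tuple(assign))
            return
        i = order[pos]
        for j in sorted(problem.allowed[i]):
            if remaining[j] >= sizes[i]:
                remaining[j] -= sizes[i]
                assign[i] = j
                dfs(pos + 1)
                remaining[j] += sizes[i]
                assign[i] = -1
                if overflow:
                    return

    dfs(0)
    solutions = [AssignmentSolution(t) for t in sorted(found)]
    return EnumerationResult(solutions, overflow, problem)


def consensus(result: EnumerationResult) -> list[ConsensusDyad]:
    """Class-to-peak pairs present in every enumerated solution.

    These dyads are unambiguous despite the ambiguity of the full solution
    set, so they are the ones deemed correct and learnt.  Order of the
    solutions does not matter; an overflowed enumeration is rejected
    because its solution set is incomplete.
    """
    if result.overflow:
        raise SolutionOverflowError("consensus over an overflowed enumeration")
    if not result.solutions:
        return []
    k = len(result.problem.class_sizes)
    dyads = []
    for i in range(k):
        peaks_used = {s.class_to_peak[i] for s in result.solutions}
        if len(peaks_used) == 1:
            (j,) = peaks_used
            dyads.append(ConsensusDyad(i, result.problem.peaks[j].position))
    return dyads
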