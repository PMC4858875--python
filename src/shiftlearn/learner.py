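"""The self-learning loop: assign, extract consensus, batch-commit, repeat.

Iteration 0 runs the assigner on integrals alone; every later iteration
additionally constrains each class by the shift predicted from the database
as it stood at the *start* of the iteration.  Consensus dyads collected
during an iteration are committed in one batch at its end, so shifts learnt
in one cycle are only available from the next one onwards — this makes the
end-of-iteration database independent of the order in which the training
molecules are processed.  Training stops when two consecutive iterations
add no new database entries, or at the iteration cap.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import assigner, predictor
from .chem_model import Molecule, proton_classes
from .config import DEFAULT_CONFIG, LearnerConfig

#: (molecule, raw peak list [(ppm, integral), ...])
TrainingRecord = tuple[Molecule, Sequence[tuple[float, float]]]
#: (molecule, {proton atom index -> reference shift ppm})
ReferenceRecord = tuple[Molecule, Mapping[int, float]]


@dataclass
class EvalMetrics:
    """Prediction quality against reference assignments.

    Error fractions are relative to the number of *predicted* reference
    protons; coverage fractions are relative to all reference protons, so
    per-radius coverages sum to the overall coverage.  An empty prediction
    set reports ``None`` (never a misleading zero) for the error metrics.
    """

    mae: float | None
    frac_within_02: float | None
    frac_above_1: float | None
    mean_epsilon: float | None
    coverage: float
    coverage_by_radius: dict[int, float]
    n_reference: int
    n_predicted: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["coverage_by_radius"] = {str(k): v for k, v in self.coverage_by_radius.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvalMetrics":
        d = dict(d)
        d["coverage_by_radius"] = {int(k): v for k, v in d["coverage_by_radius"].items()}
        return cls(**d)


@dataclass
class IterationReport:
    iteration: int
    attempted: int
    solved: int
    overflowed: int
    infeasible: int
    new_entries: int
    db_size: int
    metrics: EvalMetrics | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["metrics"] = self.metrics.to_dict() if self.metrics is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IterationReport":
        d = dict(d)
        if d.get("metrics") is not None:
            d["metrics"] = EvalMetrics.from_dict(d["metrics"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "IterationReport":
        return cls.from_dict(json.loads(s))


def run_iteration(db: predictor.ShiftDatabase, iteration: int,
                  training: Sequence[TrainingRecord],
                  config: LearnerConfig = DEFAULT_CONFIG) -> IterationReport:
    """One pass over the training set against the frozen start-of-iteration db.

    Consensus dyads from all molecules are collected first and committed in
    a single batch at the end.  Infeasible and overflowed molecules are
    counted and skipped, never fatal.
    """
    attempted = solved = overflowed = infeasible = 0
    pending = []  # (molecule, classes, dyads)
    for molecule, peaks in training:
        attempted += 1
        classes = proton_classes(molecule, config.exclude_labile)
        if not classes:
            continue
        predictions = None
        if iteration > 0:
            predictions = {
                i: predictor.predict(db, molecule, c.representative,
                                     config.r_max, config.r_min)
                for i, c in enumerate(classes)
            }
        try:
            problem = assigner.build_problem(
                molecule, peaks, predictions=predictions, iteration=iteration,
                config=config, classes=classes,
            )
        except assigner.InfeasibleProblemError:
            infeasible += 1
            continue
        result = assigner.enumerate_assignments(problem, cap=config.solution_cap)
        if result.overflow:
            overflowed += 1
            continue
        if not result.solutions:
            continue
        solved += 1
        pending.append((molecule, classes, assigner.consensus(result)))

    new_entries = 0
    for molecule, classes, dyads in pending:  # batch commit
        for dyad in dyads:
            new_entries += predictor.add_observation(
                db, molecule, classes[dyad.class_index].representative,
                dyad.delta, iteration, config.r_min, config.r_max,
            )
    return IterationReport(
        iteration=iteration, attempted=attempted, solved=solved,
        overflowed=overflowed, infeasible=infeasible,
        new_entries=new_entries, db_size=len(db),
    )


def train(training: Sequence[TrainingRecord],
          config: LearnerConfig = DEFAULT_CONFIG,
          test_set: Sequence[ReferenceRecord] | None = None,
          ) -> tuple[predictor.ShiftDatabase, list[IterationReport]]:
    """Run iterations until two in a row learn nothing, or the cap is hit."""
    db = predictor.ShiftDatabase()
    reports: list[IterationReport] = []
    for iteration in range(config.max_iterations):
        report = run_iteration(db, iteration, training, config)
        if test_set is not None:
            report.metrics = evaluate(db, test_set, config)
        reports.append(report)
        if len(reports) >= 2 and reports[-1].new_entries == 0 \
                and reports[-2].new_entries == 0:
            break
    return db, reports


def evaluate(db: predictor.ShiftDatabase, test_set: Sequence[ReferenceRecord],
             config: LearnerConfig = DEFAULT_CONFIG) -> EvalMetrics:
    """Compare predictions with reference dyads; failures count against coverage only."""
    errors: list[float] = []
    epsilons: list[float] = []
    radius_hits: Counter[int] = Counter()
    n_reference = 0
    for molecule, references in test_set:
        for proton, ref_delta in references.items():
            n_reference += 1
            pred = predictor.predict(db, molecule, proton, config.r_max, config.r_min)
            if not pred.ok:
                continue
            errors.append(abs(pred.delta_hat - ref_delta))
            radius_hits[pred.radius_used] += 1
            if pred.epsilon is not None:
                epsilons.append(pred.epsilon)
    n_predicted = len(errors)
    if n_predicted:
        arr = np.asarray(errors)
        mae = float(arr.mean())
        frac_within = float((arr < 0.2).mean())
        frac_above = float((arr > 1.0).mean())
    else:
        mae = frac_within = frac_above = None
    return EvalMetrics(
        mae=mae,
        frac_within_02=frac_within,
        frac_above_1=frac_above,
        mean_epsilon=float(np.mean(epsilons)) if epsilons else None,
        coverage=n_predicted / n_reference if n_reference else 0.0,
        coverage_by_radius={
            r: radius_hits[r] / n_reference for r in sorted(radius_hits)
        },
        n_reference=n_reference,
        n_predicted=n_predicted,
    )


@dataclass
class ErrorCDF:
    """Binned cumulative error distribution: 100 bins of ``bin_width`` plus
    one terminal bin holding every error at or beyond the last edge."""

    cumulative: np.ndarray  # length n_bins + 1, monotone, last value 1 (or all 0)
    bin_width: float
    empty: bool

    @property
    def edges(self) -> np.ndarray:
        n = len(self.cumulative) - 1
        return np.append(np.arange(n + 1) * self.bin_width, np.inf)


def error_cdf(errors: Sequence[float], bin_width: float = 0.01,
              n_bins: int = 100) -> ErrorCDF:
    """Cumulative fractions over ``n_bins`` fixed-width bins plus an open last bin."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size and (errors < 0).any():
        raise ValueError("errors must be non-negative")
    edges = np.append(np.arange(n_bins + 1) * bin_width, np.inf)
    if errors.size == 0:
        return ErrorCDF(np.zeros(n_bins + 1), bin_width, empty=True)
    counts, _ = np.histogram(errors, bins=edges)
    return ErrorCDF(np.cumsum(counts) / errors.size, bin_width, empty=False)
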