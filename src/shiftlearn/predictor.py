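"""Shift database and cascading fragment-code prediction.

Every assigned proton contributes one database entry per sphere radius
``r_min..r_max``.  A prediction spans the largest sphere first and walks
down: the first radius with at least one exact code match determines the
result — the median shift over the matches, with an uncertainty equal to
their sample standard deviation.  If even the smallest sphere finds no
match the prediction fails (a status, not an exception).
"""
from __future__ import annotations

import sqlite3
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hose
from .chem_model import Molecule
from .config import DEFAULT_CONFIG, LearnerConfig

OK = "ok"
FAILED = "failed"


@dataclass(frozen=True)
class ShiftEntry:
    code: str
    radius: int
    delta: float  # ppm
    molecule_id: str
    iteration: int


@dataclass(frozen=True)
class Prediction:
    status: str
    delta_hat: float | None = None  # median over matches, ppm
    epsilon: float | None = None    # sample std over matches, ppm; None when m < 2
    m: int = 0                      # number of matched entries
    radius_used: int | None = None

    @property
    def ok(self) -> bool:
        return self.status == OK


class ShiftDatabase:
    """Multiset of (code, radius) -> observed shift entries.

    Multiple entries may exist per key (the same fragment observed in
    different molecules); exact duplicates — same code, radius, shift and
    source molecule — are silently dropped so that re-learning a dyad in a
    later iteration is a no-op.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, int], list[ShiftEntry]] = {}
        self._seen: set[tuple[str, int, float, str]] = set()

    def __len__(self) -> int:
        return len(self._seen)

    def add(self, entry: ShiftEntry) -> bool:
        """Insert one entry; returns False if it was an exact duplicate."""
        key = (entry.code, entry.radius, entry.delta, entry.molecule_id)
        if key in self._seen:
            return False
        self._seen.add(key)
        self._entries.setdefault((entry.code, entry.radius), []).append(entry)
        return True

    def lookup(self, code: str, radius: int) -> list[ShiftEntry]:
        return self._entries.get((code, radius), [])

    def all_entries(self) -> list[ShiftEntry]:
        out = [e for entries in self._entries.values() for e in entries]
        out.sort(key=lambda e: (e.code, e.radius, e.delta, e.molecule_id))
        return out

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write to a single-file sqlite store."""
        with sqlite3.connect(path) as con:
            con.execute("DROP TABLE IF EXISTS shift_entries")
            con.execute(
                "CREATE TABLE shift_entries ("
                "code TEXT, radius INTEGER, delta_ppm REAL,"
                " molecule_id TEXT, iteration INTEGER)"
            )
            con.executemany(
                "INSERT INTO shift_entries VALUES (?,?,?,?,?)",
                [
                    (e.code, e.radius, e.delta, e.molecule_id, e.iteration)
                    for e in self.all_entries()
                ],
            )

    @classmethod
    def load(cls, path: str | Path) -> "ShiftDatabase":
        db = cls()
        with sqlite3.connect(path) as con:
            rows = con.execute(
                "SELECT code, radius, delta_ppm, molecule_id, iteration"
                " FROM shift_entries"
            ).fetchall()
        for code, radius, delta, mol_id, iteration in rows:
            db.add(ShiftEntry(code, radius, delta, mol_id, iteration))
        return db

    def to_tsv(self, path: str | Path) -> None:
        """Flat-file dump; the inspectable interchange format."""
        df = pd.DataFrame(
            [
                {
                    "code": e.code,
                    "radius": e.radius,
                    "delta_ppm": e.delta,
                    "molecule_id": e.molecule_id,
                    "iteration": e.iteration,
                }
                for e in self.all_entries()
            ],
            columns=["code", "radius", "delta_ppm", "molecule_id", "iteration"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShiftDatabase":
        db = cls()
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            db.add(ShiftEntry(row.code, int(row.radius), float(row.delta_ppm),
                              str(row.molecule_id), int(row.iteration)))
        return db


def add_observation(db: ShiftDatabase, molecule: Molecule, proton: int, delta: float,
                    iteration: int, r_min: int = 2, r_max: int = 4) -> int:
    """Store one assigned (proton, shift) dyad at every radius; returns entries added."""
    if not (delta == delta and abs(delta) != float("inf")):
        raise ValueError("delta must be finite")
    added = 0
    for code in hose.encode_all_radii(molecule, proton, r_min, r_max):
        if db.add(ShiftEntry(code.code, code.radius, delta, molecule.id, iteration)):
            added += 1
    return added


def predict(db: ShiftDatabase, molecule: Molecule, proton: int,
            r_max: int = 4, r_min: int = 2) -> Prediction:
    """Cascade from the largest sphere down to the smallest.

    Pure function of its arguments: repeated calls return identical
    results, and smaller radii are never consulted once a match is found.
    """
    if r_min < 1 or r_min > r_max:
        raise ValueError("require 1 <= r_min <= r_max")
    for r in range(r_max, r_min - 1, -1):
        code = hose.encode(molecule, proton, r)
        entries = db.lookup(code.code, r)
        if entries:
            deltas = [e.delta for e in entries]
            m = len(deltas)
            return Prediction(
                status=OK,
                delta_hat=float(statistics.median(deltas)),
                epsilon=float(statistics.stdev(deltas)) if m >= 2 else None,
                m=m,
                radius_used=r,
            )
    return Prediction(status=FAILED)


def scaled_uncertainty(epsilon: float, m: int, iteration: int) -> float:
    """Inflate a sample standard deviation for small samples / early iterations.

    Returns ``epsilon * (1 + m**(-I/2))``: factor 2 at iteration 0, decaying
    towards 1 as iterations accumulate, faster for larger match counts.
    """
    if m < 2:
        raise ValueError("scaled_uncertainty requires m >= 2")
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return epsilon * (1.0 + m ** (-iteration / 2.0))


def assignment_tolerance(prediction: Prediction, iteration: int,
                         config: LearnerConfig = DEFAULT_CONFIG) -> float:
    """Shift-matching window, in ppm, granted to an assignment candidate.

    Predictions with fewer matches than the low-match threshold get the wide
    fallback window (20 ppm by default) since no reasonable uncertainty
    estimate exists; all others get three times the scaled uncertainty,
    floored so a zero standard deviation cannot exclude every peak.
    """
    if not prediction.ok:
        raise ValueError("assignment_tolerance requires a successful prediction")
    if prediction.m < config.low_match_threshold or prediction.epsilon is None:
        return config.fallback_tolerance
    return max(
        config.tolerance_floor,
        3.0 * scaled_uncertainty(prediction.epsilon, prediction.m, iteration),
    )
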