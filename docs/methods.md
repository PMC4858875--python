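# Methods

## Model

The package treats ¹H shift prediction as nearest-environment lookup. The
local environment of a proton at radius *r* (its *n*-sphere) is the
substructure within *r* bonds of the proton; *r* = 1 is the attached heavy
atom. The working assumption is that protons with identical environments at
a sufficiently large radius resonate at nearly the same frequency, so a
database of (environment code, observed shift) pairs is itself a predictor:
query the largest radius first, fall back one sphere at a time, and report
the median of the matches with their sample standard deviation as the
uncertainty. Below the minimum radius (default 2) prediction fails rather
than extrapolate — a 1-sphere rarely distinguishes chemically distinct
protons.

The loop closes over assignment: peak integrals quantise to proton-class
sizes, so enumerating all integral-balanced assignments and keeping the
class→peak dyads common to *all* of them yields assignments that need no
prior shift knowledge. Those consensus dyads seed the database; the
database then narrows later assignments through shift windows, which
produces more consensus, and so on.

## Environment codes

The canonical code is this package's own dialect; the loop only requires
that database writes and queries share one encoder, so internal consistency
is the design goal rather than compatibility with any historical byte
format. Properties and choices:

- encoding is a rooted, depth-limited expansion over the heavy-atom
  skeleton: every non-backtracking walk from the proton's heavy atom, with
  a branch that returns onto an ancestor emitted as a ring-closure marker
  `&`. Rings are therefore distinguished from chains within a sphere.
- each atom contributes element, formal charge (`+1`/`-1` suffix), and an
  attached-hydrogen count (`H<n>`). The count is emitted only for atoms at
  depth < *r*: a hydrogen on a depth-*r* atom lies *r*+1 bonds from the
  proton, outside the sphere. The central proton itself is excluded from
  its carbon's count.
- bonds are `-`, `=`, `#`, `:` (aromatic, as perceived by the sanitiser).
- at every atom, branches are sorted by the lexicographic order of their
  complete sub-codes. This makes the string deterministic and invariant
  under atom renumbering, and equal for symmetry-equivalent protons
  (property-tested with random permutations).

Equivalence of protons is constitutional: two hydrogens are equivalent iff
a graph automorphism of the element/charge/bond-order-labelled graph maps
one onto the other. Stereochemistry and diastereotopicity are ignored
throughout, consistent with constitution-only environment codes. The
implementation uses iterative neighbourhood-label refinement (RDKit
canonical ranking with tie-breaking disabled); because refinement can in
principle over-merge on pathological regular graphs, the test suite checks
it against a brute-force automorphism enumeration (networkx VF2) on all
fixture molecules.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `r_min`, `r_max` | 2, 4 | bonds | radius window for database entries and cascade |
| `max_iterations` | 10 | — | iteration cap (indices 0–9) |
| `low_match_threshold` | 2 | matches | below this, the fallback window applies |
| `fallback_tolerance` | 20 | ppm | window for low-match predictions |
| `tolerance_floor` | 0.02 | ppm | lower bound on the 3ε window |
| `solution_cap` | 10 000 | solutions | enumeration overflow limit |
| `exclude_labile` | off | — | drop O/N/S-bound protons from scope |

The assignment window is 3·ε·(1 + m^(−I/2)) for a prediction with m ≥ 2
matches at iteration I: the factor starts at 2 and decays toward 1, guarding
against the standard deviation being a poor uncertainty estimate early in
training or at small m. The low-match threshold is configurable to 3 —
there is an argument that even two matches give a fragile ε — but defaults
to 2. The tolerance floor exists because duplicate observations give ε = 0,
and a zero window would lock every assignment out and deadlock the loop;
0.02 ppm is below typical peak-position reproducibility, so it only rescues
the degenerate case. Sample (m−1) standard deviation is used; the inflation
factor already addresses small samples, and the sample convention is the
conservative one.

Integral normalisation rescales raw (arbitrary-unit) integrals so they sum
to the in-scope proton count, then rounds half-away-from-zero; a peak list
that cannot balance after rounding is infeasible and the molecule is
skipped for that iteration. Several classes may share one peak when the
integer integrals add up (overlapping signals). If enumeration exceeds the
solution cap, nothing is learnt from that molecule — an unconstrained
early-iteration problem can be factorial, and a truncated solution set
would make "present in all solutions" meaningless.

"No improvement" for the stopping rule is operationalised as "zero new
unique database entries", the only monotone internal signal; entries are
deduplicated on (code, radius, shift, source molecule), so re-deriving a
known dyad is a no-op and the rule fires as soon as two consecutive passes
re-derive only known facts.

## Synthetic corpora

The generator emulates the statistical structure the loop assumes, at desk
scale:

- molecules grow from a small fragment grammar — C/O/N single-bond growth
  (weights 0.60/0.20/0.20), six-membered aromatic rings (weight 0.20),
  heteroatoms bonding only to carbon — over 2–9 heavy atoms. This yields
  ethers, amines, alkyl chains and substituted benzenes: enough shared
  substructure across a 150-molecule corpus for fragments to recur, which
  is what the learner needs.
- ground truth is a *shift rule*: each radius-2 environment code maps to a
  base shift, evenly spaced over 0.5–9.5 ppm in seed-shuffled order, plus
  Gaussian noise of σ = 0.05 ppm drawn once per class per molecule
  (equivalent protons must share one signal). Because truth is a function
  of the radius-2 environment, the `r_min = 2` predictor is asymptotically
  unbiased on these corpora and its mean error should approach the noise
  floor — which makes "error converges to ≈ σ" a meaningful end-to-end
  check of the whole loop.
- peak lists carry integrals equal to class sizes; signals within
  0.02 ppm merge at their integral-weighted mean.

What this does *not* emulate: multiplet structure and scalar couplings,
lineshapes, solvent/temperature/concentration effects, labile-proton
exchange, integration error, and the long-tailed fragment-frequency
distribution of real chemical libraries. Passing the synthetic recovery
test therefore shows the loop's mechanics are sound (bootstrapping,
batching, consensus, cascade), not that real-spectrum accuracy matches any
particular figure; accuracy on experimental corpora must be measured with
`scripts/external_corpus_experiment.py` on real data.

Problem sizes used in the shipped tests — 150 training / 30 test molecules,
up to 10 iterations — are the package's chosen desk-scale study
conditions; at these sizes the full suite runs in seconds.

## Numerical and degenerate-case choices

- Median of an even match count is the mean of the two central values.
- Rounding of scaled integrals is half-away-from-zero.
- Enumeration output is sorted lexicographically (class order, then peak
  index); the most-constrained-first branch order is a speed heuristic only
  and is asserted against an exhaustive oracle.
- Disconnected SDF records (salts/solvates) keep the largest connected
  component with a warning; V3000 records are rejected outright.
- Evaluation over zero predictions reports missing values (`None`), never
  zero — a silent zero would reward an empty database. Error fractions are
  relative to predicted protons; coverage fractions are relative to all
  reference protons, so per-radius coverages sum to overall coverage.
- The cumulative error distribution uses 100 bins of 0.01 ppm plus one
  terminal bin for errors ≥ 1 ppm.

## Known limitations

- Constitution-only equivalence merges diastereotopic protons that real
  spectra can resolve.
- Refinement-based symmetry detection is oracle-checked on fixtures, not
  proven; exotic regular graphs could over-merge classes.
- Exact-string fragment matching cannot interpolate: environments absent
  from the training corpus are never predicted at any radius, and
  single-match predictions carry the permissive 20 ppm window, which can
  propagate an early wrong assignment until more data arrives.
- The assigner uses integrals and shift windows only; spin–spin (2D)
  correlation constraints and solution ranking are out of scope.
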