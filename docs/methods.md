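# Methods

## The screen in outline

The toolkit reconstructs the desk-scale computational stages of a peptide
affinity-maturation screen against the extracellular Ig1–Ig3 modules of
VEGFR. The starting point is the 12-residue VEGF-A exon-6 fragment
QKRKRKKSRYKS, whose receptor-contact core RKRKKSR (positions 3–9, 1-based
inclusive) is never altered. Two in-silico metrics are computed per
candidate — a docking-style binding energy and a binding-site window score —
and candidates are validated downstream by a competition binding assay whose
analysis (IC50 fitting, fold affinity) is also implemented here. The
expensive upstream predictors (structure prediction, molecular dynamics,
docking, the binding-site prediction service) are out of scope: their
*tabular outputs* are first-class inputs, and deterministic surrogates stand
in for them in tests.

## Search space and generators

A `MutableTemplate` is a base peptide, a core span that must match the core
motif exactly, and a set of mutable positions disjoint from the core. With
the template's five mutable positions (1, 2, 10, 11, 12) and the 20-residue
alphabet, the variant space has 20⁵ = 3 200 000 members, enumerated lazily in
lexicographic order of the mutable-position residue tuple so any run is
reproducible and the full space is countable in seconds without
materialisation.

The candidate generators implement the two published design heuristics as
bounded, composable rules: flanks drawn from the hydrophilic basic residues
{R, K, H} or from the strongly hydrophobic residues {I, L, V, F}, appended at
either terminus of the core. Generation is made finite by `max_insertions`
(total flank residues, default 4) and the overall 14-residue length cap. The
published candidate lists mix terminal additions with flank substitutions and
state no exhaustive rule; bounded flank generation around the core was chosen
because it reproduces the published all-basic-flank candidates and keeps the
candidate set enumerable and deduplicable by exact string equality. For 13-
and 14-mers no indexed template is defined — they are treated as core +
flanks, not as mutable-position templates.

## Hill climbing

The published screen names hill climbing but not its flavour, restart count
or stopping rule, so the simplest fully reproducible variant is used:
**steepest descent** — evaluate every single-position substitution at the
mutable positions, move to the best *strictly* improving neighbour, stop at a
local optimum or after `max_iterations` sweeps. Ties among equally good
neighbours go to the lexicographically smallest sequence. Restart 1 starts
from the template base (the natural anchor of the screen); the remaining
restarts start from variants sampled uniformly with a seeded generator.
When `restarts` is at least the size of the variant space, the starts are
instead the full enumeration, which turns the probabilistic "enough restarts
find the global minimum" into an exact guarantee on small spaces — this is
what the brute-force equivalence tests exercise (every space ≤ 512 variants).
Because the published restart budget is unknown, the published table of 17
docking hits is not regenerable by construction; it ships verbatim instead.

Replicate docking energies (the protocol ran each docking five times) are
collapsed by an explicit `best_of_replicates` = minimum, not hidden inside
the oracle. The hit filter is **inclusive** (energy ≤ −5.2 kcal/mol): the
published hit table contains rows at exactly −5.2, so "lower than" is read
as ≤.

## Window scoring

A window of length *L* slides over the peptide with stride 1 (exhaustive
sliding); *L* is capped at 10, the input limit of the upstream binding-site
predictor. A peptide shorter than the window — notably the 7-residue core —
is scored as one whole-sequence window. Each window's score is the sum of
reciprocal p-values over its top *n* = 10 predicted sites; if a provider
returns fewer sites the sum runs over what is available, and extra sites
beyond *n* are discarded from the small-p end upward (the best sites are
kept). P-values are validated strictly to (0, 1]; zero is an error, never
clamped, since 1/p diverges.

The aggregate multiplies each window score by `1 + log(S_k / S_core)` and
averages over windows: windows scoring above the core are amplified, windows
far below it (below S_core/e under the natural log) contribute negatively.
The log base is not fixed by the published description and the printed score
tables cannot disambiguate it without the underlying p-values, so it is a
configuration parameter with **natural log** as the default. Useful exact
identities (all tested): when every window scores exactly S_core the
aggregate equals S_core; scaling all scores by c > 0 scales the aggregate by
c; decreasing any p-value strictly increases its window's score.

## Competition assay model

The assay is the standard radioligand competition setup: a fixed tracer
concentration, an unlabelled competitor at 0, 1.3, 6.5, 32.5, 65, 650 and
6500 nmol/L, bound counts measured per well. No curve model was named in the
source (a statistics package was used), so the field-standard four-parameter
log-logistic one-site competition curve is used:

    y(c) = bottom + (top − bottom) / (1 + (c / IC50)^h)

Parameters: `top` — signal at zero competitor (arbitrary counts); `bottom` —
non-specific signal; `IC50` — half-maximal inhibitory concentration, nmol/L;
`h` — Hill slope, dimensionless. The curve is evaluated in linear
concentration, so the zero-concentration wells pin `top` directly instead of
being dropped from a log axis.

**Simulator.** Signals are the model mean times `(1 + cv·N(0,1))` —
multiplicative Gaussian noise, reflecting count-proportional assay error —
truncated at zero, with a seeded generator. Defaults emulate the protocol:
duplicate wells, cv = 0.05, top = 1000, bottom = 50, h = 1. The simulator
reproduces dose-dependent displacement with realistic well-to-well scatter;
it does **not** model plate effects, tracer depletion, radioactive decay or
between-day drift, so passing recovery tests show the estimator is correct
for the stated error model, not that any real assay meets that model.

**Fitting.** Nonlinear least squares (trust-region reflective, via
`scipy.optimize.curve_fit`) with initialisation top = max mean signal,
bottom = min mean signal, IC50 = geometric mean of the nonzero
concentrations, h = 1, and bounds keeping IC50 and h positive and bottom
non-negative. Flat data (relative signal span below 10⁻⁶) and optimiser
failures are reported as non-converged with no IC50 — never a fabricated
estimate. The IC50 standard error comes from the fit covariance. At the
protocol's noise level the median of 50 simulated duplicate assays recovers
the true IC50 to within a few percent for all three published values
(80, 185, 464 nmol/L); the test tolerance is 15 %.

Fold affinity is reference-IC50 / candidate-IC50, reported raw, to one
decimal, and to the nearest integer (the published habit for headline folds).
The count of candidates "better than the reference" uses strict inequality;
no published value ties the 464 nmol/L reference.

## Fixtures

The four published tables ship verbatim as TSV package data with SHA-256
checksums and exact row-count validation (17 docking hits + reference; 10 +
10 scored candidates with their two baselines, 27.5 and 23.7, kept as
printed though they differ between tables; 20 assayed candidates +
reference). They derive from cluster-scale docking and an external
prediction service and are therefore exercised only through counting,
filtering and rank-order checks, never regenerated. One 13-mer appears in
the assay table without a counterpart in the earlier tables; it is stored as
printed, unreconciled. Table "±" spreads are provenance metadata, never
fitted, and whether they are SD or SEM is unrecorded.

## Pipeline and selection

The full screen joins both in-silico metrics per candidate. They are not
commensurable and the source does not define how they combined into the
final shortlist, so the report presents both side by side and selects a
configurable **union of top-k by each metric** (default k = 10) — an
interpretation, documented as such. Candidates missing oracle or provider
data are flagged in the report, never dropped, so candidate counts are
conserved across stages; each stage logs its counts and the seed. The config
file is flat `key = value` text with defaults mirroring the protocol
(L = 10, n = 10, threshold −5.2 kcal/mol, reference 464 nmol/L).

## Surrogates

Two deterministic stand-ins make the toolkit testable without the upstream
services; both are synthetic and labelled as such.

* **Energy surrogate** — a fixed per-residue weight table (basic and
  aromatic residues favourable, acidic unfavourable, mirroring the
  electrostatics-dominated interface) summed over the composition and offset
  by −3 kcal/mol so typical basic peptides land near the docking range of
  −5 kcal/mol. Purely compositional, hence order-invariant.
* **P-value surrogate** — each window's sequence is hashed (MD5, stable
  across processes and runs) to seed a generator that draws 10 p-values in
  (0, 1], sharpened toward small values as the window's basic-residue
  fraction rises.

They preserve the contracts the real predictors satisfy (determinism, value
ranges) but carry no structural information; results obtained with them
validate the machinery, not any biological prediction.

## Numerical and scale choices

Positions are 1-based and inclusive everywhere, matching the field's
sequence-numbering convention. Energies are finite floats in kcal/mol;
p-values strictly in (0, 1]; concentrations non-negative nmol/L. The test
suite and the reproduction script run everything at enumerable scale: toy
hill-climb spaces of at most 512 variants (checked against brute force), the
full 3.2-million-variant enumeration only counted, and 50 simulated assays
per recovery estimate — sizes chosen so every check is exact or tightly
seeded. Known limitations: the hill climb models the published search only
up to its unstated hyperparameters; the window-score log base is a
convention; the assay simulator's error model is idealised; and the
published score tables are inputs, not reproducible outputs.
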