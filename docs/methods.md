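# Methods

This note documents the models behind `dartsdeconv`, the defaults and why
they were chosen, the numerical choices, and the known limits of what the
synthetic benchmarks demonstrate.

## Coverage and the screen

Sequence coverage is the interval-union statistic: peptides are mapped to
1-based inclusive intervals (every exact occurrence, including overlapping
ones; unmatched peptides are reported, never dropped), duplicated
observations collapse, and coverage = 100 × |union| / length. Isoleucine
and leucine are distinct by default — the synthetic data are
self-consistent — with an `il_equivalent` switch for real search-engine
output, where the two are indistinguishable by mass.

The screen keeps proteins with degradation and stabilization both above 5
coverage points (strict inequality). "More than 5%" admits two readings;
absolute points is the default and a relative-percent mode is provided.
Fold change is `cov_drug / cov_pronase`, undefined (flagged, not dropped)
at zero pronase coverage; such proteins still pass or fail on the point
deltas. Ranking is by descending stabilization, then fold change, then
protein id, so output is reproducible under ties and input permutation.

## The synthetic DARTS experiment

An LC-MS/MS evidence table pools peptides over an astronomically large
population of protein molecules, so the generator does not sample one
molecule's digest. Cleavage is modeled per bond: trypsin cuts after K/R
(not before P) with certainty during sample preparation; pronase cuts any
other bond with probability `p_pronase` per molecule. A fragment's relative
abundance in the pool is then

    a(s, e) = P(cut at left boundary) · P(cut at right boundary)
              · Π P(no cut at interior bonds),

with protein termini as certain boundaries. Fragments with
`a < min_abundance` are below the identification limit and never reported;
fragments inside the detectable length window (7–30 residues, the typical
MS-observable range) are observed with probability `p_detect = 0.7`.
Detection draws are keyed by peptide identity (protein, start, end), not by
condition — a peptide's ionizability is intrinsic — so identical digests
yield identical tables, and a pronase-free "pronase" arm is exactly the
control arm. Cleavage substreams are keyed per condition and per protein by
stable hashing, so enlarging the proteome never perturbs existing proteins.

Drug protection multiplies the pronase cleavage probability inside the
target's footprint (± a 5-residue flank) by `1 − protection`, with
`protection = protection_max / (1 + (EC50/dose)^h)` — dose-dependent
stabilization with a logistic form, applied only to the designated target.

Defaults: `p_pronase = 0.30`, `min_abundance = 0.04`. These two interact
and were set analytically, not by trial: a fully tryptic peptide of length
l survives pronase with abundance `0.7^(l−1)`, so the pronase arm retains
only short tryptic peptides (l ≤ 9) — strong degradation; semi-specific
peptides in the pronase arm top out near `0.3 · 0.7^6 ≈ 0.035`, just below
the identification limit, while semi-specific peptides inside a protected
footprint (residual nicking rate 0.06 at saturation) reach
`0.062 · 0.94^6 ≈ 0.042`, just above it. The limit therefore sits exactly
in the regime where limited proteolysis is informative: pronase erases
coverage, and protection restores it even across footprint stretches that
trypsin alone cannot render observable. The demo footprint default (central
45% of the target) yields a stabilization signal on the order of ten
coverage points at saturating dose, the magnitude typical of a
high-fold-change DARTS hit.

What the generator does *not* emulate: spectrum-level effects (m/z,
retention time, co-elution), abundance-dependent detectability, shared
peptides between homologs, missed cleavages beyond the two-stage digest,
and real amino-acid composition (sequences are uniform over the 20
standard residues). One consequence worth knowing: for a target whose
footprint overlaps long trypsin-blind stretches, the drug arm can slightly
*exceed* control coverage, because residual nicking reveals regions trypsin
cannot — the ordering control ≥ drug ≥ pronase holds for proteome- and
across-target means, while drug > pronase (protection visible) and
control > pronase (degradation) hold per target. Passing screens on these
data show the cascade logic and effect-size calibration are right; they do
not certify performance on real, inhomogeneous proteomes.

## Dose-response and isotherm fits

The 4PL is parameterized as `(bottom, log span, log EC50, log hill)`:
span > 0 keeps bottom ≤ top, the log keeps EC50/hill positive, and fitting
in log EC50 makes the estimate exactly scale-equivariant. Initialization is
from data quartiles (extreme responses for the plateaus; the first dose
reaching half-signal for EC50; hill 1). Levenberg-Marquardt with tight
tolerances; a fit that fails to converge or worsens the initial heuristic
raises rather than returning silently. The hill slope is free by default
and can be pinned (`fix_hill=1` for simple binding).

The 1:1 isotherm uses the cancellation-free root
`fb = 2L / (S + sqrt(S² − 4PL))`, `S = P + L + Kd`, stable in the dilute
limit where it reduces to `L/(L + Kd)`. Protein concentration is a fixed
experimental input; baseline and (signed) amplitude are free, Kd is fit in
log space. Uncertainty for both fits: seeded case-resampling bootstrap
(500 resamples by default), percentile intervals; degenerate resamples are
skipped. With few points the percentile interval on a log-scale parameter
can be very wide or one-sided — that is the honest answer, not an error.

Packaged scenarios: a dose series at EC50 280 µM over 7 half-log doses
(10–10 000 µM, noise sd 0.03) and a binding trace at Kd 204 µM with 0.05 µM
protein over 12 half-log ligand points (noise sd 0.02 on the bound
fraction). Single noisy titrations of this size carry 10–30% spread in
EC50/Kd; recovery is therefore assessed on means over 20 seeded replicates
(observed: within ~2% of truth).

## Ensemble alanine scanning

The ledger machinery is standard: snapshots from an equilibrated ensemble
(200 at 50 ps spacing in the full-scale protocol), single-trajectory
approximation (mutant energies evaluated on wild-type geometries),
`ΔΔG = ΔG_WT − ΔG_Mut` with destabilizing mutations negative, records
sorted most-destabilizing first, tiers at ΔΔG ≤ −2 (hotspot) and ≤ −0.5
(contributor), both configurable.

The energy function is deliberately minimal: Coulomb with
distance-dependent dielectric ε(r) = 4r (a common implicit-screening
surrogate) plus 12-6 Lennard-Jones under Lorentz-Berthelot combination,
12 Å cutoff by default, no solvation, surface, or entropy terms. Absolute
ΔΔG values are therefore *not* comparable to PB/GB-based scans; what is
preserved — and what the tests certify against brute-force all-pairs
recomputation to 1e-8 kcal/mol — is the ledger's structure: exact
per-residue additivity of the decomposition, ensemble averaging, the sign
convention, and the ordering of planted contacts versus distal residues.
Mutation truncates side-chain atoms beyond Cβ and resets the retained Cβ to
an alanine template charge (−0.1825 e, Amber-derived); the residue name is
kept, which makes the operation idempotent; GLY/PRO/ALA targets are
rejected. Toy complexes place residues on a 6 Å lattice with parameters on
the outermost side-chain atom, the single-atom ligand at an exact contact
distance, and Gaussian positional jitter across snapshots.

## System-preparation arithmetic

Ion counts: base salt pairs `n = round(molarity · n_water / 55.5)` (water
molarity configurable; 55.345 satisfies the same reference values), then
neutralization by removing cations for a positive solute charge (anions for
negative), guaranteeing electroneutrality or raising when the box is too
small. The solute net charge is an explicit input. Rounding is half-up
everywhere, documented; the reference configuration (16 000 waters, 0.15 M,
+4) gives 39 cations / 43 anions, stable for water counts in
[15 725, 16 095]. Leaflet composition rounds the sterol count at the stated
ratio (110 primary at 10:1 → 11). Snapshot schedules use a half-open
`(start, end]` window so a 10 ns window at 50 ps gives exactly 200 frames;
non-integral windows warn and floor.

## Pipeline and reproducibility

One pydantic-validated JSON config drives all stages; every random draw
derives from the single root seed through hashed substreams, and the run
summary is byte-identical across repeated runs. Each stage persists its
inputs/outputs (FASTA, TSV evidence, CSV tables, multi-MODEL PDB +
parameter sidecar), and every writer round-trips with the corresponding
reader, so stages can be re-run individually from disk. Problem sizes in
the shipped tests and demos (30–40 proteins of 60–400 residues, 50 screen
replicates, 20-snapshot test ensembles, 20-replicate fit averages) were
chosen as the smallest sizes at which the statistical claims are stable.
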