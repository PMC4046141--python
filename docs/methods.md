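# Methods

`aldh10evo` models how plant ALDH10 aminoaldehyde dehydrogenases (AMADHs)
acquired betaine aldehyde dehydrogenase (BADH) activity — the committed step
of glycine betaine (GB) synthesis — through mutation of the residue at the
position equivalent to 441 of the spinach enzyme (SoBADH numbering). This
note records the models, their assumptions, the defaults and the design
choices made where the design was genuinely open.

## Codon pathway enumeration

The genetic code is represented as a graph on the 64 DNA codons with edges
between codons differing at exactly one position. The distance between two
amino acids is the shortest path between their codon sets; pathways are
enumerated exhaustively by depth-first search with a depth cap of the
minimum length plus a configurable surplus.

Decisions:

* **Code and alphabet.** Standard nuclear code (NCBI table 1), DNA alphabet;
  RNA input (U) is normalized to T. Other codes can be loaded from a
  two-column text table but are never the default.
* **Stop exclusion.** Stop codons are excluded as path interiors by default:
  a nonsense intermediate truncates the protein and cannot be a functional
  evolutionary intermediate. A flag disables the exclusion for completeness;
  endpoints may be stops only when a stop is explicitly queried.
* **Silent interiors.** An interior codon synonymous with the source or
  destination amino acid is kept in the path but flagged *silent* and
  excluded from the set of evolutionary intermediates — the intermediates of
  interest are changed proteins, not synonymous codons.
* **Orderings.** Substitution orderings count as distinct paths
  (ATT→GTT→GCT and ATT→ACT→GCT are two pathways through different
  intermediates).

Under these rules Ile→Ala and Ile→Cys each need two substitutions, with
intermediate sets {Val, Thr} and {Phe, Ser} respectively; the whole
enumeration is cross-checked in the tests against an independent
breadth-first-search oracle over all 21×21 ordered amino-acid pairs.

## Isoenzyme classification rules

Sequences are consumed as an aligned protein FASTA with a designated
reference; residue numbering is 1-based over the ungapped reference and
alignment columns are 1-based.

* **Residue type.** The residue in the 441-equivalent column names the type
  (I441, A441, C441, V441, T441, S441, F441); gaps, X and any other residue
  map to `other`, never to a guess.
* **Activity rule.** A441/C441/S441/T441 → AMADH+BADH; I441/V441/F441 →
  AMADH-only. The S441 and F441 calls are inferred from engineered variants
  (no natural S441/F441 enzyme is known) and the `other` type yields
  AMADH-only with a low-confidence flag.
* **PTS1 detection.** Peroxisomal targeting is read from the C-terminal
  tripeptide against a position-wise consensus. Two presets exist because
  two consensus definitions are in circulation for these enzymes:
  `results-text` (S/A)-(K/R)-(L/M/I), the default, and `figure-legend`
  (S/A/C)-(K/R/H)-(L/M). Only the final three residues matter; a sequence
  whose alignment ends in gaps where the reference still has residues is
  C-terminally truncated and its PTS1 state is reported as unknowable.
* **Location.** Peroxisomal iff PTS1 matches. Chloroplast targeting is not
  inferred (the relevant BADH-active enzymes lack a typical
  chloroplast-targeting signal), so everything else is one
  "non-peroxisomal" bucket.
* **GB phenotype.** Per species: any non-peroxisomal BADH-active isoenzyme →
  high accumulator; else any peroxisomal BADH-active one → low/moderate
  accumulator (peroxisomal GB synthesis is limited by substrate transport);
  else non-accumulator.
* **Monophyly.** On an unrooted tree a tip set is monophyletic iff some
  bipartition separates exactly that set. The clade size reported alongside
  is the smallest rooted (as-written) clade containing the set, which can
  exceed the set size purely through root placement.
* **ε280.** Molar absorptivity from composition with coefficients 5500
  (Trp), 1490 (Tyr) and, for oxidized protein, 125 per cystine (cysteines
  assumed fully paired). The default is the reduced protein; 13 Trp + 10
  Tyr reproduces the 86 400 M⁻¹cm⁻¹ used for these enzymes.

## Kinetic models

Initial velocities v/E (s⁻¹) versus substrate (µM) are fitted to either the
Michaelis–Menten equation or, where the aldehyde inhibits at high
concentration, the total-substrate-inhibition law

    v/E = kcat·S / (Km + S·(1 + S/K_IS)),

which reduces to Michaelis–Menten as K_IS → ∞ and peaks at S = √(Km·K_IS).
Total (not partial) inhibition is assumed; assays rarely reach
concentrations that distinguish the two, and partial inhibition is out of
scope.

Numerical choices: parameters are fitted in log space (which enforces
positivity) by damped least squares (`scipy.optimize.least_squares`,
`method="lm"`), converging when the relative parameter change falls below
1e-8, capped at 500 iterations per parameter. Initial guesses are kcat₀ =
max observed rate, Km₀ = interpolated half-saturation concentration, K_IS₀ =
10× the top concentration — robust for saturating designs. Standard errors
come from the linearized covariance at the optimum mapped back through the
delta method; with replicate purification batches these are *fit* errors,
not between-batch standard deviations, and are labelled as such. Degenerate
inputs (fewer than 4–5 points, all-equal rates) are rejected before fitting.
A fitted K_IS is flagged unreliable when the assayed range stops short of
√(Km·K_IS): the data then never see the downturn and the constant is
unidentified — the reason inhibition constants for these enzymes are
typically not reported.

Catalytic efficiency is kcat/Km × 1000 (kcat s⁻¹, Km µM → mM⁻¹s⁻¹); the
unit conversion lives in exactly one function. Variants are split into
BADH-active vs AMADH-only by their efficiency with betaine aldehyde against
a threshold of 5 mM⁻¹s⁻¹ — the midpoint of the empirical gap (1.1 … 15)
between the two observed groups; any threshold inside the gap gives the
same split, and the threshold is configurable.

The reference parameter tables embedded in `aldh10evo.published` reproduce
their own printed efficiencies from printed kcat and Km to within 5% plus a
unit in the last digit in every cell except one (A441C in the NAD⁺ block
with BAL, where the printed ratio appears to be a mean of per-batch ratios);
the test suite asserts that this is the only exception.

## Thermal stability

Denaturation of these enzymes is irreversible, so no equilibrium
thermodynamics (ΔH, van't Hoff) is extracted — only the apparent Tm, the
midpoint of a single Boltzmann sigmoid

    y(T) = bf + (bu − bf) / (1 + exp((Tm − T)/s))

with constant baselines (sloped baselines are deliberately not implemented).
Initial guesses: baselines from the first/last 10% of points, Tm from the
half-range crossing, slope 2 °C. The slope is fitted in log space; a flat
trace or a fitted midpoint outside the scanned range is an error, not a
result. Tm is reported to 0.1 °C. Raw ellipticity (mdeg) converts to mean
residue ellipticity via θ·MRW/(10·c·l) with a mean residue mass of 109.1.
Variants are grouped by ΔTm against a reference with a ±5 °C band
(reference-like / stabilized / destabilized); the scan rate is metadata
only — no kinetic-denaturation model.

## Synthetic data

Every generator is a pure function of its parameters and a seed
(`numpy.random.default_rng`); identical inputs give byte-identical outputs.

* **Sequences.** A fixed, arbitrary 500-residue template (deterministic,
  marked 441 column, C-terminal SKL) — *not* a real spinach BADH sequence.
  Family members differ at the 441 column per a composition whose default,
  88 I / 19 A / 10 C / 3 V / 2 T over 122 sequences, mirrors the observed
  family composition; codons are drawn uniformly among synonymous codons
  unless weights are given; C-termini are PTS1-intact, point-mutated or
  truncated (5–30 residues, padded with alignment gaps) in configurable
  proportions, default 0.7/0.2/0.1; group labels default to the 30:82
  monocot:eudicot split of the sequence set the composition mimics. States
  are assigned, not evolved — no substitution-model simulation — so passing
  tests demonstrate pipeline correctness, not power against real alignment
  noise, paralogy or alignment error.
* **Kinetics.** Rates from the substrate-inhibition law with multiplicative
  Gaussian noise (spectrophotometric error scales with signal); default
  grids 8 points over 0.02–2 mM (BAL-like) and 10 points over 0.5–200 µM
  (APAL-like, matching assays capped at 0.2 mM).
* **Melt curves.** Boltzmann signal on a 1 °C grid over 20–90 °C with
  additive Gaussian noise; default baselines −25 → −5 mdeg.
* **Trees.** Random binary topologies with tips grouped into labelled
  clades and 441-states assigned per clade, so monophyly outcomes are known
  by construction; the default mimics the recurring two-clades-per-family
  pattern (one all-Ile clade, one mixed).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the scales above: the full 21×21 codon-pathway sweep, the 122-sequence
family, 100 noisy melt curves, and simulate-then-fit sweeps over the
published parameter scale. These sizes were chosen to exercise every rule
and identifiability regime the analysis depends on.

## Known limitations

* No tree inference, alignment construction, bootstrap or substitution-model
  selection: alignments and trees are consumed, not built.
* No bi-substrate mechanism, pH/temperature dependence or product
  inhibition in the kinetic models; partial substrate inhibition is not
  fitted.
* No CD spectral deconvolution; far-/near-UV spectra are out of scope.
* The phenotype rule is deliberately minimal — it encodes the observed
  association between isoenzyme location/type and GB accumulation, not a
  metabolic model; real accumulation also requires choline monooxygenase
  activity, correct targeting and osmotic-stress regulation.
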