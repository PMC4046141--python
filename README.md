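# aldh10evo

Tools for analysing how plant ALDH10 aminoaldehyde dehydrogenases (AMADHs)
acquired betaine aldehyde dehydrogenase (BADH) activity — and with it the
ability to make the osmoprotectant glycine betaine (GB) that underlies
drought, salt and cold tolerance in many plants.

The substrate specificity of these enzymes is gated by a single buried
residue, position 441 in spinach BADH (SoBADH) numbering: Ile-type
isoenzymes reject betaine aldehyde (BAL), while Ala- or Cys-type
isoenzymes oxidize it. Because every Ile codon differs from every Ala or
Cys codon at two nucleotides, the evolutionary change had to pass through a
one-substitution intermediate. The package implements the quantitative
stages of that analysis for phylogeneticists and enzymologists:

* **Codon pathways** (`aldh10evo.genetic_code`) — the 64-codon
  single-nucleotide-substitution graph; minimal mutational pathways between
  amino acids, their intermediates, stop-codon reachability (the mechanism
  of peroxisomal-signal loss) and codon-usage tables. Ile→Ala passes
  through Val or Thr; Ile→Cys through Phe or Ser.
* **Isoenzyme classification** (`aldh10evo.classify`) — map the
  441-equivalent alignment column, type each sequence (I441, A441, …),
  detect the C-terminal peroxisomal targeting signal (PTS1) against a
  position-wise consensus, and apply the activity rule
  (A/C/S/T → AMADH+BADH, I/V/F → AMADH-only), the location rule and the
  per-species GB-accumulation rule; tree annotation and monophyly tests.
* **Kinetics** (`aldh10evo.kinetics`) — Michaelis–Menten and
  total-substrate-inhibition rate laws, v/E = kcat·S/(Km + S(1 + S/K_IS)),
  fitted by damped least squares in log-parameter space;
  catalytic efficiencies (kcat/Km, mM⁻¹s⁻¹) and the two-group
  BADH-active/AMADH-only classification.
* **Thermal stability** (`aldh10evo.stability`) — apparent Tm from a single
  Boltzmann sigmoid fitted to circular-dichroism melt curves, mean-residue-
  ellipticity conversion, and stability grouping by ΔTm.
* **Synthetic data** (`aldh10evo.simulate`) — seeded generators for aligned
  families with controlled 441-states and PTS1 fates, velocity curves, melt
  traces and clade-structured trees, so the whole pipeline runs and is
  tested without any downloads.

The fitting stages follow the familiar model/results idiom: construct a
model from a dataset, call `fit()`, read estimates, standard errors and a
`summary()` off the results object.

## Worked example

Enumerate the parsimonious pathways from Ile to Ala:

```text
$ aldh10evo pathways --from I --to A
I -> A: minimum 2 substitution(s), 6 path(s)
intermediate amino acids on minimal paths: TV
  ATA -> ACA -> GCA  [T]
  ATA -> GTA -> GCA  [V]
  ATC -> ACC -> GCC  [T]
  ATC -> GTC -> GCC  [V]
  ATT -> ACT -> GCT  [T]
  ATT -> GTT -> GCT  [V]
```

Every minimal route needs two substitutions, and the intermediate enzyme
carries either Val or Thr at position 441 — the two residues actually found
in rare natural isoenzymes.

Fit a noisy synthetic APAL saturation curve (5% multiplicative noise,
generated from kcat 0.99 s⁻¹, Km 3.9 µM, K_IS 400 µM) and a melt curve
(Tm 60 °C, σ 0.4 mdeg):

```python
import aldh10evo as a

ds = a.gen_kinetics(kcat=0.99, Km=3.9, K_IS=400.0, cv=0.05, seed=7,
                    variant="wild-type", substrate="APAL")
print(a.fit_si(ds).summary())

mc = a.gen_melt(tm=60.0, sigma=0.4, seed=7, variant="A441V")
print(a.fit_melt(mc).summary())
```

```text
Kinetic fit: SubstrateInhibitionModel  [wild-type / APAL]
  n = 10 points, SSR = 0.004712
   kcat = 1.021 +/- 0.0387 s^-1
     Km = 4.423 +/- 0.457 uM
   K_IS = 346.0 +/- 58.8 uM
  kcat/Km = 230.7 mM^-1 s^-1

Boltzmann melt fit  [A441V]
  n = 71 points, ||resid|| = 2.804
  Tm_app = 60.0 +/- 0.065 C
  slope  = 2.04 +/- 0.057 C
  baselines: folded -25.18, unfolded -4.957
```

The fit recovers the generating parameters within their standard errors:
kcat ≈ 1.02 ± 0.04 s⁻¹ vs the true 0.99, and an apparent Tm of 60.0 °C —
the ~10 °C stabilization seen for the Val- and Ile-type variants relative
to the ~50 °C wild type.

Other CLI verbs: `classify`, `fit-kinetics`, `fit-melt`, `simulate`, and
`run --config cfg.yaml` for the full pipeline (pathways → classification →
kinetics → stability) writing tab-separated report tables.

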