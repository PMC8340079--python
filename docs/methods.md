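# Methods

## Problem and model

A deconvoluted intact-mass spectrum of a glycoprotein is a list of neutral
masses with relative intensities. Each signal is explained by one or more
glycoforms: assignments of one glycan species (or none) to each
glycosylation site of the chain. The package models annotation as a
two-stage search. Stage 1 decomposes the residual mass (peak minus backbone)
into monosaccharide compositions over the four-unit alphabet
Hex/HexNAc/Fuc/Neu5Ac by complete bounded enumeration; stage 2 enumerates
the per-site species tuples from a site-specific quantitative library whose
summed composition matches a stage-1 hit exactly. The probability model
behind the scoring is independence across sites: the prior weight of a
glycoform is the product of the site-specific relative abundances, and hit
scores are these products normalized to 100% within a peak. The same model,
applied at the level of whole chains, annotates the spectrum of a
noncovalent heterodimer: the two chains act as two pseudo-sites whose
"species" are whole-chain glycoforms, paired independently, with the
theoretical dimer mass the exact sum of the chain masses (noncovalent
association adds no mass).

Assumptions worth making explicit:

* **Site independence.** Abundances multiply across sites; cooperative or
  anti-cooperative glycosylation is not modeled. The same assumption enters
  the dimer level as independent chain pairing.
* **Permutations are distinct.** A glycoform is an ordered per-site tuple;
  the same two glycans on swapped sites are two assignments. Each distinct
  tuple is counted once.
* **O-glycans as regions.** O-glycosylation in Ser/Thr-rich stretches
  cannot be localized by intact or peptide-level data, so O-sites are
  modeled as regions with a glycan-count capacity (two per region here);
  region species carry one or two core-1 units with 0–4 sialic acids.
* **Occupancy is a species.** The reserved species `unmodified` makes
  partial site occupancy an ordinary library entry, so macro- and
  microheterogeneity share one combinatorial treatment.

## Mass scales and tables

Two mass modes exist because subunit spectra are isotopically resolved
(monoisotopic masses) while native spectra of the complex are not (average
masses). Monosaccharide residue masses and modification masses are bundled
data (`data/*.tsv`), derived from atomic compositions with monoisotopic
masses and IUPAC 2013 standard atomic weights respectively; amino-acid
elemental compositions come from pyteomics and are evaluated against the
same two atomic tables, so both scales share one code path. Average-mode
rounding reproduces the deltas seen between neighboring signals of real
spectra: Neu5Ac 291, Fuc 146, HexNAc+Hex 365, 2×Fuc 292 Da.

Backbone chemistry: one water per chain, carbamidomethylation (+57.021/
+57.052 Da) on every cysteine not engaged in a disulfide, −2 H per
disulfide bond. Variable modifications considered during annotation are
Met/Trp oxidation (0..k alternatives; assignments differing only in
oxidation are merged, matching how oxidized satellite signals are summed
into their parent proteoform) and the Asn→Asp deamidation scar (+0.984 Da)
that PNGase F leaves at formerly occupied N-sites, which is carried by the
deamidated `unmodified` species so that occupancy bookkeeping survives the
in-silico digest.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| Subunit tolerance | 20 ppm | matches isotopically resolved Orbitrap subunit data |
| Dimer tolerance | ±3 Da (symmetric) | unresolved native peaks of a ~37 kDa complex |
| Library cutoff | 0.3% fractional abundance | keeps chain libraries near the ~120-entry scale the pair search tolerates; coverage is always reported against the pre-truncation total, and abundances are renormalized for scoring only |
| Coverage threshold | 0.04% | reporting threshold for "how many glycoforms explain the signal" |
| Stage-1 bounds | library capacity | per-unit sums of site maxima; complete w.r.t. anything stage 2 could assign. Standalone decomposition defaults to Hex ≤ 40, HexNAc ≤ 40, Fuc ≤ 8, Neu5Ac ≤ 16, generous for a ~12 kDa glycan load |
| Na-adduct window | +21.982 Da ± tol | satellites inherit the parent's assignments with a flag; their intensity is not added to the parent (conservative) |
| −1 Da rescue | off | re-searches unannotated peaks at +1.00235 Da and flags them as deconvolution-artifact candidates instead of widening the tolerance |

Ranking is by descending hit score, then ascending |mass error|, then
lexicographic label. Peaks with no assignment are flagged and reported with
their best near-miss composition (smallest |error| within the library's
capacity, searched in a window of max(2 Da, 10×tol)) — that is how a
−1 Da-shifted peak is diagnosed rather than silently absorbed.

Abundance aggregation excludes only satellite peaks that *inherited* their
assignments from an adduct parent; a peak with assignments of its own always
counts, because in dense glycoform ladders genuine signals routinely sit
~22 Da above other signals.

## Synthetic data

The generator emulates the statistical structure of deconvoluted spectra of
a gonadotropin-like glycoprotein: per-site categorical abundances drawn
from a flat Dirichlet prior; occupancy below 100% encoded exactly as an
`unmodified` weight; glycoform enumeration above an abundance floor;
isobaric collapse of theoretical masses within a resolution window (0.1 Da
subunit-like, 3 Da dimer-like) into single peaks carrying the summed
abundance; Gaussian mass error (ppm or Da); multiplicative log-normal
intensity noise; optional +21.982 Da satellites and −1 Da artifacts. The
ground truth records every peak's contributor set pre-noise plus the
population quality attributes.

The frozen reference scenarios (`glycoform.scenarios`) use the bundled
mature hCG chain sequences: a β-like subunit with two N-sites (12
biantennary/tri-antennary/high-mannose species each; the first N-site 62.6%
occupied) and three O-regions (9 core-1 species each), abundance floor
1e-6 (~50 000 glycoforms, ~1 000 peaks); and a native heterodimer with ≤60
glycoforms per chain (56×56 pairs) at average masses. These sizes keep a
complete run of the benchmarks under a minute on one CPU.

What the generator does **not** emulate: isotopologue envelopes and
charge-state ladders (annotation operates downstream of deconvolution),
correlated site preferences, glycan-dependent chain association,
intensity-dependent mass error, and chemical noise/baseline. Passing
recovery benchmarks therefore demonstrates the correctness of the
combinatorial search and scoring under the stated statistical model, not
robustness to deconvolution failures in real raw data.

## Numerical choices

* Stage-1 enumeration solves the innermost (Fuc) count in closed form and
  prunes on partial mass; completeness is property-tested against brute
  force.
* ppm tolerances are evaluated at the intact peak mass, not the residual.
* Isobaric collapse is greedy over the mass-sorted glycoform list: a
  cluster absorbs entries within the window of its first (lowest-mass)
  member; the peak mass is the abundance-weighted mean of its members.
* In the 20 ppm mass-error benchmark the search tolerance is 50 ppm
  (2.5 σ): a window below the error σ would discard ~1/3 of genuine peaks
  by construction. "Well-separated" peaks are those whose nearest
  neighboring cluster lies more than 3× the tolerance window away.
* Quality-attribute closure is judged against the library-implied full
  population (floor 0), because annotation legitimately redistributes
  abundance over every library-expressible glycoform, including those the
  floored spectrum never emitted.
* Degrees are clipped to [0, 1]; glycoforms with zero capacity for an
  attribute are excluded from its weighted mean, and an all-zero-capacity
  input raises a distinct error rather than returning 0.

## Known limitations

* The nomenclature grammar covers complex (A/S/G/F with LacN extensions),
  high-mannose/hybrid (M-series) and core-1 O-glycans; linkage isomers,
  sulfation, phosphorylation and Neu5Gc are out of scope (the mass tables
  are data, so the alphabet can be extended without touching code).
* The dimer pair search is exact but quadratic in chain-library size; the
  ~120-entries-per-chain warning marks where it becomes noticeably large.
* Hit scores are prior-weighted explanations, not posterior probabilities:
  a glycoform absent from the library can never be assigned, and a biased
  library biases every downstream abundance (the documented failure mode of
  library-constrained annotation).
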