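# Methods

## Scope and model overview

The package decides, for each miRNA up-regulated in infarcted myocardium,
whether the SERCA2 3'-UTRs carry binding sites that are (a) energetically
favorable as an intermolecular duplex and (b) locally accessible, i.e. not
buried in competing secondary structure. Binding strength and local
structure are both expressed as Gibbs free energies at 37 °C (kcal/mol)
under one nearest-neighbor parameter table, so the accessibility criterion
compares like with like.

## Energy model

The parameter table (`data/nn_params.tsv`, version string logged on load)
is a Turner-2004-style RNA/RNA set: the ten Watson–Crick/Watson–Crick
stack increments are the standard published values; G:U-containing stacks
are representative literature-style values; duplex initiation is
+4.1 kcal/mol; bulge and internal loops are affine in loop size
(3.8 + 0.4·n and 4.0 + 0.3·n); hairpin loops are tabulated for sizes 3–9
with a 1.75·RT·ln(n/9) extrapolation; multibranch loops are linear
(3.4 offset + 0.4 per branch). No dangling ends, coaxial stacks, or
temperature dependence. The table is a documented, swappable text asset:
the published site tables were produced by external tools whose parameters
are not restated anywhere, so reproducing their printed ΔG values is
explicitly not attempted — all screen logic depends only on energy
*differences* under a consistent model.

Both dynamic programs share this table:

- **Duplex DP** (`duplex_thermo`): minimizes over antiparallel,
  non-crossing chains of pairs between the two molecules, with no
  intramolecular pairs and loop sides capped at 6 nt. Rounding to one
  decimal happens only when writing tables, never inside the DP. The empty
  pairing scores 0, so reported duplex energies are ≤ 0 in practice
  (initiation alone is never optimal).
- **Folder** (`flank_fold`): Zuker-style MFE with hairpin loops ≥ 3 nt,
  stacking, capped bulge/internal loops, and linear multibranch scoring.
  The open chain scores 0, so the MFE is never positive; the published
  tables contain a few +0.3 flank entries, which we treat as artifacts of
  the original tool and do not reproduce.

Both are verified exactly against independent enumeration oracles in the
test suite (all legal chains for duplexes up to 8 nt; all legal structures
for sequences up to 18 nt). An optional hook logs — never asserts — the
energy difference against an external folder when `RNAfold` is installed.

## Screening decisions

- **Seed region = miRNA positions 1–8** from the 5' end. G:U wobble counts
  as pairing for energy and for the candidate-window filter, but *not*
  toward "perfect" seed complementarity, which requires Watson–Crick
  pairing at all eight positions; "partial" is any nonempty proper subset.
  Matched positions beyond 8 are recorded but never influence the class.
- **Candidate windows**: lengths |miRNA| ± 3 (the slack bounds the bulge
  budget), stepped by 1, kept when ≥ 4 of 8 seed positions can oppose a
  pairable base without gaps. This is deliberately permissive: the energy
  stage, not the pre-filter, decides.
- **Duplex ceiling −15 kcal/mol**, chosen to bracket the weakest published
  site (−18.1) with margin; configurable.
- **Accessibility** passes when the gap ΔG_flank − ΔG_bind is ≥ 10 kcal/mol
  against *at least one* flank. The one-flank reading is forced by the
  published data themselves: selected rows exist whose two gaps are 7.1
  and 10.8, which a both-flanks rule would have excluded. Consistently,
  every row of both shipped site tables passes at gap 10 (a suite
  invariant).
- **Flank windows are 70 nt**, exclude the site, truncate silently (logged)
  at UTR boundaries, and an empty flank scores 0 — the least structured
  value, so a boundary site is never spuriously accessible via a
  nonexistent flank.
- **Hot-spots** merge sites transitively on shared UTR positions (1-based
  inclusive; zero-gap overlap merges). A merged cluster with ≥ 2 distinct
  mature names (miR-320a/b/c/d count as distinct; families are reporting
  only) is cooperative. On the SERCA2a table this yields exactly the seven
  cooperative clusters the study describes; on the SERCA2b table the same
  rule yields eight, not the nine the study text mentions — the original
  clustering convention for that isoform is not reconstructible from the
  text, so the package reports what its stated rule produces.

## Integration decisions

- **Up-regulation threshold +0.1 log2**: the only reading under which the
  shipped DE table yields the study's count of ten up-regulated miRNAs
  (+0.04 excluded, +0.32 included). Configurable.
- Name matching strips `hsa-` and ignores case; arm suffixes (-5p/-3p) are
  significant. Genomic-locus suffixes on cluster partners (miR-133a-1 →
  miR-133a) are stripped only when a family number remains.
- A record is *clustered* when at least one of its loci names a partner
  gene ("as single gene" notes do not count); clusters are identified by
  (chromosome, member set), so the two miR-1/miR-133a loci are two
  clusters. The partner-closure rule yields five fully represented
  clusters from the shipped table where the study text says four; since
  the study's cluster-identity convention is ambiguous, the report lists
  the clusters rather than asserting either count.
- ND entries in the DE table become absent values, never 0. The extracted
  DE table prints 42 rows although its own text counts 43 deregulated
  miRNAs; the fixture ships the printed rows, and every derived count
  (10 up, 15 predicted, 25 families, 25 clustered) checks out on them.
- Prediction sets are consumed as name lists (union or intersection mode);
  the four external prediction algorithms are not reimplemented.

## Expression stages

- **Arrays**: background is a running median (window 21 probes) of the
  per-probe background estimates, subtracted and clamped at 1 intensity
  unit. Cyclic LOWESS (span 0.4, ≤ 10 sweeps) normalizes channel pairs on
  the M-vs-A scale, preserving per-probe total intensity, and stops — or
  declines to touch an already-normalized matrix — once max |median M|
  < 0.01. Detection needs strictly-above-level signal in ≥ 3 of 5
  replicate probes. The balanced ratio is (M_forward − M_swap)/2, which
  cancels additive dye effects. DE is a per-miRNA two-sided one-sample
  t-test of the 15 pooled balanced ratios (3 arrays × 5 replicates)
  against 0 at α = 0.01 with no multiple-testing correction, matching the
  original decision rule; pooling across arrays is our declared choice.
  Heat-map ordering uses average linkage on 1 − Pearson with per-row
  centering/scaling applied only for display, never for testing.
- **qPCR**: efficiency from the five-step 3-fold dilution ladder
  (triplicates) by least squares of Cq on log10 input; fits outside
  (1, 2.2] are rejected. Replicate Cqs are averaged per sample *before*
  the Pfaffl ratio, oriented control − case (remote − infarct) so a ratio
  below 1 means lower in infarct. Wilcoxon signed-rank switches from the
  exact null to the normal approximation above n = 15 pairs.

## Synthetic data

Generators are pure functions of (parameters, seed); one pipeline seed
fans out per generator by CRC-based stream naming. They emulate: ~800-nt
i.i.d. UTRs at a chosen GC fraction; planted sites as exact reverse
complements whose flanks are rejection-sampled to fold ≥ −5 kcal/mol
(accessible) or carry 16-bp G/C hairpins folding ≤ −25 kcal/mol
(inaccessible) — hairpins go into *both* flanks, because under the
one-flank criterion a site stays accessible while either side is open;
the −5/−25 targets straddle the 10 kcal/mol criterion with margin for any
duplex down to about −53 kcal/mol. Arrays: log-normal baselines, a smooth
background gradient, a sigmoid intensity-dependent bias on channel 1, and
planted log2 effects across 3 arrays × 2 orientations × 5 replicates.
qPCR: Cq = baseline − log_E(input) with per-(sample, preservation)
loading offsets; FFPE adds a +3-cycle shift and doubles the scatter,
which inflates cell SDs but cancels inside efficiency-corrected ratios.

What the synthetic data does **not** emulate: probe cross-hybridization,
sequence-dependent labeling bias, spatial array artifacts beyond a smooth
gradient, RNA degradation profiles, or biological covariance between
miRNAs. Passing recovery tests therefore demonstrates that the pipeline's
inference is correct under its stated noise model, not that the original
tissue results would be regenerated from raw data (which are not
published).

## Problem sizes and determinism

The suite verifies the DPs exhaustively at small n (duplexes ≤ 8 nt, folds
≤ 18 nt), runs array-recovery simulations at 36 probes × 200 seeds, and
screens planted 800–1000-nt UTRs end to end; these sizes were chosen so
every property runs comfortably on one CPU while keeping the statistical
assertions (≥ 95% sensitivity, ≤ 5% false positives, ±0.05 efficiency)
well-powered. All randomness is seeded; screens and reports are
deterministic given their inputs.

## Known limitations

- Energy parameters are a documented approximation; absolute ΔG values are
  not comparable with other tools, only internally.
- No partition-function (ensemble) accessibility; MFE structure only.
- No conservation filtering, no statistical enrichment of hot-spots, and
  no pattern-discovery site finding; candidate discovery is seed+energy.
- Single-reference-gene qPCR normalization only (no geNorm/NormFinder).
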