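# Methods

## The scoring model

`tagsite` scores every residue of a query protein for its suitability as an
internal epitope-tag insertion point. Four per-residue features, each
normalised to [0, 1] with high values meaning "tolerant of an insertion",
enter the score:

1. **Conservation entropy.** Shannon entropy of the residue's column in a
   multiple sequence alignment of the query with one ortholog per species,

   H(X) = − Σ_a p(x_a) log₂ p(x_a),

   summed over the 20 standard amino acids and divided by the maximum
   possible entropy, log₂(20) = 4.32 bits. Variable columns (high entropy)
   tolerate insertions; invariant columns do not.
2. **Secondary structure.** DSSP-style codes are binned: defined elements
   (G, H, I helices, E strand, P polyproline) score 0, coil (C) scores 1.
   The codes the binning rule leaves open default to T, S → 1 (turn/bend,
   loop-like) and B → 0 (an isolated bridge still pairs strand backbone);
   both sets are configurable (`StructureFeatureConfig.zero_codes` /
   `one_codes`).
3. **Relative solvent accessibility.** RSA = SASA / SA_max per residue
   type, clamped at 1 (annotated areas can exceed the tripeptide maxima).
   SA_max defaults to the theoretical (Gly-X-Gly) maxima of Tien et al.;
   the empirical scale is selectable by name.
4. **Disordered-binding complement.** 1 − BR, where BR is the predicted
   probability that the residue lies in a disordered protein-binding
   segment. No smoothing is applied to BR itself.

Per residue *i* two scores are formed:

* **E_i = min(features)** — the minimum-feature score. A single
  unfavourable feature vetoes the site, which is the behaviour wanted for
  an insertion that must not disturb structure, interfaces, or conserved
  positions.
* **S_i = Σ_f w_f·x_f** — a weighted sum with default weights
  w = (entropy 1.5, secondary structure 1, RSA 1, DBR 1), range [0, 4.5].
  S_i is reported per residue and used as a benchmark feature, but ranking
  is by E_i: the minimum is the decision rule, the sum is descriptive.

E_i is then smoothed with a centred 7-residue sliding window, truncated at
the chain ends so the first three positions average 4, 5 and 6 residues
(`terminal_mode="clipped"`). An alternative convention in which the three
positions at each end all average the four terminal residues is available as
`terminal_mode="terminal4"`; the two differ only at six positions per chain.
Candidate sites are the positions with the highest windowed E_i (ties broken
by ascending position; everything tied with the k-th candidate is kept), and
the two terminal positions are always reported alongside for comparison with
conventional end-tagging.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| species panel | 7 vertebrates (cow, dog/wolf, chicken, human, mouse, fugu, western clawed frog) | orthologs entering the alignment; configurable for non-vertebrate queries |
| entropy norm | 4.32 | printed-precision log₂(20); `full_precision_norm=True` uses the exact value |
| weights w | 1.5 / 1 / 1 / 1 | entropy up-weighted in S_i |
| window | 7 (odd) | sliding-window width for E_i smoothing |
| top_k | 5 | candidates reported (plus ties, plus terminals) |
| probe radius / points | 1.4 Å / 960 | Shrake–Rupley fallback SASA |
| missing_residue_policy | score_zero | residues absent from the structure annotation are never recommended |

Entropy counts gaps and non-standard codes (X, B, Z, U) as missing data, not
as a 21st symbol — the normalisation is over 20 amino acids, so adding a gap
to a column never changes H. The query row is included in the column
frequencies (all alignment rows count equally). Columns with fewer than two
counted residues get H = 0 and a warning.

## Numerical and interface choices

* All per-residue inputs are re-indexed onto the query sequence (1-based,
  order of appearance) after a hard check that the annotated sequence equals
  the query sequence; author numbering in structure files is discarded.
* The windowed mean is computed by full convolution with an explicit centre
  slice, so tracks shorter than the window are handled exactly; a unit test
  pins it against a brute-force double loop to 1e-12.
* Reported candidate scores are rounded to 2 decimals in console output;
  the TSV keeps full precision.
* RSA for residues without a tabulated maximum (code X) is set to 0 with a
  warning rather than raised, keeping the veto conservative.
* When no secondary-structure/accessibility annotation file is supplied but
  an all-atom structure is, RSA is computed with the built-in Shrake–Rupley
  surface (biotite backend, deterministic for a fixed point count) and the
  secondary-structure track is set to 1 everywhere with a prominent warning
  — coordinates alone cannot assign elements, so that run scores only
  conservation, exposure and binding.

## Benchmark protocol

Tag-site prediction is evaluated through its inverse: classifying labelled
in-frame insertion variants as pathogenic or benign. The design matrix is
(entropy, RSA, SS score, DBR, S_i, E_i) plus one-hot indicators of the SS
code (first level dropped); a logistic regression (unregularised by default,
`regularized=True` for L2) is fit on a stratified 80:20 split (floor(0.8·n)
per class to train, remainder to test, deterministic per seed) and scored
with precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = their harmonic mean,
pathogenic positive, threshold 0.5. Zero denominators yield 0. On linearly
separable data the unregularised maximum-likelihood estimate does not exist;
the solver's failure to converge is recorded (`MetricsRecord.converged`)
rather than raised, because the thresholded predictions remain well-defined
(and perfect) in exactly that regime. `repeat_eval` re-splits and refits
under derived seeds and reports the mean and sample s.d. of F1, mirroring
the repeated-split shape of published comparisons.

## What the simulator does and does not emulate

The variant simulator draws class-conditional features: benign insertions
at variable, exposed, coil, non-binding positions (Beta mean 0.62,
concentration 8, coil probability 0.75), pathogenic the reverse (mean 0.38,
coil 0.30, helix/strand-heavy non-coil codes), with class sizes 401
pathogenic / 433 benign matching the curated reference set's class
structure. S_i and E_i are always derived from the sampled features through
the scoring functions, never sampled independently.

It does **not** emulate: correlation among features at a real position
(entropy and exposure co-vary in real proteins), within-protein position
dependence, annotation noise, or class overlap as severe as real clinical
data. Consequently the default-regime F1 (~0.92 over repeated splits) is
higher than F1 values reported on real curated variant sets (~0.7–0.8);
passing the benchmark property suite shows the protocol machinery is
correct (perfect separation ⇒ F1 = 1, label-free data ⇒ F1 ≈ 0.5, counts
partition the test set, more separation ⇒ more F1), not that the features
carry that much signal in real data. Likewise the synthetic protein bundles
engineer regime contrast (diversified columns, coil, exposed, non-binding
inside "taggable" regions; single-feature vetoes elsewhere), so end-to-end
recovery of the engineered region validates plumbing and ranking, not
biological accuracy.

Problem sizes used by the test suite and the acceptance script — 100-residue
fixture proteins, 20 generator seeds, 200–834-variant simulations, 20
repeated splits — were chosen as the smallest sizes at which the Monte-Carlo
checks are stable.

## Known limitations

* Reproducing published per-residue scores for real proteins requires live
  resources (sequence/structure retrieval, a homolog database over the
  species panel, an external secondary-structure binary, a disorder
  predictor service); offline, the package consumes their file outputs.
* Whether published runs scored the open DSSP codes T/S/B as 0 or 1 is not
  recoverable from the method description; the defaults above are exposed in
  configuration so they can be calibrated against published per-residue
  score tables.
* The number of repeated splits behind published F1 standard deviations is
  unstated; `repeat_eval` exposes it as a parameter.
* No tag-construct design (linkers, multimerised tags) and no structural
  modelling of the tagged product — the output is a ranked list of insertion
  positions with provenance.
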