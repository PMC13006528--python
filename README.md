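# tagsite

**tagsite** predicts where inside a protein an epitope tag (e.g. V5,
`GKPIPNPLLGLDST`) can be inserted with minimal risk of destroying the
protein's fold or function. Terminal tags are convenient but often break
proteins whose N or C terminus is structured or mediates interactions;
internal insertion points can be far safer — if chosen well. The intended
users are molecular biologists tagging proteins in model organisms and
anyone benchmarking insertion-tolerance predictors.

## The score

Four per-residue features, each normalised to [0, 1] with high = tolerant of
insertion:

* **Shannon entropy** of the residue's column in a multiple sequence
  alignment with one ortholog per species,
  H(X) = −Σ_a p(x_a) log₂ p(x_a), divided by log₂(20) = 4.32 — variable
  positions tolerate insertions;
* **secondary structure**: DSSP codes G/H/I/E/P (helix, strand,
  polyproline) → 0, coil → 1;
* **relative solvent accessibility**: RSA = SASA / SA_max, clamped to 1 —
  exposed positions tolerate insertions;
* **disordered-binding complement** 1 − BR, where BR is the predicted
  probability the residue sits in a disordered binding region.

Per residue these combine into the **minimum-feature score**
E_i = min over the four features (one bad feature vetoes a site) and a
weighted sum S_i = Σ w_f·x_f (default w: entropy 1.5, others 1). E_i is
smoothed with a 7-residue sliding window (4–6 residues at the three terminal
positions) and positions with the highest windowed E_i are reported as
candidate insertion sites, always alongside the two termini for comparison.
A logistic-regression benchmark on labelled in-frame insertion variants
(simulated offline; real variant tables supported as a TSV schema) ties the
score to pathogenicity prediction via precision/recall/F1. See
`docs/methods.md` for the full model description.

## Worked example

Generate a synthetic 100-residue protein whose residues 40–50 are engineered
to be taggable (variable columns, coil, exposed, non-binding) and score it:

```sh
tagsite fixtures --length 100 --region 40:50:taggable --seed 7 --out demo/inputs
tagsite score --sequence demo/inputs/query.fasta \
              --alignment demo/inputs/aligned.fasta \
              --dssp demo/inputs/model.dssp \
              --anchor2 demo/inputs/anchor2.txt \
              --top-k 3 --out demo/out
```

prints

```
query: QUERY (100 residues)
top candidate insertion sites (position, windowed E, raw E):
     43  0.64  0.58
     44  0.63  0.64
     47  0.63  0.64
terminal positions for comparison:
      1  0.00  0.00
    100  0.00  0.00
wrote demo/out/residue_scores.tsv and demo/out/tag_sites.json
```

All three top-ranked sites fall inside the engineered 40–50 window: every
feature there scores high, so the minimum (raw E ≈ 0.6, limited by column
entropy) survives the windowed average, while the helical background scores
E_i = 0 — the secondary-structure feature vetoes it, including both termini.
`residue_scores.tsv` holds the full-precision per-residue table (position,
aa, the four features, e_min, s_weighted, e_windowed); `tag_sites.json` the
ranked candidates; `--plot` adds a two-panel track figure.

Any `score` option can also live in a flat `key = value` config file
(`tagsite score --config run.cfg`, `#` starts a comment); command-line flags
override file values.

For a real protein, supply your own inputs: the query FASTA, an aligned
FASTA of the query with its orthologs (or a BLAST tabular file plus homolog
FASTA — one best hit per species is selected by lowest E-value and aligned
with mafft), a DSSP output file for the predicted structure (classic or
mmCIF dialect) and an IUPred2A/ANCHOR-style disorder file.

The benchmark subcommand simulates a labelled variant set and evaluates the
logistic model:

```sh
tagsite benchmark --seed 1 --repeats 20 --out metrics.json
```

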