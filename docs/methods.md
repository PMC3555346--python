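# Methods

## Model and assumptions

The package predicts non-exchangeable ¹H shifts (H2, H8, H5, H6, H1′, H2′,
H3′) for RNA residues in A-form helical context. The unit of prediction is
the central residue of a *WC-BP triplet*: residues i−1, i, i+1 must all be
base-paired (Watson–Crick or G:U wobble) with their partners stacked
consecutively on the complementary strand (partner(i−1) = partner(i)+1 and
partner(i+1) = partner(i)−1). Residues without such a context — loops,
bulges, stem termini at the closing pair, pseudo-helical arrangements with
non-consecutive partners — get no prediction and are reported as such,
never silently dropped.

The shift is modeled as a constant (the canonical uNu context: flanking
WC-paired uridines, WC-paired i−2 and i+2 neighbors) plus additive
increments for 15 binary neighborhood attributes. Two modeling rules matter
and are fixed by the worked arithmetic of the reference parameterization:

* **Wobble substitutes for identity.** When the i−1 neighbor is a G paired
  with U, `pre_gu` is set *instead of* `pre_g`; a U in a wobble sets
  `pre_ug` (replacing the WC-U baseline). Symmetrically on the 3′ side.
  At most one `pre_*` and one `suc_*` flag can therefore be active.
* **Loop vs terminal context is exclusive per side.** `5ter` means residue
  i−2 does not exist; `5loop` means it exists but is unpaired, in a
  mismatched (non-WC, non-wobble) pair, or engaged in a long-range
  contact. A WC/wobble-paired i−2 sets neither.

Mismatched bracket pairs in dot-bracket input (e.g. A:C) are demoted to
unpaired-with-`in_loop`, which routes them into the loop attributes; the
annotation TSV can additionally mark paired residues as `in_loop` or
`long_range` for contexts dot-bracket cannot express.

The additive form deliberately ignores sample conditions (pH, temperature,
ionic strength), ring-current effects computable from 3D coordinates, and
any non-linear attribute interactions. It is a nearest-neighbor increment
model in the tradition of group-contribution shift prediction, chosen for
robustness at the corpus sizes available for RNA.

## Packaged coefficients

`load_packaged_table()` returns the reference parameterization: 19 rows
(A: H2,H8,H1′,H2′,H3′; G: H8,H1′,H2′,H3′; C/U: H5,H6,H1′,H2′,H3′), each
with the constant, the 15 increments (ppm, four decimals), and fit
statistics (corr, rms, nobs, xcorr, xrms, ntrim). Increments excluded by
variable selection are stored as explicit zeros so fitted and packaged
tables share one schema; structurally impossible increments (a central
wobble for A or C) are zero by construction. Internal consistency checks:
the per-row retained counts sum to 3758 and the trimmed counts to 38.
Aromatic constants fall in 5.5–8.2 ppm, ribose constants in 4.3–4.7 ppm,
so synthetic data generated from the table occupies realistic spectral
windows.

## Training pipeline

Fitting operates independently per (nucleotide, atom) group on the binary
15-column design plus intercept.

* **Estimation and selection.** Default `method="bic"`: ordinary least
  squares followed by greedy backward elimination — repeatedly drop the
  regressor whose removal most improves the Bayesian information
  criterion, stop when no single removal improves it. Eliminated and
  design-unsupported (never-observed) attributes get coefficients of
  exactly 0. `method="ols"` disables selection; `method="lasso"` takes the
  support of an information-criterion lasso path and refits OLS on it.
  BIC backward elimination was chosen as the default because it matches
  the intent of information-criterion subset selection while remaining
  fully deterministic and dependency-light; the acceptance properties are
  insensitive to which of the three is used.
* **Outlier trimming.** Exactly two passes: fit on all data, compute the
  residual rms, drop observations with |residual| strictly greater than
  3×rms (ties at the threshold are retained), refit on the remainder. The
  multiplier is configurable but defaults to 3. `nobs` reports the
  retained count and `ntrim` the number dropped.
* **Re-referencing.** Depositions from different labs carry constant
  referencing offsets. The default (self-referenced) scheme runs the
  complete per-group analysis once, computes each deposition's offset as
  the mean prediction error of its *retained* shifts pooled over all atom
  types, subtracts it from every shift of that deposition, and reruns the
  complete analysis. A deposition with no eligible retained shifts gets
  offset 0 with a warning.

  An identifiability caveat is worth stating precisely: because per-group
  least squares leaves zero-mean residuals, the count-weighted mean of
  self-referenced offsets is pinned near zero — a constant can always be
  traded between all offsets and the 19 regression constants. Self
  offsets therefore measure *relative* referencing errors between
  depositions, and translating one deposition's shifts moves every
  offset (and, through selection flips, the coefficients) slightly rather
  than just the one offset. When an external anchor exists, pass
  `reference=<table>`: offsets become plain mean deviations from that
  fixed table's predictions, the gauge is externally anchored, and adding
  a constant to one deposition changes exactly that offset by exactly
  that constant, leaving everything downstream bit-identical. Single
  depositions are always re-referenced this way (see Validation).
* **Cross-validation.** Stratified k-fold (default 10) with one stratum
  per atom group; fold assignment is a seeded permutation, so results are
  reproducible. Held-out predictions are pooled across folds before
  computing xcorr/xrms per group. Groups smaller than the fold count fall
  back to leave-one-out. Note that with 90 % training folds a rare
  attribute can lose design support in a fold; its held-out error then
  reflects the missing increment. This is honest out-of-sample behavior,
  and the reason two-fold cross-validation reports systematically larger
  xrms than ten-fold.
* **Group means.** `compute_group_means` reports 〈δ〉 per triplet sequence
  and atom, and 〈δ〉 restricted to canonical contexts (identity attributes
  only — no wobble, terminal or loop flags). Empty groups are absent, not
  zero.

## Validation of single depositions

`validate_deposition` re-references one deposition against a coefficient
table using a **10 %-trimmed mean** of the deviations (the plain mean is
available via `trim_fraction=0`): a deposition under scrutiny may contain
the very outliers being hunted, and trimming keeps them from corrupting
the offset. Each shift then gets z = (δ_obs − offset − δ_pred)/rms with the
per-group rms from the table, and is flagged when |z| strictly exceeds the
threshold (default 3). Flag sets are monotone in the threshold and
invariant to uniform referencing shifts of the input (up to trimming
granularity). Rows are ordered by |z| descending; shifts on ineligible
residues appear at the end with no prediction.

## Synthetic data

The generator emulates a curated corpus of helical-RNA depositions. Each
deposition is a multi-hairpin secondary structure — by default 4 stems of
7–11 pairs with 3–6 nt hairpin loops and 1–3 nt linkers, starting and
ending in a stem so terminal triplet contexts occur; each pair is a G:U
wobble with probability 0.10, otherwise a uniformly random WC pair.
Attributes are always derived from the generated structure by the real
annotation module, never sampled directly, so generator and annotator
cannot drift apart. Observed shifts are generating-table predictions plus
i.i.d. Gaussian noise (σ = 0.05 ppm), a per-deposition offset drawn from
N(0, 0.03 ppm), and, with probability 0.01 per shift, a gross outlier
displaced by ±10σ. The default 20-deposition corpus yields roughly 300
observations per atom group and covers each of the 15 attributes at least
10 times. All randomness flows from one seed; a truth sidecar records
offsets and outlier positions for recovery tests.

What the generator does **not** emulate: condition-dependent shift
variation (pH, temperature, salt), correlated assignment errors,
heteroscedastic noise across atom types, tetraloop/base-triple chemistry
beyond the attribute vocabulary, and non-contiguous or author-specific
residue numbering. Passing recovery tests therefore demonstrates
correctness of the pipeline under the model's own assumptions, not
predictive accuracy on new experimental depositions.

## Numerical choices

* 1-based residue numbering, 5′→3′; "preceding" means i−1 on the central
  residue's own strand. External numbering is mapped with an explicit
  offset (`ShiftTable.renumbered`).
* Trimming uses strict inequality; BIC uses a 1e-30 variance floor so
  noiseless groups remain finite; degenerate groups (identical responses)
  return the mean with zero increments.
* Coefficient CSVs store constants/increments via `repr` (exact float
  round-trip) and statistics at four decimals; report CSVs use fixed
  four-decimal formatting and sorted keys so identical inputs give
  byte-identical files.
* Worked-example comparisons are made in integer units of the printed
  precision (1e-4 ppm) to keep binary floating-point representation out
  of decimal comparisons.
* The NMR-STAR reader is a minimal, read-only tokenizer covering 2.1 and
  3.1 atom-chemical-shift loops; it normalizes prime/star/unicode atom
  spellings, skips non-model atoms with a logged count, rejects files
  without a shift loop, and keeps ambiguous assignments (code > 1) out of
  training by default.

## Known limitations

Exchangeable (imino/amino) protons, ¹³C/¹⁵N nuclei, tetraloop and
base-triple parameterizations, secondary-structure *prediction*, and
coordinate-based ring-current calculations are out of scope. The packaged
rms values are corpus-level statistics; for unusual chemistries or
conditions the 3σ screen should be read as a triage tool, not a verdict —
flagged shifts may equally indicate genuine tertiary contacts, which is
precisely what makes them interesting.
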