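# rnaproton

Prediction and validation of non-exchangeable **¹H NMR chemical shifts in
RNA** from secondary structure alone.

NMR assignment of RNA is hard: chemical-shift dispersion is poor and most
helical protons crowd into narrow spectral windows. For residues inside
A-form helices, however, the ¹H shifts are determined almost entirely by the
local base-pair neighborhood. `rnaproton` exploits this: every residue that
sits at the center of three consecutive stacked base pairs (a **WC-BP
triplet**) gets a predicted shift for its H2/H8/H5/H6 aromatic and
H1′/H2′/H3′ ribose protons, and observed assignments can be screened against
those predictions to catch misassignments, referencing errors, and contact
sites.

## The model

For a central nucleotide N flanked by neighbors n(i−1) and n(i+1), the
predicted shift of each proton is an additive increment sum

```
δ_pred = δ_const + Σ_k  c_k · x_k ,      x_k ∈ {0, 1}
```

where δ_const is the shift of that proton in a canonical **uNu** triplet
(both flanking residues WC-paired uridines, WC-paired i−2 and i+2
neighbors) and the 15 binary attributes x_k encode the neighborhood:

| attributes | meaning |
|---|---|
| `pre_a`, `pre_c`, `pre_g` | identity of the i−1 residue when it is not a WC-paired U |
| `pre_gu`, `pre_ug` | the i−1 residue is the G (resp. U) of a G:U wobble — *substitutes* for the identity attribute |
| `suc_a`, `suc_c`, `suc_g`, `suc_gu`, `suc_ug` | same for the i+1 residue |
| `5ter`, `3ter` | the triplet terminates the molecule (no i−2 / i+2 residue) |
| `5loop`, `3loop` | the i−2 / i+2 residue is in a loop, bulge, or mismatched pair |
| `GU` | the central pair itself is a G:U wobble |

There are 19 (nucleotide, proton) combinations, each with its own
coefficient row (A has H2 but no H5; G has neither H2 nor H5; C/U have H5/H6
but no H2/H8). A packaged reference coefficient table covering all 19 rows,
with per-row rms values, ships with the package; you can also fit your own
table from a corpus of annotated depositions (per-atom-group least squares
with BIC variable selection, two-pass 3×rms outlier trimming, automatic
per-deposition re-referencing, and stratified 10-fold cross-validation).

## Worked example

```python
>>> from rnaproton import AtomKey, TripletAttributes, load_packaged_table, predict_shift
>>> table = load_packaged_table()
>>> key = AtomKey("A", "H2")
>>> predict_shift(key, TripletAttributes("A"), table)                # canonical uAu
7.0299
>>> round(predict_shift(key, TripletAttributes("A", frozenset({"pre_g", "suc_c", "loop5"})), table), 4)
7.8478
>>> round(predict_shift(key, TripletAttributes("A", frozenset({"pre_gu", "suc_c", "loop5"})), table), 4)
7.9216
```

The first value is the canonical-context constant for adenosine H2. The
second adds the increments for a 5′ G neighbor (+0.6899), a 3′ C neighbor
(+0.0658), and an i−2 residue in a loop (+0.0622). In the third, the 5′ G
sits in a G:U wobble, so the wobble increment (+0.7637) replaces the G
identity increment — wobble context shifts A-H2 further downfield.

From the shell, the same predictions for a whole molecule:

```
rnaproton predict --structure hairpin.db --sequence hairpin.seq
```

and screening of an assigned deposition (dot-bracket or annotation-TSV
secondary structure, shifts as NMR-STAR or TSV):

```
rnaproton validate entry.str --annotations entry.annot.tsv --z-threshold 3
```

which re-references the deposition (10 %-trimmed mean deviation) and flags
every assignment deviating by more than 3 per-group rms units. `rnaproton
simulate` writes a synthetic training corpus with known truth, and
`rnaproton fit` runs the full training pipeline on a corpus manifest.

## Annotation TSV dialect

Secondary structure that dot-bracket cannot express (stacked-but-unpaired
residues, long-range contacts) uses a 6-column tab-separated file:

```
index  base  partner  pair_class  in_loop  long_range
1      G     .        unpaired    1        0
2      U     13       wobble      0        0
...
```

`partner` is `.` for unpaired residues; `pair_class` is `WC`, `wobble`, or
`unpaired`; `in_loop`/`long_range` are 0/1 flags. Numbering is 1-based and
contiguous.

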