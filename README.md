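# metox

Sequence and structure determinants of methionine oxidation.

Methionine sulphurs oxidize to methionine sulfoxide (MetO) under peroxide
stress, but not uniformly: some sites are reliably hit, others resist.
Solvent accessibility alone does not explain the difference. `metox`
implements the analysis chain that identifies the **S-aromatic motif** — a
methionine whose SD sulphur lies within 7 Å of the geometric centre of an
aromatic ring (Phe/Tyr/Trp) — as a structural determinant that damps the
sulphur's reactivity toward oxidants. It is aimed at structural
bioinformaticians and protein engineers who want to score methionine
oxidation liability from sequence and structure, and at anyone who needs
the underlying statistical machinery with exact, testable conventions.

The package provides, as a plain Python library:

- **composition** — methionine-content statistics with a bootstrap
  empirical null (10⁴ resamples) and an add-one empirical p-value.
- **seqenv** — the differential sequence-environment statistic: for
  residue *i* at offset *j* ∈ {−10..−1, +1..+10} around paired
  oxidation-prone / oxidation-resistant methionines,
  `Z_ij = (f_ij^ox − f_ij^res) / sqrt[(f^ox(1−f^ox) + f^res(1−f^res))/n]`,
  with interval diagnostics against the standard-normal null.
- **features** — 40 nearest-residue distance predictors (NT_X/CT_X) and
  the random-forest protocol (1000 trees, mtry 6, stratified 75/25 split,
  10-fold × 5 CV, recursive feature elimination with an AUC-vs-size curve).
- **structure** — aromatic ring centroids, SD-to-centroid distances, the
  7 Å motif call, distance histograms, homo-oligomer chain deduplication
  and primary-structure separation summaries.
- **accessibility** — an internal Shrake–Rupley SASA implementation
  (probe 1.4 Å, 960 lattice points) with Gly-X-Gly relative
  accessibilities and exposed/buried stratification at 5% and 20%.
- **stats** — Fisher's exact test (hypergeometric enumeration in
  log-space, exact rational path, both sidedness conventions) and exact
  binomial tails, implemented from first principles.
- **reactivity** — the rule classifier "motif ⇔ low reactivity", its
  confusion-matrix benchmark on the packaged therapeutic-protein fixture,
  and oxidation-by-motif contingency tables.
- **synthetic** — generators for proteomes, planted flanking biases, toy
  structures with exact motif ground truth, and logistic oxidation labels,
  so every stage is testable without downloads.
- **io_data** — FASTA / site-table / PDB / mmCIF I/O and alignment-based
  sequence↔structure residue mapping.

## Worked example

```sh
python examples/reactivity_benchmark.py
```

prints

```
benchmark: 35 methionines from 8 proteins (20 low / 15 high reactivity)
confusion: TP=17 TN=13 FP=2 FN=3
accuracy    85.7%   (30 of 35 correct)
sensitivity 85.0%   (low-reactivity methionines recovered)
specificity 86.7%   (high-reactivity methionines recovered)
Fisher exact p (one-sided) = 3.02e-05  [enrichment]

prokaryotic check (glutamine synthetase (E. coli)): 13/15 correct, binomial tail P[X >= 13] = 0.00369
```

Reading: across eight therapeutic proteins whose methionine oxidation
kinetics were measured in vitro, the bare geometric rule "forms an
S-aromatic motif ⇒ low reactivity" classifies 30 of 35 methionines
correctly, with the positive class (low reactivity) recovered at 85% and
the negative class at 86.7%. The enrichment of motif-formers in the
low-reactivity group would occur by chance about 3 times in 100 000; the
independent prokaryotic spot-check (13/15 correct on E. coli glutamine
synthetase) has a fair-coin tail probability of 0.0037.

`examples/motif_geometry.py` shows the geometric leg on a structure with
planted ground truth (60/60 methionines recovered, bimodal nearest-ring
distance histogram), and `examples/sequence_environment.py` the planted
glutamate bias surfacing as z ≈ 13 at the planted offsets while the rest
of the 400-cell matrix stays near the null.

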