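"""Detect S-aromatic motifs in a structure with known planted geometry.

Builds a toy structure in which a chosen fraction of methionines has a
phenylalanine ring centroid placed 4.5-6.5 A from the SD sulphur (the rest
at >= 9.5 A), then runs the geometric motif caller and summarises the
nearest-ring distance distribution.
"""

from metox import (
    distance_histogram,
    gen_toy_structure,
    linear_separations,
    s_aromatic_calls,
    separation_summary,
)

toy = gen_toy_structure(n_mets=60, motif_fraction=0.5, seed=4)
calls = s_aromatic_calls(toy.model, cutoff=7.0)

n_motif = sum(c.forms_motif for c in calls)
correct = sum(c.forms_motif == toy.motif_flags[c.resnum] for c in calls)
print(f"{len(calls)} methionines, {n_motif} called motif-forming "
      f"({correct}/{len(calls)} match the planted truth)")

hist = distance_histogram(calls, bin_width=0.5)
occupied = [(e, c) for e, c in zip(hist.edges, hist.counts) if c > 0]
print("nearest-ring distance histogram (bin left edge: count):")
print("  " + ", ".join(f"{e:.1f}: {c}" for e, c in occupied))
print(f"first local minimum near {hist.first_minimum} A, separating the "
      "contact population from the distal one (in real structures this "
      "valley sits at ~7 A and fixes the motif threshold)")

pairs = linear_separations(calls)
print("\nprimary-structure separations of motif pairs:")
print(separation_summary(pairs).to_string())

# Interacting partners are often far apart in sequence: spatial S-aromatic
# contacts are a tertiary-structure feature, not a flanking-sequence one.
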