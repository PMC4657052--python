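"""Does the motif-oxidation association survive exposure stratification?

Burial is a classic confounder: motif-forming methionines tend to be less
exposed, and buried residues oxidize less. This example simulates exactly
that scenario — motif methionines drawn more buried, oxidation odds rising
with exposure, conditional motif odds ratio 0.3 — and shows that the
association persists when the test is restricted to exposed methionines.
Shrake-Rupley accessibilities are computed on a toy structure first to show
the structural pipeline; the stratified simulation then uses accessibilities
with the confounded distribution.
"""

import numpy as np

from metox import (
    SyntheticConfig,
    fisher_exact,
    gen_oxidation_labels,
    gen_toy_structure,
    oxidation_contingency,
    residue_sasa,
    s_aromatic_calls,
    sites_from_labels,
    stratify_by_exposure,
)
from metox.accessibility import SasaRecord
from metox.structure import MotifCall

# --- structural leg: per-residue SASA on a toy structure -------------------
toy = gen_toy_structure(n_mets=8, seed=12)
for rec in residue_sasa(toy.model)[:3]:
    print(f"{rec.resname} {rec.chain}/{rec.resnum}: SASA {rec.sasa:6.1f} A^2, "
          f"relative accessibility {rec.rel_accessibility:.2f}")
print("(isolated toy residues are fully exposed; the confounded simulation "
      "below draws realistic burial)\n")

# --- simulated study with burial confounding -------------------------------
rng = np.random.default_rng(12)
n = 1118
motif = rng.random(n) < 600 / 1118
acc = np.where(motif, rng.uniform(0.0, 0.6, n), rng.uniform(0.0, 1.0, n))
cfg = SyntheticConfig(beta_acc=1.5)  # exposure raises oxidation odds
labels = gen_oxidation_labels(motif, acc, cfg, seed=12)

calls = [
    MotifCall(chain="A", resnum=i + 1, sd=(0.0, 0.0, 0.0), contacts=(), forms_motif=bool(m))
    for i, m in enumerate(motif)
]
sasa = [SasaRecord("A", i + 1, "MET", 224.0 * a, a) for i, a in enumerate(acc)]
oxidized = {("A", i + 1): bool(ox) for i, ox in enumerate(labels)}

for threshold, label in ((0.0, "all methionines "), (0.05, "exposed > 5%  "), (0.20, "exposed > 20% ")):
    t = stratify_by_exposure(calls, sasa, oxidized, threshold=threshold)
    res = fisher_exact(t)
    print(f"{label}: n {t.total:4d}, table ({t.a:3d}, {t.b:3d} / {t.c:3d}, {t.d:3d}), "
          f"OR {t.odds_ratio:.2f}, two-sided p {res.p_two_sided:.2e}")

# The odds ratio stays well below 1 within the exposed strata, so reduced
# solvent access alone cannot explain why motif methionines resist oxidation.
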