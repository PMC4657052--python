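"""Write a complete synthetic study to disk: FASTA, site table, structure.

Every downstream command (`metox seqenv`, `metox motifs`, `metox sasa`, ...)
can be exercised on these files; the ground truth (planted bias, motif
flags) is known by construction.
"""

import sys
from pathlib import Path

import pandas as pd

from metox import SyntheticConfig, gen_proteome, gen_toy_structure, plant_env_bias, write_pdb
from metox.io_data import write_fasta, write_sites

out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("synthetic_study")
out.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(n_proteins=200, seed=33)
proteome, sites = plant_env_bias(gen_proteome(cfg), cfg)
write_fasta(proteome, out / "proteome.fasta")
write_sites(sites, out / "sites.tsv")
print(f"{len(proteome)} proteins -> {out/'proteome.fasta'}")
print(f"{len(sites)} labelled methionines "
      f"({sum(s.oxidized for s in sites)} oxidized) -> {out/'sites.tsv'}")

toy = gen_toy_structure(n_mets=80, seed=33)
write_pdb(toy.model, out / "toy_structure.pdb")
pd.DataFrame(
    [{"resnum": r, "motif": int(toy.motif_flags[r])} for r in toy.met_resnums]
).to_csv(out / "toy_truth.tsv", sep="\t", index=False)
print(f"toy structure ({len(toy.met_resnums)} methionines, "
      f"{sum(toy.motif_flags.values())} motif-forming) -> {out/'toy_structure.pdb'}")
print(f"planted motif truth -> {out/'toy_truth.tsv'}")
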