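"""Score map-vs-map agreement over the solvent shell.

Builds the solvent-shell mask (1.8-3.5 A from well-resolved RNA atoms),
then scores a comparison map against the reference two ways: similarity
(cross-correlation, mutual information) and voxel classification
(precision/recall against the reference's 3-sigma positives). A shuffled
map provides the chance floor.
"""

import numpy as np

from rnaswim import (FixtureSpec, atom_q_scores, classification_curves,
                     compare_densities, make_fixture, render_synthetic_maps,
                     residue_q_table, shuffle_within_mask,
                     solvent_shell_mask)
from rnaswim.map_io import map_stats

fx = make_fixture(FixtureSpec(seed=0))
comparison, _, _ = render_synthetic_maps(fx["solvated"], 2.2, noise_sd=0.02,
                                         seed=99)

residue_q = residue_q_table(fx["model"],
                            atom_q_scores(fx["full"], fx["model"]))
shell = solvent_shell_mask(fx["full"], fx["model"], residue_q)
print(f"solvent shell: {shell.n_voxels} voxels, "
      f"1.8-3.5 A from residues with Q > 0.6")

for name, comp in (("independent map", comparison),
                   ("shuffled map",
                    shuffle_within_mask(fx["full"], shell.mask, seed=7))):
    sim = compare_densities(fx["full"], comp, shell)
    curves = classification_curves(fx["full"], comp, shell)
    print(f"\n{name}:")
    print(f"  CCC {sim.ccc:.3f}   MI {sim.mi:.3f} bits")
    print(f"  AUPRC {curves.auprc:.3f}   AUROC {curves.auroc:.3f}   "
          f"max MCC {curves.max_mcc:.3f}")

prevalence = float((fx["full"].values[shell.mask]
                    > map_stats(fx["full"]).threshold(3.0)).mean())
print(f"\npositive prevalence in the shell: {prevalence:.3f}")
print("An informative comparison map scores AUPRC near 1; shuffling the"
      "\nshell destroys all spatial signal, dropping AUPRC to prevalence"
      "\nand AUROC to 0.5.")
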