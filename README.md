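# rnaswim

Segmentation-guided water and ion modelling (SWIM) and solvent-shell
analysis for high-resolution (~2 Å) cryo-EM density maps of RNA.

At ~2 Å resolution, cryo-EM maps of RNA resolve not only the nucleotides
but the first hydration layer: ordered waters and inner-sphere Mg²⁺ ions
appear as discrete density peaks 1.8–3.5 Å from the RNA surface. Deciding
which peaks are solvent — and which are noise, ions, or the RNA's own
atoms — requires combining map statistics, per-point resolvability, and
coordination chemistry. This package is for structural biologists
modelling solvent into RNA maps and for methods developers studying how
much solvent structure a density map actually contains.

## The method

**Q score.** The resolvability of a point *P* in a map is the normalized
cross-correlation (about the mean) between map values sampled on
concentric spherical shells around *P* (radii 0–2.0 Å, step 0.1 Å) and a
reference Gaussian `g(r) = exp(−r²/2σ²)` with σ = 0.6 Å, excluding sample
points nearer to another atom than to *P*. Q = 1 means a perfectly
resolved atom; Q ≈ 0 means noise. Per-residue Q is the unweighted mean
over heavy atoms, and solvent B-factors are assigned as `B = 150(1 − Q)`.

**SWIM.** With avgD and σ the mean and standard deviation of all voxels
of the full map, the map is watershed-segmented (26-connectivity, no
grouping) at avgD + 3σ. Segments are visited in decreasing-volume order;
each segment's interpolated density maximum *P*max is tested by an
ordered rule cascade:

1. Q(*P*max) ≥ 0.7 in the full map **and both half-maps**;
2. the nearest nucleotide's residue Q ≥ 0.6;
3. density at *P*max ≥ avgD + 5σ;
4. no clash — a non-polar atom (C, P) within 3.2 Å vetoes water, a
   carbon within 3.0 Å vetoes an ion, and a peak < 1.8 Å from any
   modelled atom is that atom's own density;
5. **Mg²⁺** if an O or non-protonated N lies 1.8–2.5 Å away and no
   protonated (donor) N lies 1.8–3.4 Å away;
6. otherwise **water** if any N/O lies 2.5–3.4 Å away or a placed Mg²⁺
   lies 1.8–2.5 Å away;
7. discard waters within 2.5 Å of an accepted water (minWaterD) and ions
   within 4.5 Å of an accepted ion (minIonD).

Passes repeat until nothing new is accepted (placed Mg²⁺ become water
binders in later passes).

**Consensus.** A placement is cross-validated between two independent
map/model pairs when it superimposes within 1 Å after least-squares
alignment of the local RNA (all nucleotides with an atom within 10 Å)
*and* binds the same RNA atoms (close binders 2.5–3.2 Å for water,
1.8–2.2 Å for Mg²⁺; matched within expanded windows 2.5–3.5 / 1.8–2.5 Å).

**Shell metrics.** Map-vs-map agreement over the solvent shell
(1.8–3.5 Å from residues with Q > 0.6) is scored by cross-correlation and
mutual information (20 density bins) after Z-score normalization, and as
a voxel-classification task: reference voxels above 3σ are positives, the
comparison threshold is swept, and precision–recall/ROC curves, AUPRC,
AUROC and the maximal Matthews correlation coefficient are reported.

**Solvent dynamics.** For coordinate ensembles, the package computes
frame-averaged solvent densities (waters/ų ↔ mol/L via
`n = c·N_A/10²⁷`; bulk water 55 M ≈ 0.033/ų), binding sites (1 Å peak
deduplication), occupancy (frames with a water within 2 Å of the peak
and the same binders, over frames where the RNA stays within 3.4 Å of
the reference), positional spread (RMSF), and Mg²⁺ residence times
tolerating single-frame gaps.

A `synthetic` module generates fully self-contained fixtures — an
idealized A-form duplex, planted rule-valid solvent, rendered full/half
maps with independent noise, and ensembles with planted occupancy and
spread — so every capability is testable without deposited data.

## Worked example

```sh
python examples/model_solvent_into_map.py
```

prints (abridged):

```
SWIM modelled 12 waters and 2 Mg2+ ions (planted: 12 waters, 2 Mg2+)

kind        peak(sigma)  min Q   dist to planted (A)
magnesium         20.3  0.976               0.036
water             13.5  0.978               0.016
water             18.6  0.979               0.039
...
```

Each accepted placement reports its peak density in σ units (all ≥ 5 by
rule 3), the weakest of its three Q scores (all ≥ 0.7 by rule 1), and
its distance to the nearest planted site — sub-0.1 Å recovery at this
signal-to-noise, with no false positives. The other examples demonstrate
consensus cross-validation (`cross_validate_consensus.py`), shell
similarity/classification scoring (`score_shell_agreement.py`),
ensemble occupancy/RMSF analysis (`analyze_solvent_dynamics.py`), and
the stringency of the acceptance criteria
(`assess_criteria_stringency.py`).

The same workflow is available as a CLI for deposited data:

```sh
swim synth --outdir fixtures/                 # or fetch real maps
swim run --map full.mrc --half1 h1.mrc --half2 h2.mrc \
         --model model.cif --out solvated.cif --log swim.tsv
swim consensus --a solvated_a.cif --b solvated_b.cif --out pairs.tsv
swim compare --ref a.mrc --comp b.mrc --model a.cif --out metrics.json
```

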