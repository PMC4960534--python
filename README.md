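# ltpdigest

Analysis toolkit for the digestibility of plant non-specific lipid
transfer proteins (nsLTPs) — small ~9 kDa allergens with a hydrophobic
cavity that binds fatty acids and phospholipids. The package links three
measurements that together ask *whether lipid binding changes how an LTP
is broken down by gastroduodenal proteases*:

1. **Competitive fluorescence binding.** A fluorescent fatty-acid tracer
   (cis-parinaric acid) reports occupancy of the LTP cavity. Direct
   titration gives the tracer dissociation constant from the rectangular
   hyperbola F = F₀ + F_max·[L]/(K_d + [L]) (a Hill exponent is
   optional). Displacement of the tracer by a non-fluorescent competitor
   is fitted with a four-parameter logistic — or, for proteins that
   transiently co-bind tracer and competitor, a rise-then-fall "bell"
   model whose descending limb carries the IC₅₀. The inhibition constant
   follows from Cheng–Prusoff, K_i = IC₅₀ / (1 + [tracer]/K_d), and the
   binding free energy from ΔG = −RT ln K_i (K_i molar, T = 298.15 K,
   R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹).

2. **Limited-proteolysis mass mapping.** A folded LTP is cut at only a
   few exposed sites, so observed peptides are intervals bounded by *any*
   two cut points, not just adjacent ones. The package predicts cleavage
   boundaries from protease specificity rules (trypsin after K/R,
   chymotrypsin after F/Y/W/L, neither before Pro, plus documented
   nonstandard sites), enumerates all C(b+2, 2) candidate fragments,
   computes average and monoisotopic masses from an embedded residue-mass
   table, and assigns observed MALDI peak lists within a ppm tolerance.
   Assigned intensities become per-residue coverage maps, ranked
   cleavage-site calls, and between-condition fold changes.

3. **Structural flexibility metrics.** Kabsch least-squares superposition
   and Cα RMSD between liganded/unliganded structures; Shrake–Rupley
   solvent-accessible surface area (probe 1.4 Å, 960 sphere points,
   Bondi radii) — in particular of the conserved Tyr79 whose displacement
   out of the cavity exposes the Tyr79–Thr80 chymotryptic site; and
   per-residue RMSF over coordinate ensembles after removing rigid-body
   motion by superposition onto the first frame.

A seeded synthetic-data module (`ltpdigest.simulate`) generates
titrations, displacement curves, peak lists and coordinate ensembles with
known ground truth, so every stage is testable without downloads, and
`ltpdigest.datasets` bundles the published wheat LTP1 reference data
(mature 90-residue chain, digest peak profile, comparative binding table).

## Worked example

```python
from ltpdigest import DisplacementModel
from ltpdigest.simulate import gen_displacement

fix = gen_displacement(ki=3.6, tracer_kd=4.5, tracer_conc=2.0, cv=0.05, seed=7)
print(DisplacementModel(fix.series).fit(model="logistic4").summary())
```

```
Binding fit: logistic4 [synthetic]
  converged: True   n = 15   residual SS = 1332
           top = 549.5 +/- 8.46
        bottom = 40.65 +/- 11
          ic50 = 5.368 +/- 0.421
         slope = 0.9189 +/- 0.0627
  IC50 = 5.37 uM   Ki = 3.72 uM   dG = 7.41 kcal/mol
```

The simulated competitor has a true K_i of 3.6 µM; with 2 µM tracer of
K_d 4.5 µM the implied IC₅₀ is 3.6·(1 + 2/4.5) = 5.2 µM. At 5% noise the
fit recovers IC₅₀ = 5.37 µM and converts it back through Cheng–Prusoff to
K_i = 3.72 µM (3% off truth), at ΔG ≈ 7.4 kcal/mol.

Mapping the bundled wheat digest peak list onto the in-silico fragment
space:

```python
from ltpdigest import (assign_peaks, call_cleavage_sites, cleavage_sites,
                       enumerate_fragments, protease)
from ltpdigest.datasets import wheat_digest_peaklist, wheat_ltp1

protein = wheat_ltp1()
rules = [protease("trypsin"), protease("chymotrypsin", extra_sites=(7,))]
boundaries = [k for k, _ in cleavage_sites(protein, rules)]
fragments = enumerate_fragments(protein, boundaries, mode="limited")
assignments = assign_peaks(wheat_digest_peaklist("alone"), fragments, tolerance=250)
print(call_cleavage_sites(assignments, protein_length=90).head(4).to_string(index=False))
```

```
 boundary  n_fragments  summed_intensity                    fragments
       39            5            4019.0 1-39|17-39|40-56|40-67|40-79
       56            5            1922.0 1-56|17-56|40-56|57-67|57-89
       79            4            2282.0       1-79|40-79|68-79|80-90
       67            4            1246.0       1-67|40-67|57-67|68-79
```

16 of the 24 observed peaks are assigned at 250 ppm, and the three
top-ranked internal boundaries — 39/40 (tryptic Arg39), 56/57 and 79/80
(chymotryptic Tyr79) — are the protein's major limited-proteolysis sites.

The same analyses run from the shell via the `ltpdigest` console script
(`digest`, `binding`, `structure`, `simulate` subcommands), each writing
delimited tables plus a JSON run manifest.

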