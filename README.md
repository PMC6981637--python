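# cholinib

Analytics for a cholinesterase-inhibitor discovery campaign built around
tetrahydroquinoline (THQ) hybrids bearing isoxazoline (series 5, two
stereocenters) or isoxazole (series 6, one stereocenter) moieties. The
package re-implements, as a tested and reusable pipeline, the desk-side
computations of such a study:

* **Compound registry and mass calculus** — a transcribed 44-compound
  registry (5a–5p, 6a–6ab) with molecular-formula arithmetic: average and
  monoisotopic masses, elemental-analysis percentages, ESI adduct m/z
  ([M+H]⁺, [M+Na]⁺, [M+K]⁺, [2M+Na]⁺, neutral losses), and the stereoisomer
  enumeration used to set up docking (2^n per compound, 120 in total).
* **Activity analytics** — selectivity index SI = IC₅₀(BChE)/IC₅₀(AChE);
  conversion of IC₅₀ to an experimental binding free energy
  ΔG<sub>expt</sub> = RT·ln IC₅₀ (Ki ≈ IC₅₀ approximation, T = 298.15 K);
  a rule-of-five screen over supplied descriptors.
* **Enzyme-inhibition kinetics** — the general modifier rate law
  v = V<sub>max</sub>·S / (K<sub>m</sub>(1 + I/K<sub>i</sub>) + S(1 + I/K<sub>i</sub>′)),
  nesting competitive, uncompetitive, noncompetitive and mixed inhibition;
  nonlinear fitting with multi-start initialization; Lineweaver–Burk
  diagnostics; AICc-based mechanism discrimination; 4-parameter-logistic
  IC₅₀ dose–response fits.
* **Ensemble-docking consensus** — no-fit core RMSD over a shared scaffold
  atom map; deterministic leader clustering (2.0 Å threshold) partitioned
  by chirality; top-5 population filtering with a ≥10 poses-per-ligand rule;
  per-ligand representative selection; cluster ranking by the R² of
  ΔG<sub>pred</sub> vs ΔG<sub>expt</sub>.
* **Interaction fingerprints** — geometric detection of π-stacking
  (sandwich / parallel-displaced / T-shaped), conventional and weak C–H
  hydrogen bonds, and cation–π contacts, summarized per residue as ligand
  counts with mean ± SD distances.
* **Synthetic data** — seeded generators that stand in for the commercial
  docking/rescoring engines: pose ensembles with planted binding modes whose
  true-mode energies correlate linearly with ΔG<sub>expt</sub>, kinetics
  tables with multiplicative noise over the assay design (eight substrate
  levels from 3.75×10⁻³ to 0.48 mM; inhibitor levels 0/2.12/4.24 µM),
  dose–response curves, and interaction scenes built to specified contact
  geometries — each with a ground-truth sidecar.

## Worked example

```python
>>> from cholinib import parse_formula, elemental_percentages, adduct_mz
>>> f = parse_formula("C23H25N3O2")          # parent THQ-isoxazoline
>>> {el: round(p, 2) for el, p in elemental_percentages(f).items()}
{'C': 73.57, 'H': 6.71, 'N': 11.19, 'O': 8.52}
>>> adduct_mz(f, "[M+H]+")[0]
376
>>> from cholinib import selectivity_index, ic50_to_dg
>>> round(selectivity_index(22.00, 4.24), 2)  # AChE-selective: SI > 1
5.19
>>> round(ic50_to_dg(4.24e-6).dg, 2)          # kcal/mol at 298.15 K
-7.33
```

The elemental percentages and the m/z 376 reproduce the calculated
analytical values for the parent compound; the SI of 5.19 says the compound
inhibits AChE about five times more potently than BChE, and −7.33 kcal/mol
is the corresponding experimental binding free energy used in the consensus
fit.

End-to-end on synthetic data (energies planted to correlate with activity
at R² = 0.85):

```sh
$ cholinib simulate poses --seed 4 --out ens/
wrote 1200 poses (planted R^2 0.850) to ens
$ cholinib consensus ens/poses.sdf --scores ens/scores.csv \
    --core-map ens/core_map.txt --activity-table ens/activity.csv --out cons.json
chosen cluster R-0: R^2 = 0.954 (population 720, 12 ligands fitted)
```

The chosen cluster is the planted binding mode; its fitted R² fluctuates
around the planted value from seed to seed.

```sh
$ cholinib simulate kinetics --out kin.csv --seed 1
$ cholinib kinetics fit kin.csv --model auto
...
selected: competitive
```

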