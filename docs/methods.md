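# Methods

This note documents the models, conventions and numerical choices behind
`cholinib`, and what the synthetic benchmarks do and do not demonstrate.

## Mass calculus

Average molecular weights use the IUPAC 2021 conventional standard atomic
weights; monoisotopic masses use principal-isotope exact masses (¹²C = 12 by
definition). Elemental percentages are 100·(count·weight)/MW and sum to 100
within rounding. Adduct m/z values add the neutral cation atom mass and
neglect the electron mass (5.5×10⁻⁴ Da, below the 4-decimal display
precision used for high-resolution values); nominal m/z is the rounded exact
value. Average masses can differ from literature tables in the third decimal
depending on the atomic-weight revision used there, so comparisons against
printed average MWs should allow ±0.01 g/mol; monoisotopic arithmetic is
exact to display precision.

The compound registry is data transcription, not computation: one CSV row
per compound with series, C-6/C-8 substituents, C-3 aryl pattern, Hill
formula, stereocenter count, yield, physical state and the printed [M+H]⁺
value where one was reported. Printed values that are internally
inconsistent (e.g. a [2M+Na]⁺ that does not equal 2M+23, or a fragment-loss
label one hydrogen off its printed m/z) are preserved in
`data/known_discrepancies.csv` rather than silently corrected, and the
affected compounds are excluded from spot-check assertions. Stereoisomer
enumeration is 2^n per compound — the chemotype has no meso forms — giving
16·4 + 28·2 = 120 docking inputs for the full registry.

## Activity conversions

ΔG_expt = R·T·ln(IC₅₀) with R = 1.987×10⁻³ kcal/(mol·K), T = 298.15 K and
IC₅₀ in mol/L. This rests on the Cheng–Prusoff-style approximation
Ki ≈ IC₅₀; the absolute offset it introduces is irrelevant downstream
because the consensus regression is affine-invariant in its inputs. The
selectivity index is IC₅₀(BChE)/IC₅₀(AChE), so values above 1 mean
AChE-selective. The rule-of-five screen uses strict inequalities
(MW > 500, logP > 5, HBD > 5, HBA > 10) on supplied descriptors; descriptor
prediction is out of scope.

## Inhibition kinetics

All mechanisms are parameterized by the general modifier equation

    v = Vmax·S / ( Km·(1 + I/Ki) + S·(1 + I/Ki′) )

with terms dropped per mechanism (competitive: no Ki′; uncompetitive: no
Ki; noncompetitive: Ki = Ki′; mixed: both, free). The nesting makes
information-criterion comparison across mechanisms coherent.

Fitting is nonlinear least squares in log-parameter space (free positivity
constraint) with Levenberg–Marquardt from a deterministic multi-start grid:
Km seeded from the uninhibited Lineweaver–Burk line, Vmax from 1.2× the
maximum observed rate, Ki from the midpoint of the inhibitor range, each
scaled by ×⅓/×1/×3. The default objective minimizes *relative* residuals,
which is the maximum-likelihood choice when rate noise scales with signal —
the constant-CV regime typical of absorbance-rate read-outs and the noise
model of the synthetic generator; an absolute-residual option is available.
SSR and AICc refer to the minimized objective, with
AICc = n·ln(SSR/n) + 2p + 2p(p+1)/(n−p−1).

Mechanism selection follows the standard evidence convention: mechanisms
within ΔAICc < 2 of the minimum are treated as equally supported, and among
the supported set the one with the fewest parameters is selected (ties by
AICc). Preferring the supported nested special case over its generalization
avoids the ~15% chance rate at which one spurious extra parameter would
otherwise win a pure minimum-AICc vote; runs with more than one supported
mechanism are flagged ambiguous. Parameter standard errors come from the
Jacobian at the optimum via the delta method on the log scale.

Dose–response curves are fit with the four-parameter logistic
y = bottom + (top−bottom)/(1+(IC₅₀/x)^hill), bottom and top constrained to
[0, 100], hill to [0.1, 10], IC₅₀ fit on the log scale from a small
deterministic start grid. Five concentrations and an inhibition span of at
least 30 percentage points are required; non-monotone data (Kendall τ
< 0.2) triggers a warning, not an error.

## Ensemble-docking consensus

Poses are assumed pre-aligned to a common receptor frame; when several
receptors are supplied the Cα RMSD is checked (< 1 Å) and a warning is
emitted otherwise — no superposition is ever applied. Cross-ligand RMSD is
defined over a user-supplied core atom map (the scaffold shared by all
ligands: THQ ring, pyrrolidone anchor, methylene bridge, isoxazole/
isoxazoline core) with correspondence fixed by atom names: no fitting, no
symmetry correction. This keeps an exact closed-form oracle available for
testing.

Clustering is deterministic leader clustering within each chirality
partition: poses sorted by (rescoring energy ascending, ligand id, receptor
id, pose index); each pose joins the first cluster whose *leader* is within
the threshold (2.0 Å default), else founds a new cluster. Hierarchical
average linkage (SciPy) is available as an alternative; both must — and do —
recover planted modes exactly whenever the inter-mode distance exceeds twice
the threshold and the jitter is at most a quarter of it. Cluster filtering
keeps clusters where every covered ligand contributes at least
`min_poses_per_ligand` poses (default 10; a cluster-total variant is
available, since the population rule admits both readings), then the top 5
by population, ties by cluster id.

Representatives default to the lowest rescoring energy per ligand (ties by
pose index). A `best_fit_greedy` mode starts there and hill-climbs
single-ligand swaps while the R² against ΔG_expt strictly improves. That
mode peeks at the experimental values during pose selection — a circularity
inherent in "best fit to experiment" selection — so it is an explicit
opt-in, never the default.

The consensus fit regresses ΔG_expt on the representatives' rescoring
energies by OLS and ranks the filtered clusters by R² (squared Pearson
correlation), ties by population then id; ligands without experimental
activity ride through clustering but are excluded from fitting, and
clusters with fewer than three fittable ligands are reported but not
selectable.

## Interaction fingerprints

Detection is purely geometric; criteria live in one overridable config
block. π-stacking uses centroid distance d, interplanar angle θ folded to
[0°, 90°], and the lateral offset of the partner centroid in the first
ring's plane: sandwich (θ ≤ 30°, d ≤ 5.5 Å, offset ≤ 1.5 Å),
parallel-displaced (same, 1.5 < offset ≤ 4.0 Å), T-shaped (60° ≤ θ ≤ 90°,
d ≤ 6.0 Å). Hydrogen bonds require donor–acceptor ≤ 3.5 Å and D–H···A
≥ 120°, reporting the donor–acceptor distance; weak aromatic C–H bonds
require H···A ≤ 3.0 Å and ≥ 110°, reporting the H–acceptor distance (the
two conventions are kept distinct because literature tables mix them).
Cation–π requires cation–centroid ≤ 6.0 Å within 45° of the ring axis.
These windows follow common published conventions; the contact distances
typically reported for the aromatic gorge of acetylcholinesterase
(≈3.6 Å sandwich on Phe330, ≈4.1 Å displaced on Trp84, ≈4.6–4.9 Å T-shaped,
≈2–3.2 Å hydrogen bonds) all fall inside them, which the tests assert.

Ring planes are least-squares (SVD) fits with a 0.3 Å out-of-plane
tolerance and a sign canonicalized toward +z (ties toward +x, then +y).
Donor/acceptor typing is a rules table — N/O with an attached hydrogen
(≤ 1.3 Å) donate, N/O accept, aromatic carbons with hydrogens are weak
donors — not bond-order perception. Receptor aromatic rings come from
residue templates (Phe, Tyr, Trp ×2, His); cations from Lys NZ and the Arg
guanidinium centroid; ligand rings and cationic atoms are configuration.
Summaries group contacts by (residue, type) with distinct-ligand counts and
sample SD (n−1; 0.00 for singletons).

## Synthetic benchmarks

The pose generator plants `n_modes` rigid copies of a random dummy-atom
scaffold, separated by `mode_separation` (8 Å default) along one axis, and
jitters each pose isotropically (σ = 0.3 Å default), 100 poses per ligand
over 2 receptors for 12 ligands. Activity values anchor on the printed
lead-compound IC₅₀s (4.24/22.00 µM; 3.97 µM; 8.80 µM for the reference
drug) padded with log-uniform draws in 1–100 µM — a realistic µM screening
range. True-mode rescoring energies follow a·ΔG_expt + b + ε with ε drawn
once per ligand (rescoring near-identical geometries yields near-identical
energies; a per-pose draw would couple min-energy representative selection
to the noise and bias the recovered R² upward) plus a 1% per-pose
perturbation; σ_ε is calibrated from the realized ΔG_expt spread so the
planted R² equals 0.85. Decoy-mode energies sit `decoy_offset` higher, at
the same scale but uncorrelated with activity. Generators are pure
functions of (config, seed); written files embed the config hash.

What passing these benchmarks shows: the pipeline recovers a planted
activity-correlated binding mode, with the fitted R² inside the Fisher-z
95% interval of the planted value in ≥45/50 seeds, and discriminates
competitive from mixed inhibition at 2% CV in ≥45/50 seeds with parameters
within 10%. What it does not show: performance on real docking poses, whose
energy errors are neither Gaussian nor ligand-independent, whose binding
modes are not isotropic blobs, and whose cluster structure can be far less
separated than 4× the jitter; nor anything about the physics of the
replaced docking/rescoring engines.

Problem sizes in the tests and the acceptance script (50 consensus seeds at
1200 poses each, 50+50 kinetics seeds on the 8×3×3 design, 100 dose–response
seeds, 100 interaction scenes) were chosen to keep the full run in tens of
seconds while leaving the binomial acceptance margins meaningful.

## Orchestration

`run_all` executes registry checks → activity conversion → consensus →
interaction summarization → kinetics (when a rate table is supplied),
aggregates stage errors, and writes a JSON report plus a manifest (inputs,
SHA-256 hashes, package version, seed). The report is deterministic per
(inputs, seed) — timing goes to the log — so reruns hash identically. When
no pose set is supplied the benchmark ensemble is generated from the run
seed; the interaction stage runs on a generated site scene emulating
representative-pose geometry, since abstract scaffold poses carry no
receptor context.

## Known limitations

* The registry ships only activity values printed verbatim in the source
  text; full assay tables are not available, and missing cells stay missing.
* Fragment-loss adduct arithmetic supports single neutral losses from the
  [M+H]⁺ grammar; exotic adduct labels are out of grammar and recorded as
  discrepancies where printed.
* The interaction scene generator composes contacts geometrically; heavily
  crowded scenes can in principle realize incidental contacts beyond the
  intended set, so truth checks assert recovery of intended contacts, not
  scene-wide exclusivity.
* Kinetics covers initial-rate data only: no progress curves, substrate
  inhibition, or tight-binding corrections.
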