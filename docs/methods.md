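# Methods

This note documents the models, conventions and design choices behind
`mfe2dh`, in the spirit of a model-description appendix: what each stage
assumes, which parameters matter, what the synthetic generators do and do
not emulate, and where the genuinely open choices were made.

## Coordinate ensembles

A trajectory is a shared per-atom topology (chain, residue number, residue
name, atom name) plus a dense `(n_frames, n_atoms, 3)` coordinate array in
Å.  Residue numbering is taken verbatim from the input file (1-based, no
renumbering), so the panel's residue labels (T15, N158, E232, R248, W249)
address atoms directly.  The two monomers of the dimer are chains A and B.

Multi-model PDB is the primary on-disk format (read/written through
biotite); a whitespace-table dialect (`frame time_ps chain resnum resname
atom x y z`) exists for hand-editable fixtures.  PDB carries no time
stamps, so frame times are assigned at a uniform spacing, default
**100 ps/frame**: 500 frames then span 50 ns, the production length of the
simulations being post-processed.  The spacing is a free parameter — the
source simulations' save interval is not recorded in the inputs — and
enters no result except through the analysis window, which is specified as
a *fraction* of the run precisely to stay invariant to it.  Alternate
locations and insertion codes are ignored (first altloc kept).  Single-model
files are accepted and round-trip as one-frame trajectories.

## Hydrogen-bond persistence

The bond criterion is purely geometric and heavy-atom: a donor–acceptor
pair is bonded in a frame if its shortest distance is ≤ **3.5 Å**.  No
angular term is applied by default (an explicit choice: the analysis this
reproduces used shortest donor–acceptor distances, and the synthetic
trajectories place no hydrogens); the chemistry table defines which N/O
atoms may donate or accept, and group shorthand (`NH`→NH1/NH2,
`OE`→OE1/OE2, `OD`→OD1/OD2) resolves to the per-frame minimum over the
atoms actually present.

Occupancy is computed over an **analysis window of [0.4, 1.0]** of the
trajectory, discarding the first 40% as equilibration (20 ns of a 50 ns
run).  A bond is **stable (+)** in a monomer when its window occupancy is
≥ **0.70**; otherwise fluctuating (−).  The published analysis states no
numeric cutoff for its +/− calls, so 0.70 is an editorial default chosen to
separate "stable existence" from "clear fluctuation" robustly on programmed
fixtures (a stable bond with 0.15 Å jitter has occupancy ≈ 1.0; a bond
broken at the window boundary has ≈ 0.0; an intermittent 50/50 flicker
≈ 0.5); it is configurable in `HBondParams`.  Intra-monomer bonds are
evaluated once per chain; inter-monomer bonds in both directed chain
pairings (A→B and B→A); the dimer consensus is the AND of all per-monomer
calls, implementing the requirement that effects be similar in both
monomers before they count.

Replacement-partner search: when a variant orphans one side of a bond, all
complementary donor/acceptor atoms within **5 Å** (default) of the retained
atom in the first frame — excluding the lost partner and the retained
atom's own residue — are ranked by their occupancy against the retained
atom.  Ties rank by address.

## Clustering and hinge detection

Pairwise frame RMSDs use Kabsch superposition (proper rotations only) on CA
atoms by default.  Clustering follows the gromos/Daura greedy algorithm:
take the frame with the most neighbours within the RMSD cutoff (ties →
lowest frame index) as a center, remove it and its neighbours, repeat.  The
**cutoff defaults to 1.0 Å** on CA atoms; the source analysis says only
"default parameters", so this mirrors the common gromos default and is
exposed.  The "middle structure" of a cluster is the member minimizing the
summed RMSD to all other members (the gromos convention), not the temporal
midpoint; ties break to the lowest frame index.

The Gaussian network model places one node per residue (CA), connects nodes
within **10 Å** (the conventional GNM/HingeProt radius), and diagonalizes
the resulting Kirchhoff (graph-Laplacian) matrix.  Eigenvalues below 1e-9
are treated as zero; their multiplicity equals the number of connected
components (a disconnected graph is reported with a warning rather than an
error).  Hinges are reported between consecutive residues whose slow-mode
components change sign, provided the same-sign runs flanking the crossing
both span at least **4 residues**; shorter runs are treated as noise.  The
detection is invariant to the arbitrary global sign of the eigenvector, and
sign runs never cross chain boundaries.

Sensitivity note: hinge positions from this pipeline depend on the contact
cutoff and on the segment filter.  On compact two-domain test structures
the linker hinge is robust across cutoffs that preserve the two-domain
topology, but raising `min_segment` beyond the size of a rigid flank
suppresses detection entirely; reproducing hinge assignments on a specific
crystal structure therefore requires stating both parameters.  The shipped
checks validate the pipeline on synthetic two-domain structures with a
known hinge; the `hinge` CLI subcommand applies it to any PDB file.

## Enzyme kinetics

`MichaelisMentenModel` fits v = V_max·S/(K_m+S) by unweighted nonlinear
least squares (per-point weights optional), initialized at V_max⁰ = max
observed rate and K_m⁰ = the substrate concentration whose rate is closest
to V_max⁰/2, with non-negativity bounds.  Standard errors are asymptotic
(from the covariance at the optimum).  Substrate is in µM, rates in
µmol·min⁻¹·mg⁻¹.

Turnover: `vmax_to_kcat` implements the dimensional conversion k_cat =
V_max·M/(6.0·10⁴·sites) (specific activity × subunit mass, minutes to
seconds).  For this panel the conversion of the wild-type V_max with the
36.14 kDa subunit gives ≈ 2.7 s⁻¹, far from the published 1330 s⁻¹ — the
published turnover numbers evidently rest on an assay- or site-basis that
the printed quantities do not determine.  The package therefore treats
published k_cat values as *data* (attached to a fit via `with_kcat`), and
never re-derives them.  Catalytic efficiency is the plain quotient
k_cat/K_m on the s⁻¹·µM⁻¹ scale; relative efficiency is rounded to a whole
percent; tabulated efficiencies are reported to 3 significant figures.

## Thermal stability

The melt model is a logistic two-state transition between linear baselines
(see README for the formula).  A van 't Hoff ΔH parametrization is
deliberately avoided: only T_m is interpreted, so the transition slope is a
free shape parameter (1/°C) and temperatures stay in °C.  Initialization:
baselines from the first/last 20% of points, T_m at the steepest interior
point of the numerical derivative; T_m is bounded to the scanned interval.
A fit whose transition amplitude at T_m is under 5% of the total signal
range is rejected as "no transition detectable" (this also enforces
baseline identifiability, b_u ≠ b_f at T_m); a T_m within 2% of the
interval edge triggers a warning.  The estimate is invariant to affine
rescaling of the signal axis.  ΔT_m is native minus variant, so positive
values mean destabilization.

## Synthetic data

The generators emulate the *phenomenology* the analysis stages consume, not
the physics that produced it:

* `make_toy_dimer` builds a two-chain extended backbone (N, CA, C, O plus
  one polar side-chain atom per residue, 3.8 Å CA spacing, deterministic
  0.1 Å wobble).  It is a topology-and-geometry stand-in for a folded
  dimer, not a protein model.
* `simulate_trajectory` jitters all atoms isotropically (default 0.15 Å)
  and re-places each programmed acceptor along the donor→acceptor axis so
  the donor–acceptor distance follows its `BondProgram` exactly (plus the
  program's own jitter).  Only acceptors move to realize programs — the
  simplest mechanism that reproduces the observed distance traces (3 Å
  stable; 3→5 Å and 3→7 Å steps; two-state flicker) without a force field.
  Defaults: 500 frames ≙ 50 ns, first 40% later treated as equilibration.
* `simulate_kinetics` draws rate = MM(S)·(1+ε), ε ~ N(0, 5%) by default:
  multiplicative noise, matching how initial-rate errors scale.  The assays
  emulated spanned 0.5–30 µM substrate.
* `simulate_melting_curve` adds Gaussian noise (mdeg) to the two-state
  signal; default baselines (−20 + 0.02·T folded, −4 + 0.01·T unfolded
  mdeg) and slope 0.4 /°C give a realistic 222 nm ellipticity melt over
  25–90 °C.  Published T_m values alone constrain this stage, so recovery
  is demonstrated on synthetic curves, not archival data.

All draws descend from one integer seed through spawned substreams;
identical seeds give bitwise-identical outputs.  Noise magnitudes are free
parameters (the emulated assays report none): 5% relative on rates and
~2% of transition amplitude on melts are used as realistic defaults.

What passing tests on this data do **not** show: correctness on real MD
ensembles (correlated motions, anisotropic fluctuations, water-mediated
bridges, donor-side motion) or on real assay data (systematic instrument
drift, substrate depletion).  They show that each estimator recovers known
ground truth under its stated noise model and that the stages compose.

## Mechanism classification

The classifier maps three evidence channels to one call.  Thresholds
(configurable, editorial): activity impaired below **10%** of native
efficiency — or when kinetics are undeterminable, which for this assay
(NAD⁺-dependent turnover) is itself evidence of cofactor-site damage;
destabilized at **ΔT_m ≥ 5 °C**; both ⇒ mixed; neither ⇒ minor.

Attribution of an activity loss to a site class uses the kinetic signature
before bond counting: K_m elevated ≥ 3× native together with lost
substrate-territory bonds (substrate cavity, loops above it, catalytic-
triad surroundings) ⇒ substrate binding; undeterminable kinetics or a
preponderance of lost NAD⁺-site/Rossmann-sheet bonds ⇒ cofactor binding.
Bond-site majorities alone cannot make this call: a variant that loosens
the cofactor groove also shakes neighbouring cavity bonds and vice versa,
so the channels must arbitrate.  On the packaged published panel the rules
yield: T15A mixed (cofactor + stability), N158D and W249G
substrate-binding-impaired, E232K stability-impaired, R248C minor.  The
rule set is monotone in the activity threshold: lowering it can only move
variants out of activity-impaired classes.

Clinical severity is deliberately not computed; the patient observations in
the panel table are documentation.

## Known limitations

* Bond calls on real trajectories would ignore water-mediated bridges and
  hydrogen positions; the distance-only criterion over-counts marginal
  geometries that an angle term would reject.
* The occupancy cutoff (0.70) and the mechanism thresholds are calibrated
  to reproduce a specific published panel's qualitative conclusions; other
  systems may need different values.
* The Daura clustering is O(n²) in frames with a Python-level RMSD loop;
  it is intended for ensembles of hundreds, not tens of thousands, of
  frames.
* The GNM hinge reproduction on the panel's crystal structure is sensitive
  to the contact cutoff and segment filter (see above) and requires the
  user to supply the structure file.
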