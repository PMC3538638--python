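# mfe2dh

Structure–function analysis of disease variants of the 3R-hydroxyacyl-CoA
dehydrogenase (DH) domain of human MFE-2, the peroxisomal multifunctional
enzyme whose loss causes D-bifunctional protein (D-BP) deficiency.  The
package characterizes a panel of five patient variants (T15A, N158D, E232K,
R248C, W249G) against the wild-type enzyme along three evidence channels and
integrates them into a per-variant molecular-mechanism call.

It is aimed at structural bioinformaticians and enzymologists who have
coordinate ensembles (MD snapshots as multi-model PDB) and assay tables
(substrate–rate pairs, thermal-melt curves) and want a reproducible,
scriptable version of the classic variant workup.

## What it computes

**Hydrogen-bond persistence.**  For each watched donor–acceptor pair the
per-frame shortest heavy-atom distance d(t) is traced (minimum over atom
groups such as Arg NH1/NH2) and the occupancy

    occ = #{frames in analysis window : d(t) ≤ 3.5 Å} / #window frames

is computed over the post-equilibration window (default: the last 60% of
the run).  A bond is called stable (+) in a monomer if occ ≥ 0.70, and the
dimer consensus is stable only if both monomers agree.  The packaged watch
list covers the 18 monitored bonds of the DH dimer (NAD⁺ site, substrate
cavity, catalytic-triad surroundings, dimerization contacts).

**Conformational analysis.**  Kabsch least-squares superposition and RMSD;
gromos (Daura) greedy clustering — repeatedly extract the frame with the
most RMSD neighbours within a cutoff — with middle-structure extraction;
and a Gaussian network model on CA nodes whose slowest internal mode marks
hinge residues at sign crossings.

**Enzyme kinetics.**  Nonlinear least squares of v = V_max·S/(K_m+S)
(`MichaelisMentenModel.fit()`), turnover numbers, catalytic efficiency
k_cat/K_m and percent-of-native activity.

**Thermal stability.**  Two-state melt fit with linear baselines,
signal(T) = b_f + (b_u − b_f)/(1 + e^{−s(T−T_m)}), yielding T_m and
ΔT_m = T_m(native) − T_m(variant) (`TwoStateMeltModel.fit()`).

**Mechanism integration.**  Rules over the three channels classify each
variant as cofactor_binding_impaired, substrate_binding_impaired,
stability_impaired, mixed, or minor (thresholds: <10% of native efficiency
⇒ activity-impaired; ΔT_m ≥ 5 °C ⇒ destabilized; K_m ≥ 3× native plus lost
substrate-site bonds ⇒ substrate attribution).

A seeded synthetic-data module generates toy-dimer trajectories with
programmable bond behaviour (stable / breaking 3→5 Å or 3→7 Å /
intermittent), Michaelis–Menten rate tables and two-state melting curves,
so the whole pipeline is testable without MD runs or wet-lab data.

## Worked example

```python
import numpy as np
import mfe2dh as m

# synthetic wild-type assay data (seeded), then the model fits
truth = m.datasets.assay_truth("NATIVE", noise_sd=0.05)
rates = m.simulate_kinetics(truth, np.geomspace(0.5, 30, 12), seed=42)
print(m.fit_michaelis_menten(rates).with_kcat(1330.0).summary())
```

```
Michaelis-Menten fit
====================
n points                    12
V_max (umol/min/mg)      4.439 +/- 0.089
K_m (uM)                0.5659 +/- 0.062
RSS                     0.3282
k_cat (1/s)               1330
k_cat/K_m (1/s/uM)        2350
```

With 5% noise on twelve points the fit recovers the generating parameters
(V_max 4.44 µmol·min⁻¹·mg⁻¹, K_m 0.54 µM) within one standard error; the
efficiency 2350 s⁻¹µM⁻¹ is within 5% of the noise-free value 2460.

```python
reports = m.published_panel_reports()      # published panel tables as input
print(reports["E232K"].summary())
```

```
Variant E232K
  catalytic efficiency : 83.3% of native
  delta T_m            : +8.0 C vs native
  bonds lost vs native : T15 OG1 - N99 N, T15 OG1 - A100 N, L103 N - F45 O, ...
  mechanism            : stability_impaired
```

E232K keeps 83% of the native catalytic efficiency but melts 8 °C earlier
and loses dimer-interface bonds: the disease mechanism is destabilization,
not loss of catalysis.  The same call sequence classifies N158D and W249G
as substrate-binding-impaired (efficiency collapses, K_m rises 16× and 5×),
T15A as mixed cofactor/stability, and R248C as minor.

The `mfe2dh` console script exposes the stages as subcommands
(`simulate`, `hbonds`, `cluster`, `hinge`, `kinetics`, `melt`, `report`).

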