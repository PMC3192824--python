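# pathmetad

A toolkit for reconstructing free-energy landscapes of large
conformational transitions with combined adaptive-biasing techniques,
exercised end to end on synthetic toy systems with known answers.

It was built around the problem of G-protein-coupled receptor (GPCR)
activation: the inactive → active transition of a receptor (outward
swing of TM6, breaking of the R3.50–E6.30 "ionic lock", rotamer flip of
the W6.48 "toggle switch") is far too slow for plain molecular
dynamics, but can be characterised by

1. **ratchet (adiabatic-bias) dynamics** — a harmonic penalty
   ½k(χ − χ₀ − min_past)² on the RMSD-to-target χ that only acts when
   the system backslides past its best value so far — to generate
   transition pathways;
2. **agglomerative clustering** (average linkage) of the pooled pathway
   frames, cut at 30 clusters, from which n = 10 medoids homogeneously
   covering the pathway become ordered reference states R₁..R₁₀;
3. **path collective variables** over those references,

       s = Σⱼ (j−1) e^{−γ d(R,Rⱼ)} / [(n−1) Z],   z = −(1/γ) ln Z,
       Z = Σⱼ e^{−γ d(R,Rⱼ)},

   with d the squared Cα fit-RMSD and γ = 1/0.25 Å⁻², so s measures
   progress along and z distance from the pathway;
4. **well-tempered metadynamics** on (s, z) — Gaussian hills of initial
   height w = 0.4 kcal/mol every τ = 8 ps, widths (σ_s, σ_z) =
   (0.1, 1 Å²), bias factor (T+ΔT)/T = 11 — whose converged bias yields
   the free energy F = −(T+ΔT)/ΔT · V;
5. **reweighting** of the biased trajectory onto unbiased observables —
   the activation descriptors d_IL, χ_TS and Δd_TM6 — and basin/barrier
   analysis of the projected surfaces.

Because realistic receptor simulations need force fields, membranes and
hundreds of nanoseconds, the package ships synthetic systems where the
free energy is known exactly: analytic tilted double wells, and a
labelled 28-bead "mini-receptor" whose two end states reproduce the
canonical descriptor values of the inactive (d_IL ≈ 3 Å, χ_TS ≈ 163°,
Δd_TM6 = 0) and active (≈ 12 Å, ≈ 55°, ≈ 5.9 Å) states and whose
energy is a double well along the activation mode.  Every stage of the
method is validated against those ground truths.

## Worked example

```python
import numpy as np
from pathmetad import make_mini_receptor, compute_descriptors, make_double_well
from pathmetad.biasing import WellTemperedConfig, run_metadynamics, free_energy_estimate
from pathmetad.reweighting import find_basins_and_barriers

# the labelled mini-receptor and its activation descriptors
mr = make_mini_receptor(seed=0)
for name, state in [("inactive", mr.inactive), ("active", mr.active)]:
    d = compute_descriptors(state, mr.inactive, mr.residue_map, mr.align_mask)
    print(f"{name:>8}: d_IL = {d.d_il:5.2f} A   chi_TS = {d.chi_ts:6.1f} deg"
          f"   delta_d_TM6 = {d.delta_d_tm6:4.2f} A")

# well-tempered metadynamics on a 3 kcal/mol double well
pot = make_double_well(barrier=3.0)
cfg = WellTemperedConfig(w=0.4, tau=0.5, temperature=300.0, delta_t=3000.0,
                         sigma=(0.12,), cv_names=("x",))
traj, bias = run_metadynamics(pot, cfg, steps=400_000, dt=0.002, seed=1,
                              integrator="overdamped", diffusion=1.0)
fes = free_energy_estimate(bias)          # F = -1.1 V, min-shifted
table = find_basins_and_barriers(fes, min_depth=0.5)
print(table.minima.to_string(index=False))
print(table.transitions.to_string(index=False))
```

prints

```
inactive: d_IL =  3.00 A   chi_TS =  163.0 deg   delta_d_TM6 = 0.00 A
  active: d_IL = 12.00 A   chi_TS =   55.0 deg   delta_d_TM6 = 5.90 A
        x        F  starred
-1.012911 0.000000     True
 0.959881 0.070374    False
 x_saddle  F_saddle  barrier
 0.019364  3.063288 3.063288
```

The mini-receptor's end states hit their construction targets exactly,
and an 800-ps well-tempered run recovers the two minima near x = ±1
(equally stable to within thermal noise; the star marks the most stable
basin, ties broken toward lower x) and the 3 kcal/mol barrier to
2% — the landscape the potential was built with.

## Command line

The same pipeline is scriptable from a shell:

```sh
pathmetad abmd        --steps 40000 --seed 1 --out run/pool
pathmetad build-path  --pool run/pool --out run/path
pathmetad metad       --path-refs run/path/path_refs.pdb \
                      --mask-file run/pool/ca_mask.txt --out run/metad
pathmetad reweight    --colvar run/metad/COLVAR --hills run/metad/HILLS \
                      --out run/COLVAR_w
pathmetad fes         --colvar run/COLVAR_w --axis s:60 \
                      --out run/fes_s.dat --basins-out run/basins.tsv
```

All files are plain text: PDB and XYZ for structures, the
`#! FIELDS`-headed COLVAR/HILLS dialects for time series and hills, TSV
for tables, flat YAML for configuration.  Every output records the tool
version, a configuration hash and the seed.

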