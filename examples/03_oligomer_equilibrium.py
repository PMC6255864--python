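"""2D dissociation constants and the equilibrium oligomer distribution.

Refits a noiseless binding curve, then builds the stepwise monomer-
addition equilibrium model from the published constants and locates the
concentration at which each oligomer population peaks.
"""
import numpy as np

import hsafm as H

# binding-curve fit: fraction bound = [A] / ([A] + Kd)
kd_true = 220.0
a = np.logspace(np.log10(22.0), np.log10(2200.0), 8)
fit = H.fit_kd_curve(a, a / (a + kd_true))
print(f"refit of noiseless binding curve: Kd = {fit.kd:.1f} µm⁻² "
      f"(generated with {kd_true})")

kds = H.annexin_kd_matrix()
print("\npublished monomer-row constants (µm⁻²):", kds.monomer_row.tolist())

grid = np.logspace(0, 4, 800)
sweep = H.equilibrium_sweep(grid, kds)
for col, name in [("f2", "dimer"), ("f3", "trimer"), ("f4", "tetramer")]:
    i = int(sweep[col].idxmax())
    print(f"{name:9s} mass fraction peaks at c_total ~ {grid[i]:7.1f} µm⁻² "
          f"(f = {sweep[col].iloc[i]:.2f})")
print("the dimer peak sits near its formation Kd (220 µm⁻²); each larger "
      "species peaks at a successively higher concentration")

state = H.equilibrium_distribution(500.0, kds)
f = state.pooled_fractions()
print(f"\nat 500 µm⁻² (the critical coverage): unit fractions "
      f"1-mer..4-mer, pooled = {np.round(f, 3).tolist()}")
dg = H.oligomer_free_energy(state.densities[1], state.densities[0])
print(f"dimer/monomer free-energy difference: {dg:+.2f} kBT")

be = H.membrane_binding_free_energy(c_surface=1.0, c_bulk_molar=127e-9)
print(f"\nmembrane binding at the dilute condition: P = {be.partition_coefficient:.3f}, "
      f"dG0 = {be.delta_g0:+.1f} kBT (2 nm slab convention)")
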