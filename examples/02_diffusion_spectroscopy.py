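"""Full height-spectroscopy pipeline at the dilute membrane condition.

Simulates annexin-V trimers (1.0 µm⁻², D = 0.8 µm² s⁻¹) diffusing under
the tip for 20 s, then recovers the surface concentration from the
occupied-time fraction and deconvolves the dwell-time distribution.
"""
import hsafm as H

species = H.SpeciesPopulation(geometry=H.SpeciesGeometry(), density=1.0,
                              diffusion=0.8)
cfg = H.SimulationConfig(box_side=2.0, species=(species,), duration=20.0, seed=1)
trace = H.simulate_diffusion_trace(cfg)

sigma = H.estimate_noise_sigma(trace)
spec = H.compute_threshold(sigma)
dwells = H.detect_events(trace, spec)
occ = H.surface_concentration(dwells, species.geometry.w)

print(f"detection width w      : {species.geometry.w:.1f} nm")
print(f"events detected        : {dwells.n_events}  ({dwells.event_rate:.1f} s⁻¹; "
      "measured rates at this condition are a few per second)")
print(f"occupied time fraction : {occ.time_fraction:.2e}")
print(f"surface concentration  : {occ.concentration:.2f} µm⁻²  (simulated: 1.0, "
      "measured spread at this condition: ±0.6)")

mix = H.fit_dwell_mixture(dwells)
print(f"\ndwell mixture: {mix.n_components} component(s), "
      f"reduced chi2 {mix.red_chisq:.2f}")
for i, c in enumerate(mix.components, 1):
    print(f"  component {i}: {c.mean * 1e6:6.1f} ± {c.sd * 1e6:5.1f} µs, "
          f"weight {c.weight:.2f}")
print("The dominant peak is the single-trimer passage time; note that "
      "microscopic sojourns\nunder a point detector are shorter than the "
      "w²/4D timescale (33 µs) -- see docs/methods.md.")
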