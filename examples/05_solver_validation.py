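"""Validate the FE solver against closed-form elasticity solutions.

The patch test must reproduce a uniform uniaxial stress state to machine
precision; the end-loaded cantilever is compared with Euler-Bernoulli
beam theory (tip deflection FL^3/3EI, root-fiber stress FLc/I).
"""

from clawfsa.validation import cantilever_benchmark, patch_test

patch = patch_test()
print(f"patch test: max |vm - F/A| / (F/A) = {patch['vm_max_rel_error']:.2e} "
      f"({patch['n_elements']} elements)  [should be ~1e-14]")

bench = cantilever_benchmark(resolution=(40, 8, 8))
print(f"cantilever tip deflection: FE {bench['deflection_fe_mm']:.3f} mm vs "
      f"beam {bench['deflection_beam_mm']:.3f} mm "
      f"({bench['deflection_rel_error']*100:.1f}% off)")
print(f"root-fiber bending stress: FE {bench['root_stress_fe_mpa']:.1f} MPa vs "
      f"beam {bench['root_stress_beam_mpa']:.1f} MPa "
      f"({bench['root_stress_rel_error']*100:.1f}% off)")
# The residual % reflects linear-tet discretization (and shear deflection
# absent from the beam model), not solver error: the patch test is exact.
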