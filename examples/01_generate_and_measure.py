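"""Generate a synthetic claw, measure it, and scale it to a common area.

Claw comparisons across specimens require equal surface areas so the same
total force produces comparable stress levels; this script shows the
measurement and scaling steps on a generated claw.
"""

from clawfsa import ClawParams, generate_claw_mesh, measure_claw, scale_to_surface_area

claw = generate_claw_mesh(
    ClawParams(
        length_mm=50.0,
        centerline_arc_deg=60.0,
        base_depth_mm=12.0,
        base_width_mm=8.0,
        axial_segments=16,
        circumferential_segments=8,
    )
)
m = measure_claw(claw)
print(f"claw mesh: {claw.n_nodes} nodes, {claw.n_tets} tets")
print(f"L = {m.length_mm:.2f} mm, D = {m.depth_mm:.2f} mm, W = {m.width_mm:.2f} mm")
print(f"L/W = {m.ratio_LW:.3f}, L/D = {m.ratio_LD:.3f}, D/W = {m.ratio_DW:.3f}")
print(f"surface area = {m.surface_area_mm2:.1f} mm^2, volume = {m.volume_mm3:.1f} mm^3")
# D/W is the mediolateral-flattening index: 1.5 here by construction
# (base depth 12 / base width 8); L is a chord-like extent of the curved claw.

scaled = scale_to_surface_area(claw, 1000.0)
sm = measure_claw(scaled)
print(f"after scaling to 1000 mm^2: area = {sm.surface_area_mm2:.6f} mm^2, "
      f"volume = {sm.volume_mm3:.1f} mm^3 (ratios unchanged: D/W = {sm.ratio_DW:.3f})")
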