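"""From a tracked recording to forces and per-cycle kinetics.

A longer (4 s) small scene is rendered so the spectral frequency
estimate and cycle segmentation have enough beats to work with; the
script prints the stiffness, resting tension, beating frequency and
the mean +/- SEM of the per-cycle metrics — the same numbers the batch
runner writes into its summary table.
"""

import dataclasses

import pillartrack as pt

spec = dataclasses.replace(
    pt.standard_scene("circular-std"),
    frame_shape=(100, 240), gap0_px=120.0, tissue_axes_px=(95.0, 36.0),
    circle_radius_px=12.0, amp_px=8.0, duration_s=4.0)
stack, _ = pt.render_video(spec)
config = pt.platform_for(spec)

traces = pt.track(stack, config)
force = pt.deflection_to_force(traces, config)
print(f"stiffness k = {force.k_uN_per_um:.3f} uN/um, "
      f"resting tension = {force.resting_tension_uN:.2f} uN, "
      f"peak force = {force.F_uN.max():.2f} uN")

filtered, freq, cycles = pt.analyze_trace(force.F_uN, config.fps)
print(f"beating frequency: {freq:.2f} Hz, {len(cycles)} complete cycles")

agg = pt.aggregate_metrics(cycles)
for name in ("peak_force_uN", "contraction_time_10_90",
             "relaxation_time_90_10", "contraction_velocity",
             "relaxation_velocity"):
    print(f"  {name}: {agg[name + '_mean']:.3f} +/- "
          f"{agg[name + '_sem']:.3f}")
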