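"""Simulate a paced heart and compare optical vs electrical activation maps.

An anisotropic wavefront (600/300 mm/s) spreads from a mid-free-wall
electrode; every optical fiber reports an AP through fast-dye kinetics at
SNR 15 and every electrode a matched unipolar electrogram.  The analysis
pipeline recovers both activation maps and the per-electrode difference
between eLAT_SG and the mean oLAT_50% of the six surrounding fibers --
sub-millisecond agreement is the hallmark of a fast indicator.
"""
import numpy as np

from panomap import (
    EllipsoidSpec,
    Modality,
    SimulationConfig,
    build_activation_map,
    build_mesh,
    compute_egm_metrics,
    concordance,
    generate_layout,
    segment_beats,
    simulate,
)
from panomap.optical import analyze_trace
from panomap.simulate import INDICATORS

ellipsoid = EllipsoidSpec(2.75, 3.5, 6.0, truncation_fraction=0.25)
layout = generate_layout(ellipsoid, 0.7, 64, 294, seed=1)
mesh = build_mesh(ellipsoid, 0.35)

eids = layout.site_ids(Modality.ELECTRICAL)
epos = layout.positions(Modality.ELECTRICAL)
origin = eids[int(np.argmin(np.abs(epos[:, 2] + 1.5) + np.abs(epos[:, 0] - 2.0)))]

config = SimulationConfig(
    layout=layout, mesh=mesh, origin_site=origin,
    theta_long=600.0, theta_trans=300.0,
    indicator=INDICATORS["fast_dye"], seed=7,
).with_target_snr(15.0)
dataset = simulate(config)

optical_metrics = {}
for trace in dataset.optical_traces:
    aps = [m for m in analyze_trace(trace) if not m.excluded]
    if aps:
        optical_metrics[trace.fiber_id] = aps[0]
electrical_metrics = {}
for egm in dataset.electrograms:
    m = compute_egm_metrics(egm, beat_window=segment_beats(egm)[0])
    if not m.excluded:
        electrical_metrics[egm.electrode_id] = m

optical_map = build_activation_map(optical_metrics, layout, 0, "olat_50")
electrical_map = build_activation_map(electrical_metrics, layout, 0, "elat_sg")
report = concordance(optical_map, electrical_map, layout)

print(f"usable fibers: {len(optical_metrics)}/294, electrodes: {len(electrical_metrics)}/64")
print(f"total activation time: optical {optical_map.total_activation_time:.1f} ms, "
      f"electrical {electrical_map.total_activation_time:.1f} ms")
mean_abs = np.mean(np.abs(list(report.differences.values())))
print(f"oLAT_50% - eLAT_SG over {len(report.differences)} electrodes: "
      f"{report.mean:+.2f} +/- {report.sd:.2f} ms (mean |diff| {mean_abs:.2f} ms)")
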