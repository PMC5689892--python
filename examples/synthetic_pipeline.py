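"""End-to-end synthetic pipeline: phantom -> boluses -> fidelity + dose.

Builds a canthus-like phantom (Gaussian skin valley, 30 mm circular field,
6 MeV), designs the reference bolus, rebuilds it from its own CT-like
contours (the print route), degrades it into a shifted and air-gapped
paraffin staircase (the manual route), and reports Matching Level and
per-metric dose differences of both against the reference plan under a toy
depth-dose engine.  Deterministic for a fixed seed.
"""

from bolusforge.synthetic import simulate

report = simulate(seed=1)

print(f"reference bolus volume: {report.reference_volume_mm3:.0f} mm^3")
print(f"ML printed:  {report.ml_printed.ml:.1f}%")
print(f"ML paraffin: {report.ml_paraffin.ml:.1f}%")
for metric in ("near_min", "mean", "near_max"):
    print(f"dD {metric:9s} printed {report.dd_printed[metric]:+6.2f}%   "
          f"paraffin {report.dd_paraffin[metric]:+6.2f}%")
print(f"paraffin air-gap fraction: {report.air_gap_paraffin:.3f} "
      "(configured rate 0.05)")
# The printed route tracks the reference closely (high ML, small |dD|);
# the hand-layered route loses fidelity and perturbs every dose metric at
# least as much - the qualitative clinical finding this package encodes.
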