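"""Run the 12-marker rectification validation study and print the report.

Twelve 2 cm markers at viewing tilts 0-60 degrees and varied camera
distances are photographed, orthorectified, and measured in both conditions.
The table mirrors a before/after comparison of morphological attributes:
values in brackets are relative standard deviations.
"""

from orthoskin.study import marker_study

summary, measurements, report = marker_study(seed=0)

print(f"markers: {int(summary['n_markers'])}\n")
print(f"{'':22s}{'Original':>18s}{'Orthorectified':>18s}")
rows = [
    ("Shear angle (deg)", "shear_angle_dev_deg"),
    ("Axis ratio", "axis_ratio"),
    ("Area (cm^2)", "area_cm2"),
]
for label, attr in rows:
    o = report.summary["original"][attr]
    r = report.summary["orthorectified"][attr]
    print(
        f"{label:22s}{o['mean']:10.2f} ({o['rel_std']:.2f}){r['mean']:11.2f} ({r['rel_std']:.2f})"
    )
print(
    "\nA correctly rectified circular marker has axis ratio 1.00 and area\n"
    "pi*1^2 = 3.14 cm^2; rectification removes the tilt- and distance-\n"
    "dependence that dominates the raw-image measurements."
)
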