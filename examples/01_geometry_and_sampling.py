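"""Scan geometry: magnification, voxel size, and why tilting helps.

Builds the two acquisition geometries of a microfocus scanner — a
conventional CT scan at moderate zoom and a laminographic (tilted-axis)
scan at high zoom — and evaluates the two truncation-free-imaging
conditions for a wide, flat specimen.
"""

from auglam import (
    ScanGeometry,
    ScanMode,
    check_ct_sampling,
    effective_voxel_size,
    magnification,
    missing_cone_fraction,
)

DET = dict(detector_pixel=0.16, detector_shape=(512, 512))  # 81.92 mm panel

ct = ScanGeometry(mode=ScanMode.CT, sdd=1135, sod=220, **DET)
cl = ScanGeometry(mode=ScanMode.CL, sdd=1135, sod=137, theta=29.8, **DET)

print(f"CT:  M = {magnification(ct):.2f}, "
      f"effective voxel = {effective_voxel_size(ct)*1e3:.1f} um")
print(f"CL:  M = {magnification(cl):.2f}, "
      f"effective voxel = {effective_voxel_size(cl)*1e3:.1f} um")
print(f"missing-cone solid-angle fraction at theta=29.8 deg: "
      f"{missing_cone_fraction(29.8):.4f}")
print()

# A flat specimen, 100 mm wide but only 5 mm thick.
for name, geom in (("CT", ct), ("CL", cl)):
    rep = check_ct_sampling(100.0, 5.0, geom)
    verdict = "OK" if rep.valid else f"FAILS ({rep.limiting_condition})"
    print(f"{name} of a 100 x 5 mm slab: {verdict}")

print()
print("The tilted scan images the wide slab at ~1.6x higher magnification")
print("without truncation, at the price of a missing double cone covering")
print("~13% of frequency directions (axial blurring).")
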