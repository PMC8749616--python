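"""Decompose one thermogram into its ten grayscale color components.

A false-color thermogram encodes temperature as color; texture analysis
needs grayscale planes.  Each frame is split into R, G, B (copied), Y
(brightness), U/V and I/Q (chrominance axes of YUV/YIQ) and H/S
(hue/saturation) — ten planes, since brightness is shared.
"""

import thermotex as tt

frames, _ = tt.generate_cohort(tt.CohortDesign(
    n_nonpregnant=1, n_pregnant_per_subgroup=1, seed=7))
frame = frames[-1]

planes = tt.transform_all(frame.image)
print(f"{len(planes)} component planes: {', '.join(planes)}")
for cid, plane in planes.items():
    roi = plane[frame.mask]
    print(f"  {cid}: ROI mean {roi.mean():6.1f}, range {roi.min():3d}..{roi.max():3d}")

print("\nGray pixels map to 128 on every chrominance axis (U, V, I, Q) and to "
      "0 saturation; warm red-annotated pixels push R, V, I upward.")
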