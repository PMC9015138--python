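"""Detect the brain/bladder cropping boundaries on a phantom scan.

The heuristic projects the SUV volume to the xz-plane, trims the lateral
extremities, collapses to a cranio-caudal profile of SUV maxima and takes the
first and last significant peak as the scan boundaries.
"""

from petlymph import PhantomSpec, find_crop_boundaries, gaussian_smooth, generate_phantom

phantom = generate_phantom(PhantomSpec(seed=42))
vol = gaussian_smooth(phantom.volume, sigma=2.0)
b = find_crop_boundaries(vol)

tt = phantom.truth_table
brain_z = float(tt.loc[tt["class"] == "BRAIN", "centroid_z"].iloc[0])
bladder_z = float(tt.loc[tt["class"] == "BL", "centroid_z"].iloc[0])

print(f"cranial boundary (brain level):  slice {b.z_top}  "
      f"(truth brain centre {brain_z:.1f})")
print(f"caudal boundary (bladder level): slice {b.z_bottom}  "
      f"(truth bladder centre {bladder_z:.1f})")
print("Regions overlapping either boundary, or outside, are excluded from "
      "classification — this removes the brain and bladder themselves.")
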