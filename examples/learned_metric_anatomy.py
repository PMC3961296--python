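"""Inspect what the kernel metric learns on two contrasting phantoms.

The kernel matrix M weights the 4-component distance vector
(dMD, dFA, dVR, d_orient). When only orientation separates the ROI from
the background, learning concentrates weight on the orientation
component. On the default phantom — geometry-distinct background,
orientation-heterogeneous ROI — the equal-weight initialisation already
separates the ROI (the three geometry distances saturate every
ROI-background edge), and learning then sharpens whichever components
cut the foreground-background boundary hardest.
"""

import numpy as np

import dtiseg as ds
from dtiseg.simulate import PhantomSpec


def report(title, spec):
    field, truth, seeds = ds.make_phantom(spec)
    res = ds.learn(field, seeds)
    d = np.diag(res.M)
    share = d / max(np.trace(res.M), 1e-12)
    print(f"{title}")
    print(f"  DSC = {ds.dice(res.seg, truth):.2f} "
          f"after {res.n_iter} iterations")
    print(f"  diag(M*)       = {np.array2string(d, precision=2)}")
    print(f"  weight shares  (dMD, dFA, dVR, d_orient) = "
          f"{np.array2string(share, precision=2)}\n")


report(
    "orientation-only contrast (same eigenvalues everywhere):",
    PhantomSpec(roi_eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
                bg_eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
                roi_orientations=(90.0,), bg_orientations=(0.0,)),
)
report(
    "geometry contrast with orientation-heterogeneous ROI (default):",
    PhantomSpec(),
)

print("In the first case the orientation share rises above its 0.25")
print("initialisation because orientation is the only informative signal.")
print("In the second, the 4-vector kernel separates the ROI already at the")
print("identity initialisation — unlike the whole-tensor metrics — and the")
print("subsequent steps simply deepen the foreground-background cut.")
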