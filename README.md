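# dtiseg — adaptive distance-metric learning for DTI segmentation

`dtiseg` segments diffusion tensor images (DTI) from a handful of
user-drawn seed strokes. Every voxel of a DTI volume carries a 3×3
symmetric positive-definite tensor **D**; which pair of voxels counts as
"similar" depends on the anatomy being segmented — some structures are
distinguished by tensor *geometry* (how anisotropic diffusion is), others
by the *orientation* of the principal diffusion axis. Classical tensor
metrics (Euclidean, J-divergence, geodesic) blend the two signals in a
fixed way and therefore fail whenever the blend is wrong for the task.
`dtiseg` instead **learns the blend from the seeds**, jointly with the
segmentation itself.

## The model

Each voxel gets scalar features from the sorted eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ of its tensor — mean diffusivity MD = (λ₁+λ₂+λ₃)/3,
fractional anisotropy FA = √(3/2)·‖λ − MD‖/‖λ‖ and volume ratio
VR = λ₁λ₂λ₃/MD³, each min-max normalised over the volume — plus the
principal axis e₁. A pair of neighbouring voxels i, j is described by a
4-component distance vector

    d_ij = ( |ΔMD|, |ΔFA|, |ΔVR|, arccos|e_i·e_j| / (π/2) ),

three geometry components and one orientation component, all in [0, 1].
On the voxel adjacency graph (face neighbours) with edge weights from a
Mahalanobis kernel w_ij = exp(−d_ijᵀ M d_ij), the method solves

    min_{M ⪰ 0, f}  fᵀ L(M) f    subject to  f_i = y_i on seeds,

where L(M) = I − Dg^{−1/2} W Dg^{−1/2} is the normalized graph Laplacian
and y ∈ {+1, −1} encodes foreground/background strokes. The optimisation
alternates a label stage (an exact sparse solve of the hard-constrained
quadratic program) with a metric stage (adaptive projected gradient
descent on the 4×4 PSD matrix M: double the step while the cost drops,
revert and halve at the first rejection), stopping when an alternation
improves the cost by less than ε. The binary segmentation is
sign(f); accuracy is the Dice coefficient DSC = 2TP/(2TP+FP+FN).

The three classical metrics run in the same graph framework
(Gaussian-kernel weights, soft seed constraints with μ = 10) as
baselines, and a synthetic-data module generates the validation phantom:
a 15×15 tensor lattice whose ROI shares one anisotropic eigenvalue triple
but splits into two orthogonal principal orientations inside a
geometry-distinct isotropic background, with noisy variants produced by
Stejskal–Tanner DWI synthesis (12 directions, b = 1000 s/mm², one b = 0
baseline), Rician noise at a chosen SNR, and linear least-squares tensor
re-estimation.

## Worked example

```bash
python examples/clean_phantom_comparison.py
```

```
phantom: (15, 15) lattice, ROI = 45 voxels, 4 fg / 18 bg seed voxels

euclidean    DSC = 0.80   (30 voxels foreground, 1 iteration)
jdivergence  DSC = 0.80   (30 voxels foreground, 1 iteration)
geodesic     DSC = 0.80   (30 voxels foreground, 1 iteration)
learned      DSC = 1.00   (45 voxels foreground, 2 iterations)
```

The ROI's internal orientation boundary looks like a large whole-tensor
distance to every classical metric, so label propagation stops there and
each baseline recovers only the seeded 30-voxel band (DSC = 0.80). The
learned kernel discovers from the seeds that the geometry components are
the discriminative ones here and recovers all 45 ROI voxels exactly.
`examples/noise_robustness.py` repeats the comparison on noisy refitted
fields (median over 10 noise seeds): the learned metric holds DSC 1.0 at
SNR 20 and 15 and degrades gracefully at SNR 10, while all baselines stay
at or below 0.8. `examples/learned_metric_anatomy.py` prints the learned
M on contrasting phantoms and `examples/tensor_metrics.py` the underlying
features and metrics for a single tensor pair.

A thin CLI wraps the same pipeline for NIfTI volumes
(`dtiseg simulate|segment|evaluate|distances`; tensors are 6-component
upper-triangular volumes, seed masks use 1 = foreground, 2 = background).

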