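# Methods

## Measurement model

The forward model is `f = P F x + ε`, with `x ∈ C^n` the complex image, `F`
the **unitary, centered** 2D DFT (DC at grid index `(n/2, n/2)`), `P` a
binary selection of k-space locations, and `ε` complex white Gaussian noise
of standard deviation `σ` per complex sample (`σ/√2` per real/imaginary
component), added at sampled locations only. Unitary normalization is a
deliberate choice: it makes the data-fidelity and frame-splitting penalty
weights `μ` and `λ` directly comparable, since both act on the same image
scale, and it makes the zero-filled reconstruction the exact adjoint.

Three retrospective undersampling schemes are provided. 1D Cartesian and 2D
random masks draw lines/points from a center-weighted Gaussian density
(scale 0.25 of the grid) with a fully sampled central band of 4% of lines —
variable-density profiles of this shape are standard; the exact densities
are configurable module constants. Pseudo-radial masks are straight
diameters through the DC pixel on the Cartesian grid, completed by point
reflection `i -> (2c - i) mod n` so they are exactly symmetric under 180°
rotation; the spoke count is chosen by bisection to hit the requested
sampling ratio `1/R`. All masks include DC and are seeded.

## Tight frame and its learning

An `r x r` filter bank `{a_i}`, `i = 1..r²`, generates an undecimated
analysis operator `W`: subband `i` at pixel `p` is the inner product of
filter `i` with the patch anchored at `p`. Stacking the flattened filters as
the columns of `A ∈ C^{r² x r²}`, the system is a tight frame
(`W^H W = I`, perfect reconstruction) iff `A A^H = (1/r²) I` — the Unitary
Extension Principle in matrix form. With periodic boundary handling this
identity is exact on the whole image; with symmetric (reflective) boundaries
analysis and synthesis remain exact adjoints, but `W^H W` deviates near
borders, so periodic is the default and symmetric is provided for
experimentation only.

Initialization uses the full 3-level 2D Haar orthonormal basis on 8x8
blocks: the 64 separable outer products of the rows of the multi-level 1D
Haar matrix, globally scaled by `1/r`. This is the unique square
(`r²`-filter) bank consistent with a 3-level shift-invariant Haar start, and
the SVD update below requires a square bank. Subbands are ordered row-major
over the (vertical, horizontal) 1D Haar indices, coarsest first.

The data-driven step refits the bank to the current iterate. In the patch
domain, with `G ∈ C^{r² x N}` holding every stride-1 patch (one column per
pixel, periodic wrap — which makes `A^H G` *exactly* the stacked analysis
subbands; a unit test asserts this duality) and `C` the target coefficients,
the problem

```
min_A || A^H G - C ||_F   s.t.  A A^H = (1/r²) I
```

is an orthogonal Procrustes problem: with `G C^H = U Σ X^H`,
`A = (1/r) U X^H`. The constraint is satisfied to machine precision by
construction; rank-deficient `G C^H` makes the minimizer non-unique, in
which case the deterministic SVD branch is returned and a warning logged.
All patches are used (no subsampling) by default; an optional seeded
`max_patches` cap exists for speed.

## Two-level Bregman solver

Outer loop `k = 1..K` (dual `c` on k-space), inner loop of `M` sweeps
(dual `b` on coefficients, split variable `v ≈ W x`). One inner sweep:

1. **x-update** (exact, closed form): with `S1 = f - c` and
   `S2 = F[W^H(v - b)]`, set k-space to `S2` off the sampled set `Ω` and to
   `(μ S1 + λ S2)/(μ + λ)` on `Ω`, then inverse-transform. Because
   `W^H W = I`, this is the exact least-squares solution of the quadratic
   x-subproblem (verified against its normal equations in tests).
2. `v <- shrink(W x + b, 1/λ)`, the complex soft-threshold
   `z -> (z/|z|) max(0, |z| - 1/λ)`.
3. Filter update with targets `C = v - b` (skipped when
   `learn_filters=False`, which yields a fixed-frame split-Bregman solver —
   the natural ablation).
4. Re-shrink in the updated frame, then `b <- b + δ_b (W x - v)`.

After `M` sweeps: `c <- c + δ_c (F_p x - f)`. Initialization:
`x⁰` = zero-filled adjoint, Haar bank, `b = c = 0`,
`v⁰ = shrink(W x⁰, 1/λ)`. The iteration runs a fixed `K` outer steps; `σ`
does not enter a stopping rule. Everything is complex end-to-end; magnitudes
are taken only for metrics and PNG export.

### Parameters

| name | meaning | default |
|---|---|---|
| `mu` | weight of the k-space fidelity quadratic | 10 |
| `lam` | weight of the frame-splitting quadratic; shrinkage threshold is `1/lam` | 10 |
| `delta_b` | inner dual step, in (0, 1] | 1 |
| `delta_c` | outer dual step, in (0, 2) | 1 |
| `M` | inner sweeps per outer step | 3 |
| `K` | outer steps | 25 |
| `r` | filter side length (power of 2) | 8 |
| `boundary` | frame border handling | periodic |
| `learn_filters` | adapt the bank vs keep Haar | True |

The defaults are the method's published operating point and are used by all
end-to-end tests and by `scripts/acceptance.py`. Image intensities are on
the 8-bit scale ([0, 255] magnitudes), which fixes the meaning of the
threshold `1/λ` and of the noise levels `σ`.

## Synthetic phantoms

Real scanner data cannot be bundled, so experiments run on two seeded
complex phantoms whose magnitudes live in [0, 255]:

* `shepp_logan(n, phase_amplitude, seed)` — the analytic ellipse phantom
  with the modified (high-contrast) intensity table, evaluated at pixel
  centers and rescaled to peak 255;
* `piecewise_texture(n, n_regions, texture_scale, seed)` — a Voronoi
  partition with per-region levels plus Gaussian-band-limited texture;
  sharp inter-region edges make it suitable for edge-preservation checks.

Both carry a smooth random quadratic phase (default peak 0.5 rad) so the
solver is exercised on genuinely complex data, as it would be on
coil-combined in-vivo images. What the phantoms do **not** emulate: coil
sensitivity profiles, anatomical texture statistics, partial-volume
effects, or physiological/system phase of real acquisitions. Passing the
end-to-end tests therefore demonstrates the algorithm's correctness and its
gain over the zero-filled baseline under controlled conditions, not
clinical image quality.

`make_experiment` composes phantom -> mask -> forward -> noise with all
randomness derived from one seed.

## Metrics

All metrics act on magnitude images, rescaled by `255 / max(|reference|)`.
PSNR is `20 log10(255 / RMSE)` (capped at a 999 dB sentinel for identical
inputs). HFEN is the norm of the difference of Laplacian-of-Gaussian
filtered images (15x15 kernel, σ = 1.5, mean-subtracted so it annihilates
constants exactly) normalized by the filtered reference — the convention of
the dictionary-learning MRI literature. SSIM uses the standard constants
(K1 = 0.01, K2 = 0.03, L = 255, 11x11 Gaussian window, σ = 1.5).

## Numerical choices

* Periodic analysis/synthesis run in the Fourier domain (exact circular
  correlation with the conjugate filter / its adjoint); symmetric boundaries
  use an explicit pad–correlate path and a scatter-plus-fold exact adjoint.
* Complex SVD throughout the filter update; the unitary-factor phase
  ambiguity is harmless because only the product `U X^H` is used.
* Degenerate `x`-update cases are exact by construction: an empty mask
  returns `W^H(v - b)`; `μ = λ` averages the two k-space terms.
* Dual updates are plain accumulations, so their defining identities hold
  bitwise; determinism is end-to-end (same config + seed give bit-identical
  outputs, manifests include SHA-256 digests to verify it).
* Non-finite iterates abort with an error naming the outer iteration.

## Problem sizes

The bundled experiments run at 256x256 (noiseless radial R = 3 headline
run) and 128x128 (noise sweep σ = 2, 4, 6, 8), sizes at which the full
K = 25, M = 3 schedule completes in minutes on one CPU while reproducing
the method's qualitative behavior.

## Known limitations and observed behavior

* **Adaptivity does not pay on piecewise-constant phantoms.** The
  multi-level Haar basis is already an (essentially) optimal sparsifier for
  the Shepp-Logan magnitude, and the learned frame measurably *reduces* its
  l1 sparsity; on the noiseless headline run the `learn_filters=False`
  ablation converges faster and scores higher PSNR at the fixed K = 25
  (57.5 dB vs 45.4 dB, both far above the 24.0 dB zero-filled baseline).
  The adaptive frame's value lies on images whose structure a fixed wavelet
  basis does not match — the regime the method was designed for; on these
  phantoms the ablation is the stronger baseline and is reported alongside.
* **The outer data-consistency residual is not monotone.** With the inner
  problem solved inexactly (M = 3), the outer dual overshoots: the residual
  `||F_p x - f||` decays for the first ~10 outer steps, then drifts up
  slowly even as PSNR rises monotonically (fraction of non-increasing
  consecutive steps 0.46 on the 256x256 headline run). Raising M restores
  near-exact convergence (at M = 10 the fixed-frame solver reaches the
  86 dB machine-accuracy regime) but departs from the published schedule.
* The frame is undecimated and square (`r²` filters of size `r x r`);
  overcomplete/decimated variants, 3D frames, multi-coil models and
  non-Cartesian (NUFFT) trajectories are out of scope.
* With symmetric boundaries `W^H W ≠ I` near borders, so the closed-form
  x-update is no longer the exact subproblem minimizer there; periodic is
  the supported default.
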