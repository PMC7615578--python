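# microtract

White-matter microstructural phenotyping from multishell diffusion MRI, built
as a fully synthetic, testable pipeline.  The package targets the analysis
style used in developmental and clinical neuroimaging studies that combine
ultra-strong-gradient acquisitions (b up to 6000 s/mm²) with biophysical
modeling: it simulates cohorts of subjects with known ground truth, estimates
a panel of eleven diffusion metrics, fits the two-compartment Standard Model
of white matter from rotationally-invariant spherical moments, profiles
quantities along tract centerlines, and condenses the metric panel into
correlated "biophysical principal components" (BPCs) with age and group
statistics.

It is aimed at methods researchers who want a self-contained sandbox in which
every estimator can be checked against the generating truth — no participant
data are required at any point.

## The models

**Acquisition.** Five shells at b = 0.5, 1.2, 2.4, 4.0, 6.0 ms/µm²
(= 500…6000 s/mm²) with 30/30/60/60/60 directions plus 14 b=0 volumes;
Stejskal–Tanner weighting b = γ²G²δ²(Δ − δ/3) with Δ = 23.3 ms, δ = 7 ms.
Direction sets come from seeded electrostatic repulsion.

**Standard Model (BSM).** The per-direction signal is the spherical
convolution of a Watson orientation distribution (concentration κ) with the
fiber-response kernel

    K(b, ξ) = f·exp(−b·D_c·ξ²) + (1−f)·exp(−b·De⊥ − b·(De∥−De⊥)·ξ²)

— an intracellular "stick" of signal fraction f and axial diffusivity D_c
plus an anisotropic Gaussian extracellular compartment.  Per shell, the
l-th rotational invariant factorizes as S_l = K_l·p_l, where K_l is the
kernel's Legendre projection and p_l the ODF moment; fitting uses l ∈ {0, 2}
on all shells, with invariants averaged over tract segments first to boost
effective SNR (they are rotation-invariant, so tract curvature does not
bias the average).

**Metric panel.** DTI (FA, D̄, D⊥, D∥; fit at b ≤ 1.2), DKI (K̄, K⊥, K∥;
fit at b ≤ 2.4) and the spherical mean/standard deviation of the normalized
signal at the lowest and highest shells (Ṡ_μ, Ṡ_σ at b = 0.5 and 6.0).

**Statistics.** PCA on the metric correlation matrix with Horn's parallel
analysis for component retention and oblimin (γ=0) rotation; KMO and
Bartlett sphericity adequacy checks; linear age models compared to quadratic
by AICc; pooled-variance t-tests with Hedge's g; Benjamini–Hochberg FDR per
analysis family.

## Worked example

```python
import numpy as np
from microtract import (
    CohortSpec, SMParams, make_default_protocol, sm_signal, add_noise,
    rotinv_from_signal, segment_average, fit_standard_model,
)

scheme = make_default_protocol(seed=1)          # 254 volumes, 5 shells
truth = SMParams(f=0.6, d_c=2.2, de_par=2.0, de_perp=0.7, kappa=16.0)

clean = sm_signal(truth, scheme)                # noise-free forward signal
noisy = add_noise(np.tile(clean, (50, 1)), snr=50.0, model="rician", seed=7)

invs = rotinv_from_signal(noisy, scheme, sigma=1 / 50.0)   # per-voxel s_l0, s_l2
fit = fit_standard_model(segment_average(invs), seed=3)
print({k: round(getattr(fit.params, k), 3)
       for k in ("f", "d_c", "de_par", "de_perp", "kappa")})
```

Output from this exact snippet:

```
{'f': 0.618, 'd_c': 2.354, 'de_par': 1.84, 'de_perp': 0.701, 'kappa': 14.243}
```

A 50-voxel segment at SNR 50 recovers f and the extracellular diffusivities
within a few percent of the truth (0.6, 2.0, 0.7); D_c and κ are the least
precise parameters of this model — the ordering that
`precision_simulation` quantifies systematically.

The cohort-level entry point is `run_full_analysis(CohortSpec(seed=0))`,
which returns tidy tables: the per-subject metric panel, BPC loadings and
scores, age regressions, DEL-vs-ASM group comparisons (both FDR-corrected),
Standard Model fits, along-tract profiles and tract volumes.

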