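# ionsaxs

SAXS-driven modelling of the RNA solution state.

RNA structure prediction gives plausible atomistic models, but two things
keep those models from matching solution scattering data: predicted
structures carry none of the Mg²⁺ ions that stabilize and neutralize folded
RNA, and a single rigid conformation rarely represents a flexible molecule
in solution. `ionsaxs` addresses both. Given an atomistic model (or an
ensemble of candidate conformations) and a measured small-angle X-ray
scattering profile, it

1. computes theoretical profiles with the **Debye formula**,
   I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q·dᵢⱼ)/(q·dᵢⱼ),
   with per-atom solution form factors
   fᵢ(q) = f_v,i(q) − c₁·G(q,c₁)·f_s,i(q) + c₂·sᵢ·f_w(q)
   (vacuum, excluded-volume and hydration-layer terms; sᵢ is the atom's
   fractional solvent accessibility);
2. scores models by
   χ² = (1/S) Σᵢ [(I_exp(qᵢ) − c·I(qᵢ,c₁,c₂)) / σ(qᵢ)]²,
   with the scale c solved analytically and (c₁,c₂) either fixed at 1
   (the default, to avoid overfitting) or grid-optimized over their
   conventional bounds;
3. predicts candidate **Mg²⁺ binding sites**: solvent-accessible surface
   probes are classified by a small graph neural network (graph attention +
   graph convolution layers over the 8 Å atomic neighborhood of each probe,
   encoded purely by distances, hence rigid-motion invariant);
4. selects the ion subset that minimizes χ² by **branch-and-bound beam
   search** over precomputed subprofiles, so each candidate subset is scored
   in time independent of RNA size; and
5. fits **multistate models** — small sets of conformations with
   non-negative weights solved by NNLS — when no single conformation fits
   within the noise.

Guinier analysis (Rg and I(0)), dimensionless Kratky curves and model-based
P(r) histograms are included for standard profile diagnostics. A synthetic
data module generates every fixture needed to exercise the pipeline
end-to-end with known ground truth: idealized RNA-like helices, hinge-
perturbed ensembles, noisy simulated profiles, Mg²⁺-like binding pockets,
and labeled coordination-shell graphs for classifier training.

## Worked example

Plant two Mg²⁺ ions in oxygen-lined pockets on a synthetic helix, simulate
a noisy "experimental" profile, and recover the ions from scattering alone:

```python
import numpy as np
from ionsaxs.synthetic import (make_helix, make_binding_pockets,
                               simulate_profile, NoiseModel)
from ionsaxs.structures import assign_accessibility
from ionsaxs.saxs import default_q_grid, guinier_rg, fit_chi2, compute_partials
from ionsaxs.ionselect import precompute, branch_and_bound, SelectionConfig

helix, centers = make_binding_pockets(make_helix(12), n_pockets=2, seed=1)
model = assign_accessibility(helix)
q = default_q_grid(0.4, 101)
exp = simulate_profile(model, q, NoiseModel(0.002, 0.0005, seed=42), ions=centers)

rg = guinier_rg(exp)
print(f"Guinier: Rg = {rg.rg:.2f} +/- {rg.rg_err:.2f} A")

part = compute_partials(model, q)
print("RNA only:  ", fit_chi2(exp, part).summary())

cache = precompute(model, centers, q)
sel = branch_and_bound(exp, cache, SelectionConfig())
print("with ions: ", sel.fit.summary())
```

Output:

```
Guinier: Rg = 13.57 +/- 0.02 A
RNA only:   chi2 = 2.5526  c = 1.01184  c1 = 1.000  c2 = 1.000
with ions:  chi2 = 0.5945  c = 1.00008  c1 = 1.000  c2 = 1.000
```

The bare model misses the data by χ² ≈ 2.6; adding the two selected ions
(the χ² trajectory drops 2.55 → 0.84 → 0.59 as they are accepted) brings
the fit within the noise, and the scale factor c returns to 1 because the
simulated intensity is then fully accounted for.

The same stages are available from the shell:

```sh
ionsaxs simulate sim --n-bp 12 --seed 1      # writes sim.pdb + sim.dat
ionsaxs train-ionnet model.npz --seed 0      # classifier on synthetic shells
ionsaxs fit sim.pdb sim.dat
ionsaxs place-ions sim.pdb sim.dat --checkpoint model.npz
ionsaxs run pipeline.cfg                     # full pipeline from a config file
```

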