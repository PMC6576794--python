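# landscape-kinetics

Inference of epigenetic potential landscapes for drug-induced cancer
cell-state evolution, from two independent kinds of data.

BRAF-mutant melanoma cells under BRAF-inhibitor treatment do not simply die
or resist: over ~2.5 months they slide along a de-differentiation
trajectory, from a drug-sensitive **melanocytic** state (MART-1⁺) through a
transient, slow-cycling **neural-crest-like** state (MART-1⁻/NGFR^high) to a
drug-tolerant **mesenchymal** state (MART-1⁻/NGFR⁻).  This package
implements, as a tested and reusable pipeline, the two complementary
statistical-physics analyses of that transition:

1. **Surprisal analysis** of a kinetic series of bulk transcriptomes.
   Treating the cell population as an entropy-maximizing system under
   time-dependent constraints, the log-expression of transcript *i* at
   time *t* is decomposed via SVD as

   ln *X*ᵢ(*t*) = −λ₀(*t*) *G*ᵢ₀ − Σⱼ λⱼ(*t*) *G*ᵢⱼ,

   a time-invariant global steady state (λ₀ nearly constant) plus a few
   constraints, each a time-dependent amplitude λⱼ(*t*) times a
   time-independent gene pattern *G*ᵢⱼ.  The free-energy-like potential
   *F*(*t*) = Σⱼ λⱼ(*t*)⟨*G*ⱼ⟩ with ⟨*G*ⱼ⟩ = Σᵢ *X*ᵢ*G*ᵢⱼ scores the
   relative stability of the population transcriptome at each timepoint.

2. **A growth-modified Fokker-Planck model** of two-marker flow-cytometry
   snapshots.  Events are reduced to a 1-D reaction coordinate *x* (arc
   length along a principal curve fitted to the pooled (log MART-1,
   log NGFR) clouds, in units *q*), kernel-density estimated per
   timepoint, and modeled by

   ∂*P*/∂*t* = −∂ₓ[μ(*x*)*P*] + *D* ∂ₓ²*P* + α(*x*)*P*,

   where μ = −∂ₓU is the drift of a potential landscape, *D* (q²/day) is a
   constant diffusivity measured independently from sorting-relaxation
   experiments via the Gibbs relation *U* = −(*D*/2) ln *p*∞, and α(*x*)
   is a piecewise-constant state-dependent net growth rate (melanocytic
   rate anchored at 0; neural-crest α₁ and mesenchymal α₂ free).  The
   drift (a 20-knot cubic spline) and (α₁, α₂) are fitted to the measured
   density series by multi-start gradient descent on the L² loss.

The two landscapes are compared only by the signs of their slopes across
the three states.  Both identify the neural-crest state as the attractor
(potential minimum), yet the population ends mesenchymal: state-dependent
net growth outcompetes landscape relaxation.  A synthetic-data module
generates every input with this structure planted, so all estimators are
validated by parameter recovery against known ground truth.

## Worked example

```python
import numpy as np
from landscape_kinetics import synthetic as syn, surprisal as sa
from landscape_kinetics import trajectory as traj, inference as inf

# surprisal analysis of a 10,000-gene, 7-timepoint kinetic transcriptome
truth = syn.m397_like_transcriptome_truth(n_genes=10_000, noise_sd=0.1, seed=0)
X = sa.filter_genes(syn.gen_transcriptome(truth))   # mean > 0.5, CV > 0.15
dec = sa.fit_surprisal(X, "auto")
fes = sa.free_energy(dec, X)
print(round(100 * np.ptp(dec.lambda0) / dec.lambda0.mean(), 3))  # 0.442
for t, F in zip(fes.timepoints, fes.F):
    print(f"D{t:<3.0f} F = {F:9.0f}")

# diffusivity from a sorting-relaxation experiment
nt = syn.drug_naive_simulation_truth(seed=0)
clouds = syn.gen_sorting_relaxation(nt, gate=(3.1, 6.0), times=[0, 1, 2, 4, 7, 10])
dens = traj.estimate_density(clouds.true_coords, clouds.times, grid=nt.grid)
print(round(inf.fit_diffusivity(dens, nt.steady_state()), 4))    # 0.3556
```

Output:

```
0.442
D0   F =    -27539
D3   F =    -16156
D11  F =   -120351
D17  F =   -253829
D21  F =   -195390
D46  F =    -17270
D73  F =    -50102
0.3556
```

The steady-state amplitude λ₀(*t*) varies by only 0.44% over 73 days of
treatment — the global baseline is time-invariant and all dynamics live in
the constraints.  *F*(*t*) dips through the neural-crest-dominated
timepoints (days 11–21): the transient intermediate state is the most
stable the population visits, and the final mesenchymal timepoint sits
above it.  The sorting-relaxation fit recovers the planted diffusivity
0.35 q²/day to 1.6% from 10⁴ sampled cells per timepoint.

The full pipeline (simulation → surprisal → principal curve → densities →
diffusivity → landscape fit → growth rates → landscape comparison) runs as

```sh
landscape-kinetics run-all --out runs/demo --seed 0
```

and writes every stage artifact plus `manifest.json` to the run directory.

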