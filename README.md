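# mnrelations

Quantitative power-law relationships between the morphometric and
electrophysiological properties of spinal alpha-motoneurons (MNs), and
tools to use them: cross-study meta-regression in a normalized space,
iterative referencing of every property to MN size, fivefold
cross-validation, scaling to absolute SI units via fold-range arguments
and Rall cable theory, generation of inter-consistent MN property
profiles and pools, and muscle-unit (mU) size couplings that bear on
Henneman's size principle.

## The problem and the model

Electrophysiologists have measured pairs of MN properties — axonal
conduction velocity (ACV), afterhyperpolarization duration (AHP), input
resistance (R), rheobase (I_th), capacitance (C), membrane time constant
(τ) and indices of MN size (soma diameter D_soma, neuron surface area
S_neuron) — in many separate studies, each covering only a subset of
properties, with its own calibration and its own slice of the MN pool.
This package implements the cross-study procedure that turns those
scattered datasets into one consistent mathematical framework:

1. **Normalization.** Within each study, every property column is
   rescaled to percent of its within-study maximum. Percent-of-maximum
   normalization is scale-invariant, so multiplicative inter-study
   calibration offsets vanish before studies are merged.
2. **Power-law regression.** Each merged ("global") dataset {A;B} is
   fitted by ordinary least squares in log-log space, giving
   A = k·B^a with 95% confidence bounds, r² (squared Pearson correlation
   of the logs) and a slope t-test p-value.
3. **Size referencing.** Properties are processed in the order ACV, AHP,
   R, I_th, C, τ. Each {A;B} dataset is converted to {A;S_MN} through the
   previously derived inverse size law S_MN = f(B) (admitted only when the
   forward fit has r² > 0.3 and p < 0.01), the converted datasets are
   merged and refitted, and all pairwise laws follow exactly by analytic
   inversion and composition of the size laws.
4. **Validation.** Fivefold cross-validation per dataset: normalized
   maximum error (nME), normalized RMSE and r² between predicted and
   held-out observed values.
5. **Unit scaling.** The empirical size fold range q_S propagates through
   each exponent c into a theoretical fold q_T = q_S^|c|; a theoretical
   [A_min, A_max] is anchored at the empirical midpoint, and intercepts
   are fixed so that the smallest MN maps onto the appropriate extreme of
   each range. Rall's equivalent-cylinder identities
   (L = π(τ/τ₁ − 1)^(−1/2), C = (τ/R)·L/tanh L, R_m = R·S·tanh L/L)
   extend the framework to specific membrane quantities, and the
   composed near-Ohmic I_th–R law yields the voltage threshold ΔV_th.

The bundled adult-cat framework (absolute SI constants, e.g.
I_th = 3.8·10⁸·S_neuron^2.52, R = 1.7·10⁻¹⁰·S_neuron^−2.43) lets you
reconstruct a complete MN profile from any single measured property, or
sample whole pools of inter-consistent MN models.

A synthetic-data module generates study-structured corpora with known
ground truth (latent right-skewed size distribution, per-study scale
offsets and sub-range sampling, multiplicative log-space noise), so every
pipeline stage is testable without any external data.

## Worked example

Reconstruct the full profile of a cat MN whose input resistance is 1 MΩ:

```bash
$ mnrel profile --seed-property R --value 1 --units MOhm
{
  "S_neuron": 3.2940000792990517e-07,
  "D_soma": 5.8945264576930405e-05,
  "R": 1000000.0,
  "R_m": 0.19764000475794297,
  "C": 5.971607558302457e-09,
  "C_m": 0.01812874139205603,
  "tau": 0.004388046620302799,
  "I_th": 1.5536878308103228e-08,
  "AHP": 0.06822496983247042,
  "ACV": 89.16534207188921,
  "dV_th": 0.015536878308103227
}
```

Reading the numbers: a 1 MΩ MN sits in the middle of the cat pool — a
~59 µm soma with ≈0.33 mm² of membrane, a rheobase of ≈16 nA, a time
constant of ≈4.4 ms, an AHP of ≈68 ms and an axonal conduction velocity
of ≈89 m/s; the product I_th·R gives a ≈16 mV depolarization threshold.
All values are SI; every pair of outputs is consistent with the bundled
framework's published constants (which are rounded to 2 significant
figures, so chained reconstructions agree to ~10–20%, not exactly).

The same flow in Python:

```python
import mnrelations as mn

spec = mn.SyntheticSpec(seed=0)                       # 17-pair cat-like corpus
corpus = mn.generate_corpus(spec)
rs = mn.derive_relationships(mn.build_globals(corpus))
print(rs.size_laws["I_th"])                           # I_th vs S_MN, normalized
pool = mn.generate_pool(100, seed=0)                  # 100 consistent MN models
```

## Analysis pipeline

The numbered drivers under `analysis/` run the full study end to end and
write their tables under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_corpus.py` | synthetic 17-pair study corpus (46 studies, 2760 points) |
| `02_derive_relationships.py` | normalization, homogeneity gates, size-law derivation |
| `03_crossvalidate.py` | fivefold CV metrics (nME, nRMSE, r²) per dataset |
| `04_scale_to_si.py` | fold ranges, SI intercepts, Rall extensions, ΔV_th |
| `05_build_pool.py` | pool of 100 inter-consistent MN profiles |
| `06_mu_coupling.py` | mU–MN size couplings and size-principle summary |

Run them in order: `python analysis/01_simulate_corpus.py`, etc.
Background on the modelling choices and the known limitations is in
[docs/methods.md](docs/methods.md).

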