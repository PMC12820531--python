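# repstates

Photon-level single-molecule FRET inference of helicase conformational
states.

The Rep helicase of *E. coli* switches between an open and a closed form —
and, as in-solution single-molecule FRET shows, two intermediates — with
the balance between the four states S1–S4 tuned by ionic strength and DNA
binding. Resolving those states and their interconversion kinetics from
confocal ALEX (alternating-laser-excitation) photon streams takes a chain
of specialised analyses, each of which this package implements as a tested,
reusable module over synthetic data with exact ground truth:

* **`photon_sim`** — generator for diffusing-molecule ALEX bursts
  (continuous-time Markov state switching, leakage / direct-excitation /
  γ / β distortions, background), trapped-molecule traces, and TCSPC
  decays, all with stored truth.
* **`burst_core`** — background estimation from interphoton-delay tails,
  all-photon and dual-channel sliding-window burst search, accurate FRET
  corrections (E = F_acc/(γF_DD+F_acc) with F_acc = F_DA − l·F_DD − d·F_AA),
  self-calibration of (l, d, γ, β) from the burst populations, and the
  AA ≥ 50 / size ≥ 50 / S ∈ [0.2, 0.8] population filter.
* **`mixtures`** — Gaussian-mixture decomposition of burst efficiencies
  with BIC component selection, globally constrained fits across
  conditions, and permutation tests of state weights.
* **`bva` / `h2mm`** — burst variance analysis against the shot-noise
  limit √(E(1−E)/n), and a photon-by-photon hidden Markov model: per-tick
  transition matrix propagated across interphoton gaps by eigendecomposed
  matrix powers, exact Baum–Welch, Viterbi dwells, BIC′/ICL state-count
  selection, profile-likelihood (ΔlogL = 0.5) uncertainties, and rate
  matrices k_ij = A_ij/Δt with stationary occupancies.
* **`traplevels`** — offline trapped-molecule analysis: binned traces,
  AIC-optimised K-means background, Poisson-GLR changepoint levels,
  transmission/leakage-corrected level FRET, IRF-convolved MLE lifetimes,
  30 ms level filter.
* **`decayfit`** — multi-exponential iterative-reconvolution TCSPC fitting
  and the amplitude-weighted mean lifetime τ_av = Σαᵢτᵢ/Σαᵢ.
* **`avclouds`** — accessible-volume dye clouds on PDB structures,
  mean-position distances (Rmp) and predicted ⟨E⟩ = ⟨1/(1+(r/R0)⁶)⟩.

A `repstates` command-line interface wraps the modules
(`simulate`, `bursts`, `gmm`, `bva`, `h2mm`, `trap`, `decay`, `avfret`,
`pipeline`), and `repstates.pipeline.run_pipeline` chains
simulate → bursts → mixtures → kinetics from a single TOML config.

## Worked example

Reproduce the four-state decomposition at the published burst counts
(1021 low-salt and 1013 high-salt bursts):

```python
import numpy as np
from repstates import mixtures
from repstates.fixtures import get_fixture

rng = np.random.default_rng(1)
subseeds = rng.integers(0, 2**31 - 1, size=8)

low, high = get_fixture("low_salt"), get_fixture("high_salt")
e_sel = mixtures.draw_from_fixture(low, 2048, seed=int(subseeds[0]))
k_star, _ = mixtures.select_k(e_sel, k_max=6, n_restarts=5, seed=int(subseeds[0]))

e_low = mixtures.draw_from_fixture(low, 1021, seed=int(subseeds[1]))
e_high = mixtures.draw_from_fixture(high, 1013, seed=int(subseeds[2]))
pooled, (m_low, m_high) = mixtures.global_constrained_fit(
    [e_low, e_high], K=k_star, seed=int(subseeds[1]))

print(f"BIC-selected components : {k_star}")
print(f"shared state centres    : {np.round(pooled.means, 3)}")
print(f"low-salt weights   (%)  : {np.round(m_low.weights * 100, 1)}")
print(f"high-salt weights  (%)  : {np.round(m_high.weights * 100, 1)}")
```

prints

```
BIC-selected components : 4
shared state centres    : [0.205 0.531 0.822 0.979]
low-salt weights   (%)  : [11.8 23.  47.7 17.4]
high-salt weights  (%)  : [23.5 27.  33.9 15.6]
```

Four components are selected by BIC; the shared centres land on the
S1–S4 efficiencies (0.21, 0.54, 0.82, 0.98), and the per-condition weights
recover the published 11:23:47:18 (low salt) and 25:25:33:17 (high salt)
occupancies to within the counting noise at ~1000 bursts. The same
machinery exposes the DNA-induced S2 shift (16 % → 22 %) and its
permutation-test significance, and the photon HMM recovers the extreme
state efficiencies (0.27 and 0.96 at 150 mM NaCl with DNA) together with
interconversion rates from raw simulated photon streams — see
`docs/methods.md` for the models and their assumptions.

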