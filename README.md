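# sptstates

Multi-state diffusion analysis for single-particle tracking of nuclear
proteins. The motivating system is linker histone H1, which live-cell
tracking resolves into a small number of discrete diffusive states —
a slow nucleosome-bound state, an intermediate "liquid-like" state, and
a transiently dissociated state — but the machinery is generic for any
2D tracking experiment with Markov switching between free-diffusion
states.

The package covers the full trajectory-analysis pipeline around that
claim:

- **`synthetic_data`** — generators for multi-state Brownian
  trajectories (Markov switching at frame boundaries, Gaussian
  localization error, geometric track-length attrition), CSR and
  Thomas-cluster localization patterns, and fixed-emitter precision
  data, with reference three-state (interphase) and two-state
  (metaphase) models at the published parameter values.
- **`tracking_io`** — trajectory/localization table I/O (native CSV,
  TrackMate and ThunderSTORM dialects) and the core data model
  (µm/seconds internally, nm at localization I/O).
- **`msd_analysis`** — displacement and MSD curves (time- and
  ensemble-averaged, per-cell dispersion), D and anomaly-exponent α
  fits (MSD = 4DΔt in 2D, ×1.5 for the 3D estimate), localization
  precision from fixed emitters.
- **`rl_deconvolution`** — Richardson–Lucy inversion of the van Hove
  displacement distribution Gs(r, Δt) into the single-molecule MSD
  distribution P(M) through the kernel q(r, M) = exp(−r²/M)/(πM), and
  diffusive-state counting by BIC-selected Gaussian mixtures over
  log₁₀ M.
- **`state_hmm`** — Baum–Welch EM classifier over per-frame steps
  (emission variance 2·D_s·Δt per axis), BIC state-count selection,
  Viterbi annotation, and per-state track splitting with per-state MSD.
- **`spatial_stats`** — PALM density maps (32.5-nm pixels, centered
  crop), intensity-quartile density classes, per-state step-midpoint
  enrichment (0.25 per class = random), and uncorrected Ripley
  K(r) = (S/(N−1))·(1/N)·ΣᵢΣ_{j≠i} 1[d_ij ≤ r] with L = √(K/π).
- **`meanfield_model`** — Flory–Huggins-style lattice free energy of
  stable (dyad) versus dynamic (multivalent) H1–nucleosome binding,
  f(m, n; N) = [E − T·S]/N0, with landscape minimization over the
  binding ratio (n+m)/N and mobile fraction m/(n+m).

See `docs/methods.md` for the models, numerical choices and
limitations.

## Worked example

Simulate trajectories from the three-state interphase model
(D = 0.0354, 0.114, 1.85 µm²/s at 50-ms frames, occupancies
0.30/0.60/0.10), refit the state model from the tracks alone, and
annotate steps:

```python
import numpy as np
from sptstates import synthetic_data as sd, state_hmm as sh
from sptstates import tracking_io as tio, msd_analysis as ma

spec = sd.SimulationSpec(model=sd.interphase_h1_model(), n_tracks=2000,
                         mean_track_length=21.0, loc_sd=0.0, seed=1)
tracks = tio.filter_tracks(sd.simulate_tracks(spec), min_points=5)
model = sh.select_n_states(tracks, max_states=3, seed=1, n_restarts=10)
ann = sh.annotate_states(model, tracks)
print("states:", model.n_states)
print("D (um^2/s):", np.round(model.D, 4))
print("occupancy:", np.round(model.occupancy, 3))
print("annotated occupancy:", np.round(ann.occupancy_fractions, 3))
sets, msds = sh.split_by_state(tracks, ann)
D_liq, alpha = ma.fit_diffusion(msds[2], fit_range=(0.05, 0.5))
print("liquid-like MSD fit: D = %.4f um^2/s, alpha = %.2f" % (D_liq, alpha))
```

Output:

```
states: 3
D (um^2/s): [0.0364 0.1159 1.8135]
occupancy: [0.318 0.586 0.096]
annotated occupancy: [0.317 0.586 0.097]
liquid-like MSD fit: D = 0.1104 um^2/s, alpha = 0.98
```

BIC selects three states; each fitted D lands within a few percent of
its generating value, the stationary occupancies recover 0.30/0.60/0.10,
and the liquid-like sub-tracks show near-linear MSD (α ≈ 1, apparent
D ≈ 0.11 µm²/s) — the pattern that identifies the intermediate state as
simple diffusion rather than confined or directed motion.

A CLI wraps the same functionality (`sptstates simulate-tracks`,
`simulate-palm`, `msd`, `rl`, `hmm`, `spatial`, `meanfield`); every
stochastic subcommand takes a mandatory `--seed`. For example:

```sh
sptstates meanfield --rho 0.8 --resolution 200
```

prints the free-energy minimizer at nucleosome density 0.8 with the
reference parameters (K=1000, z=6, δ=1.5, ε=μ=J=1 kBT), whose mobile
fraction x* ≈ 0.74 > 0.5: dense chromatin stabilizes the dynamic,
liquid-like binding mode.

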