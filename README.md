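# murodyn

Quantitative analysis of bacterial cell-wall synthesis dynamics, from
single molecules to populations.

Rod-shaped bacteria such as *E. coli* build and repair their
peptidoglycan wall with two kinds of machinery: the MreB-guided Rod
complex, which moves circumferentially as it inserts material, and
bifunctional class-A penicillin-binding proteins (PBP1a/PBP1b), which
bind transiently where synthesis is needed. `murodyn` implements the
measurements used to study this system:

* **Two-state single-molecule analysis** — the central statistic. A
  membrane protein switching between an immobile ("bound", presumably
  synthesis-engaged) and a diffusive state produces frame-to-frame
  displacement magnitudes distributed as a Rayleigh mixture

  ```
  p(r) = f_b · r/s_b² · exp(−r²/2s_b²) + (1−f_b) · r/s_f² · exp(−r²/2s_f²),
  s_i² = 2 D_i (ℓ·Δt) + 2 σ_loc²
  ```

  for frame lag ℓ, frame interval Δt and per-coordinate localization
  error σ_loc. Maximum-likelihood (or CDF least-squares) fitting of
  this mixture yields the bound fraction `f_b`, the free diffusion
  coefficient `D_free` and σ_loc; `D_bound` can be fixed at 0 or left
  free to verify immobility.
* **Spot detection and tracking** — bandpass filtering, subpixel 2-D
  Gaussian localization, detection capping, greedy nearest-neighbour
  linking with gap closing, temporal Gaussian smoothing.
* **Directed-motion statistics** — per-step velocity distributions and
  the flux statistic (summed end-to-end length of qualifying tracks
  per movie time per cell area), a proxy for Rod-complex activity.
* **Morphometrics** — total-regression cell axes, curvature-based pole
  detection, length/diameter, illumination-corrected fluorescence
  concentration, phase-contrast sharpness filtering.
* **Population kinetics** — Durbin-Watson-gated doubling-time fits,
  radiolabel incorporation/turnover kinetics with a shared turnover
  rate, osmotic-shock extension ratios with exact/Monte-Carlo
  permutation tests, and the muropeptide cross-linking index
  (dimers% + 2·trimers%).
* **Synthetic data** — every input the pipeline consumes can be
  generated with known ground truth, so each stage is verifiable by
  parameter recovery.

## Worked example

`examples/two_state_bound_fraction.py` simulates 5,000 trajectories at
the near-wild-type operating point (20% bound, D_free = 0.075 µm²/s,
σ_loc = 35 nm, Δt = 60 ms) and fits the mixture:

```
jumps used (lag 1): 34842
bound fraction:     19.5%  (95% CI 18.1-20.6%)
D_free:             0.0738 um^2/s
localization error: 35.0 nm
```

The bound fraction is the share of molecules in the near-immobile
state; its confidence interval comes from bootstrap resampling of
whole tracks. The other examples cover the imaging chain
(`detect_and_link.py`), directed-motion flux (`mreb_flux.py`),
morphometrics (`cell_morphometrics.py`), growth/incorporation
kinetics (`growth_and_incorporation.py`) and osmotic-shock statistics
(`osmotic_shock.py`); each prints the quantities it computes next to
the generating truth.

A thin CLI wraps the stage runner: `murodyn stages` lists the
available stages, `murodyn run --config cfg.yaml` executes one from a
YAML/JSON config and prints an artifact manifest with content hashes.

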