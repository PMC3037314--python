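# qsnoise

Stochastic dynamics and noise decomposition of quorum-sensing (QS)
autoinducers near the activation threshold.

## The problem

Gram-negative bacteria sense their population density by producing, exchanging
and detecting a small diffusible signaling molecule (an autoinducer such as an
acyl homoserine lactone).  Near the activation threshold the synthase gene is
expressed constitutively at a very low level — as little as one mRNA molecule
per cell at a time — so the signal a cell reads is corrupted by two distinct
noise sources: *transcriptional* noise from the random presence/absence of the
single transcript, and *intrinsic* (molecular) noise from the discreteness of
synthesis, degradation and transport events at ~20 molecules per cell.

`qsnoise` models a well-stirred population of `N` cells coupled through one
shared extracellular pool.  Per cell `i`:

    off_i ⇌ on_i            rates β (on), α (off)      — telegraph mRNA, M ∈ {0,1}
    on_i  → on_i + A_i      rate k₊                    — autoinducer synthesis
    A_i   → ∅               rate k₋                    — degradation/dilution
    A_i  ⇌  A_ext           rates D (out), r·D (in)    — membrane exchange
    A_ext → ∅               rate k₋                    — pool dilution

with `r = V/V_ext` the cell-to-medium volume ratio.  In units of the signal
lifetime `1/k₋` and the maximal concentration `c_A⁺ = k₊/(k₋V)`, neglecting
molecular noise, the intracellular concentration obeys

    dc̃/dt̃ = ĉ_M(t̃) + k₊_eff(⟨c̃⟩) − (1+D̃)·c̃ ,      D̃ = D/k₋ ,

driven by the dichotomous process ĉ_M ∈ {0,1}.  Its stationary law is known in
closed form — after the substitution x = (1+D̃)c̃ − k₊_eff it is a
Beta(β̃/(1+D̃), α̃/(1+D̃)) distribution — giving exact expressions for the
mean, support, shape class and squared coefficient of variation

    η²_tran = α̃(1+D̃+D̃Nr)² / [ β̃(1+D̃)(1+D̃Nr)²(1+D̃+α̃+β̃) ] .

The package provides:

* **`qsnoise.params`** — parameter sets, non-dimensionalization, nM↔count
  conversion, calibration of k₊ to a target mean, named presets γ₁–γ₄.
* **`qsnoise.analytics`** — the complete closed-form stationary theory.
* **`qsnoise.ssa`** — exact Gillespie simulation of the full N-cell system
  (numba-compiled), including a dual-reporter variant.
* **`qsnoise.pdmp`** — the reduced piecewise-deterministic process (the
  intrinsic-noise-free oracle).
* **`qsnoise.noise`** — noise decomposition η²_total = η²_int + η²_tran and
  the diffusion-scan experiment.
* **`qsnoise.cli`** — a `qsnoise` command with `analytics`, `simulate`,
  `dual`, `pdmp` and `scan` subcommands.

## Worked example

```python
>>> import qsnoise as q
>>> p = q.preset("gamma2", D_t=100)        # (α̃, β̃) = (15, 5), N=100, r=1e-5
>>> round(p.k_plus, 2)                     # k₊ calibrated so ⟨c_A⟩ = 25 nM
166.05
>>> q.classify_shape(15, 5, 100).name      # α̃, β̃ < 1+D̃: bimodal regime
'INTERIOR_MIN'
>>> round(q.transcriptional_noise(15, 5, 100, 100, 1e-5), 4)
2.0736
>>> r = q.ssa_run(p, t_end=800, t_burn=300, seed=1)
>>> round(r.mean_nM, 1), round(r.eta2_total, 2)
(24.9, 2.12)
```

The simulated total noise (2.12) exceeds the transcriptional closed form
(2.07) by the intrinsic contribution ≈ 1/n̄ ≈ 0.044, the inverse of the ~22.6
molecules per cell at 25 nM.  Scanning D̃ with `q.diffusion_scan` shows the
headline phenomenology: total noise *rises* with weak diffusion (a colored-
noise effect: the mRNA correlation time competes with the exchange time),
peaks near D̃ ≈ 10² at η² > 1 — where fluctuations exceed the mean — and
decays at strong diffusion, while the intrinsic component stays flat.
Biologically observed transport rates fall on either side of the peak.

Or from the shell:

```
qsnoise analytics --preset gamma2 --d-t 100 --out rec.json
qsnoise scan --preset gamma2 --grid 0,1,10,100,1000 --replicates 8 --seed 1 --out scan.csv
```

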