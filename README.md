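# revlearn

Modelling and statistics for probabilistic reversal-learning experiments in
volatile environments — the kind of task where two stimuli carry reciprocal
reward probabilities that change every few dozen trials, and where the
scientific questions are about how people track those changes and how their
belief updates show up in oscillatory neural activity.

The package is aimed at computational-psychiatry and cognitive-neuroscience
researchers who want a tested, seedable pipeline covering:

- **Task and agent simulation** — piecewise-constant contingency schedules
  (five mappings per 160-trial block, reversals every 26–38 trials), agents
  governed by the binary Hierarchical Gaussian Filter (HGF), and two-group
  synthetic cohorts.
- **Hierarchical Bayesian modelling** — forward filtering of the 2- and
  3-level binary HGF, three response models based on the unit-square sigmoid
  p(y=1) = m^ζ/(m^ζ + (1−m)^ζ) (fixed ζ, or volatility-coupled
  ζ_k = exp(−μ₃⁽ᵏ⁻¹⁾)), multi-start quasi-Newton MAP inversion with Laplace
  log-model evidence, and random-effects Bayesian model selection
  (expected frequencies and exceedance probabilities).
- **Behavioural statistics** — win-stay/lose-shift/switch rates, permutation
  and sign-flip tests with probability-of-superiority effect sizes and
  bootstrap CIs, a synchronised-rearrangement 2×2 factorial test, adaptive
  two-stage FDR, Spearman correlations.
- **Neural deconvolution** — Morlet time-frequency amplitude, a convolution
  GLM with Fourier basis sets that deconvolves overlapping event-locked
  responses (Y = Xβ, X = U∗B, response images Rᵢ = Bβᵢ), baseline
  normalisation, collinearity screening, and spectrotemporal cluster-based
  permutation tests with FWER control.

In the HGF, beliefs about the outcome tendency (level 2) and its
log-volatility (level 3) are coupled Gaussian random walks: the level-2 step
size is exp(κμ₃ + ω₂), so estimated volatility scales the learning rate.
Updates are precision-weighted prediction errors; for binary outcomes the
level-2 weight reduces to σ₂, giving ε₂ = σ₂δ₁.

## Worked example

```python
from revlearn import (AgentParams, generate_schedule, simulate_agent,
                      fit_map, summarize_behaviour, ceiling_win_rate)

schedule = generate_schedule(blocks=2, trials_per_block=160, seed=42)
print("ceiling win rate:", round(ceiling_win_rate(schedule), 3))

agent = AgentParams(omega2=-3.0, omega3=-6.0, mu3_0=1.0)   # volatile believer
trials, traj = simulate_agent(agent, schedule, model="hgf3_mu3", seed=7)
s = summarize_behaviour(trials)
print(f"win rate {s.win_rate:.3f}  lose-shift {s.lose_shift:.3f}  "
      f"switch {s.switch_rate:.3f}")

fit = fit_map(trials, model="hgf3_mu3", seed=0)
print("log-model evidence:", round(fit.lme, 1))
print("MAP omega2:", round(fit.map_params.omega2, 2),
      " mu3_0:", round(fit.map_params.mu3_0, 2))
```

Output:

```
ceiling win rate: 0.744
win rate 0.613  lose-shift 0.629  switch 0.470
log-model evidence: -214.8
MAP omega2: -1.29  mu3_0: 1.06
```

The ceiling win rate (0.744) is what an oracle choosing the currently
more-rewarded stimulus would earn on this schedule.  The simulated agent
holds a high initial volatility expectation (μ₃⁽⁰⁾ = 1), which makes its
decision noise large (ζ_k = e^(−μ₃) < 1), hence frequent switching (0.47)
and a win rate well below ceiling.  Refitting the generating model recovers
the initial volatility expectation almost exactly (1.06 vs 1.0); the tonic
volatility ω₂ is recovered with more error on a single session, consistent
with the package's parameter-recovery study.

Fitted estimators also come in scikit-learn form (`HGFEstimator`,
`ConvolutionGLM` with `fit`/`get_params` and trailing-underscore
attributes), and a thin CLI (`revlearn simulate|cohort|fit|bms|behav`)
wraps the same functions.

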