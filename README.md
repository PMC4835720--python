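# flynet

Directed interaction networks from fly trajectories, and stochastic
actor-oriented models (SAOMs) of how those networks evolve.

`flynet` is for behavioural ecologists who record small groups of
individually identified animals — here, groups of 8 *informed* and 4
*uninformed* female *Drosophila melanogaster* interacting in a 100 mm
arena for 4 h — and want to ask *who drives the interaction dynamics*:
which class of individuals starts contacts faster, receives them faster,
reciprocates, or sticks to its own class, and how those tendencies
change over the experiment. The pipeline:

1. **Extraction** (`flynet.trajectories`) — directed interaction events
   from per-frame tracked positions: proximity below 1.1 mean body
   lengths, persistence above five frames (0.5 s at 10 fps), the faster
   fly over the four preceding frames credited as initiator.
2. **Panels** (`flynet.netbuild`) — events binned into 10-min slices and
   binarized into directed adjacency matrices; consecutive slices
   screened with the Jaccard index (> 0.2 passes); replicates labelled
   Followed / Avoided from the uninformed flies' egg counts (proportion
   on the informed medium > 0.8 / < 0.2).
3. **SAOM engine** (`flynet.saom`) — network evolution as a
   continuous-time Markov chain: each actor gets `Poisson(λ)` change
   opportunities per period and toggles outgoing ties by a multinomial
   logit on the evaluation function `f_i(x) = Σ_k β_k s_ik(x)` over
   seven effects (density, recip, inPop, outAct, altX, egoX, sameX).
   Estimation is Method of Moments with first-observation conditioning,
   solved by Robbins–Monro stochastic approximation; multi-group fits
   share β across replicates with per-period, per-group rates; Wald
   tests, convergence t-ratios, forward stepwise selection and
   simulation-based goodness of fit included.
4. **Dynamics** (`flynet.dynamics`) — the monadic model
   (density + egoX + altX + sameX) refitted on windows of increasing
   length; the ego/alter Wald-t series regressed on time and condition,
   linear vs quadratic compared by F-test.
5. **Synthetic data** (`flynet.synthdata`) — arena trajectories with
   class-asymmetric contact behaviour, SAOM panels with known
   parameters, and egg counts, so the whole pipeline is testable without
   the original recordings.

See `docs/methods.md` for the model, estimator and generator details.

## Worked example

Simulate a panel from a known model and recover its parameters:

```python
from flynet import (EffectSpec, ModelSpec, MoMSettings,
                    generate_panel, fit_mom)

truth = ModelSpec([EffectSpec("density", -1.5),
                   EffectSpec("recip", 0.8),
                   EffectSpec("egoX", -0.5)])
panel = generate_panel(n_actors=12, covariate_split=(8, 4), n_periods=5,
                       model=truth, lam=4.0, seed=7)
fit = fit_mom(panel, truth, MoMSettings(seed=1))
print(fit.summary())
```

```
SAOM Method-of-Moments fit (converged=True, max |conv t| = 0.022)
    effect       est       se        t        p
   density   -1.1170   0.1642   -6.802   0.0000
     recip    0.1467   0.5598    0.262   0.7933
      egoX   -0.7431   0.2897   -2.565   0.0103
rates[sim]: 4.062 3.458 2.554 3.266
```

Each row is one effect: the Method-of-Moments estimate of its weight β
in the evaluation function, its standard error, the Wald t (= est/se)
and the two-sided normal p-value. Negative density means flies dissolve
more ties than chance would create (sparse networks); the estimates
land within one to two standard errors of the generating values
(−1.5, 0.8, −0.5) — a single 12-fly, 5-wave panel carries limited
information, which is why the real analysis pools many replicates in a
multi-group fit. The `rates` line is the estimated number of change
opportunities per fly per 10-min period (truth: 4). `converged=True`
reports the standard bar: every effect's convergence t-ratio below 0.1.

The full pipeline — synthetic arena recordings → events → panels →
screening → per-condition multi-group fits → incremental dynamics —
runs from one config:

```sh
flynet run-study --config study.yaml --seed 1 --out results/
```

with `study.yaml` as small as:

```yaml
synthetic:
  groups_per_condition: 2
effects: [density, recip, egoX, altX, sameX]
```

Each stage is also a separate subcommand (`flynet extract`,
`build-panel`, `screen`, `fit`, `gof`, `dynamics`, `trend`,
`simulate-traj`, `simulate-panel`).

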