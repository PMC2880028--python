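# kincal

Systematic calibration of mass-action ODE models of cell-signaling
networks — the kind of stiff, nonlinear, 10-100-parameter models used for
receptor-triggered apoptosis, where most rate constants are uncertain to
orders of magnitude and time-series data exist for only one or two
readouts.

Fitting all parameters of such a model at once is both hopeless
(unidentifiable) and wasteful (cost grows exponentially with dimension).
`kincal` implements a serial three-stage workflow instead:

1. **Qualitative validation.** Before spending any optimization budget,
   check the *signs* of the readout's sensitivity to initial protein
   concentrations against known biology.  The normalized local
   sensitivity S_ij(t) = (∂y_i/∂p_j)(p_j/y_i) is integrated over time,
   ∫|S_ij| dt, and averaged over parameter vectors sampled within their
   uncertainty bounds; keeping the sign of ∫S_ij dt instead gives a
   signed distribution per input.  An inhibitor whose sensitivity comes
   out positive means a structural model error — revise before fitting.
2. **Dominant-parameter selection.**  Rank all rate constants by three
   global sensitivity indices — the averaged local index above, and the
   Sobol first-order (S1_j) and total-effect (ST_j) variance fractions
   estimated by the Saltelli paired-matrix Monte-Carlo scheme (which
   needs no derivatives, so it also ranks discontinuous features such as
   the death delay time t_delay).  Ranked spectra are L-shaped; the
   dominant set is cut at the L-curve elbow (maximum chord distance in
   rank vs log-magnitude), typically ~8 parameters.
3. **Global estimation of the dominant subspace.**  Weighted least
   squares F(p) = Σ w_i(ŷ_i − y_i(p))² on plateau-censored data, with
   the non-dominant parameters pinned at nominal, minimized by any of:
   bounded L-BFGS-B from one start; deterministic multi-start from every
   point of the 3-level log grid (3^8 = 6561 starts for eight
   parameters); a (μ, λ) stochastic-ranking evolution strategy (SRES);
   or the SRES → L-BFGS-B hybrid that combines the global survey with
   fast local refinement.

All sampling, gridding and optimization happens in log10 parameter space
with multiplicative bound tiers (×100 / ×10 / ×2 around nominal), and
every stochastic step takes an explicit seed.

Because the networks this targets rarely ship with reusable data, the
package bundles a synthetic testbed: a 16-species snap-action death
cascade (receptor → initiator caspase → effector caspase → substrate
cleavage, with an inhibitor pool and a releasable pro-apoptotic store
that generate the characteristic long-delay/sharp-switch dynamics) plus
a generator for noisy single-cell-like reporter datasets with known
ground truth.  Every stage of the workflow is testable end-to-end
against that truth.

## Worked example

```python
import numpy as np
from kincal import (build_toy_cascade, toy_parameter_space, simulate,
                    extract_features, global_average_sensitivity,
                    qualitative_report)

model = build_toy_cascade()          # certified snap-action fixture
space = toy_parameter_space(model)   # tiered bounds around nominal
grid = np.linspace(0, 720, 241)      # 3-min reporter grid, minutes

feats = extract_features(simulate(model.with_initial(L=250.0), grid=grid))
print(f"t_delay = {feats.t_delay:.1f} min, t_switch = {feats.t_switch:.1f} min")

res = global_average_sensitivity(
    model.with_initial(L=250.0), space,
    inputs=["XIAP", "Smac_m", "pC6"], output="cleaved_fraction",
    times=grid, n_samples=24, seed=11)
print(qualitative_report(res, {"XIAP": "negative", "Smac_m": "positive",
                               "pC6": "insensitive"})
      [["input", "expectation", "median", "status"]].to_string(index=False))
```

prints

```
t_delay = 133.3 min, t_switch = 26.2 min
 input expectation    median status
  XIAP    negative -0.964319   PASS
Smac_m    positive  0.180940   PASS
   pC6 insensitive  0.000000   PASS
```

i.e. at the top ligand dose the simulated cell dies after a ~2.2 h delay
with a ~26 min switch; across 24 parameter-space samples the inhibitor
(XIAP analog) always *suppresses* cleavage, the mitochondrial store
(Smac analog) always *promotes* it, and the dispensable caspase-6-analog
branch has no effect — the model passes the qualitative gate.

The same workflow is scriptable from the shell:

```sh
kincal make-fixtures fixtures/
kincal qualitative config.yaml   # exit 1 if any expected sign fails
kincal rank config.yaml          # 3 rankings + elbow cutoffs + comparison
kincal calibrate config.yaml     # local | multistart | sres | hybrid
kincal sweep config.yaml         # fit-vs-k and cost-vs-k table
```

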