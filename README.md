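# concertsync

Surrogate-based analysis of audience synchrony: do the members of a
concert audience — each wired for heart rate, skin conductance and
respiration, and filmed from above for body movement — respond to the
music *together*?  The package implements the two synchrony statistics
used to answer that question, the preprocessing and motion-energy
extraction that feed them, the per-participant *synchrony contribution*
that links group synchrony to individual self-report, and the stepwise
regressions on trait/experience covariates.  A synthetic audience
generator with known ground truth makes every stage testable end to end
without access to recordings.

## The statistics

**SUSY (bivariate surrogate synchrony).**  Two series are cut into
segments of 30 s.  In each aligned segment pair the Pearson
cross-correlation r(τ) is computed at every lag τ ∈ ±5 s,
Fisher-transformed Z = atanh r, and averaged over lags and segments
without absolute values, so Z > 0 indicates in-phase and Z < 0
anti-phase coordination.  Misaligned segment pairings (i ≠ j) provide
n(n−1) surrogates that preserve each series' distribution and
within-segment autocorrelation while destroying temporal alignment.
The effect size is the z-score of real synchrony in its own null:

    ES = (Z_real − mean Z_surr) / sd Z_surr.

**mv-SUSY (multivariate, λmax method).**  All m movement series are cut
into 5-s segments; per segment, the largest eigenvalue λmax of the
m × m inter-participant correlation matrix measures the strength of the
leading common mode (λmax = 1 for mutual independence, m for identical
series).  Empirical synchrony is the mean segment λmax; the null
shuffles segment order independently within each series (1000
permutations), and ES is defined as above.

**Synchrony contribution.**  Per participant X: the mean ES of all
dyads containing X (SUSY channels), or ES_total − ES_without_X with
shared surrogate seeds (mv-SUSY).  Contributions are individual-level
scalars and serve as responses in stepwise backward regressions that
stop at the AIC minimum and then drop nonsignificant predictors.

**Motion energy.**  Movement per participant is the count of pixels
changing by more than a threshold between consecutive video frames
inside that participant's region of interest, at 15 frames/s.

## Worked example

```python
import numpy as np
from concertsync import (AudienceSpec, Channel, MvConfig, audience_susy,
                         generate_audience, mv_susy_concert, t_test_vs_zero)

spec = AudienceSpec(m=10, duration_s=300, seed=7,
                    gains=np.full(10, 0.6), lags_s=np.zeros(10))
channels, truth = generate_audience(spec)

dyads = audience_susy(channels[Channel.HR])["concert"]
es = [d.es for d in dyads.values() if not d.missing]
tt = t_test_vs_zero(es)
print(f"HR: mean dyadic ES = {np.mean(es):.2f}, t({tt.df}) = {tt.t:.2f}")

mv = mv_susy_concert(channels[Channel.MOVE], MvConfig(n_perm=1000, seed=7))
print(f"MOVE: lambda_max = {mv.lambda_max:.2f} vs surrogate "
      f"{mv.lambda_surr_mean:.2f}, ES = {mv.es:.1f}")
```

Output:

```
HR: mean dyadic ES = 0.58, t(44) = 15.50
MOVE: lambda_max = 2.14 vs surrogate 1.93, ES = 11.8
```

The 45 heart-rate dyads of this coupled audience average an effect size
of 0.58 surrogate standard deviations above the null (t strongly
significant), and the movement series share a common mode (λmax 2.14)
far above its shuffled null (11.8 surrogate SDs) — the audience is
synchronized by construction, and both statistics recover it.

The same pipeline runs from the shell:

```sh
sync simulate --m 10 --duration-s 300 --seed 7 --out concert/
sync run --in concert/ --out report/ --seed 7
```

which writes synchrony/test tables per piece and concert, contribution
tables, regression summaries and a run manifest.

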