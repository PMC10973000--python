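# dccabci

Riemannian decoding of motor-imagery EEG with detrended cross-correlation
features.

## The problem

Motor-imagery brain–computer interfaces classify short EEG epochs by their
spatial covariance structure: imagining a left- or right-hand movement
desynchronises the sensorimotor rhythm over the contralateral hemisphere,
which shows up as a class-dependent covariance pattern. Covariance matrices
are symmetric positive definite (SPD), so the natural classifier operates on
the SPD manifold: the **minimum-distance-to-mean (MDM)** rule stores one
Karcher mean per class and assigns each epoch to the nearest prototype under
the affine-invariant Riemannian metric (AIRM),

δ(P₁, P₂) = ‖log(P₁^{-1/2} P₂ P₁^{-1/2})‖_F.

Real EEG, however, is contaminated by slow local trends (electrode drift,
sweat, movement) that inflate the sample covariance matrix (SCM), and by
between-session covariance shifts. This package addresses both:

- **DCCA features.** Detrended cross-correlation analysis estimates the
  covariance of each channel pair from the residuals of ordinary
  least-squares line fits inside every window of *s* samples, averaged over
  windows — covariance with local non-stationarities removed. Done pairwise
  it yields an SPD matrix that replaces the SCM. A one-pass streaming form
  (rtDCCA) maintains running window sums so the matrix is available after
  every sample at constant per-sample cost, making the feature usable
  online.
- **Recentering.** Matrices are conjugated by the inverse square root of a
  reference (the Karcher mean of a session), aligning sessions; for online
  use the reference is updated causally along geodesics, epoch by epoch.

The package also provides the CSP+LDA benchmark decoder, the online
evidence-accumulation trial protocol (exponential smoothing, per-class
thresholds, 7-s timeout) and its metrics (accuracy, Cohen's κ, binomial
chance level, bar dynamics, command-delivery κ_norm), group statistics
(Friedman, Wilcoxon, Benjamini–Hochberg FDR, Lilliefors), exploratory
DCCC-network and DFA-topography contrasts, and a synthetic two-class EEG
generator so that every stage is testable without recordings.

Estimators follow scikit-learn conventions (`fit`/`transform`/`predict`,
`get_params`, trailing-underscore fitted attributes) and compose with
sklearn pipelines.

## Worked example

Train on one synthetic session, decode a second session (shifted covariance,
drift-contaminated) causally with adaptive recentering:

```python
import numpy as np
from dccabci import (GeneratorSpec, generate_session, DccaTransformer,
                     ShrinkageCovariance, Recenter, MDM, cohen_kappa,
                     chance_level)
from dccabci.synthetic import epochs_from_session
from dccabci.decode_eval import pseudo_online_replay, accuracy

spec = GeneratorSpec(n_channels=8, n_runs=1, trials_per_run=20,
                     trial_s=5.0, gap_s=1.0, seed=0)
train, test = generate_session(spec, 0), generate_session(spec, 1)
Xtr, ytr, _ = epochs_from_session(train, step_s=0.25)
Xte, yte, _ = epochs_from_session(test, step_s=0.25)

for name, tf in [("DCCA(s=128)", DccaTransformer(scale=128)),
                 ("SCM", ShrinkageCovariance())]:
    Ftr, Fte = tf.fit(Xtr).transform(Xtr), tf.transform(Xte)
    rc = Recenter().fit(Ftr)
    model = MDM().fit(rc.transform(Ftr), ytr)
    preds, _ = pseudo_online_replay(Fte, model, adaptation="adaptive",
                                    reference=rc.reference_)
    classes = list(model.classes_)
    t = np.zeros((2, 2))
    for a, b in zip(yte, preds):
        t[classes.index(a), classes.index(b)] += 1
    print(f"{name:12s} accuracy={accuracy(t):.3f} kappa={cohen_kappa(t):.3f}")
print(f"chance level (n={len(yte)} epochs): {chance_level(len(yte), 2):.3f}")
```

Output:

```
DCCA(s=128)  accuracy=0.953 kappa=0.906
SCM          accuracy=0.865 kappa=0.729
chance level (n=340 epochs): 0.582
```

Both decoders operate far above the p = 0.001 binomial chance level (0.582
for 340 test epochs), and the DCCA features absorb the injected polynomial
drifts that distort the sample covariance, giving the higher sample-wise
Cohen's κ (0.906 vs 0.729 on this seed).

A command-line surface wraps the same pipeline:

```bash
dccabci simulate --seed 1 --out session0
dccabci train --data session0 --features dcca --scale 128 --rebias --model m.json
dccabci evaluate --data session0 --model m.json --scheme adaptive --out metrics.csv
```

## Documentation

See `docs/methods.md` for the model, parameter and design notes, the
synthetic-data assumptions, and known limitations.
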