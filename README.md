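# vennose

**Venn-machine multiprobability prediction for electronic-nose sensor arrays.**

Electronic noses classify volatile samples from the joint response of an
array of cross-sensitive gas sensors. For risk-bearing decisions a predicted
label alone is not enough — the classifier must also say how likely that
label is to be right, and that probability must be *valid*: over many
predictions, the reported probabilities should match the observed frequency
of correct predictions. Classical probabilistic classifiers (naive Bayes,
softmax regression, Platt-calibrated SVMs) deliver a probability but rest on
parametric assumptions; when the model is misspecified — the normal
situation for real sensor data — the probabilities are biased even when the
labels are fine.

The Venn machine fixes this with a transductive construction. To predict a
label for a new object `x` given training examples `z_1..z_{n-1}`:

1. hypothesize each possible label `y ∈ Y` and form the augmented set
   `{z_1, …, z_{n-1}, (x, y)}`;
2. assign every example in the augmented set to a *category* via a
   **taxonomy** — here, the label predicted for it by a classifier trained
   on the remaining examples;
3. the empirical label distribution of the category containing `(x, y)` is
   row `p_y` of a `K×K` matrix `P`;
4. each column's *quality* is its minimum entry; predict the label `j_best`
   with the highest-quality column and report that column's
   `[min, max] = [P_l, P_u]` as the probability interval.

Under the single assumption that examples are i.i.d., the intervals are
valid: the cumulative count of correct predictions tracks the cumulative
interval bounds, whatever the underlying classifier. The package provides
three taxonomies — Gaussian naive Bayes, softmax regression, and one-vs-one
RBF SVMs (whose pairwise decision values are also Platt-calibrated and
coupled into point probabilities for the classical baseline) — plus the
validity criteria used to compare them:

- `d_ln` — mean log loss of the probability assigned to the predicted label
  (intervals first collapsed to the log-loss minimax point
  `p = P_u / (1 − P_l + P_u)`);
- `d_sq` — root-mean-square loss (square-loss minimax
  `p = P_u + P_l²/2 − P_u²/2`);
- `d1` — end-point gap between the average reported probability and the
  fraction of correct predictions (for intervals, the worse of the
  lower-bound and upper-bound gaps).

Feature extraction for raw sensor transients is included: baseline
subtraction `V = V_s − V_o`, then per sensor the maximal absolute response,
the area under the response curve, and min/max of the exponential moving
average of the derivative at three smoothing factors — 8 features per
sensor, min-max scaled to [0, 1] on training data only.

## Worked example

```python
import numpy as np
from vennose import select_from_matrix

P = np.array([[0.11, 0.78, 0.11],
              [0.00, 0.91, 0.09],
              [0.10, 0.70, 0.20]])
label, (p_lower, p_upper) = select_from_matrix(P, ("A", "B", "C"))
print(label, p_lower, p_upper)   # B 0.7 0.91
```

Column B's minimum entry (0.70) beats the other columns' (0.00, 0.09), so
the prediction is **B** with probability interval **[0.70, 0.91]**: the
claim is that this prediction is correct with probability at least 0.70 and
at most 0.91.

A full comparison on deliberately misspecified features
(`python examples/02_offline_comparison.py`):

```
method      rate    d_ln    d_sq      d1
nb        78.33%  0.9118  0.4168  0.1594
vm-nb     78.33%  0.5104  0.4059  0.0104
```

Same classifier, same accuracy — but the Venn predictor's reported
probabilities track the actual correct-prediction rate (d1 = 0.01 vs 0.16),
because its guarantee needs only i.i.d. sampling, not a correct model.
The other scripts in `examples/` walk through a single interval prediction,
an online run (validity holding at every step while the intervals narrow
from mean width 0.36 to 0.08), and the raw-sensor pipeline.

There is also a thin CLI:

```sh
vennose simulate --seed 3 --out-dir data/
vennose extract-features --recordings data/ --out features.csv
vennose predict-offline --data features.csv --method vm-svm --mode induct --out-dir run/
vennose predict-online  --data features.csv --method vm-nb --init-per-class 3 --seed 17 --out-dir run-online/
vennose evaluate-validity --pred run/predictions.csv --out report.json --plot validity.png
```

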