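"""One Venn multiprobability prediction, step by step.

Builds a small 3-class Gaussian training set, predicts one held-out
point with the naive-Bayes taxonomy, and prints the full probability
matrix: row y is the label distribution of the test point's category
when we *hypothesize* its label is y.  The predicted label is the
column whose worst-case (minimum) entry is highest, and the column's
min/max is the probability interval — the claim "this prediction is
correct with probability between P_l and P_u".
"""

import numpy as np

from vennose import default_class_means, generate_feature_table, venn_predict

data = generate_feature_table(20, default_class_means(3, 4, 1.9), 1.0, seed=11)
x = data.X[0]
train = data.without(0)

pred = venn_predict(train, x, taxonomy="nb", mode="loo")

print("label alphabet:", train.labels)
print("probability matrix P (rows = hypothesized label):")
for lab, row in zip(train.labels, pred.matrix):
    print(f"  {lab}: " + "  ".join(f"{v:.3f}" for v in row))
print(f"predicted label: {pred.label} (true label: {data.y[0]})")
print(f"probability interval: [{pred.p_lower:.3f}, {pred.p_upper:.3f}]")
print("-> the interval width reflects how much the hypothesis about the")
print("   test label can sway the empirical evidence; on larger training")
print("   sets it narrows toward a single probability.")
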