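"""Shared test fixtures: the worked-example matrix and an independent
brute-force Venn reimplementation (explicit loops, no shared code with
the package's own Venn machinery)."""

import numpy as np

WORKED_MATRIX = np.array([
    [0.11, 0.78, 0.11],
    [0.00, 0.91, 0.09],
    [0.10, 0.70, 0.20],
])


def brute_force_venn(X, y, labels, x):
    """Leave-one-out NB taxonomy, per-hypothesis category distribution,
    and the column rule — all as explicit Python loops."""
    from sklearn.naive_bayes import GaussianNB

    labels = list(labels)
    K = len(labels)
    P = []
    for y_hyp in labels:
        Xa = [list(row) for row in X] + [list(x)]
        ya = list(y) + [y_hyp]
        n = len(ya)
        cats = []
        for i in range(n):
            Xtr = [Xa[j] for j in range(n) if j != i]
            ytr = [ya[j] for j in range(n) if j != i]
            clf = GaussianNB()
            clf.fit(np.array(Xtr), np.array(ytr))
            cats.append(clf.predict(np.array([Xa[i]]))[0])
        target = cats[-1]
        member_labels = [ya[i] for i in range(n) if cats[i] == target]
        row = [sum(1 for lab in member_labels if lab == want) / len(member_labels)
               for want in labels]
        P.append(row)
    qualities = [min(P[i][j] for i in range(K)) for j in range(K)]
    j_best = qualities.index(max(qualities))  # first max: smallest index
    col = [P[i][j_best] for i in range(K)]
    return labels[j_best], min(col), max(col), np.array(P)
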