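"""Naive, loop-everything reference implementations of the four cluster
validity indices, evaluated straight from their definitions.  Deliberately
independent of the vectorised package code."""

import numpy as np


def naive_cvis(D, labels, medoid_indices):
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    k, n = len(uniq), len(labels)
    med = {u: medoid_indices[i] for i, u in enumerate(uniq)}
    clusters = {u: [i for i in range(n) if labels[i] == u] for u in uniq}

    # silhouette
    svals = []
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            svals.append(0.0)
            continue
        a = sum(D[i][j] for j in own if j != i) / (len(own) - 1)
        b = min(sum(D[i][j] for j in clusters[u]) / len(clusters[u])
                for u in uniq if u != labels[i])
        svals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    silhouette = sum(svals) / n

    # Calinski-Harabasz with medoid scatter
    gmed = min(range(n), key=lambda i: sum(D[i][j] for j in range(n)))
    W = sum(D[i][med[labels[i]]] ** 2 for i in range(n))
    B = sum(len(clusters[u]) * D[med[u]][gmed] ** 2 for u in uniq)
    ch = (B / (k - 1)) / (W / (n - k)) if W > 0 else float("nan")

    # COP
    cop = 0.0
    for u in uniq:
        mem = clusters[u]
        intra = sum(D[i][med[u]] for i in mem) / len(mem)
        outside = [j for j in range(n) if j not in mem]
        denom = min(max(D[i][j] for i in mem) for j in outside)
        cop += len(mem) * intra / denom
    cop /= n

    # modified Davies-Bouldin (DB*)
    S = {u: sum(D[i][med[u]] for i in clusters[u]) / len(clusters[u])
         for u in uniq}
    db = 0.0
    for u in uniq:
        others = [v for v in uniq if v != u]
        num = max(S[u] + S[v] for v in others)
        den = min(D[med[u]][med[v]] for v in others)
        db += num / den
    db /= k

    return {"silhouette": silhouette, "calinski_harabasz": ch,
            "cop": cop, "davies_bouldin_star": db}
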