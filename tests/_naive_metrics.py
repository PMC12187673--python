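"""Literal loop-based reference implementations of the 15 validity indices.

Written independently of the package's vectorized code paths: every index
is computed with plain Python loops straight from its definition, at
O(N^2)-O(N^3) cost, for use as a test oracle on small instances only.
"""

import math


def _groups(labels):
    order = sorted(set(labels))
    return [[i for i, l in enumerate(labels) if l == g] for g in order]


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _centroid(X, members):
    d = len(X[0])
    return [sum(X[i][j] for i in members) / len(members) for j in range(d)]


def naive_metric_vector(X, labels):
    X = [[float(v) for v in row] for row in X]
    n = len(X)
    d = len(X[0])
    groups = _groups(labels)
    k = len(groups)
    bary = _centroid(X, list(range(n)))
    cents = [_centroid(X, g) for g in groups]

    tss = sum(_dist(X[i], bary) ** 2 for i in range(n))
    e_t = sum(_dist(X[i], bary) for i in range(n))
    t_k = [sum(_dist(X[i], cents[c]) ** 2 for i in groups[c]) for c in range(k)]
    e_w = sum(_dist(X[i], cents[c]) for c in range(k) for i in groups[c])
    wc = sum(t_k)
    ball_hall = sum(t_k[c] / len(groups[c]) for c in range(k)) / k
    banfield = sum(len(groups[c]) * math.log(t_k[c] / len(groups[c])) for c in range(k))
    max_cd = max(_dist(cents[a], cents[b]) for a in range(k) for b in range(a + 1, k))
    min_cd = min(_dist(cents[a], cents[b]) for a in range(k) for b in range(a + 1, k))
    pbm = ((1.0 / k) * (e_t / e_w) * max_cd) ** 2

    wg_total = 0.0
    for c in range(k):
        ratios = []
        for i in groups[c]:
            own = _dist(X[i], cents[c])
            other = min(_dist(X[i], cents[c2]) for c2 in range(k) if c2 != c)
            ratios.append(own / other)
        wg_total += len(groups[c]) * max(0.0, 1.0 - sum(ratios) / len(ratios))
    wg = wg_total / n

    cluster_of = {}
    for c, g in enumerate(groups):
        for i in g:
            cluster_of[i] = c
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if cluster_of[i] == cluster_of[j] else between).append(
                _dist(X[i], X[j])
            )
    xie_beni = (wc / n) / min(between) ** 2
    ray_turi = (wc / n) / min_cd**2
    mclain_rao = (sum(within) / len(within)) / (sum(between) / len(between))
    all_d = sorted(within + between)
    nw = len(within)
    s_min = sum(all_d[:nw])
    s_max = sum(all_d[-nw:])
    c_index = (sum(within) - s_min) / (s_max - s_min) if s_max > s_min else 0.0
    dunn = min(between) / max(within)

    sil_cluster_means = []
    for c in range(k):
        vals = []
        for i in groups[c]:
            if len(groups[c]) == 1:
                vals.append(0.0)
                continue
            a = sum(_dist(X[i], X[j]) for j in groups[c] if j != i) / (len(groups[c]) - 1)
            b = min(
                sum(_dist(X[i], X[j]) for j in groups[c2]) / len(groups[c2])
                for c2 in range(k)
                if c2 != c
            )
            vals.append((b - a) / max(a, b))
        sil_cluster_means.append(sum(vals) / len(vals))
    silhouette = sum(sil_cluster_means) / k

    # Pearson correlation between pair distance and same-cluster indicator
    pairs = [
        (_dist(X[i], X[j]), 1.0 if cluster_of[i] == cluster_of[j] else 0.0)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    md = sum(p[0] for p in pairs) / len(pairs)
    mi = sum(p[1] for p in pairs) / len(pairs)
    cov = sum((p[0] - md) * (p[1] - mi) for p in pairs)
    vd = sum((p[0] - md) ** 2 for p in pairs)
    vi = sum((p[1] - mi) ** 2 for p in pairs)
    point_biserial = cov / math.sqrt(vd * vi)

    def _pop_var_norm(members):
        cen = _centroid(X, members)
        return math.sqrt(
            sum(
                (sum((X[i][j] - cen[j]) ** 2 for i in members) / len(members)) ** 2
                for j in range(d)
            )
        )

    sd_scattering = sum(_pop_var_norm(g) for g in groups) / k / _pop_var_norm(list(range(n)))
    sd_separation = (max_cd / min_cd) * sum(
        1.0 / sum(_dist(cents[a], cents[b]) for b in range(k) if b != a) for a in range(k)
    )

    return {
        "tss": tss,
        "wc_dispersion": wc,
        "ball_hall": ball_hall,
        "banfield_raftery": banfield,
        "pbm": pbm,
        "wemmert_gancarski": wg,
        "xie_beni": xie_beni,
        "ray_turi": ray_turi,
        "mclain_rao": mclain_rao,
        "c_index": c_index,
        "dunn": dunn,
        "silhouette": silhouette,
        "point_biserial": point_biserial,
        "sd_scattering": sd_scattering,
        "sd_separation": sd_separation,
    }
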