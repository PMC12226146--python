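"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from the defining formulas with no shared code
paths with :mod:`lesionnet`: triple-loop Floyd-Warshall, exhaustive simple-
path enumeration for betweenness, literal triangle sums for clustering,
explicit neighbour-subgraph rebuilds for local efficiency, pairwise
residualization for partial correlations, definitional sums of squares for
the mixed ANOVA, and a sort-and-cut ranking rule for hubscores.
"""

from __future__ import annotations

import itertools

import numpy as np

TIE_TOL = 1e-12


def lengths_from_weights(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    l = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i == j:
                l[i, j] = 0.0
            elif w[i, j] > 0:
                l[i, j] = 1.0 / w[i, j]
    return l


def floyd_warshall_oracle(lengths: np.ndarray) -> np.ndarray:
    d = lengths.copy().astype(float)
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def betweenness_enumeration_oracle(lengths: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive enumeration of all simple paths.

    For every unordered pair (s, t), finds all simple paths, keeps those
    whose total length is minimal (within TIE_TOL), and credits each
    intermediate node with (paths through it) / (number of shortest paths).
    """
    n = lengths.shape[0]
    b = np.zeros(n)
    adj = [
        [j for j in range(n) if j != i and np.isfinite(lengths[i, j])]
        for i in range(n)
    ]

    def all_paths(s, t):
        paths = []

        def dfs(node, visited, total):
            if node == t:
                paths.append((total, tuple(visited)))
                return
            for nxt in adj[node]:
                if nxt not in visited:
                    visited.append(nxt)
                    dfs(nxt, visited, total + lengths[node, nxt])
                    visited.pop()

        dfs(s, [s], 0.0)
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            shortest = [p[1] for p in paths if p[0] <= best + TIE_TOL]
            sigma = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                b[v] += through / sigma
    return b


def clustering_literal_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if wn[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(j + 1, n):
                if j == i or h == i:
                    continue
                total += (wn[i, j] * wn[j, h] * wn[i, h]) ** (1 / 3)
        out[i] = 2 * total / (k * (k - 1))
    return out


def local_efficiency_literal_oracle(w: np.ndarray) -> np.ndarray:
    """Rebuilds each neighbour subgraph explicitly; distances within it are
    Floyd-Warshall on cube-rooted connection lengths."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    out = np.zeros(n)
    for i in range(n):
        nbr = [j for j in range(n) if wn[i, j] > 0]
        k = len(nbr)
        if k < 2:
            continue
        m = len(nbr)
        sub_len = np.full((m, m), np.inf)
        for a in range(m):
            sub_len[a, a] = 0.0
            for c in range(m):
                if a != c and wn[nbr[a], nbr[c]] > 0:
                    sub_len[a, c] = (1.0 / wn[nbr[a], nbr[c]]) ** (1 / 3)
        d = floyd_warshall_oracle(sub_len)
        total = 0.0
        for a in range(m):
            for c in range(m):
                if a == c or not np.isfinite(d[a, c]) or d[a, c] == 0:
                    continue
                total += (wn[i, nbr[a]] * wn[i, nbr[c]]) ** (1 / 3) / d[a, c]
        out[i] = total / (k * (k - 1))
    return out


def local_assortativity_oracle(w: np.ndarray) -> np.ndarray:
    """Edge-by-edge accumulation of each node's contribution to the
    edge-weighted excess-strength correlation."""
    n = w.shape[0]
    s = w.sum(axis=1)
    edges = [(i, j, w[i, j]) for i in range(n) for j in range(n) if i != j and w[i, j] > 0]
    wts = np.array([e[2] for e in edges])
    x = np.array([s[i] - wt for i, _, wt in edges])
    y = np.array([s[j] - wt for _, j, wt in edges])
    wsum = wts.sum()
    xm = (wts * x).sum() / wsum
    ym = (wts * y).sum() / wsum
    sxx = (wts * (x - xm) ** 2).sum()
    syy = (wts * (y - ym) ** 2).sum()
    denom = np.sqrt(sxx * syy)
    out = np.zeros(n)
    for (i, _, _), wt, xv, yv in zip(edges, wts, x, y):
        out[i] += wt * (xv - xm) * (yv - ym) / denom
    return out


def partial_corr_residualization_oracle(x: np.ndarray) -> np.ndarray:
    """Partial correlations by residualizing each pair on all other columns
    (with intercept) and correlating the residuals."""
    t, n = x.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            design = np.column_stack([np.ones(t), x[:, others]])
            ri = x[:, i] - design @ np.linalg.lstsq(design, x[:, i], rcond=None)[0]
            rj = x[:, j] - design @ np.linalg.lstsq(design, x[:, j], rcond=None)[0]
            r = np.corrcoef(ri, rj)[0, 1]
            out[i, j] = out[j, i] = r
    return out


def hubscore_ranking_oracle(nodal: dict[str, np.ndarray], quantile: float = 0.2) -> np.ndarray:
    """Hubscores by explicit quantile thresholds on sorted values.

    Uses numpy's linear-interpolation quantile and the >=-top / <=-bottom
    tie rule, mirroring the documented convention so disagreements expose
    real ranking bugs rather than convention mismatches.
    """
    n = len(next(iter(nodal.values())))
    score = np.zeros(n, dtype=int)
    for metric, side in (
        ("strength", "top"),
        ("betweenness", "top"),
        ("path_length", "bottom"),
        ("clustering", "bottom"),
    ):
        vals = np.asarray(nodal[metric], dtype=float)
        defined = ~np.isnan(vals)
        v = np.sort(vals[defined])
        if side == "top":
            thr = np.quantile(v, 1 - quantile)
            met = (vals >= thr) & defined
        else:
            thr = np.quantile(v, quantile)
            met = (vals <= thr) & defined
        score += met.astype(int)
    return score


def mixed_anova_ss_oracle(values: np.ndarray, groups: np.ndarray) -> dict:
    """Definitional sums-of-squares mixed ANOVA for balanced designs.

    ``values`` is subjects x within-levels; ``groups`` assigns each subject
    to one of two groups of equal size.  Returns F statistics, partial eta
    squared per effect, and the Greenhouse-Geisser epsilon from the
    double-centred covariance of the within-level columns.
    """
    levels = np.unique(groups)
    assert len(levels) == 2
    n_subj, k = values.shape
    g = len(levels)
    n_per = n_subj // g
    assert all((groups == lev).sum() == n_per for lev in levels)

    grand = values.mean()
    subj_means = values.mean(axis=1)
    group_means = np.array([values[groups == lev].mean() for lev in levels])
    level_means = values.mean(axis=0)
    cell_means = np.array([values[groups == lev].mean(axis=0) for lev in levels])

    ss_total = ((values - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = n_per * k * ((group_means - grand) ** 2).sum()
    ss_err_between = ss_between_subj - ss_group
    ss_within_total = ss_total - ss_between_subj
    ss_level = n_subj * ((level_means - grand) ** 2).sum()
    ss_inter = n_per * (
        (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
    ).sum()
    ss_err_within = ss_within_total - ss_level - ss_inter

    df_group, df_err_b = g - 1, n_subj - g
    df_level, df_err_w = k - 1, (n_subj - g) * (k - 1)
    df_inter = (g - 1) * (k - 1)

    f_group = (ss_group / df_group) / (ss_err_between / df_err_b)
    f_level = (ss_level / df_level) / (ss_err_within / df_err_w)
    f_inter = (ss_inter / df_inter) / (ss_err_within / df_err_w)

    # GG epsilon from the double-centred covariance of the level columns.
    cov = np.cov(values, rowvar=False, ddof=1)
    centered = (
        cov
        - cov.mean(axis=0, keepdims=True)
        - cov.mean(axis=1, keepdims=True)
        + cov.mean()
    )
    eps = np.trace(centered) ** 2 / ((k - 1) * (centered**2).sum())

    return {
        "F_group": f_group,
        "F_level": f_level,
        "F_interaction": f_inter,
        "eta_p2_group": ss_group / (ss_group + ss_err_between),
        "eta_p2_level": ss_level / (ss_level + ss_err_within),
        "eta_p2_interaction": ss_inter / (ss_inter + ss_err_within),
        "gg_epsilon": eps,
        "df": {
            "group": (df_group, df_err_b),
            "level": (df_level, df_err_w),
            "interaction": (df_inter, df_err_w),
        },
    }


def mann_whitney_exact_oracle(a, b) -> float:
    """Two-sided exact p by enumeration of all group assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    na = len(a)

    def u_stat(xs, ys):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)

    u_obs = u_stat(a, b)
    mean_u = na * len(b) / 2
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def random_weighted_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric weight matrix in [0, 1], zero diagonal."""
    w = rng.uniform(0.05, 1.0, (n, n))
    mask = rng.random((n, n)) < density
    w = w * mask
    w = np.triu(w, k=1)
    w = w + w.T
    return w
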