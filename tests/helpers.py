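"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's computational paths: the likelihood
oracle enumerates every monotone latent-state history directly, the geometry
oracle is a pairwise-distance union-find, and the zonal oracle walks raster
cells one by one.
"""

import numpy as np


def brute_force_likelihood(y, p, phi):
    """Total probability of history ``y`` by enumerating extirpation years.

    The latent alive state is monotone non-increasing with z[1] = 1, so each
    history corresponds to a first-dead year tau in {2..T+1}; sum the Bernoulli
    products over all of them.  Returns (likelihood, P(alive at T | y)).
    """
    T = len(y)
    total = 0.0
    survived_term = 0.0
    for tau in range(2, T + 2):
        prior = phi ** (tau - 2) * ((1.0 - phi) if tau <= T else 1.0)
        like = 1.0
        possible = True
        for t in range(T):  # year t+1
            alive = (t + 1) < tau
            if alive:
                like *= p[t] if y[t] else (1.0 - p[t])
            elif y[t]:
                possible = False
                break
        if possible:
            contrib = prior * like
            total += contrib
            if tau == T + 1:
                survived_term = contrib
    return total, (survived_term / total if total > 0 else 0.0)


def params_for_history(p, phi):
    """Params/effort encoding an arbitrary per-year detection vector.

    With gamma0 = 0, beta_effort = 1 and e_t = logit(p_t), the model's
    detection probability reproduces p_t exactly; alpha = logit(phi) with zero
    covariates reproduces phi.
    """
    from cjspersist.likelihood import Params, logit

    params = Params(
        alpha=[float(logit(phi))],
        beta_hs=0.0,
        beta_rain=0.0,
        beta_imp=0.0,
        gamma0=0.0,
        beta_trend=0.0,
        beta_effort=1.0,
    )
    e = np.array([float(logit(pt)) for pt in p])
    return params, e


def union_find_from_distances(dist, max_dist):
    """Single-linkage component count from a full pairwise-distance matrix."""
    n = len(dist)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i][j] <= max_dist:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    return len({find(i) for i in range(n)})


def union_find_components(xy, max_dist):
    """Number of single-linkage components among planar points within ``max_dist``."""
    xy = np.asarray(xy, dtype=float)
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    return union_find_from_distances(d, max_dist)


def per_cell_zonal_mean(raster, polygon):
    """Zonal mean by looping raster cells and point-in-polygon testing centers."""
    from shapely.geometry import Point

    xs, ys = raster.cell_centers()
    vals = []
    for i in range(raster.nrows):
        for j in range(raster.ncols):
            v = raster.values[i, j]
            if np.isfinite(v) and polygon.contains(Point(xs[j], ys[i])):
                vals.append(v)
    return float(np.mean(vals)) if vals else np.nan
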