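"""Independent naive-loop reference implementations used only by tests.

Deliberately written in the most literal way possible (triple loops,
exhaustive pair enumeration, hand product-limit) so they share no code or
algorithmic shortcuts with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def naive_glcm(levels, mask, L, distance, directions):
    counts = np.zeros((L, L))
    nx, ny, nz = levels.shape
    for d in directions:
        dx, dy, dz = (distance * o for o in d)
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        continue
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        a, b = levels[x, y, z] - 1, levels[u, v, w] - 1
                        counts[a, b] += 1
                        counts[b, a] += 1
    return counts / counts.sum()


def naive_glcm_features(p):
    L = p.shape[0]
    ent = 0.0
    ct = 0.0
    con = 0.0
    iv = 0.0
    idn = 0.0
    px = [sum(p[i][j] for j in range(L)) for i in range(L)]
    py = [sum(p[i][j] for i in range(L)) for j in range(L)]
    mu_i = sum((i + 1) * p[i][j] for i in range(L) for j in range(L))
    mu_j = sum((j + 1) * p[i][j] for i in range(L) for j in range(L))
    hxy1 = 0.0
    for i in range(L):
        for j in range(L):
            v = p[i][j]
            if v > 0:
                ent -= v * math.log2(v)
                if px[i] * py[j] > 0:
                    hxy1 -= v * math.log2(px[i] * py[j])
            ct += ((i + 1) + (j + 1) - mu_i - mu_j) ** 2 * v
            con += (i - j) ** 2 * v
            if i != j:
                iv += v / (i - j) ** 2
            idn += v / (1 + abs(i - j) / L)
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hy = -sum(q * math.log2(q) for q in py if q > 0)
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    return {
        "entropy": ent,
        "cluster_tendency": ct,
        "contrast": con,
        "inverse_variance": iv,
        "information_measure": imc1,
        "idn": idn,
    }


def naive_ngtdm(levels, mask, L, eps=1e-6):
    nx, ny, nz = levels.shape
    s = np.zeros(L)
    n = np.zeros(L)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nb = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                                nb.append(levels[u, v, w])
                if not nb:
                    continue
                lev = levels[x, y, z]
                s[lev - 1] += abs(lev - sum(nb) / len(nb))
                n[lev - 1] += 1
    n_valid = n.sum()
    p = n / n_valid
    coarseness = 1.0 / (eps + float((p * s).sum()))
    complexity = 0.0
    for i in range(L):
        for j in range(L):
            if n[i] > 0 and n[j] > 0:
                complexity += (
                    abs((i + 1) - (j + 1))
                    * (p[i] * s[i] + p[j] * s[j])
                    / (n_valid * (p[i] + p[j]))
                )
    return coarseness, complexity


def naive_glrlm(levels, mask, L, directions):
    """Direction-averaged run-length matrix by literal line scanning."""
    nx, ny, nz = levels.shape
    maxlen = max(levels.shape)
    mats = []
    for d in directions:
        runs = {}
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        continue
                    # start of a run: predecessor missing or different
                    px_, py_, pz_ = x - d[0], y - d[1], z - d[2]
                    prev_same = (
                        0 <= px_ < nx and 0 <= py_ < ny and 0 <= pz_ < nz
                        and mask[px_, py_, pz_]
                        and levels[px_, py_, pz_] == levels[x, y, z]
                    )
                    if prev_same:
                        continue
                    length = 1
                    u, v, w = x + d[0], y + d[1], z + d[2]
                    while (
                        0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                        and mask[u, v, w]
                        and levels[u, v, w] == levels[x, y, z]
                    ):
                        length += 1
                        u, v, w = u + d[0], v + d[1], w + d[2]
                    runs[(levels[x, y, z], length)] = runs.get(
                        (levels[x, y, z], length), 0
                    ) + 1
        m = np.zeros((L, maxlen))
        for (lev, length), c in runs.items():
            m[lev - 1, length - 1] = c
        mats.append(m)
    return sum(mats) / len(mats)


def naive_gln(levels, mask, L, directions):
    r = naive_glrlm(levels, mask, L, directions)
    return float((r.sum(axis=1) ** 2).sum() / r.sum())


def naive_nestd_map(intensities, levels, mask, L, radius):
    nx, ny, nz = intensities.shape
    rng_roi = intensities[mask].max() - intensities[mask].min()
    out = np.full(intensities.shape, np.nan)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                vals, lvs = [], []
                for dx in range(-radius, radius + 1):
                    for dy in range(-radius, radius + 1):
                        for dz in range(-radius, radius + 1):
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                                vals.append(intensities[u, v, w])
                                lvs.append(levels[u, v, w])
                n = len(vals)
                ent = 0.0
                for lev in set(lvs):
                    f = lvs.count(lev) / n
                    ent -= f * math.log2(f)
                e_norm = ent / math.log2(L)
                mu = sum(vals) / n
                sd = math.sqrt(sum((v_ - mu) ** 2 for v_ in vals) / n)
                s_norm = sd / rng_roi if rng_roi > 0 else 0.0
                out[x, y, z] = e_norm - s_norm
    return out


def naive_cindex(scores, labels):
    num = 0.0
    den = 0
    for i, (si, yi) in enumerate(zip(scores, labels)):
        for sj, yj in zip(scores, labels):
            if yi == 1 and yj == 0:
                den += 1
                if si > sj:
                    num += 1.0
                elif si == sj:
                    num += 0.5
    return num / den


def naive_km(times, events):
    """Product-limit curve as [(t, S(t))] at each distinct event time."""
    order = sorted(set(t for t, e in zip(times, events) if e == 1))
    s = 1.0
    curve = []
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1 - d / at_risk
        curve.append((t, s))
    return curve


def naive_cox_loglik(beta, times, events, x):
    """Breslow/Efron-free partial likelihood for untied event times."""
    ll = 0.0
    for i, (ti, ei) in enumerate(zip(times, events)):
        if not ei:
            continue
        risk = [j for j, tj in enumerate(times) if tj >= ti]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll
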