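"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles (fixed-step
integration, definitional formulas, brute-force resampling) and shares no
code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from pdcest.bloch import _check_pools, _equilibrium, _evolution_matrix


def rk4_zspectrum(pools, sat, offsets, dt=1e-5):
    """Fixed-step RK4 integration of the same Bloch-McConnell ODE system,
    one constant-RF segment per pulse / delay (CW when n_pulses=1)."""
    water, solutes, mts = _check_pools(pools)
    m0 = _equilibrium(water, solutes, mts)
    out = []
    for off in offsets:
        y = m0.copy()
        segments = []
        for _ in range(sat.n_pulses):
            segments.append((sat.pulse_duration, sat.omega1))
            if sat.interpulse_delay > 0:
                segments.append((sat.interpulse_delay, 0.0))
        for duration, w1 in segments:
            a = _evolution_matrix(water, solutes, mts, sat, off, w1)
            n = int(round(duration / dt))
            for _ in range(n):
                k1 = a @ y
                k2 = a @ (y + 0.5 * dt * k1)
                k3 = a @ (y + 0.5 * dt * k2)
                k4 = a @ (y + dt * k3)
                y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y[2])
    return np.array(out)


def games_howell_hand(groups):
    """Long-form Games-Howell: explicit per-pair q statistic and
    Welch-Satterthwaite df, straight from the definitions."""
    out = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = np.asarray(groups[i], float), np.asarray(groups[j], float)
            na, nb = a.size, b.size
            va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            diff = a.mean() - b.mean()
            se = np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            q = abs(diff) * np.sqrt(2.0) / se
            p = sps.studentized_range.sf(q, k, df)
            out.append((diff, float(p), float(df)))
    return out


def permutation_ttest_pvalue(a, b, n_perm=20_000, seed=0):
    """Two-sided permutation p-value for the difference of means."""
    rng = np.random.default_rng(seed)
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[:n].mean() - perm[n:].mean()) >= observed - 1e-12
    return count / n_perm


def levene_hand(groups):
    """Levene's test computed as a one-way ANOVA on absolute deviations
    from the group means, from scratch."""
    devs = [np.abs(np.asarray(g, float) - np.mean(g)) for g in groups]
    k = len(devs)
    n_total = sum(d.size for d in devs)
    grand = np.concatenate(devs).mean()
    ssb = sum(d.size * (d.mean() - grand) ** 2 for d in devs)
    ssw = sum(((d - d.mean()) ** 2).sum() for d in devs)
    w = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = sps.f.sf(w, k - 1, n_total - k)
    return float(w), float(p)


def anova_regression(groups):
    """One-way ANOVA via an explicit dummy-coded linear model fit."""
    y = np.concatenate([np.asarray(g, float) for g in groups])
    k = len(groups)
    x = np.zeros((y.size, k))
    pos = 0
    for j, g in enumerate(groups):
        x[pos : pos + len(g), j] = 1.0
        pos += len(g)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    df_b, df_w = k - 1, y.size - k
    f = ((ss_tot - ss_res) / df_b) / (ss_res / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))
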