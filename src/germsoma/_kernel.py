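"""Numba kernels for the birth-death event loop.

State lives in flat buffers of capacity n+1 (the population transiently
holds one extra cell between daughter insertion and death).  ``break_after``
flags mark severed adjacencies; fragments are the maximal runs between
flags.  All randomness is consumed from a pre-drawn matrix of uniforms so
the kernel is bit-reproducible and independent of numba's own RNG state.

Per-step uniform layout (one row of ``u`` per event):

  0      reproducer selection (fitness-proportional)
  1      daughter placement side (< 0.5 left of parent, else right)
  2      daughter differentiation
  3..6   per-trait mutation occurrence
  7..10  per-trait mutation step, mapped to [-delta, +delta]
  11     death index, uniform over the n+1 cells present
"""

import numpy as np
from numba import njit

N_UNIFORMS = 12


@njit(cache=False)
def _fill_neighbors(break_after, j, n, reach, gaussian, sd, idx_buf, w_buf):
    """Collect the interacting neighbours of cell ``j`` along its fragment.

    Walks up to ``reach`` positions on each side, stopping at chain breaks,
    at full wraparound, and before any position is visited twice.  Returns
    the neighbour count; indices/weights are written into the buffers.
    """
    cnt = 0
    # rightwards
    p = j
    for d in range(1, reach + 1):
        if break_after[p] == 1:
            break
        p = (p + 1) % n
        if p == j:
            break
        idx_buf[cnt] = p
        if gaussian:
            w_buf[cnt] = np.exp(-(d * d) / (2.0 * sd * sd))
        else:
            w_buf[cnt] = 1.0
        cnt += 1
        if cnt >= n - 1:
            return cnt
    # leftwards
    p = j
    for d in range(1, reach + 1):
        prev = (p - 1) % n
        if break_after[prev] == 1:
            break
        p = prev
        if p == j:
            break
        idx_buf[cnt] = p
        if gaussian:
            w_buf[cnt] = np.exp(-(d * d) / (2.0 * sd * sd))
        else:
            w_buf[cnt] = 1.0
        cnt += 1
        if cnt >= n - 1:
            return cnt
    return cnt


@njit(cache=False)
def _exchange(
    pheno, traits, break_after, n, reach, gaussian, sd, gamma, symmetric, w_produce, g, h,
    idx_buf, w_buf,
):
    """Fill g (carbohydrate received by N-fixers) and h (fixed nitrogen
    received by photosynthetics).  Donor export is split over the donor's
    opposite-type neighbours in proportion to interaction weight; export
    with no eligible recipient is lost."""
    for i in range(n):
        g[i] = 0.0
        h[i] = 0.0
    # carbohydrate: photosynthetic donors -> nitrogen-fixing recipients
    for j in range(n):
        if pheno[j] == 1:
            cnt = _fill_neighbors(break_after, j, n, reach, gaussian, sd, idx_buf, w_buf)
            wsum = 0.0
            for t in range(cnt):
                if pheno[idx_buf[t]] == 0:
                    wsum += w_buf[t]
            if wsum > 0.0:
                give = (1.0 - traits[j, 0]) * w_produce
                for t in range(cnt):
                    i = idx_buf[t]
                    if pheno[i] == 0:
                        g[i] += give * w_buf[t] / wsum
    # fixed nitrogen: nitrogen-fixing donors -> photosynthetic recipients
    for j in range(n):
        if pheno[j] == 0:
            cnt = _fill_neighbors(break_after, j, n, reach, gaussian, sd, idx_buf, w_buf)
            wsum = 0.0
            for t in range(cnt):
                if pheno[idx_buf[t]] == 1:
                    wsum += w_buf[t]
            if wsum > 0.0:
                if symmetric:
                    export = (1.0 - traits[j, 2]) * w_produce
                else:
                    export = gamma * (1.0 - traits[j, 2]) * g[j]
                for t in range(cnt):
                    i = idx_buf[t]
                    if pheno[i] == 1:
                        h[i] += export * w_buf[t] / wsum


@njit(cache=False)
def _fitness(
    pheno, traits, cost_pending, g, h, n, sigma, eps, gamma, cost_frac, cost_const,
    cost_constant_mode, cost_active, symmetric, w_produce, W,
):
    """Division propensity per cell: growth limited by the scarcer resource,
    with the base fitness eps and any pending differentiation cost."""
    for i in range(n):
        if pheno[i] == 1:
            own = traits[i, 0] * w_produce
            w = eps + sigma * min(own, h[i])
        else:
            if symmetric:
                own = traits[i, 2] * w_produce
                w = eps + min(own, g[i])
            else:
                w = eps + gamma * traits[i, 2] * g[i] / (1.0 + gamma)
        if cost_active and cost_pending[i] == 1:
            if cost_constant_mode:
                w = max(w - cost_const, eps * 0.1)
            else:
                w = w * (1.0 - cost_frac)
        W[i] = w


@njit(cache=False)
def _run_steps(
    pheno, traits, cost_pending, break_after, n, u, events,
    sigma, eps, gamma, cost_frac, cost_const, cost_constant_mode, cost_active,
    reach, gaussian, sd, symmetric, broken, mu, delta, w_produce,
):
    """Execute ``u.shape[0]`` birth-death events in place.

    Buffers have capacity n+1; the first n entries are the population.
    ``events`` rows receive (reproducer, side, differentiated, mutation
    mask, death index)."""
    g = np.empty(n + 1)
    h = np.empty(n + 1)
    W = np.empty(n + 1)
    idx_buf = np.empty(n + 1, np.int64)
    w_buf = np.empty(n + 1)
    for t in range(u.shape[0]):
        _exchange(
            pheno, traits, break_after, n, reach, gaussian, sd, gamma, symmetric,
            w_produce, g, h, idx_buf, w_buf,
        )
        _fitness(
            pheno, traits, cost_pending, g, h, n, sigma, eps, gamma, cost_frac,
            cost_const, cost_constant_mode, cost_active, symmetric, w_produce, W,
        )
        # fitness-proportional reproduction
        total = 0.0
        for i in range(n):
            total += W[i]
        target = u[t, 0] * total
        acc = 0.0
        r = n - 1
        for i in range(n):
            acc += W[i]
            if acc >= target:
                r = i
                break
        cost_pending[r] = 0
        # daughter insertion: cell index ins, edge flag inserted at parent's
        # original index r (parent-daughter edge is always intact)
        right = u[t, 1] >= 0.5
        if right:
            ins = r + 1
            parent = r
        else:
            ins = r
            parent = r + 1
        for i in range(n, ins, -1):
            pheno[i] = pheno[i - 1]
            cost_pending[i] = cost_pending[i - 1]
            for k in range(4):
                traits[i, k] = traits[i - 1, k]
        for i in range(n, r, -1):
            break_after[i] = break_after[i - 1]
        break_after[r] = 0
        pheno[ins] = pheno[parent]
        cost_pending[ins] = 0
        for k in range(4):
            traits[ins, k] = traits[parent, k]
        # differentiation of the daughter, per the parent's phenotype
        if pheno[parent] == 1:
            p_d = traits[parent, 1]
        else:
            p_d = traits[parent, 3]
        differentiated = 0
        if u[t, 2] < p_d:
            pheno[ins] = 1 - pheno[ins]
            differentiated = 1
            if cost_active:
                cost_pending[ins] = 1
        # per-trait mutation of the daughter
        mut_mask = 0
        for k in range(4):
            if u[t, 3 + k] < mu:
                mut_mask |= 1 << k
                v = traits[ins, k] + (2.0 * u[t, 7 + k] - 1.0) * delta
                if v < 0.0:
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                traits[ins, k] = v
        # uniform random death over the n+1 cells now present
        m = n + 1
        d = int(u[t, 11] * m)
        if d >= m:
            d = m - 1
        merged = 1 if broken else 0
        for i in range(d, m - 1):
            pheno[i] = pheno[i + 1]
            cost_pending[i] = cost_pending[i + 1]
            for k in range(4):
                traits[i, k] = traits[i + 1, k]
        if d == 0:
            for i in range(0, m - 2):
                break_after[i] = break_after[i + 1]
            break_after[m - 2] = merged
        else:
            break_after[d - 1] = merged
            for i in range(d, m - 1):
                break_after[i] = break_after[i + 1]
        events[t, 0] = r
        events[t, 1] = 1 if right else 0
        events[t, 2] = differentiated
        events[t, 3] = mut_mask
        events[t, 4] = d
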