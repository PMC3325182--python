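"""Pure-Python reference implementation of one birth-death event.

Independent of the numba kernel but consuming the identical per-step
uniform layout, so kernel and reference can be compared state-for-state.
Written for clarity, not speed: plain lists, explicit neighbour walks,
naive double loops.
"""

from __future__ import annotations

import math

import numpy as np


def ref_neighbors(break_after, j, n, reach, gaussian, sd):
    """(index, weight) pairs for cell j, walking each side up to reach."""
    out = []
    seen = {j}
    p = j
    for d in range(1, reach + 1):
        if break_after[p]:
            break
        p = (p + 1) % n
        if p in seen:
            break
        seen.add(p)
        w = math.exp(-(d * d) / (2 * sd * sd)) if gaussian else 1.0
        out.append((p, w))
    p = j
    for d in range(1, reach + 1):
        prev = (p - 1) % n
        if break_after[prev]:
            break
        p = prev
        if p in seen:
            break
        seen.add(p)
        w = math.exp(-(d * d) / (2 * sd * sd)) if gaussian else 1.0
        out.append((p, w))
    return out


def ref_exchange(pheno, traits, break_after, reach, gaussian, sd, gamma, symmetric, w_produce):
    """Naive double-loop evaluation of the resource flows g and h."""
    n = len(pheno)
    g = [0.0] * n
    h = [0.0] * n
    for j in range(n):
        if pheno[j] != 1:
            continue
        nbrs = ref_neighbors(break_after, j, n, reach, gaussian, sd)
        wsum = sum(w for i, w in nbrs if pheno[i] == 0)
        if wsum > 0:
            give = (1.0 - traits[j][0]) * w_produce
            for i, w in nbrs:
                if pheno[i] == 0:
                    g[i] += give * w / wsum
    for j in range(n):
        if pheno[j] != 0:
            continue
        nbrs = ref_neighbors(break_after, j, n, reach, gaussian, sd)
        wsum = sum(w for i, w in nbrs if pheno[i] == 1)
        if wsum > 0:
            if symmetric:
                export = (1.0 - traits[j][2]) * w_produce
            else:
                export = gamma * (1.0 - traits[j][2]) * g[j]
            for i, w in nbrs:
                if pheno[i] == 1:
                    h[i] += export * w / wsum
    return g, h


def ref_fitness(pheno, traits, cost_pending, g, h, params):
    n = len(pheno)
    W = [0.0] * n
    for i in range(n):
        if pheno[i] == 1:
            w = params.eps_base + params.sigma * min(traits[i][0] * params.w_produce, h[i])
        elif params.symmetric_variant:
            w = params.eps_base + min(traits[i][2] * params.w_produce, g[i])
        else:
            w = params.eps_base + params.gamma * traits[i][2] * g[i] / (1 + params.gamma)
        if params.cost_active and cost_pending[i]:
            if params.cost_mode == "constant":
                w = max(w - params.cost_const, params.eps_base * 0.1)
            else:
                w *= 1.0 - params.cost_frac
        W[i] = w
    return W


def ref_step(state, params, u):
    """One event on a plain-list state dict {pheno, traits, cost, flags}."""
    from germsoma.resource_exchange import interaction_reach

    pheno = state["pheno"]
    traits = state["traits"]
    cost = state["cost"]
    flags = state["flags"]
    n = len(pheno)
    reach = interaction_reach(params)
    gaussian = params.kernel == "gaussian"
    g, h = ref_exchange(
        pheno, traits, flags, reach, gaussian, params.gaussian_sd,
        params.gamma, params.symmetric_variant, params.w_produce,
    )
    W = ref_fitness(pheno, traits, cost, g, h, params)
    target = u[0] * sum(W)
    acc = 0.0
    r = n - 1
    for i in range(n):
        acc += W[i]
        if acc >= target:
            r = i
            break
    cost[r] = 0
    right = u[1] >= 0.5
    ins = r + 1 if right else r
    parent = r if right else r + 1
    pheno.insert(ins, None)
    traits.insert(ins, None)
    cost.insert(ins, 0)
    flags.insert(r, 0)
    pheno[ins] = pheno[parent]
    traits[ins] = list(traits[parent])
    p_d = traits[parent][1] if pheno[parent] == 1 else traits[parent][3]
    if u[2] < p_d:
        pheno[ins] = 1 - pheno[ins]
        if params.cost_active:
            cost[ins] = 1
    for k in range(4):
        if u[3 + k] < params.mu_mut:
            v = traits[ins][k] + (2 * u[7 + k] - 1) * params.delta_mut
            traits[ins][k] = min(1.0, max(0.0, v))
    m = n + 1
    d = min(int(u[11] * m), m - 1)
    merged = 1 if params.topology == "broken" else 0
    del pheno[d], traits[d], cost[d]
    if d == 0:
        del flags[0]
        flags[m - 2] = merged
    else:
        flags[d - 1] = merged
        del flags[d]
    return state


def state_from_population(pop):
    return {
        "pheno": [int(x) for x in pop.phenotype],
        "traits": [list(map(float, row)) for row in pop.traits],
        "cost": [int(x) for x in pop.cost_pending],
        "flags": [int(x) for x in pop.break_after],
    }


def state_arrays(state):
    return (
        np.array(state["pheno"], dtype=np.int8),
        np.array(state["traits"], dtype=float),
        np.array(state["cost"], dtype=np.uint8),
        np.array(state["flags"], dtype=np.uint8),
    )
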