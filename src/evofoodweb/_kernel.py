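"""Numba-compiled inner loops for per-habitat equilibration.

These kernels duplicate, for speed, the reference-path computations in
:mod:`evofoodweb.trophic_network` and :mod:`evofoodweb.biomass_equilibrium`
(Gaussian kernel strengths, competition-normalized shares, the linear
biomass solve, and the one-at-a-time extinction cascade).  The test suite
asserts agreement between the two paths on randomized webs; any change here
must keep that agreement.

Trophic levels are computed by Jacobi iteration of
``TL_i = 1 + mean(TL of prey)`` with the resource at level 0.  Self-links
are excluded from a species' own prey set, and species without any prey are
assigned the sentinel 0.0 and are skipped when averaging over a consumer's
prey (such species carry no biomass and are removed by the cascade in the
same step).  Post-cascade, every species has an energy path to the
resource, which makes the iteration a contraction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "strength_matrix_nb",
    "equilibrate_nb",
    "cascade_nb",
    "trophic_levels_nb",
]


@njit(cache=False)
def strength_matrix_nb(m, f, s, cutoff):
    """Gaussian kernel strengths with hard cutoff; shape (n, n+1), resource col 0."""
    n = m.size
    a = np.zeros((n, n + 1))
    for i in range(n):
        si = s[i]
        lim = cutoff * si
        for jj in range(n + 1):
            mj = 0.0 if jj == 0 else m[jj - 1]
            d = f[i] - mj
            if d < 0.0:
                d = -d
            if d <= lim:
                a[i, jj] = np.exp(-(d * d) / (2.0 * si))
    return a


@njit(cache=False)
def equilibrate_nb(a, active, lam, delta, R):
    """Solve the donor-controlled transport system over the active species.

    Gains are lambda times the species' shares of its prey's biomass;
    losses are lambda times the predation pressure on the species itself,
    so community biomass totals exactly R.  Returns a length-n vector with
    0 entries for inactive (and prey-less) species.  Shares are recomputed
    over the active predator set of every prey column, so a removal
    upstream automatically renormalizes the survivors' shares.
    """
    n = a.shape[0]
    B = np.zeros(n)
    idx = np.empty(n, np.int64)
    k = 0
    for i in range(n):
        if active[i]:
            idx[k] = i
            k += 1
    if k == 0:
        return B
    gamma = np.zeros((k, k + 1))
    for cp in range(k + 1):
        j = 0 if cp == 0 else idx[cp - 1] + 1
        amax = 0.0
        for ii in range(k):
            v = a[idx[ii], j]
            if v > amax:
                amax = v
        if amax <= 0.0:
            continue
        ssum = 0.0
        for ii in range(k):
            v = a[idx[ii], j]
            if v > 0.0:
                da = (amax - v) / delta
                fv = np.exp(-da * da)
                gamma[ii, cp] = fv
                ssum += fv
        for ii in range(k):
            gamma[ii, cp] /= ssum
    M = np.eye(k)
    for j2 in range(k):
        colsum = 0.0
        for i in range(k):
            colsum += gamma[i, j2 + 1]
        M[j2, j2] += lam * colsum  # predation loss, proportional to own biomass
        for i in range(k):
            M[i, j2] -= lam * gamma[i, j2 + 1]
    b = gamma[:, 0] * R
    x = np.linalg.solve(M, b)
    for ii in range(k):
        bv = x[ii]
        if bv > 0.0:
            B[idx[ii]] = bv
    return B


@njit(cache=False)
def cascade_nb(a, ids, lam, delta, R, thr, batch):
    """Equilibrate, then remove sub-threshold species until all are viable.

    With ``batch`` False, one species is removed per round: smallest
    biomass strictly below ``thr`` first, ties broken by smaller species
    id.  With ``batch`` True every sub-threshold species is removed in the
    same round.  The system is re-solved after every round; the returned
    round numbers start at 1 (rounds >= 2 are secondary extinctions).
    Returns (final biomasses, active mask, removal indices in order,
    biomass of each at removal, removal round of each).
    """
    n = a.shape[0]
    active = np.ones(n, np.bool_)
    removed = np.empty(n, np.int64)
    removed_B = np.empty(n)
    removed_round = np.empty(n, np.int64)
    nr = 0
    B = np.zeros(n)
    rnd = 0
    while True:
        B = equilibrate_nb(a, active, lam, delta, R)
        rnd += 1
        if batch:
            any_rm = False
            for i in range(n):
                if active[i] and B[i] < thr:
                    active[i] = False
                    removed[nr] = i
                    removed_B[nr] = B[i]
                    removed_round[nr] = rnd
                    nr += 1
                    any_rm = True
            if not any_rm:
                break
        else:
            pick = -1
            bmin = 0.0
            for i in range(n):
                if active[i] and B[i] < thr:
                    if (
                        pick == -1
                        or B[i] < bmin
                        or (B[i] == bmin and ids[i] < ids[pick])
                    ):
                        pick = i
                        bmin = B[i]
            if pick == -1:
                break
            active[pick] = False
            removed[nr] = pick
            removed_B[nr] = bmin
            removed_round[nr] = rnd
            nr += 1
    return B, active, removed[:nr], removed_B[:nr], removed_round[:nr]


@njit(cache=False)
def trophic_levels_nb(a, active, tol=1e-10, max_iter=2000):
    """Trophic levels of the active species by Jacobi iteration.

    ``TL_i = 1 + mean(TL_j over prey j)`` with resource level 0; self-links
    ignored; prey-less species carry the sentinel 0.0 and do not enter
    other species' prey averages.  Inactive entries are 0.0.
    """
    n = a.shape[0]
    cur = np.zeros(n)
    has_prey = np.zeros(n, np.bool_)
    for i in range(n):
        if not active[i]:
            continue
        if a[i, 0] > 0.0:
            has_prey[i] = True
        else:
            for j in range(n):
                if j != i and active[j] and a[i, j + 1] > 0.0:
                    has_prey[i] = True
                    break
        if has_prey[i]:
            cur[i] = 1.0
    new = np.zeros(n)
    for _ in range(max_iter):
        maxdiff = 0.0
        for i in range(n):
            if not (active[i] and has_prey[i]):
                new[i] = 0.0
                continue
            tot = 0.0
            cnt = 0
            if a[i, 0] > 0.0:
                cnt += 1  # resource contributes level 0
            for j in range(n):
                if j != i and active[j] and has_prey[j] and a[i, j + 1] > 0.0:
                    tot += cur[j]
                    cnt += 1
            v = 1.0 + tot / cnt if cnt > 0 else 0.0
            new[i] = v
            d = v - cur[i]
            if d < 0.0:
                d = -d
            if d > maxdiff:
                maxdiff = d
        tmp = cur
        cur = new
        new = tmp
        if maxdiff < tol:
            break
    return cur
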