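"""Numba-compiled inner loops for the Metropolis-Hastings chain.

The kernels consume pre-generated blocks of random numbers (proposal
indices, displacement vectors, acceptance uniforms) so that the exact
same trajectory can be reproduced by the pure-Python reference path in
:mod:`chromosampler.sampler`, which consumes the same arrays.

Both kernels mutate ``points`` and the cache arrays in place and write
snapshots of the conformation whenever the global iteration counter hits
one of the (sorted) ``snap_iters``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_SQRT_2PI = 0.9189385332046727


@njit(cache=True)
def run_leg_5c(points, logterms, total, values, sigmas,
               nbr_ptr, nbr_pair, nbr_other, alpha, psi,
               idx_arr, disp_arr, uacc_arr,
               t_start, snap_iters, snap_out, greedy):
    """Advance a 5C chain by ``len(idx_arr)`` proposals.

    Returns ``(total, accepted, n_snapshots_written)``.
    """
    n_steps = idx_arr.shape[0]
    n_snap = snap_iters.shape[0]
    sp = 0
    accepted = 0
    new_terms = np.empty(nbr_pair.shape[0], dtype=np.float64)
    for s in range(n_steps):
        i = idx_arr[s]
        nx = points[i, 0] + disp_arr[s, 0]
        ny = points[i, 1] + disp_arr[s, 1]
        nz = points[i, 2] + disp_arr[s, 2]
        a = nbr_ptr[i]
        b = nbr_ptr[i + 1]
        delta = 0.0
        for q in range(a, b):
            j = nbr_other[q]
            dx = nx - points[j, 0]
            dy = ny - points[j, 1]
            dz = nz - points[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= 0.0:
                term = -np.inf
            else:
                p = nbr_pair[q]
                mu = psi * np.sqrt(d2) ** (-alpha)
                z = (values[p] - mu) / sigmas[p]
                term = -0.5 * z * z - np.log(sigmas[p]) - LOG_SQRT_2PI
            new_terms[q] = term
            delta += term - logterms[nbr_pair[q]]
        if greedy:
            acc = delta > 0.0
        else:
            acc = delta >= 0.0 or uacc_arr[s] < np.exp(delta)
        if acc:
            points[i, 0] = nx
            points[i, 1] = ny
            points[i, 2] = nz
            for q in range(a, b):
                logterms[nbr_pair[q]] = new_terms[q]
            total += delta
            accepted += 1
        t = t_start + s + 1
        if sp < n_snap and t == snap_iters[sp]:
            for ii in range(points.shape[0]):
                snap_out[sp, ii, 0] = points[ii, 0]
                snap_out[sp, ii, 1] = points[ii, 1]
                snap_out[sp, ii, 2] = points[ii, 2]
            sp += 1
    return total, accepted, sp


@njit(cache=True)
def run_leg_hic(points, dpow, sum_dpow, total, values, total_reads, kappa,
                nbr_ptr, nbr_pair, nbr_other, alpha,
                idx_arr, disp_arr, uacc_arr,
                t_start, snap_iters, snap_out, greedy):
    """Advance a Hi-C chain; the count-scale normalization couples all
    pairs, so each step re-sums the likelihood over all measured pairs.

    Returns ``(total, sum_dpow, accepted, n_snapshots_written)``.
    """
    n_steps = idx_arr.shape[0]
    n_pairs = values.shape[0]
    n_snap = snap_iters.shape[0]
    sp = 0
    accepted = 0
    new_dpow = np.empty(nbr_pair.shape[0], dtype=np.float64)
    for s in range(n_steps):
        i = idx_arr[s]
        nx = points[i, 0] + disp_arr[s, 0]
        ny = points[i, 1] + disp_arr[s, 1]
        nz = points[i, 2] + disp_arr[s, 2]
        a = nbr_ptr[i]
        b = nbr_ptr[i + 1]
        ok = True
        sum_new = sum_dpow
        for q in range(a, b):
            j = nbr_other[q]
            dx = nx - points[j, 0]
            dy = ny - points[j, 1]
            dz = nz - points[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= 0.0:
                ok = False
                break
            nd = np.sqrt(d2) ** (-alpha)
            new_dpow[q] = nd
            sum_new += nd - dpow[nbr_pair[q]]
        if ok:
            # swap in the tentative dpow values, compute, swap back on reject
            for q in range(a, b):
                p = nbr_pair[q]
                tmp = dpow[p]
                dpow[p] = new_dpow[q]
                new_dpow[q] = tmp
            beta = total_reads / sum_new
            new_total = 0.0
            for p in range(n_pairs):
                m = beta * dpow[p]
                var = m + kappa
                r = values[p] - m
                new_total += -0.5 * np.log(2.0 * np.pi * var) \
                    - 0.5 * r * r / var
            delta = new_total - total
            if greedy:
                acc = delta > 0.0
            else:
                acc = delta >= 0.0 or uacc_arr[s] < np.exp(delta)
            if acc:
                points[i, 0] = nx
                points[i, 1] = ny
                points[i, 2] = nz
                sum_dpow = sum_new
                total = new_total
                accepted += 1
            else:
                for q in range(a, b):
                    dpow[nbr_pair[q]] = new_dpow[q]
        t = t_start + s + 1
        if sp < n_snap and t == snap_iters[sp]:
            for ii in range(points.shape[0]):
                snap_out[sp, ii, 0] = points[ii, 0]
                snap_out[sp, ii, 1] = points[ii, 1]
                snap_out[sp, ii, 2] = points[ii, 2]
            sp += 1
    return total, sum_dpow, accepted, sp
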