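"""Jit-compiled time stepper for the compartmental cable system.

One backward-Euler step solves the voltage system with channel conductances
frozen at the gate values advanced (exactly, via exp(-dt/tau)) at the
start-of-step voltage. The linear solve is a direct two-sweep elimination on
the tree (compartments are topologically ordered, so a single child->parent
pass triangularizes the symmetric Hines matrix).
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_steps(V, gates, nsteps, dt,
              parent, g_ax, C, g_leak, e_leak,
              chan_g, chan_E, gate_chan, gate_exp,
              inf_tab, etau_tab, v0, dv,
              drive, drive_on, drive_off,
              rec_idx, rec_every, rec_out,
              compute_resid):
    """Advance the system ``nsteps`` steps of size ``dt`` in place.

    Returns (status, err_step, err_comp, max_rel_residual, last_step_max_dV)
    with status 0 = ok, 1 = divergence (|V| > 500 mV or NaN).
    """
    n = V.shape[0]
    ngate = gates.shape[0]
    nchan = chan_g.shape[0]
    nd = drive.shape[0]
    ntab = inf_tab.shape[1]
    nrec = rec_idx.shape[0]

    diag = np.empty(n)
    rhs = np.empty(n)
    gsum = np.empty(n)
    gesum = np.empty(n)
    Vold = np.empty(n)
    drv = np.zeros(n)
    openf = np.empty((nchan, n)) if nchan > 0 else np.empty((1, n))
    ax = np.zeros(n)
    delim = np.empty(n)   # eliminated diagonal
    fmul = np.empty(n)    # elimination multipliers
    relim = np.empty(n)   # work vector for solves
    resv = np.empty(n)    # refinement residual

    for r in range(nrec):
        rec_out[r, 0] = V[rec_idx[r]]
    rec_col = 0
    max_resid = 0.0
    last_delta = 0.0

    for step in range(1, nsteps + 1):
        # exact exponential gate update at frozen start-of-step voltage
        for g in range(ngate):
            for i in range(n):
                u = (V[i] - v0) / dv
                if u < 0.0:
                    u = 0.0
                elif u > ntab - 1.000001:
                    u = ntab - 1.000001
                j = int(u)
                w = u - j
                inf = inf_tab[g, j] * (1.0 - w) + inf_tab[g, j + 1] * w
                ef = etau_tab[g, j] * (1.0 - w) + etau_tab[g, j + 1] * w
                gates[g, i] = inf + (gates[g, i] - inf) * ef

        # channel open fractions and conductance sums
        for c in range(nchan):
            for i in range(n):
                openf[c, i] = 1.0
        for g in range(ngate):
            c = gate_chan[g]
            e = gate_exp[g]
            for i in range(n):
                x = gates[g, i]
                p = x
                for _ in range(e - 1):
                    p *= x
                openf[c, i] *= p
        for i in range(n):
            gsum[i] = g_leak[i]
            gesum[i] = g_leak[i] * e_leak
        for c in range(nchan):
            Ec = chan_E[c]
            for i in range(n):
                gc = chan_g[c, i] * openf[c, i]
                gsum[i] += gc
                gesum[i] += gc * Ec

        # assemble the implicit system
        for i in range(n):
            Vold[i] = V[i]
            diag[i] = C[i] / dt + gsum[i]
            rhs[i] = C[i] / dt * V[i] + gesum[i]
            drv[i] = 0.0
        for i in range(1, n):
            p = parent[i]
            diag[i] += g_ax[i]
            diag[p] += g_ax[i]
        for d in range(nd):
            if drive_on[d] <= step - 1 and step - 1 < drive_off[d]:
                for i in range(n):
                    drv[i] += drive[d, i]
        for i in range(n):
            rhs[i] += drv[i]

        # two-sweep tree solve (children have larger indices than parents),
        # keeping the factorization for one step of iterative refinement
        for i in range(n):
            delim[i] = diag[i]
            relim[i] = rhs[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / delim[i]
            fmul[i] = f
            delim[p] -= f * g_ax[i]
            relim[p] += f * relim[i]
        V[0] = relim[0] / delim[0]
        for i in range(1, n):
            V[i] = (relim[i] + g_ax[i] * V[parent[i]]) / delim[i]
        # refinement: resv = A*V - rhs, correct V by A^-1 * resv
        for i in range(n):
            resv[i] = diag[i] * V[i] - rhs[i]
        for i in range(1, n):
            p = parent[i]
            resv[i] -= g_ax[i] * V[p]
            resv[p] -= g_ax[i] * V[i]
        for i in range(n - 1, 0, -1):
            resv[parent[i]] += fmul[i] * resv[i]
        corr0 = resv[0] / delim[0]
        V[0] -= corr0
        relim[0] = corr0
        for i in range(1, n):
            corr = (resv[i] + g_ax[i] * relim[parent[i]]) / delim[i]
            relim[i] = corr
            V[i] -= corr

        bad = -1
        for i in range(n):
            if not (-500.0 < V[i] < 500.0):
                bad = i
                break
        if bad >= 0:
            return 1, step, bad, max_resid, last_delta

        if compute_resid:
            # balance at every node: capacitive + ionic current must equal
            # the signed axial inflow plus the applied drive; normalized by
            # the largest term anywhere in the system this step
            for i in range(n):
                ax[i] = 0.0
            for i in range(1, n):
                p = parent[i]
                e = g_ax[i] * (V[p] - V[i])
                ax[i] += e
                ax[p] -= e
            biggest = 1e-30
            worst = 0.0
            for i in range(n):
                cap = C[i] / dt * (V[i] - Vold[i])
                ion = gsum[i] * V[i] - gesum[i]
                r = abs(cap + ion - ax[i] - drv[i])
                if r > worst:
                    worst = r
                # scale: largest operand entering the balance (the currents
                # themselves cancel to ~0 at quiescence, so the meaningful
                # relative error is against the summand magnitudes)
                for term in (abs(C[i] / dt * V[i]), abs(gsum[i] * V[i]),
                             abs(gesum[i]), abs(ax[i]), abs(drv[i])):
                    if term > biggest:
                        biggest = term
            rel = worst / biggest
            if rel > max_resid:
                max_resid = rel

        if step == nsteps:
            m = 0.0
            for i in range(n):
                d_ = abs(V[i] - Vold[i])
                if d_ > m:
                    m = d_
            last_delta = m

        if step % rec_every == 0:
            rec_col += 1
            for r in range(nrec):
                rec_out[r, rec_col] = V[rec_idx[r]]

    return 0, -1, -1, max_resid, last_delta
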