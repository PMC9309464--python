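"""Compiled inner loop of the natal-dispersal phase.

``_disperse_cohort_impl`` processes one year's juvenile cohort
sequentially in a caller-supplied random order, mutating the patch
occupancy, slot-reservation and unpaired-resident registries as birds
settle. It is written in nopython style and compiled with numba; because
every random number it consumes is pre-drawn by the caller (tie-breaks,
mate acceptance, mate choice), the interpreted and compiled versions are
bit-identical, which the test suite exploits.

Movement rule (greedy stochastic-movement-simulator adaptation): from the
current cell, move to the 8-neighbour whose AGC is closest to the bird's
AGC optimum (ties uniform); orthogonal steps cost 1 patch length,
diagonal steps sqrt(2). The walk ends when the bird settles, runs out of
its drawn maximum distance, or has no valid neighbour.

Settlement on each newly entered patch (never the natal patch on step 0):
the patch must lie within the bird's tolerance band. Dispersers seek a
mate first: a partner-less opposite-sex conspecific resident is always
joined; failing that, a heterospecific single is accepted with the
disperser's hybridization propensity h — and a *refused* heterospecific
advance sends the bird onwards (it may retry wherever it next finds a
single, including this patch on a revisit). With no mate on offer, the
bird stakes out a 2-slot territory if >= 2 uncommitted capacity slots
remain (one slot reserved for a future mate); otherwise it walks on. Joining
consumes the resident's reserved slot if they hold one, else one free
slot.
"""

from __future__ import annotations

import numpy as np

SQRT2 = 1.4142135623730951

# settlement modes
MODE_TERRITORY = 0
MODE_JOIN = 1
DEAD = -1


def _disperse_cohort_impl(
    order,          # (nj,) int64: processing order over juveniles
    natal,          # (nj,) int64: flat natal patch index
    maxdist,        # (nj,) float64: drawn maximum dispersal distance
    juv_opt,        # (nj,) float64: AGC optimum
    juv_tol,        # (nj,) float64: AGC tolerance
    juv_species,    # (nj,) int8
    juv_sex,        # (nj,) int8
    u,              # (nu,) float64: pre-drawn uniforms
    u_off,          # (nj+1,) int64: per-juvenile offsets into u
    all_species,    # (n_adults+nj,) int8 (adults then juveniles)
    all_sex,        # (n_adults+nj,) int8
    all_reserved,   # (n_adults+nj,) bool, mutated
    buf,            # (P, W) int64 unpaired-resident ids per patch, mutated
    buf_n,          # (P,) int32, mutated
    agc,            # (P,) float64
    valid,          # (P,) bool
    cap,            # (P,) int32
    occ,            # (P,) int32, mutated
    res,            # (P,) int32, mutated
    h_by_species,   # (n_species,) float64
    n_rows, n_cols, n_adults,
    out_patch,      # (nj,) int64: settled flat patch or -1 (death)
    out_mode,       # (nj,) int8: MODE_* or -1
    out_partner,    # (nj,) int64: global id of joined resident or -1
    out_dist,       # (nj,) float64: distance travelled
    out_steps,      # (nj,) int32: steps taken
):
    width = buf.shape[1]
    cand = np.empty(8, np.int64)
    cost = np.empty(8, np.float64)
    for oi in range(order.shape[0]):
        j = order[oi]
        gid = n_adults + j
        pos = natal[j]
        md = maxdist[j]
        opt = juv_opt[j]
        tol = juv_tol[j]
        ui = u_off[j]
        dist = 0.0
        steps = 0
        out_patch[j] = DEAD
        out_mode[j] = -1
        out_partner[j] = -1
        while True:
            r = pos // n_cols
            c = pos % n_cols
            # greedy step: neighbours minimizing |AGC - optimum|
            best = 1.0e308
            nt = 0
            for dr in range(-1, 2):
                for dc in range(-1, 2):
                    if dr == 0 and dc == 0:
                        continue
                    rr = r + dr
                    cc = c + dc
                    if rr < 0 or rr >= n_rows or cc < 0 or cc >= n_cols:
                        continue
                    p2 = rr * n_cols + cc
                    if not valid[p2]:
                        continue
                    d = agc[p2] - opt
                    if d < 0.0:
                        d = -d
                    if d < best:
                        best = d
                        nt = 0
                    if d == best:
                        cand[nt] = p2
                        cost[nt] = SQRT2 if (dr != 0 and dc != 0) else 1.0
                        nt += 1
            if nt == 0:
                break  # isolated cell: disperser dies
            k = int(u[ui] * nt)
            ui += 1
            if k >= nt:
                k = nt - 1
            step_cost = cost[k]
            if dist + step_cost > md:
                break  # exceeds maximum dispersal distance: dies
            pos = cand[k]
            dist += step_cost
            steps += 1
            # settlement check on the newly entered patch
            d = agc[pos] - opt
            if d < 0.0:
                d = -d
            if d > tol:
                continue
            free = cap[pos] - occ[pos] - res[pos]
            # mate-seeking first: join a partner-less opposite-sex resident
            n_con = 0
            n_het = 0
            for b in range(buf_n[pos]):
                rid = buf[pos, b]
                if all_sex[rid] == juv_sex[j]:
                    continue
                if not all_reserved[rid] and free < 1:
                    continue  # no slot for the joiner
                if all_species[rid] == juv_species[j]:
                    n_con += 1
                else:
                    n_het += 1
            pick = -1
            if n_con > 0:
                k = int(u[ui] * n_con)
                ui += 1
                if k >= n_con:
                    k = n_con - 1
                idx = 0
                for b in range(buf_n[pos]):
                    rid = buf[pos, b]
                    if all_sex[rid] == juv_sex[j]:
                        continue
                    if not all_reserved[rid] and free < 1:
                        continue
                    if all_species[rid] == juv_species[j]:
                        if idx == k:
                            pick = b
                            break
                        idx += 1
            refused = False
            if n_con == 0 and n_het > 0:
                accept = u[ui] < h_by_species[juv_species[j]]
                ui += 1
                if accept:
                    k = int(u[ui] * n_het)
                    ui += 1
                    if k >= n_het:
                        k = n_het - 1
                    idx = 0
                    for b in range(buf_n[pos]):
                        rid = buf[pos, b]
                        if all_sex[rid] == juv_sex[j]:
                            continue
                        if not all_reserved[rid] and free < 1:
                            continue
                        if all_species[rid] != juv_species[j]:
                            if idx == k:
                                pick = b
                                break
                            idx += 1
                else:
                    refused = True
            if pick >= 0:
                rid = buf[pos, pick]
                if all_reserved[rid]:
                    res[pos] -= 1
                    all_reserved[rid] = False
                occ[pos] += 1
                # swap-remove the resident from the singles registry
                buf_n[pos] -= 1
                buf[pos, pick] = buf[pos, buf_n[pos]]
                out_patch[j] = pos
                out_mode[j] = MODE_JOIN
                out_partner[j] = rid
                break
            # a refused heterospecific advance means the bird moves on
            if refused:
                continue
            # no available mate: stake out a territory for a future pair
            if free >= 2:
                occ[pos] += 1
                res[pos] += 1
                all_reserved[gid] = True
                if buf_n[pos] < width:
                    buf[pos, buf_n[pos]] = gid
                    buf_n[pos] += 1
                out_patch[j] = pos
                out_mode[j] = MODE_TERRITORY
                break
            # unsuitable, refused, or no capacity: keep walking
        out_dist[j] = dist
        out_steps[j] = steps


try:  # compiled path; the interpreted function remains available for tests
    from numba import njit

    disperse_cohort_kernel = njit(cache=False)(_disperse_cohort_impl)
except ImportError:  # pragma: no cover
    disperse_cohort_kernel = _disperse_cohort_impl
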