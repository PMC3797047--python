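"""Numba kernels for the event-driven dynamics and pair histograms.

The simulation state lives in plain float64 arrays; the kernel advances all
particles synchronously from event to event.  Each particle owns one slot in
a per-particle event table holding its earliest known event (pair collision /
shell crossing, or a cell-boundary crossing used to refresh neighbour
predictions).  Slots are maintained with symmetric pushes so that a slot time
never exceeds the particle's true next event time; fired pair events are
always valid because any change to either partner triggers a recompute.
"""

import numpy as np
from numba import njit

# event kinds
EV_CELL = 0   # cell crossing / prediction-horizon refresh
EV_CORE = 1   # hard-core collision
EV_IN = 2     # inward crossing of a shell boundary (capture or inner bounce)
EV_OUT = 3    # outward crossing of a shell boundary (escape or bounce)

# kernel exit status
OK = 0
MAX_EVENTS = 1


@njit(cache=True)
def _min_image(d, L):
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True)
def _pair_candidate(dx, dy, dz, dvx, dvy, dvz, region, db, n_bound):
    """Earliest boundary crossing for one pair on straight-line trajectories.

    Returns (dt, boundary_index, inward); dt < 0 means no event.  ``region``
    is the pair's current region index (0 = between core and first shell edge,
    n_bound-1 = outside everything); ``db`` holds the boundary radii.
    """
    r2 = dx * dx + dy * dy + dz * dz
    b = dx * dvx + dy * dvy + dz * dvz
    v2 = dvx * dvx + dvy * dvy + dvz * dvz
    if v2 <= 0.0:
        return -1.0, -1, False
    if b < 0.0:
        d = db[region]
        disc = b * b - v2 * (r2 - d * d)
        if disc > 0.0:
            dt = (-b - np.sqrt(disc)) / v2
            if dt > -1e-12:
                if dt < 0.0:
                    dt = 0.0
                return dt, region, True
    if region < n_bound - 1:
        d = db[region + 1]
        disc = b * b - v2 * (r2 - d * d)
        if disc > 0.0:
            dt = (-b + np.sqrt(disc)) / v2
            if dt > -1e-12:
                if dt < 0.0:
                    dt = 0.0
                return dt, region + 1, False
    return -1.0, -1, False


@njit(cache=True)
def init_pair_regions(pos, L, db, pair_region):
    """Classify every pair into its potential region from current positions."""
    N = pos.shape[0]
    n_bound = db.shape[0]
    for i in range(N):
        for j in range(i + 1, N):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            g = n_bound - 1
            for s in range(n_bound - 1):
                if r < db[s + 1]:
                    g = s
                    break
            pair_region[i, j] = g
            pair_region[j, i] = g


@njit(cache=True)
def potential_energy(pair_region, ureg):
    N = pair_region.shape[0]
    pe = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            pe += ureg[pair_region[i, j]]
    return pe


@njit(cache=True)
def min_pair_distance(pos, L):
    N = pos.shape[0]
    best = 1e300
    for i in range(N):
        for j in range(i + 1, N):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
    return np.sqrt(best)


@njit(cache=True)
def pair_distance_histogram(pos, L, r_max, counts):
    """Accumulate minimum-image pair distances into uniform bins [0, r_max)."""
    N = pos.shape[0]
    m = counts.shape[0]
    inv_dr = m / r_max
    for i in range(N):
        for j in range(i + 1, N):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_max:
                counts[int(r * inv_dr)] += 1


@njit(cache=True)
def _cell_cross(pos, vel, i, cell3, cw):
    """Time for particle i to leave its registered cell, with axis and step."""
    best = 1e300
    axis = 0
    step = 1
    for a in range(3):
        v = vel[i, a]
        if v > 0.0:
            t = ((cell3[i, a] + 1) * cw - pos[i, a]) / v
            if t < best:
                best = t
                axis = a
                step = 1
        elif v < 0.0:
            t = (cell3[i, a] * cw - pos[i, a]) / v
            if t < best:
                best = t
                axis = a
                step = -1
    if best < 0.0:
        best = 0.0
    return best, axis, step


@njit(cache=True)
def _horizon(vel, i, L):
    """Brute-force mode: refresh predictions after L/8 of travel."""
    sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    if sp == 0.0:
        return 1e300
    return 0.125 * L / sp


@njit(cache=True)
def run_kernel(pos, vel, L, db, ureg, pair_region, t0, t_end, max_events,
               snap_times, snaps, log_cap, log_t, log_i, log_j, log_kind,
               log_b, force_brute, verify):
    """Advance the system from t0 to t_end (or until max_events pair events).

    With ``verify`` set, every processed pair event is cross-checked against
    a brute-force all-pairs candidate scan of the *current* state: any pair
    with an overdue crossing (earlier than the event being processed by more
    than 1e-9) counts as a scheduling violation.  This validates the
    queue/cell machinery independently of floating-point trajectory chaos.

    Returns (status, t, n_events, n_core, virial, delta_pe, n_snaps, n_log,
    n_violations).
    ``virial`` accumulates sum of impulse . r_ij over resolved pair events,
    ``delta_pe`` the net potential-energy change from shell crossings.
    Snapshots of positions are written into ``snaps`` at the (sorted, absolute)
    times in ``snap_times``.  The first ``min(log_cap, ...)`` physical events
    are recorded in the log arrays.
    """
    N = pos.shape[0]
    n_bound = db.shape[0]
    rng_range = db[n_bound - 1]

    # --- cell grid setup -------------------------------------------------
    M = int(L / rng_range)
    brute = force_brute or (M < 3) or (N < 5)
    if brute:
        M = 1
    cw = L / M
    cell3 = np.zeros((N, 3), np.int64)
    head = -np.ones((M, M, M), np.int64)
    nxt = -np.ones(N, np.int64)
    prv = -np.ones(N, np.int64)
    if not brute:
        for i in range(N):
            for a in range(3):
                c = int(pos[i, a] / cw)
                if c >= M:
                    c = M - 1
                cell3[i, a] = c
            cx, cy, cz = cell3[i, 0], cell3[i, 1], cell3[i, 2]
            h = head[cx, cy, cz]
            nxt[i] = h
            prv[i] = -1
            if h >= 0:
                prv[h] = i
            head[cx, cy, cz] = i

    ev_time = np.full(N, 1e300)
    ev_partner = np.full(N, -1, np.int64)
    ev_kind = np.zeros(N, np.int64)
    ev_b = np.zeros(N, np.int64)

    neigh = np.empty(N, np.int64)

    # --- helpers inlined (numba closures over local state are not used) --
    def _neighbors(i):
        """Collect candidate partners of i into neigh; returns count."""
        if brute:
            c = 0
            for j in range(N):
                if j != i:
                    neigh[c] = j
                    c += 1
            return c
        c = 0
        for ox in range(-1, 2):
            cx = (cell3[i, 0] + ox) % M
            for oy in range(-1, 2):
                cy = (cell3[i, 1] + oy) % M
                for oz in range(-1, 2):
                    cz = (cell3[i, 2] + oz) % M
                    j = head[cx, cy, cz]
                    while j >= 0:
                        if j != i:
                            neigh[c] = j
                            c += 1
                        j = nxt[j]
        return c

    def _update(i, t):
        """Recompute particle i's slot; symmetric-push earlier pair events."""
        if brute:
            bt = _horizon(vel, i, L)
            ev_time[i] = t + bt
            ev_partner[i] = -1
            ev_kind[i] = EV_CELL
            ev_b[i] = -1
        else:
            bt, axis, step = _cell_cross(pos, vel, i, cell3, cw)
            ev_time[i] = t + bt
            ev_partner[i] = -1
            ev_kind[i] = EV_CELL
            ev_b[i] = axis * 2 + (1 if step > 0 else 0)
        nn = _neighbors(i)
        for q in range(nn):
            j = neigh[q]
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            dvz = vel[i, 2] - vel[j, 2]
            dt, bidx, inward = _pair_candidate(
                dx, dy, dz, dvx, dvy, dvz, pair_region[i, j], db, n_bound)
            if dt < 0.0:
                continue
            te = t + dt
            if inward:
                kind = EV_CORE if bidx == 0 else EV_IN
            else:
                kind = EV_OUT
            if te < ev_time[i]:
                ev_time[i] = te
                ev_partner[i] = j
                ev_kind[i] = kind
                ev_b[i] = bidx
            if te < ev_time[j]:
                ev_time[j] = te
                ev_partner[j] = i
                ev_kind[j] = kind
                ev_b[j] = bidx

    def _advance_all(dt):
        for p in range(N):
            pos[p, 0] += vel[p, 0] * dt
            pos[p, 1] += vel[p, 1] * dt
            pos[p, 2] += vel[p, 2] * dt

    for i in range(N):
        _update(i, t0)

    t = t0
    n_events = 0
    n_core = 0
    virial = 0.0
    dpe = 0.0
    isnap = 0
    n_snap_total = snap_times.shape[0]
    n_log = 0
    n_violations = 0
    status = OK

    while True:
        # next slot event
        imin = 0
        tmin = ev_time[0]
        for i in range(1, N):
            if ev_time[i] < tmin:
                tmin = ev_time[i]
                imin = i
        # snapshots falling before the next event
        while isnap < n_snap_total and snap_times[isnap] <= tmin \
                and snap_times[isnap] <= t_end:
            dt = snap_times[isnap] - t
            if dt > 0.0:
                _advance_all(dt)
                t = snap_times[isnap]
            for p in range(N):
                for a in range(3):
                    x = pos[p, a] % L
                    if x >= L:
                        x = 0.0
                    snaps[isnap, p, a] = x
            isnap += 1
        if tmin > t_end:
            dt = t_end - t
            if dt > 0.0:
                _advance_all(dt)
            t = t_end
            break
        dt = tmin - t
        if dt > 0.0:
            _advance_all(dt)
        t = tmin

        i = imin
        kind = ev_kind[i]
        if kind == EV_CELL:
            if brute:
                # refresh horizon: re-wrap so minimum-image stays valid
                for a in range(3):
                    x = pos[i, a] % L
                    if x >= L:
                        x = 0.0
                    pos[i, a] = x
            else:
                code = ev_b[i]
                axis = code // 2
                step = 1 if (code % 2) == 1 else -1
                # unlink from old cell
                cx, cy, cz = cell3[i, 0], cell3[i, 1], cell3[i, 2]
                if prv[i] >= 0:
                    nxt[prv[i]] = nxt[i]
                else:
                    head[cx, cy, cz] = nxt[i]
                if nxt[i] >= 0:
                    prv[nxt[i]] = prv[i]
                nc = (cell3[i, axis] + step) % M
                cell3[i, axis] = nc
                # keep the coordinate consistent with the registered cell
                if step > 0 and cell3[i, axis] == 0:
                    pos[i, axis] -= L
                elif step < 0 and cell3[i, axis] == M - 1:
                    pos[i, axis] += L
                cx, cy, cz = cell3[i, 0], cell3[i, 1], cell3[i, 2]
                h = head[cx, cy, cz]
                nxt[i] = h
                prv[i] = -1
                if h >= 0:
                    prv[h] = i
                head[cx, cy, cz] = i
            _update(i, t)
            continue

        # physical pair event
        j = ev_partner[i]
        bidx = ev_b[i]
        if verify:
            # brute-force all-pairs consistency scan at the event time:
            # every minimum-image distance must agree with the tracked
            # region (a missed crossing necessarily violates this)
            for a in range(N):
                for bb in range(a + 1, N):
                    ddx = _min_image(pos[a, 0] - pos[bb, 0], L)
                    ddy = _min_image(pos[a, 1] - pos[bb, 1], L)
                    ddz = _min_image(pos[a, 2] - pos[bb, 2], L)
                    rr = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                    reg = pair_region[a, bb]
                    if rr < db[reg] - 1e-9:
                        n_violations += 1
                    elif reg < n_bound - 1 and rr > db[reg + 1] + 1e-9:
                        n_violations += 1
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        nx = dx / d
        ny = dy / d
        nz = dz / d
        vr = (vel[i, 0] - vel[j, 0]) * nx + (vel[i, 1] - vel[j, 1]) * ny \
            + (vel[i, 2] - vel[j, 2]) * nz

        bounced = False
        if kind == EV_CORE:
            dv = -vr
            bounced = True
        elif kind == EV_IN:
            du = ureg[bidx - 1] - ureg[bidx]
            if vr * vr > 4.0 * du:
                vrp = -np.sqrt(vr * vr - 4.0 * du)
                dv = 0.5 * (vrp - vr)
                pair_region[i, j] = bidx - 1
                pair_region[j, i] = bidx - 1
                dpe += du
            else:
                dv = -vr
                bounced = True
        else:  # EV_OUT
            du = ureg[bidx] - ureg[bidx - 1]
            if vr * vr > 4.0 * du:
                vrp = np.sqrt(vr * vr - 4.0 * du)
                dv = 0.5 * (vrp - vr)
                pair_region[i, j] = bidx
                pair_region[j, i] = bidx
                dpe += du
            else:
                dv = -vr
                bounced = True

        vel[i, 0] += dv * nx
        vel[i, 1] += dv * ny
        vel[i, 2] += dv * nz
        vel[j, 0] -= dv * nx
        vel[j, 1] -= dv * ny
        vel[j, 2] -= dv * nz
        virial += dv * d

        n_events += 1
        if kind == EV_CORE:
            n_core += 1
        if n_log < log_cap:
            log_t[n_log] = t
            log_i[n_log] = min(i, j)
            log_j[n_log] = max(i, j)
            log_kind[n_log] = kind
            log_b[n_log] = bidx
            n_log += 1

        _update(i, t)
        _update(j, t)
        for k in range(N):
            if k != i and k != j and (ev_partner[k] == i or ev_partner[k] == j):
                _update(k, t)

        if n_events >= max_events:
            status = MAX_EVENTS
            break

    # wrap positions into [0, L) before returning control
    for p in range(N):
        for a in range(3):
            x = pos[p, a] % L
            if x >= L:
                x = 0.0
            pos[p, a] = x

    return status, t, n_events, n_core, virial, dpe, isnap, n_log, n_violations
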