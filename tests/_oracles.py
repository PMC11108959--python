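"""Independent brute-force reimplementations of the action-dynamics measures.

Deliberately written as plain scalar loops, separate from the package's
vectorized implementations, to serve as an oracle in equivalence tests.
"""

import math

import numpy as np


def brute_force_dynamics(samples, hover_threshold_ms=250.0, m=3, r_factor=0.2):
    t = [row[0] for row in samples]
    x = [row[1] for row in samples]
    y = [row[2] for row in samples]
    n = len(t)
    out = {
        "max_x": max(x),
        "min_x": min(x),
        "max_y": max(y),
        "min_y": min(y),
    }

    # --- deviations from the straight start-end segment -------------------
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(dx, dy)
    ux, uy = dx / norm, dy / norm
    devs, projs = [], []
    for i in range(n):
        px, py = x[i] - x[0], y[i] - y[0]
        devs.append(-(ux * py - uy * px))
        projs.append(px * ux + py * uy)
    rel = [(ti - t[0]) / 1000.0 for ti in t]
    i_mad = 0
    for i in range(n):
        if abs(devs[i]) > abs(devs[i_mad]):
            i_mad = i
    i_up = max(range(n), key=lambda i: devs[i])
    i_dn = min(range(n), key=lambda i: devs[i])
    auc = 0.0
    for i in range(n - 1):
        auc += (devs[i] + devs[i + 1]) / 2.0 * (projs[i + 1] - projs[i])
    out.update(
        mad_signed=devs[i_mad],
        mad_abs=abs(devs[i_mad]),
        mad_time=rel[i_mad],
        md_above=devs[i_up],
        md_below=devs[i_dn],
        md_above_time=rel[i_up],
        md_below_time=rel[i_dn],
        ad=sum(devs) / n,
        auc=auc,
    )

    # --- directional changes ----------------------------------------------
    def flips(vals):
        increments = []
        for i in range(len(vals) - 1):
            d = vals[i + 1] - vals[i]
            if d != 0:
                increments.append(1 if d > 0 else -1)
        count = 0
        for i in range(len(increments) - 1):
            if increments[i + 1] != increments[i]:
                count += 1
        return count

    def reversals(vals):
        signs = []
        for v in vals:
            if v > 0:
                signs.append(1)
            elif v < 0:
                signs.append(-1)
        count = 0
        for i in range(len(signs) - 1):
            if signs[i + 1] != signs[i]:
                count += 1
        return count

    out.update(
        flips_x=flips(x),
        flips_y=flips(y),
        reversals_x=reversals([xi - x[0] for xi in x]),
        reversals_y=reversals([yi - y[0] for yi in y]),
    )

    # --- timing -------------------------------------------------------------
    rt = rel[-1]
    initiation = rt
    for i in range(n):
        if math.hypot(x[i] - x[0], y[i] - y[0]) > 0:
            initiation = rel[i]
            break
    idle_time = 0.0
    runs = []
    current = 0.0
    for i in range(n - 1):
        still = x[i + 1] == x[i] and y[i + 1] == y[i]
        dt = rel[i + 1] - rel[i]
        if still:
            idle_time += dt
            current += dt
        else:
            if current > 0:
                runs.append(current)
            current = 0.0
    if current > 0:
        runs.append(current)
    hovers = [r for r in runs if r >= hover_threshold_ms / 1000.0]
    out.update(
        rt=rt,
        initiation_time=initiation,
        idle_time=idle_time,
        hover_time=sum(hovers),
        n_hovers=len(hovers),
    )

    # --- kinematics -----------------------------------------------------------
    total = 0.0
    for i in range(n - 1):
        total += math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
    out["total_distance"] = total
    merged = [(rel[0], x[0], y[0])]
    for i in range(1, n):
        if rel[i] > merged[-1][0]:
            merged.append((rel[i], x[i], y[i]))
    out.update(
        max_velocity=math.nan,
        max_velocity_time=math.nan,
        max_acceleration=math.nan,
        max_acceleration_time=math.nan,
        min_acceleration=math.nan,
        min_acceleration_time=math.nan,
    )
    if len(merged) >= 2:
        vels, mids = [], []
        for i in range(len(merged) - 1):
            t0, x0, y0 = merged[i]
            t1, x1, y1 = merged[i + 1]
            vels.append(math.hypot(x1 - x0, y1 - y0) / (t1 - t0))
            mids.append((t0 + t1) / 2.0)
        iv = max(range(len(vels)), key=lambda i: vels[i])
        out["max_velocity"] = vels[iv]
        out["max_velocity_time"] = mids[iv] - merged[0][0]
        if len(merged) >= 3:
            accs, times = [], []
            for i in range(len(vels) - 1):
                accs.append((vels[i + 1] - vels[i]) / (mids[i + 1] - mids[i]))
                times.append(merged[i + 1][0] - merged[0][0])
            ia = max(range(len(accs)), key=lambda i: accs[i])
            ja = min(range(len(accs)), key=lambda i: accs[i])
            out["max_acceleration"] = accs[ia]
            out["max_acceleration_time"] = times[ia]
            out["min_acceleration"] = accs[ja]
            out["min_acceleration_time"] = times[ja]

    # --- sample entropy on diff(x) ---------------------------------------------
    u = [x[i + 1] - x[i] for i in range(n - 1)]
    out["entropy"] = brute_force_sample_entropy(u, m, r_factor)
    return out


def brute_force_sample_entropy(u, m=3, r_factor=0.2):
    nu = len(u)
    if nu < m + 2:
        return math.nan
    mean = sum(u) / nu
    sd = math.sqrt(sum((v - mean) ** 2 for v in u) / nu)
    r = r_factor * sd
    n_templates = nu - m  # templates that admit an (m+1)-extension
    B = A = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(u[i + k] - u[j + k]) for k in range(m)) <= r:
                B += 1
                if max(abs(u[i + k] - u[j + k]) for k in range(m + 1)) <= r:
                    A += 1
    if B == 0 or A == 0:
        return math.nan
    return -math.log(A / B)


def random_polyline(rng, allow_duplicate_times=True):
    """A random integer-pixel path usable by every measure (nonzero span)."""
    while True:
        n = int(rng.integers(6, 40))
        steps = rng.integers(-40, 41, size=(n - 1, 2))
        if allow_duplicate_times and rng.random() < 0.5:
            steps[rng.integers(0, n - 1)] = 0  # a stationary interval
        xy = np.concatenate([[[0, 0]], np.cumsum(steps, axis=0)]).astype(float)
        dt = rng.integers(5, 40, size=n - 1).astype(float)
        t = np.concatenate([[0.0], np.cumsum(dt)])
        if xy[-1, 0] != 0 and xy[-1, 1] != 0:
            return np.column_stack([t, xy])
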