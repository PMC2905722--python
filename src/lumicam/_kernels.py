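"""Numba-compiled cores of the photon transport loops.

Every kernel draws from an explicit multiplicative-congruential generator
(MCG) state that is passed in and returned, so serial and parallel runs can
share one reproducible stream layout.  The draw order is part of the
contract and must not change:

* isotropic volumetric launch: 3 position draws (disc radius, disc azimuth,
  height fraction), then 2 direction draws (cos(theta), azimuth);
* pencil launch: the 3 position draws only;
* interior event: 1 step draw; after the absorption deposit, 2 spin draws
  when mu_s > 0; 1 roulette draw when the weight has fallen below the
  roulette threshold;
* boundary event: 1 Fresnel draw, *skipped* when the reflectance is exactly
  0 or 1 (matched refractive indices, total internal reflection) so that a
  ballistic ray-cast and the full transport loop consume identical streams
  in the degenerate free-space medium.

All lengths are millimetres; the phantom cylinder lives in its local frame
with the axis along +z and the bottom cap at z = 0.
"""

import math

import numpy as np
from numba import njit

# Minimum accepted ray parameter at a surface; prevents self-intersection
# immediately after a boundary event.
HIT_EPS = 1e-9

# status codes returned by the transport kernels
STATUS_OK = 0
STATUS_DRAW_OVERRUN = 1
STATUS_RUNAWAY = 2
STATUS_ESCAPED = 3


@njit(cache=True)
def mcg_fill(state, a, m, out):
    """Advance the MCG ``out.size`` times, writing uniforms in (0,1)."""
    inv = 1.0 / m
    for i in range(out.shape[0]):
        state = (a * state) % m
        out[i] = state * inv
    return state


@njit(cache=True)
def mcg_advance(state, a, m, k):
    for _ in range(k):
        state = (a * state) % m
    return state


@njit(cache=True)
def hg_cos(g, xi):
    """Deflection cosine of the Henyey-Greenstein density for uniform xi."""
    if g == 0.0:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def hg_fill(state, a, m, g, out):
    inv = 1.0 / m
    for i in range(out.shape[0]):
        state = (a * state) % m
        out[i] = hg_cos(g, state * inv)
    return state


@njit(cache=True)
def spin_direction(ux, uy, uz, cos_t, phi):
    """Rotate a unit direction by polar angle acos(cos_t), azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cp
        ny = sin_t * sp
        nz = cos_t if uz >= 0.0 else -cos_t
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
        ny = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
        nz = -sin_t * cp * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def fresnel_reflectance(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i > 0."""
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    r = n1 / n2
    sin_t2 = r * r * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def cyl_first_hit(px, py, pz, ux, uy, uz, radius, height):
    """First forward intersection of a ray with a canonical cylinder.

    Returns (t, surface) with surface 0 = lateral wall, 1 = top cap,
    2 = bottom cap, or (inf, -1) when the ray misses.  Works from inside
    or outside; candidates with t <= HIT_EPS are discarded.
    """
    tbest = np.inf
    surf = -1
    a2 = ux * ux + uy * uy
    if a2 > 0.0:
        b = px * ux + py * uy
        c = px * px + py * py - radius * radius
        disc = b * b - a2 * c
        if disc > 0.0:
            sq = math.sqrt(disc)
            t1 = (-b - sq) / a2
            if HIT_EPS < t1 < tbest:
                z = pz + t1 * uz
                if -1e-9 <= z <= height + 1e-9:
                    tbest = t1
                    surf = 0
            t2 = (-b + sq) / a2
            if HIT_EPS < t2 < tbest:
                z = pz + t2 * uz
                if -1e-9 <= z <= height + 1e-9:
                    tbest = t2
                    surf = 0
    if uz != 0.0:
        t = (height - pz) / uz
        if HIT_EPS < t < tbest:
            x = px + t * ux
            y = py + t * uy
            if x * x + y * y <= radius * radius + 1e-9:
                tbest = t
                surf = 1
        t = -pz / uz
        if HIT_EPS < t < tbest:
            x = px + t * ux
            y = py + t * uy
            if x * x + y * y <= radius * radius + 1e-9:
                tbest = t
                surf = 2
    return tbest, surf


@njit(cache=True)
def transport_kernel(
    n_photons,
    state,
    a,
    m,
    radius,
    height,
    n_in,
    n_out,
    scx,
    scy,
    sz0,
    s_radius,
    s_height,
    pencil,
    pdx,
    pdy,
    pdz,
    mu_a,
    mu_s,
    g,
    w0,
    rr_threshold,
    rr_chance,
    max_events,
    draw_limit,
    grid,
    grid_on,
):
    """Trace ``n_photons`` weighted packets through the phantom cylinder.

    Returns exit arrays (position, refracted direction, weight), the exit
    count, Kahan-compensated ledger sums (absorbed, exited, roulette_net),
    the number of RNG draws consumed, a status code and the final state.
    ``grid`` is an optional absorption tally (nx, ny, nz) over the phantom
    bounding box, filled only when ``grid_on`` is true.
    """
    inv_m = 1.0 / m
    mu_t = mu_a + mu_s
    frac_a = mu_a / mu_t if mu_t > 0.0 else 0.0
    two_pi = 2.0 * math.pi

    ex = np.empty(n_photons)
    ey = np.empty(n_photons)
    ez = np.empty(n_photons)
    edx = np.empty(n_photons)
    edy = np.empty(n_photons)
    edz = np.empty(n_photons)
    ew = np.empty(n_photons)
    n_exit = 0

    abs_s = 0.0
    abs_c = 0.0
    exi_s = 0.0
    exi_c = 0.0
    rr_s = 0.0
    rr_c = 0.0
    draws = 0
    status = STATUS_OK

    gnx = grid.shape[0]
    gny = grid.shape[1]
    gnz = grid.shape[2]

    for _ in range(n_photons):
        if draw_limit > 0 and draws > draw_limit:
            status = STATUS_DRAW_OVERRUN
            break
        # --- launch ---
        state = (a * state) % m
        xi1 = state * inv_m
        state = (a * state) % m
        xi2 = state * inv_m
        state = (a * state) % m
        xi3 = state * inv_m
        draws += 3
        rad = s_radius * math.sqrt(xi1)
        phi = two_pi * xi2
        px = scx + rad * math.cos(phi)
        py = scy + rad * math.sin(phi)
        pz = sz0 + s_height * xi3
        if pencil:
            ux = pdx
            uy = pdy
            uz = pdz
        else:
            state = (a * state) % m
            ct = 2.0 * (state * inv_m) - 1.0
            state = (a * state) % m
            phd = two_pi * (state * inv_m)
            draws += 2
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            ux = st * math.cos(phd)
            uy = st * math.sin(phd)
            uz = ct

        w = w0
        local_abs = 0.0
        events = 0
        alive = True
        while alive:
            events += 1
            if events > max_events:
                status = STATUS_RUNAWAY
                alive = False
                break
            if mu_t > 0.0:
                state = (a * state) % m
                draws += 1
                d = -math.log(state * inv_m) / mu_t
            else:
                d = np.inf
            t_exit, surf_id = cyl_first_hit(px, py, pz, ux, uy, uz, radius, height)
            if surf_id < 0:
                status = STATUS_ESCAPED
                alive = False
                break
            if d < t_exit:
                # interior interaction: move, drop, spin, roulette
                px += d * ux
                py += d * uy
                pz += d * uz
                dw = w * frac_a
                local_abs += dw
                if grid_on:
                    ix = int((px + radius) / (2.0 * radius) * gnx)
                    iy = int((py + radius) / (2.0 * radius) * gny)
                    iz = int(pz / height * gnz)
                    if 0 <= ix < gnx and 0 <= iy < gny and 0 <= iz < gnz:
                        grid[ix, iy, iz] += dw
                w -= dw
                if w <= 0.0:
                    alive = False
                    continue
                if mu_s > 0.0:
                    state = (a * state) % m
                    xia = state * inv_m
                    state = (a * state) % m
                    xib = state * inv_m
                    draws += 2
                    ct = hg_cos(g, xia)
                    ux, uy, uz = spin_direction(ux, uy, uz, ct, two_pi * xib)
                if w < rr_threshold and rr_chance < 1.0:
                    state = (a * state) % m
                    draws += 1
                    if state * inv_m <= rr_chance:
                        boost = w * (1.0 / rr_chance - 1.0)
                        y = -boost - rr_c
                        t = rr_s + y
                        rr_c = (t - rr_s) - y
                        rr_s = t
                        w += boost
                    else:
                        y = w - rr_c
                        t = rr_s + y
                        rr_c = (t - rr_s) - y
                        rr_s = t
                        alive = False
            else:
                # boundary event
                px += t_exit * ux
                py += t_exit * uy
                pz += t_exit * uz
                if surf_id == 0:
                    rl = math.sqrt(px * px + py * py)
                    nx = px / rl
                    ny = py / rl
                    nz = 0.0
                elif surf_id == 1:
                    nx = 0.0
                    ny = 0.0
                    nz = 1.0
                else:
                    nx = 0.0
                    ny = 0.0
                    nz = -1.0
                cos_i = ux * nx + uy * ny + uz * nz
                if cos_i <= 0.0:
                    # numerically grazing: treat as reflection, no draw
                    refl = True
                else:
                    rf = fresnel_reflectance(n_in, n_out, cos_i)
                    if rf >= 1.0:
                        refl = True
                    elif rf <= 0.0:
                        refl = False
                    else:
                        state = (a * state) % m
                        draws += 1
                        refl = state * inv_m <= rf
                if refl:
                    c2 = 2.0 * cos_i
                    ux -= c2 * nx
                    uy -= c2 * ny
                    uz -= c2 * nz
                else:
                    eta = n_in / n_out
                    cos_t = math.sqrt(
                        max(0.0, 1.0 - eta * eta * (1.0 - cos_i * cos_i))
                    )
                    tx = eta * ux + (cos_t - eta * cos_i) * nx
                    ty = eta * uy + (cos_t - eta * cos_i) * ny
                    tz = eta * uz + (cos_t - eta * cos_i) * nz
                    tn = math.sqrt(tx * tx + ty * ty + tz * tz)
                    ex[n_exit] = px
                    ey[n_exit] = py
                    ez[n_exit] = pz
                    edx[n_exit] = tx / tn
                    edy[n_exit] = ty / tn
                    edz[n_exit] = tz / tn
                    ew[n_exit] = w
                    n_exit += 1
                    y = w - exi_c
                    t = exi_s + y
                    exi_c = (t - exi_s) - y
                    exi_s = t
                    alive = False
        if status == STATUS_RUNAWAY or status == STATUS_ESCAPED:
            break
        y = local_abs - abs_c
        t = abs_s + y
        abs_c = (t - abs_s) - y
        abs_s = t

    if status == STATUS_OK and draw_limit > 0 and draws > draw_limit:
        status = STATUS_DRAW_OVERRUN
    return (
        ex[:n_exit],
        ey[:n_exit],
        ez[:n_exit],
        edx[:n_exit],
        edy[:n_exit],
        edz[:n_exit],
        ew[:n_exit],
        n_exit,
        abs_s,
        exi_s,
        rr_s,
        draws,
        status,
        state,
    )


@njit(cache=True)
def raycast_kernel(
    n_photons,
    state,
    a,
    m,
    radius,
    height,
    n_in,
    n_out,
    scx,
    scy,
    sz0,
    s_radius,
    s_height,
    pencil,
    pdx,
    pdy,
    pdz,
    w0,
    max_events,
):
    """Ballistic ray-cast: launch and propagate straight to the boundary.

    Uses the identical launch draws and boundary rules (Fresnel draw only
    when 0 < R < 1) as :func:`transport_kernel`, so with the degenerate
    free-space medium (mu_a = mu_s = 0, g = 1) the two kernels consume the
    same stream and emit bit-identical exit records.
    """
    inv_m = 1.0 / m
    two_pi = 2.0 * math.pi
    ex = np.empty(n_photons)
    ey = np.empty(n_photons)
    ez = np.empty(n_photons)
    edx = np.empty(n_photons)
    edy = np.empty(n_photons)
    edz = np.empty(n_photons)
    ew = np.empty(n_photons)
    n_exit = 0
    exi_s = 0.0
    exi_c = 0.0
    draws = 0
    status = STATUS_OK

    for _ in range(n_photons):
        state = (a * state) % m
        xi1 = state * inv_m
        state = (a * state) % m
        xi2 = state * inv_m
        state = (a * state) % m
        xi3 = state * inv_m
        draws += 3
        rad = s_radius * math.sqrt(xi1)
        phi = two_pi * xi2
        px = scx + rad * math.cos(phi)
        py = scy + rad * math.sin(phi)
        pz = sz0 + s_height * xi3
        if pencil:
            ux = pdx
            uy = pdy
            uz = pdz
        else:
            state = (a * state) % m
            ct = 2.0 * (state * inv_m) - 1.0
            state = (a * state) % m
            phd = two_pi * (state * inv_m)
            draws += 2
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            ux = st * math.cos(phd)
            uy = st * math.sin(phd)
            uz = ct
        events = 0
        alive = True
        while alive:
            events += 1
            if events > max_events:
                status = STATUS_RUNAWAY
                alive = False
                break
            t_exit, surf_id = cyl_first_hit(px, py, pz, ux, uy, uz, radius, height)
            if surf_id < 0:
                status = STATUS_ESCAPED
                alive = False
                break
            px += t_exit * ux
            py += t_exit * uy
            pz += t_exit * uz
            if surf_id == 0:
                rl = math.sqrt(px * px + py * py)
                nx = px / rl
                ny = py / rl
                nz = 0.0
            elif surf_id == 1:
                nx = 0.0
                ny = 0.0
                nz = 1.0
            else:
                nx = 0.0
                ny = 0.0
                nz = -1.0
            cos_i = ux * nx + uy * ny + uz * nz
            if cos_i <= 0.0:
                refl = True
            else:
                rf = fresnel_reflectance(n_in, n_out, cos_i)
                if rf >= 1.0:
                    refl = True
                elif rf <= 0.0:
                    refl = False
                else:
                    state = (a * state) % m
                    draws += 1
                    refl = state * inv_m <= rf
            if refl:
                c2 = 2.0 * cos_i
                ux -= c2 * nx
                uy -= c2 * ny
                uz -= c2 * nz
            else:
                eta = n_in / n_out
                cos_t = math.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - cos_i * cos_i)))
                tx = eta * ux + (cos_t - eta * cos_i) * nx
                ty = eta * uy + (cos_t - eta * cos_i) * ny
                tz = eta * uz + (cos_t - eta * cos_i) * nz
                tn = math.sqrt(tx * tx + ty * ty + tz * tz)
                ex[n_exit] = px
                ey[n_exit] = py
                ez[n_exit] = pz
                edx[n_exit] = tx / tn
                edy[n_exit] = ty / tn
                edz[n_exit] = tz / tn
                ew[n_exit] = w0
                n_exit += 1
                y = w0 - exi_c
                t = exi_s + y
                exi_c = (t - exi_s) - y
                exi_s = t
                alive = False
        if status != STATUS_OK:
            break
    return (
        ex[:n_exit],
        ey[:n_exit],
        ez[:n_exit],
        edx[:n_exit],
        edy[:n_exit],
        edz[:n_exit],
        ew[:n_exit],
        n_exit,
        exi_s,
        draws,
        status,
        state,
    )
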