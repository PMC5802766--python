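"""Numba kernels for the per-tick agent loop.

All behavioral rules live here, compiled once and shared by both the
object-level API in :mod:`matesim.engine` and the fast whole-run driver
:func:`simulate`. Conventions:

* genotype 0 = polygamous, 1 = monogamous
* ``partner[m] == -1`` means male *m* is unpaired; ``guard_of[f]`` is
  the id of the monogamous male guarding female *f* (−1 if none; only
  ever set while mate guarding is enabled)
* ``target[m]`` is the female male *m* is currently engaged to (−1 if
  none); the engagement lasts while she remains available
* distances are Chebyshev (8-neighbour moves, one patch per tick)

Every function takes an ``np.random.Generator`` explicitly; no global
RNG state is used anywhere.
"""
from __future__ import annotations

import numpy as np
from numba import njit

BIG = np.int64(1) << 40


@njit(cache=True)
def chebyshev(ax, ay, bx, by, width, height, wrap):
    dx = abs(ax - bx)
    dy = abs(ay - by)
    if wrap:
        if width - dx < dx:
            dx = width - dx
        if height - dy < dy:
            dy = height - dy
    return max(dx, dy)


@njit(cache=True)
def is_available(f, m, pregnant, refr, genotype, partner, target,
                 mate_guarding, neutral_mode, mx, my, fx, fy,
                 width, height, wrap):
    """Can male *m* acquire female *f* as a courtship target?

    A female is available iff she is neither pregnant nor refractory,
    no male other than the candidate has her as his partner (with mate
    guarding on, her guard stands beside her and shuts everyone else
    out), and no *competing* male is strictly closer to her — equal
    distances do not block. Paired monogamous males court no one, so
    they never block access to females other than their own partner.

    Checked at target acquisition only: once engaged, a male pursues
    his target even if a rival ends up closer while both travel.
    """
    if pregnant[f] or refr[f] > 0:
        return False
    M = mx.shape[0]
    if mate_guarding:
        for mm in range(M):
            if mm != m and partner[mm] == f:
                return False
    dm = chebyshev(mx[m], my[m], fx[f], fy[f], width, height, wrap)
    for mm in range(M):
        if mm == m:
            continue
        if target[mm] >= 0 or partner[mm] >= 0:
            continue  # already spoken for: he is not competing for her
        if chebyshev(mx[mm], my[mm], fx[f], fy[f], width, height, wrap) < dm:
            return False
    return True


@njit(cache=True)
def select_target(m, mx, my, fx, fy, pregnant, refr, genotype, partner,
                  target, guard_of, width, height, wrap, mate_guarding,
                  neutral_mode):
    """Nearest available female for male *m*; ties go to the lowest id.

    The closer-male clause spreads searching males across females: at
    acquisition each receptive female draws only her nearest suitor,
    so rivals fan out to the remaining females instead of crowding.
    """
    F = fx.shape[0]
    best_d = BIG
    best_f = -1
    for f in range(F):
        if pregnant[f] or refr[f] > 0:
            continue
        if mate_guarding and guard_of[f] != -1 and guard_of[f] != m:
            continue
        d = chebyshev(mx[m], my[m], fx[f], fy[f], width, height, wrap)
        if d >= best_d:
            continue
        blocked = False
        for mm in range(mx.shape[0]):
            if mm == m:
                continue
            if target[mm] >= 0 or partner[mm] >= 0:
                continue
            if chebyshev(mx[mm], my[mm], fx[f], fy[f],
                         width, height, wrap) < d:
                blocked = True
                break
        if not blocked:
            best_d = d
            best_f = f
    return best_f


@njit(cache=True)
def step_toward(rng, x, y, tx, ty, width, height, wrap):
    """One-patch move minimizing Chebyshev distance to (tx, ty).

    Ties among the minimizing in-bounds neighbours are broken uniformly
    at random.
    """
    best = BIG
    cand_x = np.empty(8, np.int64)
    cand_y = np.empty(8, np.int64)
    nc = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            nx = x + dx
            ny = y + dy
            if wrap:
                nx = nx % width
                ny = ny % height
            elif nx < 0 or nx >= width or ny < 0 or ny >= height:
                continue
            d = chebyshev(nx, ny, tx, ty, width, height, wrap)
            if d < best:
                best = d
                nc = 0
            if d == best:
                cand_x[nc] = nx
                cand_y[nc] = ny
                nc += 1
    k = rng.integers(0, nc)
    return cand_x[k], cand_y[k]


@njit(cache=True)
def random_neighbor(rng, x, y, width, height, wrap):
    """Uniform move to one of the ≤8 in-bounds neighbour patches."""
    cand_x = np.empty(8, np.int64)
    cand_y = np.empty(8, np.int64)
    nc = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            nx = x + dx
            ny = y + dy
            if wrap:
                nx = nx % width
                ny = ny % height
            elif nx < 0 or nx >= width or ny < 0 or ny >= height:
                continue
            cand_x[nc] = nx
            cand_y[nc] = ny
            nc += 1
    k = rng.integers(0, nc)
    return cand_x[k], cand_y[k]


@njit(cache=True)
def attempt_copulation(rng, m, f, genotype, partner, guard_of, pregnant, refr,
                       father, pregnancy_chance, refractory_duration,
                       mate_guarding, neutral_mode):
    """Copulation between co-located male *m* and receptive female *f*.

    Returns 1 on conception, 0 if the female enters refractory. An
    unpaired monogamous male pair-bonds to his first copulation partner
    regardless of the outcome.

    The refractory counter is stored as duration + 1 because it is
    decremented once at the start of every tick beginning with the tick
    after the copulation: the female is then unavailable for exactly
    ``refractory_duration`` full ticks, and an always-available partner
    is copulated with every ``refractory_duration + 1`` ticks.
    """
    if (not neutral_mode) and genotype[m] == 1 and partner[m] == -1:
        partner[m] = f
        if mate_guarding:
            guard_of[f] = m
    if rng.random() < pregnancy_chance:
        pregnant[f] = True
        father[f] = genotype[m]
        refr[f] = 0
        return 1
    refr[f] = refractory_duration + 1
    return 0


@njit(cache=True)
def step_male(rng, m, mx, my, genotype, partner, target, guard_of,
              fx, fy, pregnant, refr, father,
              width, height, wrap,
              pregnancy_chance, refractory_duration, mate_guarding,
              neutral_mode):
    """Advance one male by one tick. Returns (copulations, conceptions).

    A searching male is *engaged* to at most one female (``target[m]``):
    once acquired — the nearest available female at acquisition time —
    he pursues her until she stops being available (pregnant, guarded,
    or refractory after a rival's copulation), at which point he turns
    to the remaining available females. After a copulation a polygamous
    male restarts the search from scratch: the refractory period bars
    him from simply re-courting the same female, so he necessarily goes
    after others during that window. A monogamous male is paired from
    his first copulation on.
    """
    cop = 0
    preg = 0
    p = partner[m]
    if (not neutral_mode) and genotype[m] == 1 and p >= 0:
        if mate_guarding:
            # Guarding male never moves; his partner is always available
            # to him, so he copulates the moment her refractory ends.
            if (not pregnant[p]) and refr[p] == 0:
                preg += attempt_copulation(
                    rng, m, p, genotype, partner, guard_of, pregnant, refr,
                    father, pregnancy_chance, refractory_duration,
                    mate_guarding, neutral_mode)
                cop += 1
            return cop, preg
        # Guarding disabled: wander while she is refractory or pregnant,
        # head back and copulate on arrival once she is receptive again.
        if pregnant[p] or refr[p] > 0:
            nx, ny = random_neighbor(rng, mx[m], my[m], width, height, wrap)
            mx[m] = nx
            my[m] = ny
            return cop, preg
        if mx[m] != fx[p] or my[m] != fy[p]:
            nx, ny = step_toward(rng, mx[m], my[m], fx[p], fy[p],
                                 width, height, wrap)
            mx[m] = nx
            my[m] = ny
        if mx[m] == fx[p] and my[m] == fy[p]:
            preg += attempt_copulation(
                rng, m, p, genotype, partner, guard_of, pregnant, refr,
                father, pregnancy_chance, refractory_duration,
                mate_guarding, neutral_mode)
            cop += 1
        return cop, preg

    # Searching male (polygamous, or monogamous and still unpaired).
    t = target[m]
    if t >= 0 and (pregnant[t] or (mate_guarding and guard_of[t] != -1
                                   and guard_of[t] != m)):
        t = -1  # engagement void: she is pregnant or newly guarded
        target[m] = -1
    if t >= 0 and refr[t] > 0:
        # His target is refractory (a rival got there first): he holds
        # a loose position nearby — moving around, not glued to her
        # patch — and races back the moment she is receptive again.
        nx, ny = random_neighbor(rng, mx[m], my[m], width, height, wrap)
        mx[m] = nx
        my[m] = ny
        return cop, preg
    if t == -1:
        t = select_target(m, mx, my, fx, fy, pregnant, refr, genotype,
                          partner, target, guard_of, width, height, wrap,
                          mate_guarding, neutral_mode)
        target[m] = t
    if t == -1:
        nx, ny = random_neighbor(rng, mx[m], my[m], width, height, wrap)
        mx[m] = nx
        my[m] = ny
        return cop, preg
    if mx[m] != fx[t] or my[m] != fy[t]:
        nx, ny = step_toward(rng, mx[m], my[m], fx[t], fy[t],
                             width, height, wrap)
        mx[m] = nx
        my[m] = ny
    if (mx[m] == fx[t] and my[m] == fy[t]
            and (not pregnant[t]) and refr[t] == 0):
        preg += attempt_copulation(
            rng, m, t, genotype, partner, guard_of, pregnant, refr,
            father, pregnancy_chance, refractory_duration,
            mate_guarding, neutral_mode)
        cop += 1
        target[m] = -1  # a polygamous male restarts the search next tick
    return cop, preg


@njit(cache=True)
def season_ticks(rng, n_ticks, mx, my, genotype, partner, target, guard_of,
                 fx, fy, pregnant, refr, father,
                 order, width, height, wrap,
                 pregnancy_chance, refractory_duration, mate_guarding,
                 neutral_mode):
    """Run ``n_ticks`` ticks of one breeding season.

    Each tick: decrement positive refractory counters, then step every
    male once, in a freshly shuffled order. Returns (copulations,
    conceptions) totals.
    """
    M = mx.shape[0]
    F = fx.shape[0]
    cops = 0
    pregs = 0
    n_pregnant = 0
    for f in range(F):
        if pregnant[f]:
            n_pregnant += 1
    for tick in range(n_ticks):
        if n_pregnant == F:
            # Pregnancy is absorbing within a season: once every female
            # is pregnant the rest of the season is pure random walking
            # (guards stay put). This loop draws from the RNG exactly
            # as the general path would — the same shuffle and one
            # neighbour draw per walking male — so trajectories are
            # bit-identical; only dead work is skipped.
            for _t in range(tick, n_ticks):
                for i in range(M - 1, 0, -1):
                    j = rng.integers(0, i + 1)
                    tmp = order[i]
                    order[i] = order[j]
                    order[j] = tmp
                for i in range(M):
                    m = order[i]
                    if ((not neutral_mode) and genotype[m] == 1
                            and partner[m] >= 0 and mate_guarding):
                        continue
                    nx, ny = random_neighbor(rng, mx[m], my[m],
                                             width, height, wrap)
                    mx[m] = nx
                    my[m] = ny
            break
        for f in range(F):
            if refr[f] > 0:
                refr[f] -= 1
        for i in range(M - 1, 0, -1):
            j = rng.integers(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for i in range(M):
            c, p = step_male(rng, order[i], mx, my, genotype, partner,
                             target, guard_of, fx, fy, pregnant, refr,
                             father, width, height, wrap,
                             pregnancy_chance, refractory_duration,
                             mate_guarding, neutral_mode)
            cops += c
            pregs += p
            n_pregnant += p
    return cops, pregs


@njit(cache=True)
def mutate_genotype(rng, g0, sigma):
    """Progeny genotype: threshold-round the father's genotype plus
    Gaussian noise; any value >= 0.5 maps to 1 (monogamous), else 0."""
    x = g0 + rng.normal(0.0, sigma)
    if x >= 0.5:
        return 1
    return 0


@njit(cache=True)
def place_males_random(rng, mx, my, width, height):
    for m in range(mx.shape[0]):
        mx[m] = rng.integers(0, width)
        my[m] = rng.integers(0, height)


@njit(cache=True)
def simulate(rng, n_males, fx, fy, width, height, wrap,
             generations, longevity, season_duration,
             pregnancy_chance, refractory_duration, mate_guarding,
             mutation_sigma, neutral_mode):
    """Whole-run driver: generations × longevity breeding seasons.

    Returns per-season arrays (monogamous male count, copulations,
    conceptions) and per-generation trait-pool diagnostics (size,
    monogamy fraction; NaN fraction for an empty pool).
    """
    F = fx.shape[0]
    n_seasons = generations * longevity
    monog = np.empty(n_seasons, np.int64)
    cops_out = np.empty(n_seasons, np.int64)
    pregs_out = np.empty(n_seasons, np.int64)
    pool_size_out = np.empty(generations, np.int64)
    pool_frac_out = np.empty(generations, np.float64)

    mx = np.empty(n_males, np.int64)
    my = np.empty(n_males, np.int64)
    genotype = np.empty(n_males, np.int64)
    partner = np.empty(n_males, np.int64)
    target = np.empty(n_males, np.int64)
    guard_of = np.empty(F, np.int64)
    pregnant = np.zeros(F, np.bool_)
    refr = np.zeros(F, np.int64)
    father = np.empty(F, np.int64)
    order = np.arange(n_males)
    pool = np.empty(F * longevity, np.int64)
    pool_n = 0

    # First generation: equal chance of either strategy.
    for m in range(n_males):
        genotype[m] = 1 if rng.random() < 0.5 else 0

    s_idx = 0
    for gen in range(generations):
        for _s in range(longevity):
            # Season start: bonds dissolve, females reset, males
            # re-dispersed uniformly at random.
            for m in range(n_males):
                partner[m] = -1
                target[m] = -1
            for f in range(F):
                guard_of[f] = -1
                pregnant[f] = False
                refr[f] = 0
                father[f] = -1
            place_males_random(rng, mx, my, width, height)
            cops, _c = season_ticks(
                rng, season_duration, mx, my, genotype, partner, target,
                guard_of, fx, fy, pregnant, refr, father, order,
                width, height, wrap, pregnancy_chance, refractory_duration,
                mate_guarding, neutral_mode)
            # Season end: every pregnant female contributes one
            # (possibly mutated) progeny genotype to the trait pool.
            n_preg = 0
            for f in range(F):
                if pregnant[f]:
                    pool[pool_n] = mutate_genotype(rng, father[f],
                                                   mutation_sigma)
                    pool_n += 1
                    n_preg += 1
            mono = 0
            for m in range(n_males):
                mono += genotype[m]
            monog[s_idx] = mono
            cops_out[s_idx] = cops
            pregs_out[s_idx] = n_preg
            s_idx += 1
        # Generation turnover: all males replaced at once, genotypes
        # drawn with replacement from the pool; an empty pool carries
        # the dying generation's genotypes over unchanged.
        pool_size_out[gen] = pool_n
        if pool_n > 0:
            tot = 0
            for i in range(pool_n):
                tot += pool[i]
            pool_frac_out[gen] = tot / pool_n
            for m in range(n_males):
                genotype[m] = pool[rng.integers(0, pool_n)]
        else:
            pool_frac_out[gen] = np.nan
        pool_n = 0
    return monog, cops_out, pregs_out, pool_size_out, pool_frac_out
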