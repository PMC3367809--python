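"""Numba kernels implementing the lattice dynamics of all three rule systems.

Everything stochastic in a simulation draws from numba's internal legacy
``np.random`` stream, seeded once per replicate, which is bit-identical to
NumPy's Mersenne Twister: a (model, parameters, seed) triple fully determines
a trajectory.  The object layer in the rest of the package wraps these
kernels; nothing here is part of the public API.

State encoding
--------------
sites   : (W, H) uint8   0=CLOSED, 1=OPEN, 2=OCCUPIED
ax, ay  : (n,)  int64    agent coordinates; index 0 is the rearmost agent
role    : (n,)  uint8    0=Leader, 1=Follower
pol     : (n,)  int64    polarized direction, 8 = none (Followers only)
dclock  : (n,)  int64    direction-change clock (Followers only)
pclock  : (n,)  int64    protrusion-change clock
ext     : (n,)  bool     protrusion toggle phase (extended / retracted)
plen    : (n,8) int64    per-direction protrusion length, 0..3; a positive
                         length mediates contact regardless of the toggle
                         phase (contact-preserving retraction may leave
                         lengths behind with ``ext`` False)

Parameters travel as a flat float64 vector packed by ``chainabm.params``.
"""

import math

import numpy as np
from numba import njit

# --- site states -----------------------------------------------------------
CLOSED = 0
OPEN = 1
OCCUPIED = 2

# --- roles -----------------------------------------------------------------
LEADER = 0
FOLLOWER = 1

# --- models ----------------------------------------------------------------
MODEL_ECM = 0
MODEL_CONTACT = 1
MODEL_HYBRID = 2

# --- schedulers ------------------------------------------------------------
SCHED_REPLACEMENT = 0   # n uniform agent draws with replacement per step
SCHED_SHUFFLE = 1       # each agent exactly once, freshly shuffled order

# --- termination codes -----------------------------------------------------
TERM_MAX_STEPS = 0
TERM_CHAIN_BROKEN = 1
TERM_TARGET_REACHED = 2
TERM_VELOCITY_FAILED = 3

# --- direction table: index k corresponds to the compass angle k*45 deg
# with +x = distal (toward target) and +y = posterior; index 8 = none.
NONE_DIR = 8
DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)

# --- packed-parameter layout (see chainabm.params) -------------------------
P_LDD = 0      # 9 slots
P_FDD = 9     # 9 slots
P_POS = 18
P_ATS = 19
P_LMC = 20
P_FMC = 21
P_PPC = 22
P_FRP = 23
P_LRP = 24
P_FMP = 25
P_LMP = 26
P_SID = 27
P_SIP = 28
P_MDI = 29
P_MPI = 30
P_TRACK = 31
PACK_LEN = 32

MAX_PROT_LEN = 3


@njit(cache=True)
def seed_engine(seed):
    """Seed the kernels' internal RNG stream."""
    np.random.seed(seed)


@njit(cache=True)
def _sample_cdf(cdf):
    """Draw an index 0..8 from a 9-value categorical given its CDF."""
    r = np.random.random()
    for d in range(9):
        if r < cdf[d]:
            return d
    return NONE_DIR


@njit(cache=True)
def _cdf(probs):
    c = np.empty(9)
    tot = 0.0
    for k in range(9):
        tot += probs[k]
    acc = 0.0
    for k in range(9):
        acc += probs[k] / tot
        c[k] = acc
    c[8] = 1.0
    return c


@njit(cache=True)
def _octant(dx, dy):
    """Round an integer displacement to the nearest of the 8 compass values.

    Octant boundaries fall at odd multiples of 22.5 deg whose tangent is
    irrational, so integer lattice displacements never tie.
    """
    ang = math.atan2(dy, dx)
    return int(round(ang / (math.pi * 0.25))) % 8


@njit(cache=True)
def _do_move(sites, ax, ay, i, nx, ny):
    sites[ax[i], ay[i]] = OPEN
    sites[nx, ny] = OCCUPIED
    ax[i] = nx
    ay[i] = ny


@njit(cache=True)
def _chain_mask(ax, ay, mask):
    """Mark the longest front-to-back chain and return its length.

    A chain is a sequence of distinct agents ordered front to back
    (non-increasing x) in which every consecutive pair is sequential: no
    empty site between them along y (|dy| <= 1) and at most three along
    x (|dx| <= 4).  Agents off the chain are simply skipped.  Exact
    dynamic programming over (member set, last agent) states; ties
    between equally long chains break on the smallest member bit set.
    """
    n = ax.size
    size = 1 << n
    dp = np.zeros((size, n), np.bool_)
    for i in range(n):
        dp[1 << i, i] = True
    for m in range(1, size):
        for last in range(n):
            if not dp[m, last]:
                continue
            for j in range(n):
                if (m >> j) & 1:
                    continue
                if ax[j] <= ax[last] and \
                        abs(ax[j] - ax[last]) <= 4 and \
                        abs(ay[j] - ay[last]) <= 1:
                    dp[m | (1 << j), j] = True
    best = 0
    best_m = 0
    for m in range(1, size):
        reachable = False
        for last in range(n):
            if dp[m, last]:
                reachable = True
                break
        if reachable:
            c = 0
            mm = m
            while mm:
                c += mm & 1
                mm >>= 1
            if c > best:
                best = c
                best_m = m
    for i in range(n):
        mask[i] = (best_m >> i) & 1 == 1
    return best


@njit(cache=True)
def _covers(ox, oy, d, length, tx, ty):
    """Does a protrusion ray from (ox,oy) in direction d of this length
    cover site (tx,ty)?"""
    for k in range(1, length + 1):
        if ox + k * DX[d] == tx and oy + k * DY[d] == ty:
            return True
    return False


@njit(cache=True)
def _ray_k(ox, oy, d, tx, ty):
    """Distance k if (tx,ty) lies on the ray from (ox,oy) in direction d
    within a small horizon, else 0."""
    for k in range(1, 7):
        if ox + k * DX[d] == tx and oy + k * DY[d] == ty:
            return k
    return 0


@njit(cache=True)
def _set_protrusions(plen, ext, role, pol, i, extend):
    """Toggle agent i's protrusion state.  Extension seeds one-site rays in
    every permitted direction — all eight for a hairy Leader, the leading
    edge (polarized direction) for a Follower — which then grow one site
    per time step up to the three-site maximum while the extended phase
    lasts.  Retraction removes the rays instantly."""
    if extend:
        for d in range(8):
            plen[i, d] = 0
        ext[i] = True
        if role[i] == LEADER:
            for d in range(8):
                plen[i, d] = 1
        elif pol[i] != NONE_DIR:
            plen[i, pol[i]] = 1
    else:
        ext[i] = False
        for d in range(8):
            plen[i, d] = 0


@njit(cache=True)
def _retract_with_ppc(ax, ay, plen, ext, i, ppc_t):
    """Protrusion-retraction event.  With probability PPC-true, protrusions
    currently mediating a contact are spared; the toggle phase becomes
    retracted either way."""
    n = ax.size
    keep = False
    if ppc_t > 0.0:
        keep = np.random.random() < ppc_t
    ext[i] = False
    for d in range(8):
        if plen[i, d] <= 0:
            continue
        mediating = False
        if keep:
            for j in range(n):
                if j != i and _covers(ax[i], ay[i], d, plen[i, d], ax[j], ay[j]):
                    mediating = True
                    break
        if not mediating:
            plen[i, d] = 0


@njit(cache=True)
def _tick_clocks_one(ax, ay, role, pol, dclock, pclock, ext, plen,
                     fdd_cdf, mdi, mpi, ppc_t, i):
    """Decrement agent i's clocks (floor at the firing point).  A direction
    clock firing redraws the polarized direction from FDD and resets on
    U{0..MDI}; a protrusion clock firing toggles the protrusion state and
    resets on U{0..MPI}.  Extended protrusions grow one site per step
    toward the three-site maximum."""
    if ext[i]:
        for d in range(8):
            if 0 < plen[i, d] < MAX_PROT_LEN:
                plen[i, d] += 1
    if role[i] == FOLLOWER:
        if dclock[i] > 0:
            dclock[i] -= 1
        if dclock[i] == 0:
            pol[i] = _sample_cdf(fdd_cdf)
            dclock[i] = np.random.randint(0, mdi + 1)
            if ext[i]:
                _set_protrusions(plen, ext, role, pol, i, True)
    if pclock[i] > 0:
        pclock[i] -= 1
    if pclock[i] == 0:
        if ext[i]:
            _retract_with_ppc(ax, ay, plen, ext, i, ppc_t)
        else:
            _set_protrusions(plen, ext, role, pol, i, True)
        pclock[i] = np.random.randint(0, mpi + 1)


@njit(cache=True)
def _contact_dirs(ax, ay, plen, i, dirs_buf):
    """Unique compass directions toward agents in filopodial contact with
    agent i (its rays touching their body, or theirs touching its body)."""
    n = ax.size
    m = 0
    for j in range(n):
        if j == i:
            continue
        touching = False
        for d in range(8):
            if _covers(ax[i], ay[i], d, plen[i, d], ax[j], ay[j]):
                touching = True
                break
        if not touching:
            for d in range(8):
                if _covers(ax[j], ay[j], d, plen[j, d], ax[i], ay[i]):
                    touching = True
                    break
        if touching:
            cd = _octant(ax[j] - ax[i], ay[j] - ay[i])
            dup = False
            for k in range(m):
                if dirs_buf[k] == cd:
                    dup = True
                    break
            if not dup:
                dirs_buf[m] = cd
                m += 1
    return m


@njit(cache=True)
def _record_links(ax, ay, plen, i, lo, ld, lp):
    """Record every protrusion link involving agent i: (owner, direction,
    partner) triples for rays currently covering a body site."""
    n = ax.size
    cnt = 0
    for j in range(n):
        if j == i:
            continue
        for d in range(8):
            if _covers(ax[i], ay[i], d, plen[i, d], ax[j], ay[j]):
                lo[cnt] = i
                ld[cnt] = d
                lp[cnt] = j
                cnt += 1
        for d in range(8):
            if _covers(ax[j], ay[j], d, plen[j, d], ax[i], ay[i]):
                lo[cnt] = j
                ld[cnt] = d
                lp[cnt] = i
                cnt += 1
    return cnt


@njit(cache=True)
def _maintain_links(ax, ay, role, plen, fmp_t, lmp_t, lo, ld, lp, cnt):
    """After a move, each previously linked protrusion may lengthen or
    shorten one site toward its partner's body (FMP/LMP), clamped to
    [0, 3]; on a false draw, or when the partner left the ray, the length
    is unchanged and the contact may break."""
    for t in range(cnt):
        o = lo[t]
        d = ld[t]
        p = lp[t]
        length = plen[o, d]
        if length <= 0:
            continue
        k = _ray_k(ax[o], ay[o], d, ax[p], ay[p])
        if k == 0 or k == length:
            continue
        p_m = lmp_t if role[o] == LEADER else fmp_t
        do_adjust = False
        if p_m > 0.0:
            do_adjust = np.random.random() < p_m
        if do_adjust:
            if k > length and length < MAX_PROT_LEN:
                plen[o, d] = length + 1
            elif k < length:
                plen[o, d] = length - 1


@njit(cache=True)
def _try_move(sites, ax, ay, i, d, pos_t, ats_t, W, H, ecm_gate):
    """Attempt a one-site move in direction d.  Occupied or out-of-bounds
    destinations cancel the move.  With the ECM gate active, a Closed
    destination requires a false draw from POS, and a move into an Open
    site followed by a second contiguous Open site grants an extra step
    on a true draw from ATS.  Returns True iff the agent moved."""
    nx = ax[i] + DX[d]
    ny = ay[i] + DY[d]
    if nx < 0 or nx >= W or ny < 0 or ny >= H:
        return False
    s = sites[nx, ny]
    if s == OCCUPIED:
        return False
    if not ecm_gate:
        _do_move(sites, ax, ay, i, nx, ny)
        return True
    if s == CLOSED:
        if pos_t > 0.0 and np.random.random() < pos_t:
            return False
        _do_move(sites, ax, ay, i, nx, ny)
        return True
    _do_move(sites, ax, ay, i, nx, ny)
    nx2 = nx + DX[d]
    ny2 = ny + DY[d]
    if 0 <= nx2 < W and 0 <= ny2 < H and sites[nx2, ny2] == OPEN:
        if ats_t > 0.0 and np.random.random() < ats_t:
            _do_move(sites, ax, ay, i, nx2, ny2)
    return True


@njit(cache=True)
def _ecm_update_one(sites, ax, ay, role, ldd_cdf, fdd_cdf, pos_t, ats_t,
                    W, H, i):
    """One ECM-rule update of agent i: draw a direction from LDD/FDD (none
    keeps the agent stationary) and execute it through the site-state gate."""
    if role[i] == LEADER:
        d = _sample_cdf(ldd_cdf)
    else:
        d = _sample_cdf(fdd_cdf)
    if d == NONE_DIR:
        return
    _try_move(sites, ax, ay, i, d, pos_t, ats_t, W, H, True)


@njit(cache=True)
def _contact_update_one(sites, ax, ay, role, pol, ext, plen,
                        ldd_cdf, pack, W, H, i, ecm_gate,
                        dirs_buf, lo, ld, lp):
    """One Contact-rule update of agent i.

    Precedence: a filopodial contact plus a true LMC/FMC draw triggers a
    move toward the contact (re-polarizing a Follower to that direction),
    optionally followed by an LRP/FRP retraction; otherwise a Leader moves
    by LDD and a Follower by its polarized direction.  With the ECM gate
    (Hybrid Model) the chosen direction is executed through the ECM
    site-state rules; without it, Closed sites do not impede movement.
    """
    pos_t = pack[P_POS]
    ats_t = pack[P_ATS]
    m = _contact_dirs(ax, ay, plen, i, dirs_buf)
    if m > 0:
        p_mc = pack[P_LMC] if role[i] == LEADER else pack[P_FMC]
        if p_mc > 0.0 and np.random.random() < p_mc:
            if m > 1:
                cd = dirs_buf[np.random.randint(0, m)]
            else:
                cd = dirs_buf[0]
            if role[i] == FOLLOWER:
                pol[i] = cd
                if ext[i]:
                    _set_protrusions(plen, ext, role, pol, i, True)
            cnt = _record_links(ax, ay, plen, i, lo, ld, lp)
            moved = _try_move(sites, ax, ay, i, cd, pos_t, ats_t, W, H,
                              ecm_gate)
            if moved:
                _maintain_links(ax, ay, role, plen, pack[P_FMP], pack[P_LMP],
                                lo, ld, lp, cnt)
                p_rp = pack[P_LRP] if role[i] == LEADER else pack[P_FRP]
                if p_rp > 0.0 and np.random.random() < p_rp:
                    _set_protrusions(plen, ext, role, pol, i, False)
            return
    if role[i] == LEADER:
        d = _sample_cdf(ldd_cdf)
    else:
        d = pol[i]
    if d == NONE_DIR:
        return
    cnt = _record_links(ax, ay, plen, i, lo, ld, lp)
    moved = _try_move(sites, ax, ay, i, d, pos_t, ats_t, W, H, ecm_gate)
    if moved:
        _maintain_links(ax, ay, role, plen, pack[P_FMP], pack[P_LMP],
                        lo, ld, lp, cnt)


@njit(cache=True)
def _pick_order(n, scheduler, order):
    if scheduler == SCHED_SHUFFLE:
        perm = np.random.permutation(n)
        for k in range(n):
            order[k] = perm[k]
    else:
        for k in range(n):
            order[k] = np.random.randint(0, n)


@njit(cache=True)
def advance(model, sites, ax, ay, role, pol, dclock, pclock, ext, plen,
            pack, scheduler):
    """Advance the state by one time step: tick every clock (Contact and
    Hybrid Models), then perform n agent updates in scheduler order."""
    W, H = sites.shape
    n = ax.size
    ldd_cdf = _cdf(pack[P_LDD:P_LDD + 9])
    fdd_cdf = _cdf(pack[P_FDD:P_FDD + 9])
    if model != MODEL_ECM:
        mdi = int(pack[P_MDI])
        mpi = int(pack[P_MPI])
        for i in range(n):
            _tick_clocks_one(ax, ay, role, pol, dclock, pclock, ext, plen,
                             fdd_cdf, mdi, mpi, pack[P_PPC], i)
    order = np.empty(n, np.int64)
    _pick_order(n, scheduler, order)
    dirs_buf = np.empty(8, np.int64)
    lo = np.empty(160, np.int64)
    ld = np.empty(160, np.int64)
    lp = np.empty(160, np.int64)
    for k in range(n):
        i = order[k]
        if model == MODEL_ECM:
            _ecm_update_one(sites, ax, ay, role, ldd_cdf, fdd_cdf,
                            pack[P_POS], pack[P_ATS], W, H, i)
        else:
            _contact_update_one(sites, ax, ay, role, pol, ext, plen,
                                ldd_cdf, pack, W, H, i,
                                model == MODEL_HYBRID,
                                dirs_buf, lo, ld, lp)


@njit(cache=True)
def init_state(model, pack, W, H, n_leaders, n_followers):
    """Build the initial state: a single-file chain on the mid-height row
    with Followers at x=1..nF and Leaders distal-most, every agent site
    Occupied, and (when requested) an Open track from the front agent to
    the distal edge.  Contact/Hybrid agents start with extended
    protrusions; SID/SIP control whether Follower directions and the
    protrusion clocks start synchronized."""
    n = n_leaders + n_followers
    sites = np.zeros((W, H), np.uint8)
    ax = np.empty(n, np.int64)
    ay = np.empty(n, np.int64)
    role = np.empty(n, np.uint8)
    pol = np.full(n, NONE_DIR, np.int64)
    dclock = np.zeros(n, np.int64)
    pclock = np.zeros(n, np.int64)
    ext = np.zeros(n, np.bool_)
    plen = np.zeros((n, 8), np.int64)
    row = H // 2
    for k in range(n):
        ax[k] = 1 + k
        ay[k] = row
        role[k] = FOLLOWER if k < n_followers else LEADER
        sites[ax[k], ay[k]] = OCCUPIED
    if pack[P_TRACK] > 0.5 and model != MODEL_CONTACT:
        for x in range(n + 1, W):
            sites[x, row] = OPEN
    if model != MODEL_ECM:
        fdd_cdf = _cdf(pack[P_FDD:P_FDD + 9])
        mdi = int(pack[P_MDI])
        mpi = int(pack[P_MPI])
        if pack[P_SID] > 0.5:
            common = np.random.randint(0, mdi + 1)
            for i in range(n):
                if role[i] == FOLLOWER:
                    pol[i] = 0  # distal
                    dclock[i] = common
        else:
            for i in range(n):
                if role[i] == FOLLOWER:
                    pol[i] = _sample_cdf(fdd_cdf)
                    dclock[i] = np.random.randint(0, mdi + 1)
        if pack[P_SIP] > 0.5:
            common = np.random.randint(0, mpi + 1)
            for i in range(n):
                pclock[i] = common
        else:
            for i in range(n):
                pclock[i] = np.random.randint(0, mpi + 1)
        for i in range(n):
            _set_protrusions(plen, ext, role, pol, i, True)
    return sites, ax, ay, role, pol, dclock, pclock, ext, plen


@njit(cache=True)
def run_one(model, pack, W, H, n_leaders, n_followers, max_steps,
            cumulative, scheduler, seed):
    """Run one replicate and return (persistence, termination, steps,
    final mean x of all agents).

    Persistence counts every step on which the structural chain criterion
    (a chain of >= 6 sequential agents) and the velocity criterion (chain
    centroid advanced >= 1 site over the last 10-step window, evaluated at
    checkpoints t = 10, 20, ...) both hold.  In the default (strict) mode
    the run terminates at the first failure of either criterion — the
    chain migratory pattern has broken; in cumulative mode a failure only
    suspends the counter and non-consecutive chain steps accumulate.
    Reaching the distal edge or max_steps always ends the run.
    """
    np.random.seed(seed)
    sites, ax, ay, role, pol, dclock, pclock, ext, plen = init_state(
        model, pack, W, H, n_leaders, n_followers)
    n = ax.size
    mask = np.zeros(n, np.bool_)
    cent = np.zeros(max_steps + 1)
    csize = _chain_mask(ax, ay, mask)
    if csize >= 6:
        s = 0.0
        c = 0
        for i in range(n):
            if mask[i]:
                s += ax[i]
                c += 1
        cent[0] = s / c
    else:
        cent[0] = np.mean(ax.astype(np.float64))
    persistence = 0
    vel_ok = True
    term = TERM_MAX_STEPS
    steps = 0
    for t in range(1, max_steps + 1):
        advance(model, sites, ax, ay, role, pol, dclock, pclock, ext, plen,
                pack, scheduler)
        steps = t
        csize = _chain_mask(ax, ay, mask)
        if csize >= 6:
            s = 0.0
            c = 0
            for i in range(n):
                if mask[i]:
                    s += ax[i]
                    c += 1
            cent[t] = s / c
            chain_ok = True
        else:
            cent[t] = np.mean(ax.astype(np.float64))
            chain_ok = False
            if not cumulative:
                term = TERM_CHAIN_BROKEN
                break
        if t % 10 == 0:
            vel_ok = cent[t] - cent[t - 10] >= 1.0
            if not vel_ok and not cumulative:
                term = TERM_VELOCITY_FAILED
                break
        if chain_ok and vel_ok:
            persistence += 1
        reached = False
        for i in range(n):
            if ax[i] == W - 1:
                reached = True
                break
        if reached:
            term = TERM_TARGET_REACHED
            break
    return persistence, term, steps, np.mean(ax.astype(np.float64))


@njit(cache=True)
def run_batch(model, pack, W, H, n_leaders, n_followers, max_steps,
              cumulative, scheduler, seeds):
    """Run one replicate per seed; returns (persistence, termination,
    steps, final centroid x) arrays."""
    m = seeds.size
    pers = np.empty(m, np.int64)
    term = np.empty(m, np.int64)
    steps = np.empty(m, np.int64)
    cx = np.empty(m)
    for r in range(m):
        p, te, st, c = run_one(model, pack, W, H, n_leaders, n_followers,
                               max_steps, cumulative, scheduler, seeds[r])
        pers[r] = p
        term[r] = te
        steps[r] = st
        cx[r] = c
    return pers, term, steps, cx
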