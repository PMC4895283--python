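"""Compiled numerical kernels (numba).

Folding side
------------
The intramolecular model scores a nested structure as a sum of per-pair
energies plus helix stacking terms for directly adjacent pairs (i, k) and
(i+1, k-1).  The partition function follows the unambiguous grammar

    Z[i, j)  = Z[i+1, j) + sum_k  Zb(i, k) * Z[k+1, j)
    Zb(i, k) = p(i, k) * [ Z[i+1, k) + (st(i, k) - 1) * Zb(i+1, k-1) ]

where p(i, k) = exp(-E_pair/RT) for an allowed pair (k - i > min_loop and
within the pair-span limit), st(i, k) = exp(-E_stack/RT) for the stack of
(i, k) on (i+1, k-1), and Zb is the Boltzmann sum over structures of
[i..k] in which (i, k) is paired.  The bracket works because Z[i+1, k)
already contains Zb(i+1, k-1) once, with no stack credit.

``outside`` fills the matching outside quantities O[a, b) for segment
nonterminals and Ob(i, k) for paired nonterminals.  From these,
``span_accessibility`` computes for every span [a, b) the constrained
partition function via the tightest-enclosing-pair decomposition

    Zc(a, b) = Z[0, a) * Z[b, n)
             + sum_{i<a, k>=b} Ob(i, k) * p(i, k) * Z[i+1, a) * Z[b, k)

(no stack correction appears: the pair directly inside a tightest enclosing
pair would itself enclose the window, or land inside it), and hence the
opening energy dE_acc = -RT log(Zc/Z) for all spans in O(n^3) total.

To stay inside double range for long/structured sequences, all recursions
are computed in a per-nucleotide rescaled form: each residue carries a
factor 1/sigma (so p is divided by sigma^2 and the unpaired step by sigma).
The rescaling cancels exactly in the Zc/Z ratio up to a sigma^(b-a) factor
that is restored analytically.

Duplex side
-----------
Gapless-backbone intermolecular duplexes: pairs (qi, tj) with qi strictly
increasing and tj strictly decreasing, consecutive pairs separated by an
interior loop/bulge of total unpaired length <= max_loop.  Energy =
duplex_init + stacking terms (adjacent pairs) + linear loop penalties.
Three small DPs support the exact interaction-energy search in hybridize:
right-anchored (with traceback of the left end), left-anchored, and
start-anchored with parent pointers.
"""

import numpy as np
from numba import njit

NB_OPTS = dict(cache=False, fastmath=False)


@njit(**NB_OPTS)
def inside(P, ST, hw, invsig, min_loop):
    """Scaled inside sums Z[i, j) and paired sums Zb(i, k).

    P holds scaled pair weights p(i, k) (0 = disallowed); ST holds the stack
    Boltzmann factor of pair (i, k) on pair (i+1, k-1); hw is the Boltzmann
    factor of the helix-initiation cost, paid on the innermost pair of each
    helix (the branch where (i+1, k-1) is not paired).
    """
    n = P.shape[0]
    Z = np.zeros((n + 1, n + 1))
    Zb = np.zeros((n, n))
    for i in range(n + 1):
        Z[i, i] = 1.0
    for i in range(n - 1, -1, -1):
        for k in range(i + min_loop + 1, n):
            p = P[i, k]
            if p > 0.0:
                inner = hw * Z[i + 1, k]
                if k - 1 > i + 1:
                    inner += (ST[i, k] - hw) * Zb[i + 1, k - 1]
                Zb[i, k] = p * inner
        for j in range(i + 1, n + 1):
            acc = Z[i + 1, j] * invsig
            for k in range(i + min_loop + 1, j):
                if Zb[i, k] != 0.0:
                    acc += Zb[i, k] * Z[k + 1, j]
            Z[i, j] = acc
    return Z, Zb


@njit(**NB_OPTS)
def outside(P, ST, hw, Z, Zb, invsig, min_loop):
    """Scaled outside weights O[a, b) and Ob(i, k) for :func:`inside`."""
    n = P.shape[0]
    O = np.zeros((n + 1, n + 1))
    Ob = np.zeros((n, n))
    O[0, n] = 1.0
    for a in range(0, n + 1):
        if a >= 1:
            for b in range(a, n + 1):
                acc = O[a - 1, b] * invsig
                # segment is the bracket interior of pair (a-1, b)
                if b <= n - 1 and P[a - 1, b] > 0.0:
                    acc += Ob[a - 1, b] * P[a - 1, b] * hw
                # segment is the right sibling of pair (i, a-1)
                for i in range(0, a - 1 - min_loop):
                    if Zb[i, a - 1] != 0.0:
                        acc += O[i, b] * Zb[i, a - 1]
                O[a, b] = acc
        for k in range(a + min_loop + 1, n):
            if P[a, k] <= 0.0:
                continue
            s = 0.0
            # sibling decomposition Z[a, j) -> Zb(a, k) Z[k+1, j)
            for j in range(k + 1, n + 1):
                s += O[a, j] * Z[k + 1, j]
            # stacked under pair (a-1, k+1)
            if a >= 1 and k + 1 <= n - 1 and P[a - 1, k + 1] > 0.0:
                s += Ob[a - 1, k + 1] * P[a - 1, k + 1] * (ST[a - 1, k + 1] - hw)
            Ob[a, k] = s
    return O, Ob


@njit(**NB_OPTS)
def span_accessibility(P, Z, Ob, hw, rt, lnsig, min_loop):
    """Opening energies ED[a, b] = -RT log(Zc(a,b)/Z) for every span [a, b).

    Entries with a >= b are 0.  Spans whose scaled Zc underflows to zero get
    +inf (effectively inaccessible).  The result is sanitized to be
    non-negative and monotone under span inclusion, which holds exactly in
    real arithmetic.
    """
    n = P.shape[0]
    ED = np.zeros((n + 1, n + 1))
    lnZ = np.log(Z[0, n])
    C = np.zeros(n)
    for b in range(1, n + 1):
        # C[i] = sum_{k >= b} Ob(i,k) p(i,k) hw Z[b, k); the tightest
        # enclosing pair is always the innermost of its helix here
        for i in range(min(b, n)):
            s = 0.0
            for k in range(b, n):
                if P[i, k] > 0.0:
                    s += Ob[i, k] * P[i, k] * hw * Z[b, k]
            C[i] = s
        for a in range(0, b):
            zc = Z[0, a] * Z[b, n]
            for i in range(0, a):
                zc += Z[i + 1, a] * C[i]
            if zc <= 0.0:
                ED[a, b] = np.inf
            else:
                e = -rt * (np.log(zc) - lnZ) + rt * (b - a) * lnsig
                ED[a, b] = e if e > 0.0 else 0.0
    # monotone sanitation: widening a span can never cost less
    for length in range(2, n + 1):
        for a in range(0, n - length + 1):
            b = a + length
            lo = ED[a + 1, b]
            if ED[a, b - 1] > lo:
                lo = ED[a, b - 1]
            if ED[a, b] < lo:
                ED[a, b] = lo
    return ED


# ---------------------------------------------------------------------------
# duplex kernels
# ---------------------------------------------------------------------------


@njit(**NB_OPTS)
def build_duplex_graph(P, S6, loop_open, coef, max_loop):
    """Sparse predecessor graph over the allowed cells of a window pair.

    Cells are the (qi, tj) positions that can form a duplex pair, listed in
    topological order (qi ascending, tj descending); an edge p -> c exists
    when pair c can follow pair p (strictly increasing qi, strictly
    decreasing tj, total unpaired length <= max_loop) and carries the exact
    transition cost (stacking term for adjacent pairs, linear loop penalty
    otherwise).  Built once per window and reused by every anchored DP.

    Returns (qi_arr, tj_arr, cell_of, indptr, pred, cost).
    """
    m, n = P.shape
    cell_of = np.full((m, n), -1, dtype=np.int32)
    ncells = 0
    for qi in range(m):
        for tj in range(n - 1, -1, -1):
            if P[qi, tj] >= 0:
                cell_of[qi, tj] = ncells
                ncells += 1
    qi_arr = np.empty(ncells, dtype=np.int32)
    tj_arr = np.empty(ncells, dtype=np.int32)
    for qi in range(m):
        for tj in range(n):
            c = cell_of[qi, tj]
            if c >= 0:
                qi_arr[c] = qi
                tj_arr[c] = tj
    # count then fill predecessor lists
    counts = np.zeros(ncells + 1, dtype=np.int64)
    for c in range(ncells):
        qi = qi_arr[c]
        tj = tj_arr[c]
        k = 0
        for dq in range(1, min(qi, max_loop + 1) + 1):
            rem = max_loop + 1 - dq
            for dt in range(1, min(n - 1 - tj, rem + 1) + 1):
                if cell_of[qi - dq, tj + dt] >= 0:
                    k += 1
        counts[c + 1] = k
    indptr = np.cumsum(counts)
    nedges = indptr[ncells]
    pred = np.empty(nedges, dtype=np.int32)
    cost = np.empty(nedges, dtype=np.float64)
    for c in range(ncells):
        qi = qi_arr[c]
        tj = tj_arr[c]
        e = indptr[c]
        for dq in range(1, min(qi, max_loop + 1) + 1):
            rem = max_loop + 1 - dq
            for dt in range(1, min(n - 1 - tj, rem + 1) + 1):
                p = cell_of[qi - dq, tj + dt]
                if p >= 0:
                    pred[e] = p
                    if dq == 1 and dt == 1:
                        cost[e] = S6[P[qi - 1, tj + 1], P[qi, tj]]
                    else:
                        cost[e] = loop_open + coef * ((dq - 1) + (dt - 1))
                    e += 1
    return qi_arr, tj_arr, cell_of, indptr, pred, cost


@njit(**NB_OPTS)
def duplex_right_dp(ncells, indptr, pred, cost, init):
    """Min hybrid energy of a duplex ending at each cell, with traced start.

    Returns (H, S): H[c] = optimal energy (including duplex_init) over
    duplexes whose last pair is cell c; S[c] = first pair of one optimum.
    """
    H = np.full(ncells, np.inf)
    S = np.empty(ncells, dtype=np.int32)
    for c in range(ncells):
        best = init
        bs = c
        for e in range(indptr[c], indptr[c + 1]):
            p = pred[e]
            v = H[p] + cost[e]
            if v < best:
                best = v
                bs = S[p]
        H[c] = best
        S[c] = bs
    return H, S


@njit(**NB_OPTS)
def duplex_start_bounds(ncells, indptr, pred, cost, qi_arr, tj_arr, init, EDq, EDt):
    """Per-start lower bounds on e_int over all duplexes with that first pair.

    Two families of bounds, both exploiting ED monotonicity under span
    inclusion, are combined by max:

    * query-exact: for each start row sa, a reverse DP over cells with
      qi >= sa carrying the exact query-span opening EDq[sa, ea] plus the
      single-position target bound EDt[eb, eb] <= EDt(span);
    * target-exact: symmetric, for each start column sb.
    """
    bounds = np.full(ncells, -np.inf)
    R = np.empty(ncells)
    m = 0
    n = 0
    for c in range(ncells):
        if qi_arr[c] + 1 > m:
            m = qi_arr[c] + 1
        if tj_arr[c] + 1 > n:
            n = tj_arr[c] + 1
    # query-exact sweeps, one per start row
    for sa in range(m):
        for c in range(ncells):
            if qi_arr[c] >= sa:
                R[c] = EDq[sa, qi_arr[c]] + EDt[tj_arr[c], tj_arr[c]]
            else:
                R[c] = np.inf
        for c in range(ncells - 1, -1, -1):
            if qi_arr[c] <= sa:
                continue
            rc = R[c]
            if rc == np.inf:
                continue
            for e in range(indptr[c], indptr[c + 1]):
                p = pred[e]
                v = rc + cost[e]
                if v < R[p]:
                    R[p] = v
        for c in range(ncells):
            if qi_arr[c] == sa and init + R[c] > bounds[c]:
                bounds[c] = init + R[c]
    # target-exact sweeps, one per start column
    for sb in range(n):
        for c in range(ncells):
            if tj_arr[c] <= sb:
                R[c] = EDt[tj_arr[c], sb] + EDq[qi_arr[c], qi_arr[c]]
            else:
                R[c] = np.inf
        for c in range(ncells - 1, -1, -1):
            if tj_arr[c] >= sb:
                continue
            rc = R[c]
            if rc == np.inf:
                continue
            for e in range(indptr[c], indptr[c + 1]):
                p = pred[e]
                v = rc + cost[e]
                if v < R[p]:
                    R[p] = v
        for c in range(ncells):
            if tj_arr[c] == sb and init + R[c] > bounds[c]:
                bounds[c] = init + R[c]
    return bounds


@njit(**NB_OPTS)
def duplex_heuristic_best(H, S, qi_arr, tj_arr, EDq, EDt):
    """Best e_int over right-DP cells using each cell's traced start.

    Upper bound on the exact optimum (every candidate is a real duplex).
    EDq[a, e] is the opening energy of query window span [a, e] inclusive;
    EDt[l, h] likewise for the target window.
    """
    best = np.inf
    for c in range(H.shape[0]):
        if H[c] == np.inf:
            continue
        s = S[c]
        val = H[c] + EDq[qi_arr[s], qi_arr[c]] + EDt[tj_arr[c], tj_arr[s]]
        if val < best:
            best = val
    return best


@njit(**NB_OPTS)
def duplex_anchored_dp(start, ncells, indptr, pred, cost, qi_arr, tj_arr, init, EDq, EDt):
    """Exact min e_int over duplexes whose first pair is exactly ``start``.

    Returns (best_eint, end_cell, parent) where parent holds traceback
    pointers (start's parent is itself).
    """
    sa = qi_arr[start]
    sb = tj_arr[start]
    A = np.full(ncells, np.inf)
    parent = np.full(ncells, -1, dtype=np.int32)
    A[start] = init
    parent[start] = start
    best = init + EDq[sa, sa] + EDt[sb, sb]
    bestc = start
    for c in range(start + 1, ncells):
        if qi_arr[c] <= sa or tj_arr[c] >= sb:
            continue
        cell = np.inf
        par = -1
        for e in range(indptr[c], indptr[c + 1]):
            p = pred[e]
            if A[p] == np.inf:
                continue
            v = A[p] + cost[e]
            if v < cell:
                cell = v
                par = p
        if par < 0:
            continue
        A[c] = cell
        parent[c] = par
        val = cell + EDq[sa, qi_arr[c]] + EDt[tj_arr[c], sb]
        if val < best:
            best = val
            bestc = c
    return best, bestc, parent


@njit(**NB_OPTS)
def duplex_branch_and_bound(
    ncells, indptr, pred, cost, qi_arr, tj_arr, init, EDq, EDt
):
    """Exact minimum e_int over all duplexes in the window pair.

    Branch-and-bound over the duplex's first pair: opening energies are
    monotone under span inclusion, so Hl(start) + single-position opening
    costs lower-bounds every duplex with that start.  Starts are explored in
    bound order against an incumbent from the heuristic right-anchored DP.

    Returns (best_eint, start_cell, end_cell, parent).
    """
    H, S = duplex_right_dp(ncells, indptr, pred, cost, init)
    incumbent = duplex_heuristic_best(H, S, qi_arr, tj_arr, EDq, EDt)
    bounds = duplex_start_bounds(
        ncells, indptr, pred, cost, qi_arr, tj_arr, init, EDq, EDt
    )
    order = np.argsort(bounds)

    best = np.inf
    best_start = -1
    best_end = -1
    best_parent = np.full(ncells, -1, dtype=np.int32)
    for idx in range(ncells):
        c = order[idx]
        if bounds[c] >= best or bounds[c] > incumbent + 1e-12:
            break
        val, endc, parent = duplex_anchored_dp(
            c, ncells, indptr, pred, cost, qi_arr, tj_arr, init, EDq, EDt
        )
        if val < best:
            best = val
            best_start = c
            best_end = endc
            best_parent = parent
    return best, best_start, best_end, best_parent
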