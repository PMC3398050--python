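"""The mechanistic home-range establishment model.

A home range is a contiguous (rook-adjacent, toroidal) set of at least
four 15-m cells.  Its benefit saturates with the total discounted
habitat value it encompasses,

    S    = sum_c V_c / (1 + N_c)          (N_c = other ranges covering c)
    HR_B = p1 * (1 - exp(-p2 * S))        ("exponential", default)
         = p1 * S / (p2 + S)              ("saturating", alternative)

The exponential form treats p2 as a rate: with the fitted vole
parameters it yields an interior optimal range size near 7.5 cells on
habitat of value ~1.6 and bounds packing at roughly nine ranges per
49-cell site, consistent with observed emergent behaviour; under the
saturating (half-saturation) alternative the same parameter values
drive every range to the 4-cell minimum.

its cost is a fixed metabolic demand plus a travel/exposure term,

    HR_C = p3 + sqrt(A)                   (A = number of cells)

and its net value is HR_NV = HR_B - HR_C.  A range is viable iff
HR_NV > 0.  Abundance on a grid is the maximum number of simultaneously
viable home ranges, found by iteratively adding ranges, greedily
optimising each (grow/shrink by one or two cells) in round-robin passes
to a fixpoint, and restarting from fresh random positions when a
configuration fails.

The greedy kernels are numba-compiled: the inverse fit evaluates
establishment thousands of times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from numba import njit

from .grids import CELL_AREA_HA, ValueGrid, toroidal_neighbours

__all__ = [
    "HRParams",
    "HomeRange",
    "SiteSolution",
    "hr_benefit",
    "hr_cost",
    "hr_net_value",
    "optimize_home_range",
    "establish_population",
    "greedy_best_home_range",
    "brute_force_best_home_range",
    "overlap_stats",
]

_FORMS = {"exponential": 0, "saturating": 1}

#: default benefit form
DEFAULT_FORM = "exponential"

#: strict-improvement tolerance for the greedy optimiser
_EPS = 1e-12


@dataclass(frozen=True)
class HRParams:
    """The three free home-range parameters.

    p1: benefit asymptote; p2: benefit half-saturation (shape); p3:
    area-independent home-range cost.  p1 > p3 is required for any home
    range to be potentially viable (a 4-cell range already costs
    p3 + 2).
    """

    p1: float
    p2: float
    p3: float

    def __post_init__(self):
        if not (np.isfinite(self.p1) and np.isfinite(self.p2) and np.isfinite(self.p3)):
            raise ValueError("home-range parameters must be finite")
        if self.p1 <= 0 or self.p2 <= 0 or self.p3 < 0:
            raise ValueError("require p1 > 0, p2 > 0, p3 >= 0")


#: best-fit parameters for red-backed voles in boreal mixedwood sites
VOLE_PARAMS = HRParams(p1=8.108, p2=0.222, p3=4.150)


@dataclass(frozen=True)
class HomeRange:
    """One established home range with its benefit/cost decomposition."""

    cells: frozenset
    hr_b: float
    hr_c: float
    hr_nv: float

    @property
    def area(self) -> int:
        return len(self.cells)

    @property
    def viable(self) -> bool:
        return self.hr_nv > 0.0


@dataclass(frozen=True)
class SiteSolution:
    """All home ranges established on one grid."""

    home_ranges: tuple
    overlap_counts: np.ndarray  # per-cell number of covering ranges
    grid: ValueGrid
    params: HRParams
    seed: int
    restarts_used: int

    @property
    def abundance(self) -> int:
        return len(self.home_ranges)


# ---------------------------------------------------------------------------
# numba kernels (flat arrays; cov counts ALL ranges including the focal one,
# so a focal member cell's discount 1 + N_c equals cov[c])
# ---------------------------------------------------------------------------


@njit(cache=True)
def _nv_from(S, A, p1, p2, p3, form):
    if form == 0:
        b = p1 * (1.0 - np.exp(-p2 * S))
    else:
        b = p1 * S / (p2 + S) if S > 0.0 else 0.0
    return b - p3 - np.sqrt(A)


@njit(cache=True)
def _range_stats(m, cov, V, p1, p2, p3, form):
    A = 0
    S = 0.0
    for i in range(m.size):
        if m[i] == 1:
            A += 1
            S += V[i] / cov[i]
    return S, A, _nv_from(S, A, p1, p2, p3, form)


@njit(cache=True)
def _connected_excl(m, nb, e1, e2, target):
    """True if the members of m minus {e1, e2} form one rook component."""
    n = m.size
    start = -1
    for i in range(n):
        if m[i] == 1 and i != e1 and i != e2:
            start = i
            break
    if start < 0:
        return target == 0
    visited = np.zeros(n, np.uint8)
    stack = np.empty(n, np.int64)
    sp = 0
    stack[sp] = start
    sp += 1
    visited[start] = 1
    count = 1
    while sp > 0:
        sp -= 1
        c = stack[sp]
        for j in range(4):
            u = nb[c, j]
            if m[u] == 1 and u != e1 and u != e2 and visited[u] == 0:
                visited[u] = 1
                stack[sp] = u
                sp += 1
                count += 1
    return count == target


@njit(cache=True)
def _best_move(m, cov, V, nb, p1, p2, p3, form):
    """Best strictly-improving move for the focal range, or (-1,-1,0).

    Moves: add one frontier cell, add an ordered pair of cells (second
    may neighbour the first), remove one or an ordered pair of cells
    (each removal keeps the range connected and >= 4 cells), or no-op.
    Ties broken lexicographically by affected flat cell index.
    """
    n = m.size
    S, A, cur = _range_stats(m, cov, V, p1, p2, p3, form)
    best_nv = cur
    bk1 = -1
    bk2 = -1
    bkind = 0
    found = False

    gain = np.empty(n)
    infront = np.zeros(n, np.uint8)
    frontier = np.empty(n, np.int64)
    nf = 0
    for i in range(n):
        if m[i] == 0:
            gain[i] = V[i] / (1.0 + cov[i])
            for j in range(4):
                if m[nb[i, j]] == 1:
                    infront[i] = 1
                    frontier[nf] = i
                    nf += 1
                    break

    # single additions
    for fi in range(nf):
        c = frontier[fi]
        nv = _nv_from(S + gain[c], A + 1, p1, p2, p3, form)
        if nv > cur + _EPS:
            take = False
            if not found or nv > best_nv + _EPS:
                take = True
            elif nv >= best_nv - _EPS and (c < bk1 or (c == bk1 and -1 < bk2)):
                take = True
            if take:
                found = True
                best_nv = nv
                bk1 = c
                bk2 = -1
                bkind = 1

    # ordered pair additions: c2 must touch the grown range (m + c1),
    # i.e. lie in the frontier or neighbour c1 itself
    for fi in range(nf):
        c1 = frontier[fi]
        g1 = gain[c1]
        for fj in range(nf + 4):
            if fj < nf:
                c2 = frontier[fj]
            else:
                c2 = nb[c1, fj - nf]
                if m[c2] == 1 or infront[c2] == 1:
                    continue  # already handled as a frontier candidate
            if c2 == c1:
                continue
            nv = _nv_from(S + g1 + gain[c2], A + 2, p1, p2, p3, form)
            if nv > cur + _EPS:
                take = False
                if not found or nv > best_nv + _EPS:
                    take = True
                elif nv >= best_nv - _EPS and (
                    c1 < bk1 or (c1 == bk1 and c2 < bk2)
                ):
                    take = True
                if take:
                    found = True
                    best_nv = nv
                    bk1 = c1
                    bk2 = c2
                    bkind = 2

    # removals: net value is evaluated first and the (costly)
    # connectivity check runs only for moves that would win
    removable = np.full(n, -1, np.int8)  # lazy: -1 unknown, 0 no, 1 yes
    if A - 1 >= 4:
        for c in range(n):
            if m[c] == 0:
                continue
            nv = _nv_from(S - V[c] / cov[c], A - 1, p1, p2, p3, form)
            if nv > cur + _EPS:
                take = False
                if not found or nv > best_nv + _EPS:
                    take = True
                elif nv >= best_nv - _EPS and (c < bk1 or (c == bk1 and -1 < bk2)):
                    take = True
                if take:
                    if removable[c] < 0:
                        removable[c] = 1 if _connected_excl(m, nb, c, -1, A - 1) else 0
                    if removable[c] == 1:
                        found = True
                        best_nv = nv
                        bk1 = c
                        bk2 = -1
                        bkind = 3

    # ordered pair removals: each step keeps the range connected
    if A - 2 >= 4:
        for c1 in range(n):
            if m[c1] == 0:
                continue
            l1 = V[c1] / cov[c1]
            for c2 in range(n):
                if c2 == c1 or m[c2] == 0:
                    continue
                nv = _nv_from(S - l1 - V[c2] / cov[c2], A - 2, p1, p2, p3, form)
                if nv > cur + _EPS:
                    take = False
                    if not found or nv > best_nv + _EPS:
                        take = True
                    elif nv >= best_nv - _EPS and (
                        c1 < bk1 or (c1 == bk1 and c2 < bk2)
                    ):
                        take = True
                    if take:
                        if removable[c1] < 0:
                            removable[c1] = (
                                1 if _connected_excl(m, nb, c1, -1, A - 1) else 0
                            )
                        if removable[c1] == 1 and _connected_excl(
                            m, nb, c1, c2, A - 2
                        ):
                            found = True
                            best_nv = nv
                            bk1 = c1
                            bk2 = c2
                            bkind = 4

    if not found:
        return -1, -1, 0
    return bk1, bk2, bkind


@njit(cache=True)
def _optimize_range(m, cov, V, nb, p1, p2, p3, form):
    """Greedy hill-climb for one range; mutates m and cov; True if changed."""
    changed = False
    for _ in range(100_000):
        c1, c2, kind = _best_move(m, cov, V, nb, p1, p2, p3, form)
        if kind == 0:
            break
        if kind == 1 or kind == 2:
            m[c1] = 1
            cov[c1] += 1
            if kind == 2:
                m[c2] = 1
                cov[c2] += 1
        else:
            m[c1] = 0
            cov[c1] -= 1
            if kind == 4:
                m[c2] = 0
                cov[c2] -= 1
        changed = True
    return changed


@njit(cache=True)
def _best_anchor(V, nrow, ncol):
    """Anchor (top-left) of the 2x2 block with the greatest total value."""
    best = -1.0
    br = 0
    bc = 0
    for r in range(nrow):
        for c in range(ncol):
            s = (
                V[r * ncol + c]
                + V[((r + 1) % nrow) * ncol + c]
                + V[r * ncol + (c + 1) % ncol]
                + V[((r + 1) % nrow) * ncol + (c + 1) % ncol]
            )
            if s > best + _EPS:
                best = s
                br = r
                bc = c
    return br, bc


@njit(cache=True)
def _place_block(m, cov, r0, c0, nrow, ncol):
    for dr in range(2):
        for dc in range(2):
            i = ((r0 + dr) % nrow) * ncol + ((c0 + dc) % ncol)
            if m[i] == 0:
                m[i] = 1
                cov[i] += 1


@njit(cache=True)
def _round_robin(R, kk, cov, V, nb, p1, p2, p3, form, max_passes):
    # individual ranges always improve their own net value, but one
    # range's move can degrade another's, so the joint dynamics may
    # cycle; the pass cap guards termination (normal convergence takes
    # a handful of passes)
    for _ in range(max_passes):
        any_change = False
        for r in range(kk):
            if _optimize_range(R[r], cov, V, nb, p1, p2, p3, form):
                any_change = True
        if not any_change:
            break


@njit(cache=True)
def _establish(V, nb, nrow, ncol, p1, p2, p3, form, restarts, seed, max_ranges,
               max_passes):
    np.random.seed(seed)
    n = V.size
    R = np.zeros((max_ranges, n), np.uint8)
    cov = np.zeros(n, np.int32)
    k = 0
    total_restarts = 0
    while k < max_ranges:
        kk = k + 1
        R_saved = R.copy()
        cov_saved = cov.copy()
        success = False
        for attempt in range(restarts + 1):
            if attempt == 0:
                if k == 0:
                    br, bc = _best_anchor(V, nrow, ncol)
                else:
                    br = np.random.randint(0, nrow)
                    bc = np.random.randint(0, ncol)
                _place_block(R[k], cov, br, bc, nrow, ncol)
            else:
                total_restarts += 1
                # reposition all kk ranges from fresh random initial blocks
                for r in range(kk):
                    for i in range(n):
                        if R[r, i] == 1:
                            cov[i] -= 1
                            R[r, i] = 0
                for r in range(kk):
                    br = np.random.randint(0, nrow)
                    bc = np.random.randint(0, ncol)
                    _place_block(R[r], cov, br, bc, nrow, ncol)
            _round_robin(R, kk, cov, V, nb, p1, p2, p3, form, max_passes)
            ok = True
            for r in range(kk):
                S, A, nv = _range_stats(R[r], cov, V, p1, p2, p3, form)
                if nv <= 0.0:
                    ok = False
                    break
            if ok:
                success = True
                break
        if not success:
            R[:, :] = R_saved
            cov[:] = cov_saved
            break
        k = kk
    return k, R, cov, total_restarts


# ---------------------------------------------------------------------------
# Python API
# ---------------------------------------------------------------------------


def _form_code(form: str) -> int:
    try:
        return _FORMS[form]
    except KeyError:
        raise ValueError(f"unknown benefit form {form!r}") from None


def _cells_to_mask(cells: Iterable, shape: tuple[int, int]) -> np.ndarray:
    nrow, ncol = shape
    m = np.zeros(nrow * ncol, np.uint8)
    for r, c in cells:
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError(f"cell {(r, c)} outside grid {shape}")
        m[r * ncol + c] = 1
    return m


def _mask_to_cells(m: np.ndarray, shape: tuple[int, int]) -> frozenset:
    ncol = shape[1]
    return frozenset((int(i) // ncol, int(i) % ncol) for i in np.nonzero(m)[0])


def _overlap_flat(overlap, shape) -> np.ndarray:
    if overlap is None:
        return np.zeros(shape[0] * shape[1], np.int32)
    arr = np.asarray(overlap)
    if arr.shape != shape:
        raise ValueError("overlap grid shape mismatch")
    if np.any(arr < 0):
        raise ValueError("overlap counts must be non-negative")
    return arr.astype(np.int32).ravel()


def hr_benefit(
    cells: Iterable,
    grid: ValueGrid,
    overlap=None,
    params: HRParams = VOLE_PARAMS,
    form: str = DEFAULT_FORM,
) -> float:
    """Benefit HR_B of a cell set; ``overlap`` counts OTHER ranges per cell."""
    m = _cells_to_mask(cells, grid.shape)
    if m.sum() == 0:
        raise ValueError("home range must contain at least one cell")
    ov = _overlap_flat(overlap, grid.shape)
    V = grid.values.ravel()
    S = float(np.sum(V[m == 1] / (1.0 + ov[m == 1])))
    code = _form_code(form)
    if code == 0:
        return params.p1 * (1.0 - np.exp(-params.p2 * S))
    return params.p1 * S / (params.p2 + S) if S > 0 else 0.0


def hr_cost(area: int, params: HRParams = VOLE_PARAMS) -> float:
    """Cost HR_C = p3 + sqrt(area), area in cells."""
    if area < 1:
        raise ValueError("area must be at least one cell")
    return params.p3 + float(np.sqrt(area))


def hr_net_value(
    cells: Iterable,
    grid: ValueGrid,
    overlap=None,
    params: HRParams = VOLE_PARAMS,
    form: str = DEFAULT_FORM,
) -> float:
    cells = list(cells)
    return hr_benefit(cells, grid, overlap, params, form) - hr_cost(len(cells), params)


def _make_home_range(
    m: np.ndarray, cov: np.ndarray, grid: ValueGrid, params: HRParams, form_code: int
) -> HomeRange:
    V = grid.values.ravel()
    S, A, nv = _range_stats(m, cov, V, params.p1, params.p2, params.p3, form_code)
    cost = params.p3 + float(np.sqrt(A))
    return HomeRange(
        cells=_mask_to_cells(m, grid.shape), hr_b=nv + cost, hr_c=cost, hr_nv=nv
    )


def _check_valid_range(m: np.ndarray, nb: np.ndarray) -> None:
    A = int(m.sum())
    if A < 4:
        raise ValueError("home range must contain at least 4 cells")
    if not _connected_excl(m, nb, -1, -1, A):
        raise ValueError("home range cells must form one rook-connected component")


def optimize_home_range(
    hr,
    grid: ValueGrid,
    overlap=None,
    params: HRParams = VOLE_PARAMS,
    form: str = DEFAULT_FORM,
) -> HomeRange:
    """Greedy hill-climb from an existing range (other ranges held fixed).

    At each step all legal one- and two-cell additions and removals are
    enumerated (removals keep the range connected and >= 4 cells) and
    the move with the greatest resulting HR_NV is applied, until no move
    strictly improves HR_NV.
    """
    cells = hr.cells if isinstance(hr, HomeRange) else hr
    m = _cells_to_mask(cells, grid.shape)
    nb = toroidal_neighbours(grid.shape)
    _check_valid_range(m, nb)
    ov = _overlap_flat(overlap, grid.shape)
    cov = ov + m.astype(np.int32)
    code = _form_code(form)
    _optimize_range(m, cov, grid.values.ravel(), nb, params.p1, params.p2, params.p3, code)
    return _make_home_range(m, cov, grid, params, code)


def establish_population(
    grid: ValueGrid,
    params: HRParams = VOLE_PARAMS,
    restarts: int = 20,
    seed: int = 0,
    form: str = DEFAULT_FORM,
    max_ranges: Optional[int] = None,
    max_passes: int = 15,
) -> SiteSolution:
    """Pack the maximum number of simultaneously viable home ranges.

    Starting from the best-placed 2x2 block, ranges are added one at a
    time; after each addition every range is re-optimised in round-robin
    passes until a full pass changes nothing.  If any range ends with
    HR_NV <= 0 the whole configuration is re-established from fresh
    random initial positions, up to ``restarts`` times; the abundance is
    the largest count for which all ranges are simultaneously viable.
    """
    if grid.n_cells < 4:
        raise ValueError("grid must contain at least 4 cells")
    if max_ranges is None:
        max_ranges = grid.n_cells // 4 + 8
    nb = toroidal_neighbours(grid.shape)
    code = _form_code(form)
    k, R, cov, used = _establish(
        grid.values.ravel(),
        nb,
        grid.shape[0],
        grid.shape[1],
        params.p1,
        params.p2,
        params.p3,
        code,
        int(restarts),
        int(seed) & 0x7FFFFFFF,
        int(max_ranges),
        int(max_passes),
    )
    ranges = tuple(
        _make_home_range(R[r], cov, grid, params, code) for r in range(k)
    )
    return SiteSolution(
        home_ranges=ranges,
        overlap_counts=cov.reshape(grid.shape).copy(),
        grid=grid,
        params=params,
        seed=int(seed),
        restarts_used=int(used),
    )


def greedy_best_home_range(
    grid: ValueGrid,
    params: HRParams = VOLE_PARAMS,
    restarts: int = 20,
    seed: int = 0,
    form: str = DEFAULT_FORM,
) -> HomeRange:
    """Best single home range over one deterministic start + random restarts."""
    nb = toroidal_neighbours(grid.shape)
    V = grid.values.ravel()
    code = _form_code(form)
    nrow, ncol = grid.shape
    rng = np.random.default_rng(seed)
    best = None
    for t in range(restarts + 1):
        m = np.zeros(grid.n_cells, np.uint8)
        cov = np.zeros(grid.n_cells, np.int32)
        if t == 0:
            r0, c0 = _best_anchor(V, nrow, ncol)
        else:
            r0 = int(rng.integers(nrow))
            c0 = int(rng.integers(ncol))
        _place_block(m, cov, r0, c0, nrow, ncol)
        _optimize_range(m, cov, V, nb, params.p1, params.p2, params.p3, code)
        cand = _make_home_range(m, cov, grid, params, code)
        if best is None or cand.hr_nv > best.hr_nv:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Exhaustive oracle (tests only): enumerate every connected cell set
# ---------------------------------------------------------------------------


def _connected_sets(nb_list, n, min_size, max_size):
    """Yield every rook-connected cell set of size min..max exactly once.

    ESU-style enumeration: sets are rooted at their minimum cell index
    and extended only with larger indices, so each set appears once.
    """
    for root in range(n):
        initial_ext = [u for u in nb_list[root] if u > root]
        stack = [({root}, initial_ext)]
        while stack:
            sub, ext = stack.pop()
            if len(sub) >= min_size:
                yield frozenset(sub)
            if len(sub) == max_size:
                continue
            while ext:
                w = ext[0]
                ext = ext[1:]
                # exclusive neighbourhood of w: beyond the current set and
                # its existing extension candidates
                excl = [
                    u
                    for u in nb_list[w]
                    if u > root and u not in sub and u not in ext and u != w
                ]
                seen = set(ext) | sub
                new_ext = ext + [u for u in excl if u not in seen]
                stack.append((sub | {w}, new_ext))


def brute_force_best_home_range(
    grid: ValueGrid,
    overlap=None,
    params: HRParams = VOLE_PARAMS,
    max_area: int = 8,
    form: str = DEFAULT_FORM,
) -> HomeRange:
    """Exhaustive optimum over all connected sets of 4..max_area cells.

    A test oracle: refuses grids larger than 5x5 or max_area > 8, where
    enumeration becomes combinatorially unreasonable.
    """
    if grid.n_cells > 25 or max_area > 8:
        raise ValueError("brute force limited to grids <= 5x5 and max_area <= 8")
    if max_area < 4:
        raise ValueError("max_area must be >= 4")
    nb = toroidal_neighbours(grid.shape)
    # deduplicate neighbour lists (small tori repeat neighbours)
    nb_list = [sorted(set(int(u) for u in nb[i])) for i in range(grid.n_cells)]
    ov = _overlap_flat(overlap, grid.shape)
    V = grid.values.ravel()
    disc = V / (1.0 + ov)
    code = _form_code(form)
    best_nv = -np.inf
    best_set = None
    for s in _connected_sets(nb_list, grid.n_cells, 4, max_area):
        S = float(sum(disc[i] for i in s))
        nv = _nv_from(S, len(s), params.p1, params.p2, params.p3, code)
        if nv > best_nv:
            best_nv = nv
            best_set = s
    m = np.zeros(grid.n_cells, np.uint8)
    for i in best_set:
        m[i] = 1
    cov = ov + m.astype(np.int32)
    return _make_home_range(m, cov, grid, params, code)


def overlap_stats(solution: SiteSolution) -> dict:
    """Coverage and overlap summaries for one site solution.

    Returns fractions of cells covered by 0/1/2/3+ ranges, mean and SD
    home-range size (cells and hectares), and the mean fraction of each
    range shared with at least one other range.
    """
    cov = solution.overlap_counts
    n = cov.size
    frac = {
        0: float(np.mean(cov == 0)),
        1: float(np.mean(cov == 1)),
        2: float(np.mean(cov == 2)),
        "3+": float(np.mean(cov >= 3)),
    }
    sizes = np.array([hr.area for hr in solution.home_ranges], dtype=float)
    if sizes.size:
        shared = []
        for hr in solution.home_ranges:
            cells = np.array([[r, c] for r, c in hr.cells])
            counts = cov[cells[:, 0], cells[:, 1]]
            shared.append(float(np.mean(counts >= 2)))
        mean_size = float(sizes.mean())
        sd_size = float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0
        mean_shared = float(np.mean(shared))
    else:
        mean_size = sd_size = mean_shared = 0.0
    return {
        "abundance": solution.abundance,
        "coverage_fractions": frac,
        "mean_size_cells": mean_size,
        "sd_size_cells": sd_size,
        "mean_size_ha": mean_size * CELL_AREA_HA,
        "sd_size_ha": sd_size * CELL_AREA_HA,
        "mean_fraction_shared": mean_shared,
    }
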