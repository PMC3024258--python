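"""Candidate Z-runs, ground-state search, and threshold-bounded enumeration.

A state of the molecule places 0..max_runs pairwise-disjoint Z-runs (even
length, default 8-250 bp) on the domain, separated by at least one B-form base
pair (two abutting runs are the same state as one longer run, so they are not
counted twice).  Its free energy is

    G = sum_i dg_i  +  2b * r  +  (K/2) * alpha_r(n_z, r)**2

where the first term is the sequence-dependent transition energy of the runs,
the second the nucleation cost of r runs, and the third the residual
superhelical stress energy.  The search first finds the minimum free energy
G_min and then enumerates every admissible state with G <= G_min + theta.

For fixed composition (n_z, r) the nucleation and stress terms are a constant,
so the threshold becomes a budget on the summed run transition energies; the
enumeration recurses over runs in start order with sorted, budget-based
pruning, closing the last one or two runs of a state in vectorized batches.
States are never stored: they are streamed into sufficient statistics (the
Boltzmann weight sum, a per-candidate weight total, and the state count),
which is what keeps paper-scale ensembles of ~1e9 states tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .energetics import DinucleotideEnergyTable, default_table, window_energies
from .mechanics import TopologyContext

__all__ = [
    "SearchParams",
    "CandidateRun",
    "CandidateSet",
    "SystemState",
    "SearchResult",
    "generate_candidates",
    "StateSearch",
    "find_minimum_state",
    "enumerate_states",
]

log = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass(frozen=True)
class SearchParams:
    """Run-geometry constraints and the enumeration threshold.

    theta is the free-energy window above the ground state within which all
    states are enumerated; neglected states have Boltzmann weight at most
    exp(-theta/RT) relative to the ground state.  ``theta=None`` means no
    threshold (exact enumeration; only sensible for tiny systems).
    """

    theta: float | None = 12.0
    min_run_len: int = 8
    max_run_len: int = 250
    max_runs: int = 4

    def __post_init__(self):
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive (or None for no threshold)")
        if self.min_run_len < 2 or self.min_run_len % 2:
            raise ValueError("min_run_len must be even and >= 2")
        if self.max_run_len < self.min_run_len:
            raise ValueError("max_run_len must be >= min_run_len")
        if self.max_runs < 0:
            raise ValueError("max_runs must be >= 0")

    @property
    def cap_theta(self) -> float:
        return np.inf if self.theta is None else self.theta


@dataclass(frozen=True)
class CandidateRun:
    """One candidate Z-run: start (0-based), even length, transition energy."""

    start: int
    length: int
    energy: float

    @property
    def end(self) -> int:
        """Exclusive end in unwrapped coordinates (may exceed N on a circle)."""
        return self.start + self.length


@dataclass(frozen=True)
class SystemState:
    """A set of disjoint, non-adjacent Z-runs with its total free energy."""

    runs: tuple[CandidateRun, ...]
    free_energy: float

    @property
    def n_z(self) -> int:
        return sum(r.length for r in self.runs)

    @property
    def r(self) -> int:
        return len(self.runs)

    def sort_key(self) -> tuple:
        return (self.r,) + tuple(x for run in self.runs for x in (run.start, run.length))


@dataclass
class CandidateSet:
    """All candidate runs of a sequence, energies precomputed once.

    Arrays are sorted by (start, length).  Candidates of a circular sequence
    may wrap the origin; their unwrapped end exceeds n_domain.
    """

    n_domain: int
    circular: bool
    starts: np.ndarray
    lengths: np.ndarray
    energies: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def run(self, i: int) -> CandidateRun:
        return CandidateRun(int(self.starts[i]), int(self.lengths[i]), float(self.energies[i]))


@dataclass
class SearchResult:
    """Sufficient statistics of a threshold-bounded enumeration.

    ``t_weight[i]`` is the summed relative Boltzmann weight (relative to the
    ground state) of every enumerated state that contains candidate ``i``;
    ``z_rel`` is the summed relative weight of all enumerated states.  All
    equilibrium quantities downstream derive from these.
    """

    g_min: float
    ground_state: SystemState
    states_enumerated: int
    theta: float
    beta: float
    candidates: CandidateSet
    z_rel: float
    t_weight: np.ndarray
    params: SearchParams = field(repr=False, default=None)

    @property
    def avg_n_z(self) -> float:
        return float((self.t_weight * self.candidates.lengths).sum() / self.z_rel)

    @property
    def avg_runs(self) -> float:
        return float(self.t_weight.sum() / self.z_rel)

    def coverage(self) -> np.ndarray:
        """Per-base-pair probability of being in Z-form, length n_domain."""
        n = self.candidates.n_domain
        diff = np.zeros(n + 1)
        s = self.candidates.starts
        e = s + self.candidates.lengths
        t = self.t_weight
        np.add.at(diff, s, t)
        np.add.at(diff, np.minimum(e, n), -t)
        wrap = e > n
        if wrap.any():
            diff[0] += t[wrap].sum()
            np.add.at(diff, e[wrap] - n, -t[wrap])
        # cumulative differencing leaves ~1e-16 cancellation noise
        return np.clip(np.cumsum(diff)[:n] / self.z_rel, 0.0, 1.0)

    def region_all_z(self, start: int, end: int) -> float:
        """Probability that every bp of [start, end) is Z-form.

        A contiguous all-Z region lies within a single run, so this is the
        summed weight of states containing a candidate that covers the region.
        """
        if end <= start:
            raise ValueError("empty region")
        s = self.candidates.starts
        e = s + self.candidates.lengths
        n = self.candidates.n_domain
        covers = (s <= start) & (e >= end)
        # a wrapped candidate also covers [start, end) if the region fits in
        # its wrapped tail
        wrap = e > n
        if wrap.any():
            covers |= wrap & (e - n >= end)
        return float(self.t_weight[covers].sum() / self.z_rel)


_CAND_CACHE: dict = {}
_CAND_CACHE_MAX = 4


def generate_candidates(
    codes: np.ndarray,
    circular: bool,
    params: SearchParams | None = None,
    table: DinucleotideEnergyTable | None = None,
) -> CandidateSet:
    """All (start, even length) windows within bounds, with transition energies.

    Lengths run from min_run_len to min(max_run_len, N-2) (N-1 for odd N on a
    circle, keeping at least one B-form bp); starts cover the whole circle, or
    0..N-L for a linear sequence.  Energies do not depend on sigma, so a few
    recently generated sets are cached by sequence content and bounds.
    """
    params = params or SearchParams()
    table = table or default_table()
    key = (codes.tobytes(), circular, params.min_run_len, params.max_run_len,
           id(table))
    cached = _CAND_CACHE.get(key)
    if cached is not None:
        return cached
    n = len(codes)
    all_s, all_l, all_e = [], [], []
    max_len = min(params.max_run_len, n - 2 if n % 2 == 0 else n - 1) if circular else min(
        params.max_run_len, n
    )
    for length in range(params.min_run_len, max_len + 1, 2):
        e = window_energies(codes, length, circular, table)
        s = np.arange(len(e))
        all_s.append(s)
        all_l.append(np.full(len(e), length))
        all_e.append(e)
    if all_s:
        starts = np.concatenate(all_s)
        lengths = np.concatenate(all_l)
        energies = np.concatenate(all_e)
        order = np.lexsort((lengths, starts))
        starts, lengths, energies = starts[order], lengths[order], energies[order]
    else:
        starts = np.empty(0, dtype=int)
        lengths = np.empty(0, dtype=int)
        energies = np.empty(0)
    log.debug("generated %d candidate runs for N=%d", len(starts), n)
    result = CandidateSet(
        n, circular, starts.astype(np.int64), lengths.astype(np.int64), energies
    )
    if len(_CAND_CACHE) >= _CAND_CACHE_MAX:
        _CAND_CACHE.pop(next(iter(_CAND_CACHE)))
    _CAND_CACHE[key] = result
    return result


class StateSearch:
    """Ground-state search and threshold-bounded enumeration for one (sequence,
    sigma) pair.

    The candidate set is pruned up front: a candidate can appear in an
    admissible state only if its energy plus an optimistic completion bound
    stays within theta of an upper bound on G_min.  The surviving candidates
    (sorted by start) drive a depth-first recursion over runs in start order.
    """

    def __init__(
        self,
        ctx: TopologyContext,
        candidates: CandidateSet,
        params: SearchParams | None = None,
    ):
        self.ctx = ctx
        self.params = params or SearchParams()
        self.full = candidates
        c = ctx.constants
        self.beta = 1.0 / c.rt
        self.n = candidates.n_domain
        if ctx.n_domain != candidates.n_domain:
            raise ValueError("topology context and candidate set disagree on N")
        self._setup()

    # -- tables ------------------------------------------------------------

    def _class_energy(self, n_z, r):
        """Nucleation + residual-stress energy of the (n_z, r) class."""
        c = self.ctx.constants
        alpha_r = self.ctx.alpha + n_z * c.delta_twist + 2.0 * r * c.junction_twist
        return c.run_nucleation * r + 0.5 * self.ctx.k_coeff * alpha_r * alpha_r

    def _setup(self):
        p = self.params
        cand = self.full
        m_all = len(cand)
        # index range must cover raw length sums of candidate tuples, which
        # are only later restricted by the geometry masks
        lmax = int(cand.lengths.max()) if m_all else 0
        self.nmax = p.max_runs * lmax if m_all else 0
        ns = np.arange(self.nmax + 1)
        self.B = np.stack([self._class_energy(ns, r) for r in range(p.max_runs + 1)])
        self.g_empty = float(self.B[0][0])

        if m_all == 0 or p.max_runs == 0:
            self._finish_setup(np.zeros(m_all, dtype=bool))
            return

        # upper bound on G_min from the empty and all single-run states
        lb_single = cand.energies + self.B[1][cand.lengths]
        self.g_ub = min(self.g_empty, float(lb_single.min()))

        cap0 = self.g_ub + p.cap_theta
        # lower bound on the G of any state containing candidate i
        per_k0 = self._per_k(self._g1_of(cand), self._g2_distinct(cand))
        f_any0 = self._completion(cand, 0, per_k0)
        lb = cand.energies + f_any0[1][cand.lengths]
        keep = lb <= cap0 + _TOL
        self._finish_setup(keep)

        if self.m:
            # tighter tables over the survivors
            per_k = self._per_k(self._g1_of(self.cands), self._g2_distinct(self.cands))
            self.f_any = self._completion(self.cands, 0, per_k)
            self.f_ge1 = self._completion(self.cands, 1, per_k)
            self.f_ge2 = self._completion(self.cands, 2, per_k)
        log.debug(
            "pruned candidates %d -> %d (cap %.3f)", m_all, self.m, cap0
        )

    def _finish_setup(self, keep: np.ndarray):
        cand = self.full
        self.cands = CandidateSet(
            cand.n_domain,
            cand.circular,
            cand.starts[keep],
            cand.lengths[keep],
            cand.energies[keep],
        )
        self.m = len(self.cands)
        self.S = self.cands.starts
        self.L = self.cands.lengths
        self.E = self.cands.energies
        self.END = self.S + self.L  # exclusive, unwrapped
        self._pairs = None
        if not self.m:
            inf = np.full((self.params.max_runs + 1, self.nmax + 1), np.inf)
            self.f_any = self.f_ge1 = self.f_ge2 = inf

    def _minplus(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """(min,+) convolution of two length-indexed minimum-energy arrays."""
        out = np.full(self.nmax + 1, np.inf)
        for mm in np.flatnonzero(np.isfinite(b)):
            upto = self.nmax + 1 - mm
            if upto <= 0:
                break
            np.minimum(out[mm:], a[:upto] + b[mm], out=out[mm:])
        return out

    def _g1_of(self, cand: CandidateSet) -> np.ndarray:
        """g1[m]: cheapest single candidate of length m."""
        g1 = np.full(self.nmax + 1, np.inf)
        np.minimum.at(g1, cand.lengths, cand.energies)
        return g1

    def _g2_distinct(self, cand: CandidateSet) -> np.ndarray:
        """g2[m]: cheapest energy sum of two *distinct* candidates with total
        length m (overlap still ignored) — first plus second minimum within a
        length class, first plus first across classes."""
        g1 = np.full(self.nmax + 1, np.inf)
        g1b = np.full(self.nmax + 1, np.inf)
        order = np.lexsort((cand.energies, cand.lengths))
        lens = cand.lengths[order]
        ens = cand.energies[order]
        uniq, first = np.unique(lens, return_index=True)
        g1[uniq] = ens[first]
        nxt = first + 1
        has2 = (nxt < len(lens)) & (lens[nxt.clip(max=len(lens) - 1)] == uniq)
        g1b[uniq[has2]] = ens[nxt[has2]]
        g2 = np.full(self.nmax + 1, np.inf)
        fin = np.flatnonzero(np.isfinite(g1))
        for l1 in fin:
            for l2 in fin[fin >= l1]:
                m = l1 + l2
                if m > self.nmax:
                    break
                cost = g1[l1] + g1b[l1] if l1 == l2 else g1[l1] + g1[l2]
                if cost < g2[m]:
                    g2[m] = cost
        return g2

    def _per_k(self, g1: np.ndarray, g2: np.ndarray | None = None) -> list[np.ndarray]:
        """g_k[m]: lower bound on the summed energy of k runs totalling m bp.

        Without ``g2`` this is the k-fold (min,+) power of g1 (overlap
        ignored).  With ``g2`` — the true minimum over *disjoint* pairs,
        taken from the pair table — compositions use g2 for every two runs,
        which is tighter and still a valid bound since any two runs of a
        state form an admissible pair.
        """
        per_k: list[np.ndarray] = [g1]
        for k in range(2, self.params.max_runs + 1):
            if g2 is None:
                per_k.append(self._minplus(per_k[-1], g1))
            elif k == 2:
                per_k.append(g2)
            else:
                per_k.append(self._minplus(per_k[k - 3], g2))
        return per_k

    def _completion(self, cand: CandidateSet, min_extra: int,
                    per_k: list[np.ndarray] | None = None) -> np.ndarray:
        """f[r][n] = optimistic extra cost of completing a prefix with r runs
        and n Z-bp by adding k >= min_extra more runs totalling m bp, then
        closing the class.  A valid lower bound for pruning."""
        p = self.params
        if per_k is None:
            per_k = self._per_k(self._g1_of(cand))
        f = np.full((p.max_runs + 1, self.nmax + 1), np.inf)
        for r in range(p.max_runs + 1):
            if min_extra == 0:
                f[r] = self.B[r].copy()
            for k in range(max(1, min_extra), p.max_runs - r + 1):
                gk = per_k[k - 1]
                for mm in np.flatnonzero(np.isfinite(gk)):
                    upto = self.nmax + 1 - mm
                    if upto <= 0:
                        break
                    np.minimum(
                        f[r][:upto], gk[mm] + self.B[r + k][mm:], out=f[r][:upto]
                    )
        return f

    # -- geometry ----------------------------------------------------------

    def _end_limit(self, first_start: int) -> int:
        """Exclusive unwrapped bound on the end of the last run, given the
        first run's start (circular: >= 1 B bp before the first run)."""
        if self.cands.circular:
            return self.n + first_start - 1
        return self.n

    def _pair_table(self, sub: np.ndarray, cap: float):
        """Ordered pairs (i then j, >= 1 bp gap) among the candidate subset
        ``sub`` (full-array indices, start-sorted), pruned to pairs that can
        belong to some state within ``cap`` (bound: pair energy plus the
        optimistic completion of a 2-run prefix).  Cached per (subset, cap).
        """
        key = (len(sub), int(sub[0]) if len(sub) else -1,
               int(sub[-1]) if len(sub) else -1, float(cap))
        if self._pairs is not None and self._pairs[0] == key:
            return self._pairs[1]
        s2, end2 = self.S[sub], self.END[sub]
        m2 = len(sub)
        lo = np.searchsorted(s2, end2 + 1)
        counts = (m2 - lo).clip(min=0)
        # chunk over first-run rows so transient arrays stay bounded even
        # when the relaxed subset is large; only admissible pairs are kept
        chunk_pairs = 4_000_000
        kept: list[tuple] = []
        row = 0
        while row < m2:
            hi = row
            acc = 0
            while hi < m2 and (acc == 0 or acc + counts[hi] <= chunk_pairs):
                acc += counts[hi]
                hi += 1
            block = np.arange(row, hi)
            cnt = counts[block]
            pi = np.repeat(block, cnt)
            offsets = np.concatenate(([0], np.cumsum(cnt)[:-1]))
            pj = (np.arange(cnt.sum()) - np.repeat(offsets, cnt)
                  + np.repeat(lo[block], cnt))
            gi, gj = sub[pi], sub[pj]  # back to full-array indices
            pe = self.E[gi] + self.E[gj]
            pl = self.L[gi] + self.L[gj]
            keep = pe + self.f_any[2][pl] <= cap + _TOL
            if keep.any():
                kept.append((gi[keep], gj[keep], pe[keep], pl[keep]))
            row = hi
        if kept:
            gi = np.concatenate([k[0] for k in kept])
            gj = np.concatenate([k[1] for k in kept])
            pe = np.concatenate([k[2] for k in kept])
            pl = np.concatenate([k[3] for k in kept])
        else:
            gi = gj = np.zeros(0, dtype=int)
            pe = np.zeros(0)
            pl = np.zeros(0, dtype=int)
        table = (gi, gj, pe, pl, self.S[gi], self.END[gj])
        log.debug(
            "pair table: %d admissible pairs over %d multi-run candidates",
            len(gi), m2,
        )
        self._pairs = (key, table)
        return table

    def _multi_subset(self, cap: float) -> np.ndarray:
        """Candidates that can belong to a state with >= 2 runs within cap."""
        if self.m == 0 or self.params.max_runs < 2:
            return np.zeros(0, dtype=int)
        return np.flatnonzero(self.E + self.f_ge1[1][self.L] <= cap + _TOL)

    # -- ground state ------------------------------------------------------

    def find_minimum_state(self) -> SystemState:
        """The state of globally minimal free energy (the untransformed state
        is always a competitor).  Exactly degenerate minima are resolved to
        the lexicographically smallest (r, start, length, ...) state."""
        best_g = self.g_empty
        best_members: tuple[int, ...] = ()

        def consider(members, g):
            nonlocal best_g, best_members
            if g < best_g - _TOL:
                best_g, best_members = g, members
            elif g <= best_g + _TOL:
                key = self._member_key(members)
                if key < self._member_key(best_members):
                    best_g, best_members = min(best_g, g), members

        if self.m == 0 or self.params.max_runs == 0:
            return SystemState((), float(best_g))

        # single-run states, vectorized
        g1 = self.E + self.B[1][self.L]
        j1 = int(np.argmin(g1))
        if g1[j1] <= best_g + _TOL:
            for j in np.flatnonzero(g1 <= g1[j1] + _TOL):
                consider((int(j),), float(g1[j]))

        # multi-run states over the subset that can feasibly combine
        sub = self._multi_subset(best_g)
        s2, end2 = self.S[sub], self.END[sub]

        def rec(members, e_sum, n_sum, last_end, end_limit):
            r_p = len(members)
            lo = int(np.searchsorted(s2, last_end + 1))
            idx = np.arange(lo, len(sub))
            idx = idx[end2[idx] <= end_limit]
            if not len(idx):
                return
            full = sub[idx]
            g_close = e_sum + self.E[full] + self.B[r_p + 1][n_sum + self.L[full]]
            jbest = int(np.argmin(g_close))
            if g_close[jbest] <= best_g + _TOL:
                for k in np.flatnonzero(g_close <= g_close[jbest] + _TOL):
                    consider(members + (int(full[k]),), float(g_close[k]))
            if r_p + 1 >= self.params.max_runs:
                return
            viable = full[
                e_sum + self.E[full] + self.f_ge1[r_p + 1][n_sum + self.L[full]]
                <= best_g + _TOL
            ]
            for j in viable:
                j = int(j)
                rec(
                    members + (j,),
                    e_sum + float(self.E[j]),
                    n_sum + int(self.L[j]),
                    int(self.END[j]),
                    end_limit,
                )

        if self.params.max_runs >= 2 and len(sub):
            for j in sub:
                j = int(j)
                if self.E[j] + self.f_ge1[1][self.L[j]] > best_g + _TOL:
                    continue
                rec(
                    (j,),
                    float(self.E[j]),
                    int(self.L[j]),
                    int(self.END[j]),
                    self._end_limit(int(self.S[j])),
                )
        runs = tuple(self.cands.run(i) for i in best_members)
        return SystemState(runs, float(best_g))

    def _member_key(self, members):
        return (len(members),) + tuple(
            x for i in members for x in (int(self.S[i]), int(self.L[i]))
        )

    # -- enumeration (explicit, small systems) -----------------------------

    def enumerate_states(self, max_states: int = 2_000_000) -> Iterator[SystemState]:
        """Yield every admissible state with G <= G_min + theta, exactly once.

        Explicit enumeration for small systems and oracle comparisons; the
        production path is :meth:`accumulate`, which streams the same states
        into sufficient statistics.
        """
        g_min = self.find_minimum_state().free_energy
        cap = g_min + self.params.cap_theta
        count = 0
        if self.g_empty <= cap + _TOL:
            count += 1
            yield SystemState((), self.g_empty)

        def rec(members, e_sum, n_sum, last_end, end_limit):
            nonlocal count
            r_p = len(members)
            lo = int(np.searchsorted(self.S, last_end + 1)) if members else 0
            for j in range(lo, self.m):
                if members and self.END[j] > end_limit:
                    continue
                e = e_sum + float(self.E[j])
                n_z = n_sum + int(self.L[j])
                g = e + float(self.B[r_p + 1][n_z])
                lim = end_limit if members else self._end_limit(int(self.S[j]))
                if g <= cap + _TOL:
                    count += 1
                    if count > max_states:
                        raise RuntimeError(
                            f"enumerate_states exceeded {max_states} states; "
                            "use accumulate() for large ensembles"
                        )
                    yield SystemState(
                        tuple(self.cands.run(i) for i in members + (j,)), g
                    )
                if (
                    r_p + 1 < self.params.max_runs
                    and e + float(self.f_ge1[r_p + 1][n_z]) <= cap + _TOL
                ):
                    yield from rec(members + (j,), e, n_z, int(self.END[j]), lim)

        if self.m and self.params.max_runs:
            yield from rec((), 0.0, 0, 0, 0)

    # -- enumeration (vectorized sufficient statistics) --------------------

    def accumulate(self) -> SearchResult:
        """Enumerate all states with G <= G_min + theta into sufficient
        statistics (relative Boltzmann weights; weight 1 for the ground
        state)."""
        ground = self.find_minimum_state()
        g_min = ground.free_energy
        cap = g_min + self.params.cap_theta
        beta = self.beta
        m = self.m
        t_w = np.zeros(m)
        z = 0.0
        count = 0
        if self.g_empty <= cap + _TOL:
            z += float(np.exp(-beta * (self.g_empty - g_min)))
            count += 1

        if m == 0 or self.params.max_runs == 0:
            return self._result(g_min, ground, count, z, t_w)

        # single-run states, vectorized over all candidates
        g1 = self.E + self.B[1][self.L]
        ok1 = g1 <= cap + _TOL
        if ok1.any():
            w1 = np.exp(-beta * (g1[ok1] - g_min))
            z += float(w1.sum())
            count += int(ok1.sum())
            t_w[ok1] += w1

        # states with >= 2 runs live on the feasibly-combinable subset; every
        # node closes states two runs deeper than its prefix via the pair
        # table, so 2-run prefixes become Python-level nodes only when at
        # least two further runs are plausible
        sub = self._multi_subset(cap)
        if self.params.max_runs < 2 or not len(sub):
            return self._result(g_min, ground, count, z, t_w)
        pi, pj, pe, pl, ps, pend = self._pair_table(sub, cap)

        # refine the completion bounds with the true disjoint-pair minima,
        # then re-restrict the multi-run subset and the pair table
        g2t = np.full(self.nmax + 1, np.inf)
        if len(pe):
            np.minimum.at(g2t, pl, pe)
        per_k = self._per_k(self._g1_of(self.cands), g2t)
        f_any = self._completion(self.cands, 0, per_k)
        f_ge1 = self._completion(self.cands, 1, per_k)
        f_ge2 = self._completion(self.cands, 2, per_k)
        sub = sub[self.E[sub] + f_ge1[1][self.L[sub]] <= cap + _TOL]
        if not len(sub):
            return self._result(g_min, ground, count, z, t_w)
        keep = pe + f_any[2][pl] <= cap + _TOL
        pi, pj, pe, pl, ps, pend = (a[keep] for a in (pi, pj, pe, pl, ps, pend))
        s2, end2 = self.S[sub], self.END[sub]

        def close_pairs(members, e_sum, n_sum, last_end, end_limit):
            nonlocal z, count
            lo = int(np.searchsorted(ps, last_end + 1))
            if lo >= len(pi):
                return
            sl = slice(lo, len(pi))
            if members:
                ok = pend[sl] <= end_limit
            else:
                # the pair's own first run sets the circular end limit
                if self.cands.circular:
                    ok = pend[sl] <= self.n + ps[sl] - 1
                else:
                    ok = np.ones(len(pi) - lo, dtype=bool)
            r_new = len(members) + 2
            g = e_sum + pe[sl] + self.B[r_new][n_sum + pl[sl]]
            ok &= g <= cap + _TOL
            if not ok.any():
                return
            w = np.exp(-beta * (g[ok] - g_min))
            z += float(w.sum())
            count += int(ok.sum())
            t_w[:] += np.bincount(pi[sl][ok], weights=w, minlength=m)
            t_w[:] += np.bincount(pj[sl][ok], weights=w, minlength=m)
            ws = float(w.sum())
            for i in members:
                t_w[i] += ws

        def expand(members, e_sum, n_sum, last_end, end_limit):
            # closes the states (prefix + 2 runs); recurses one run deeper
            # while at least two further runs fit under the cap
            r_p = len(members)
            close_pairs(members, e_sum, n_sum, last_end, end_limit)
            if self.params.max_runs - (r_p + 1) < 2:
                return
            lo = int(np.searchsorted(s2, last_end + 1))
            idx = np.arange(lo, len(sub))
            idx = idx[end2[idx] <= end_limit]
            if not len(idx):
                return
            full = sub[idx]
            viable = full[
                e_sum + self.E[full] + f_ge2[r_p + 1][n_sum + self.L[full]]
                <= cap + _TOL
            ]
            for j in viable:
                j = int(j)
                expand(
                    members + (j,),
                    e_sum + float(self.E[j]),
                    n_sum + int(self.L[j]),
                    int(self.END[j]),
                    end_limit,
                )

        close_pairs((), 0.0, 0, -1, 0)
        if self.params.max_runs >= 3:
            for j in sub:
                j = int(j)
                if self.E[j] + f_ge2[1][self.L[j]] > cap + _TOL:
                    continue
                expand(
                    (j,),
                    float(self.E[j]),
                    int(self.L[j]),
                    int(self.END[j]),
                    self._end_limit(int(self.S[j])),
                )
        return self._result(g_min, ground, count, z, t_w)

    def _result(self, g_min, ground, count, z, t_w) -> SearchResult:
        log.debug(
            "enumerated %d states, G_min=%.4f, Z_rel=%.6g", count, g_min, z
        )
        return SearchResult(
            g_min=float(g_min),
            ground_state=ground,
            states_enumerated=count,
            theta=self.params.cap_theta,
            beta=self.beta,
            candidates=self.cands,
            z_rel=z,
            t_weight=t_w,
            params=self.params,
        )

    # -- counting (relaxed-bound cross-check against tiling theory) --------

    def count_all_states(self) -> int:
        """Number of admissible run placements, energies ignored.

        With relaxed bounds (min_run_len=2, unlimited runs) this equals the
        dimer-tiling state count of the molecule.  For a circular molecule of
        even length the two fully-Z phasings (no B-form bp anywhere) are
        admissible tilings but are not representable as gap-separated runs,
        so they are added analytically.
        """
        total = 1  # untransformed
        stack = [((), 0, 0)]
        while stack:
            members, last_end, end_limit = stack.pop()
            lo = int(np.searchsorted(self.S, last_end + 1)) if members else 0
            idx = np.arange(lo, self.m)
            if members:
                idx = idx[self.END[idx] <= end_limit]
            total += len(idx)
            if len(members) + 1 < self.params.max_runs:
                for j in idx:
                    j = int(j)
                    lim = end_limit if members else self._end_limit(int(self.S[j]))
                    stack.append((members + (j,), int(self.END[j]), lim))
        if (
            self.cands.circular
            and self.n % 2 == 0
            and self.params.min_run_len <= self.n
            and self.params.max_runs >= 1
            and self.params.max_run_len >= self.n
        ):
            total += 2
        return total


def find_minimum_state(
    ctx: TopologyContext, candidates: CandidateSet, params: SearchParams | None = None
) -> SystemState:
    """Convenience wrapper: the minimum-free-energy state."""
    return StateSearch(ctx, candidates, params).find_minimum_state()


def enumerate_states(
    ctx: TopologyContext, candidates: CandidateSet, params: SearchParams | None = None
) -> Iterator[SystemState]:
    """Convenience wrapper: explicit threshold-bounded enumeration."""
    return StateSearch(ctx, candidates, params).enumerate_states()
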