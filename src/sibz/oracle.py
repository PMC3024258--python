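"""Exact small-system references: state counting and brute-force ensembles.

The number of dimer-tiling states of an N-bp molecule follows the Fibonacci
recursion S(N) = S(N-1) + S(N-2) with S(1) = 1, S(2) = 2 (each base pair is
either a B-form monomer or half of a Z dinucleotide unit); a circular molecule
adds the states in which base pairs 1 and N pair, giving S(N) + S(N-2).

``brute_force_ensemble`` enumerates *every* admissible run placement of a tiny
system (no threshold), computes the exact partition function and per-bp
transition probabilities, and serves as the certification oracle for the
production search.  It deliberately re-derives the topology arithmetic and
uses plain Python set operations for run geometry, sharing only the
dinucleotide energy model with the production path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .energetics import DinucleotideEnergyTable, default_table, encode, run_transition_energy

__all__ = ["StateCount", "count_states", "enumerate_tilings", "BruteForceResult",
           "brute_force_ensemble"]

_GOLDEN = (1 + math.sqrt(5)) / 2


@dataclass(frozen=True)
class StateCount:
    """Exact and golden-ratio-approximate state counts for length N."""

    n: int
    linear_count: int
    circular_count: int
    linear_approx: float

    @property
    def golden_ratio(self) -> float:
        return _GOLDEN


def _linear_counts(n: int) -> list[int]:
    s = [0] * (n + 1)
    if n >= 1:
        s[1] = 1
    if n >= 2:
        s[2] = 2
    for i in range(3, n + 1):
        s[i] = s[i - 1] + s[i - 2]
    return s


def count_states(n: int, topology: str = "linear") -> StateCount:
    """State counts from the recursion; ``topology`` is "linear" or "circular".

    The approximation phi**(N+1)/sqrt(5) (phi the golden ratio) is returned
    alongside the exact linear count.
    """
    if topology not in ("linear", "circular"):
        raise ValueError("topology must be 'linear' or 'circular'")
    if n < 1 or (topology == "circular" and n < 3):
        raise ValueError(f"invalid length {n} for {topology} topology")
    s = _linear_counts(n)
    approx = _GOLDEN ** (n + 1) / math.sqrt(5)
    circ = s[n] + s[n - 2] if n >= 3 else 0
    return StateCount(n, s[n], circ, approx)


def enumerate_tilings(n: int, circular: bool) -> int:
    """Count dimer tilings by direct recursive enumeration (independent of the
    Fibonacci recursion); feasible for N <= ~30."""
    if n > 34:
        raise ValueError("tiling enumeration is for small N only")

    def tile_linear(i: int, stop: int) -> int:
        # number of ways to tile positions i..stop-1
        if i >= stop:
            return 1
        total = tile_linear(i + 1, stop)  # monomer
        if i + 1 < stop:
            total += tile_linear(i + 2, stop)  # dimer
        return total

    if not circular:
        return tile_linear(0, n)
    # circular: bp 0 is a monomer, or pairs with bp 1, or pairs with bp n-1
    total = tile_linear(1, n)
    total += tile_linear(2, n)
    total += tile_linear(1, n - 1)
    return total


@dataclass
class BruteForceResult:
    """Exact ensemble of a tiny system (all states, no threshold)."""

    g_min: float
    z: float  # partition function relative to G_min
    p: np.ndarray
    avg_n_z: float
    avg_runs: float
    states_count: int
    states: list  # (runs tuple of (start, length), G)


def brute_force_ensemble(
    sequence: str | np.ndarray,
    sigma: float,
    circular: bool = True,
    min_run_len: int = 8,
    max_run_len: int = 250,
    max_runs: int = 2,
    a_b: float = 10.4,
    a_z: float = 12.0,
    junction_twist: float = 0.4,
    junction_nucleation: float = 5.0,
    r_gas: float = 1.9872e-3,
    temperature: float = 310.0,
    c_quad: float = 2200.0,
    table: DinucleotideEnergyTable | None = None,
    guard: int = 10_000_000,
) -> BruteForceResult:
    """Enumerate every admissible state of a small molecule exactly.

    Runs are even-length windows within the length bounds; a state is any set
    of at most ``max_runs`` runs whose base-pair sets are pairwise disjoint
    and non-adjacent (one run dilated by one bp never touches another).
    """
    table = table or default_table()
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    n = len(codes)
    alpha = sigma * n / a_b
    k_coeff = c_quad * r_gas * temperature / n
    rt = r_gas * temperature

    # candidate runs with their bp sets
    cands = []
    hi = min(max_run_len, (n - 2 if n % 2 == 0 else n - 1) if circular else n)
    for length in range(min_run_len, hi + 1, 2):
        starts = range(n) if circular else range(n - length + 1)
        for s in starts:
            bps = frozenset((s + k) % n for k in range(length)) if circular else frozenset(
                range(s, s + length)
            )
            e = run_transition_energy(codes, s, length, circular, table)
            cands.append((s, length, e.total, bps))

    def dilate(bps: frozenset) -> frozenset:
        out = set(bps)
        for b in bps:
            if circular:
                out.add((b - 1) % n)
                out.add((b + 1) % n)
            else:
                if b > 0:
                    out.add(b - 1)
                if b < n - 1:
                    out.add(b + 1)
        return frozenset(out)

    dilated = [dilate(c[3]) for c in cands]

    def g_of(combo) -> float:
        n_z = sum(c[1] for c in combo)
        r = len(combo)
        alpha_r = alpha + n_z * (1.0 / a_b + 1.0 / a_z) + 2.0 * r * junction_twist
        return (
            sum(c[2] for c in combo)
            + 2.0 * junction_nucleation * r
            + 0.5 * k_coeff * alpha_r * alpha_r
        )

    states = [((), 0.5 * k_coeff * alpha * alpha)]
    for r in range(1, max_runs + 1):
        for combo_idx in itertools.combinations(range(len(cands)), r):
            ok = True
            for a_i, b_i in itertools.combinations(combo_idx, 2):
                if dilated[a_i] & cands[b_i][3]:
                    ok = False
                    break
            if ok:
                combo = tuple(cands[i] for i in combo_idx)
                states.append(
                    (tuple((c[0], c[1]) for c in combo), g_of(combo))
                )
            if len(states) > guard:
                raise RuntimeError("brute-force state count guard exceeded")

    g_min = min(g for _, g in states)
    weights = [math.exp(-(g - g_min) / rt) for _, g in states]
    z = math.fsum(weights)
    p = np.zeros(n)
    avg_nz = 0.0
    avg_r = 0.0
    for (runs, g), w in zip(states, weights):
        for s, length in runs:
            for k in range(length):
                p[(s + k) % n] += w
        avg_nz += w * sum(length for _, length in runs)
        avg_r += w * len(runs)
    p /= z
    return BruteForceResult(
        g_min=g_min,
        z=z,
        p=p,
        avg_n_z=avg_nz / z,
        avg_runs=avg_r / z,
        states_count=len(states),
        states=states,
    )
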