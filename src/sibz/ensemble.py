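"""Equilibrium quantities of the B-Z transition ensemble.

Each enumerated state s occurs at equilibrium with relative frequency
exp(-G_s/RT)/Z.  The transition profile is the per-base-pair probability
p(x) of finding bp x in Z-form, obtained by summing the weights of all states
in which x is transformed; ensemble averages such as the expected number of
Z-form base pairs <n_Z> and of runs <r> follow the same Boltzmann average.
All weights are computed relative to the ground state, so the deepest state
has weight 1 and nothing overflows.

Region probabilities come in two flavours: ``all_z`` (the weight of states in
which every bp of the region is Z-form — the observable of a two-state "the
insert has flipped" experiment) and ``mean_p`` (the mean of p(x) over the
region).  For a single cooperative run the two nearly coincide; both are
always available and ``mean_p`` is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energetics import DinucleotideEnergyTable, default_table
from .io import SequenceContext
from .mechanics import PhysicalConstants, TopologyContext
from .statesearch import (
    CandidateSet,
    SearchParams,
    SearchResult,
    StateSearch,
    generate_candidates,
)

__all__ = [
    "TransitionProfile",
    "SweepResult",
    "OnsetResult",
    "AggregateResult",
    "boltzmann_profile",
    "profile_sequence",
    "region_probability",
    "sigma_sweep",
    "onset_sigma",
    "aggregate_profiles",
    "call_z_regions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionProfile:
    """Per-base-pair Z-probabilities over the user's sequence coordinates.

    ``avg_n_z`` is the expected number of Z-form base pairs within the
    reported sequence (equal to sum(p); the 50-T joint of an augmented linear
    sequence is excluded from reporting and contributes essentially nothing).
    """

    p: np.ndarray
    sigma: float
    theta: float
    avg_n_z: float
    avg_runs: float
    g_min: float
    states_count: int

    def __post_init__(self):
        if len(self.p) and (self.p.min() < -1e-12 or self.p.max() > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")


def boltzmann_profile(
    result: SearchResult, sigma: float = np.nan, report_len: int | None = None
) -> TransitionProfile:
    """Fold a search result into a transition profile.

    ``report_len`` truncates to the user's coordinates for augmented linear
    sequences; by default the whole domain is reported.
    """
    cov = result.coverage()
    if report_len is not None:
        cov = cov[:report_len]
    return TransitionProfile(
        p=cov,
        sigma=sigma,
        theta=result.theta,
        avg_n_z=float(cov.sum()),
        avg_runs=result.avg_runs,
        g_min=result.g_min,
        states_count=result.states_enumerated,
    )


def _profile_from(result: SearchResult, sigma: float, report_len: int) -> TransitionProfile:
    return boltzmann_profile(result, sigma, report_len)


def _search(
    ctx_seq: SequenceContext,
    sigma: float,
    params: SearchParams,
    constants: PhysicalConstants,
    candidates: CandidateSet,
) -> SearchResult:
    topo = TopologyContext(ctx_seq.n_domain, sigma, constants)
    return StateSearch(topo, candidates, params).accumulate()


def profile_sequence(
    ctx_seq: SequenceContext,
    sigma: float,
    params: SearchParams | None = None,
    constants: PhysicalConstants | None = None,
    table: DinucleotideEnergyTable | None = None,
    candidates: CandidateSet | None = None,
) -> tuple[TransitionProfile, SearchResult]:
    """Full pipeline for one sequence at one superhelix density."""
    params = params or SearchParams()
    constants = constants or PhysicalConstants()
    if candidates is None:
        candidates = generate_candidates(ctx_seq.codes, True, params, table or default_table())
    result = _search(ctx_seq, sigma, params, constants, candidates)
    return _profile_from(result, sigma, ctx_seq.report_len), result


def region_probability(
    result: SearchResult,
    region: tuple[int, int],
    mode: str = "mean_p",
    report_len: int | None = None,
) -> float:
    """Probability of a region being in Z-form, 0-based half-open coordinates.

    ``all_z``: summed weight of states in which the whole region is Z-form.
    ``mean_p``: mean per-bp transition probability over the region.
    """
    start, end = region
    if end <= start:
        raise ValueError("empty region")
    limit = report_len if report_len is not None else result.candidates.n_domain
    if start < 0 or end > limit:
        raise ValueError(f"region {region} outside reported coordinates [0, {limit})")
    if mode == "all_z":
        return result.region_all_z(start, end)
    if mode == "mean_p":
        return float(result.coverage()[start:end].mean())
    raise ValueError("mode must be 'all_z' or 'mean_p'")


@dataclass
class SweepResult:
    """Per-sigma profile summaries over a monotone sigma grid."""

    sigmas: np.ndarray
    profiles: list[TransitionProfile]
    region_curves: dict = field(default_factory=dict)
    # region name -> {"mean_p": array, "all_z": array}

    @property
    def avg_n_z(self) -> np.ndarray:
        return np.array([p.avg_n_z for p in self.profiles])

    @property
    def avg_runs(self) -> np.ndarray:
        return np.array([p.avg_runs for p in self.profiles])


def sigma_sweep(
    ctx_seq: SequenceContext,
    sigmas,
    regions: dict[str, tuple[int, int]] | None = None,
    params: SearchParams | None = None,
    constants: PhysicalConstants | None = None,
    table: DinucleotideEnergyTable | None = None,
) -> SweepResult:
    """Profiles and region probability curves over a grid of superhelical
    densities.  Candidate energies are sigma-independent and computed once."""
    sigmas = np.asarray(sigmas, dtype=float)
    if len(sigmas) > 1 and not (np.all(np.diff(sigmas) > 0) or np.all(np.diff(sigmas) < 0)):
        raise ValueError("sigma grid must be strictly monotone")
    params = params or SearchParams()
    constants = constants or PhysicalConstants()
    cand = generate_candidates(ctx_seq.codes, True, params, table or default_table())
    profiles = []
    curves = {name: {"mean_p": [], "all_z": []} for name in (regions or {})}
    for sg in sigmas:
        result = _search(ctx_seq, float(sg), params, constants, cand)
        profiles.append(_profile_from(result, float(sg), ctx_seq.report_len))
        for name, reg in (regions or {}).items():
            for mode in ("mean_p", "all_z"):
                curves[name][mode].append(
                    region_probability(result, reg, mode, ctx_seq.report_len)
                )
    curves = {
        name: {mode: np.array(vals) for mode, vals in d.items()}
        for name, d in curves.items()
    }
    for name, d in curves.items():
        gap = np.abs(d["mean_p"] - d["all_z"]).max() if len(sigmas) else 0.0
        log.debug("region %s: max |mean_p - all_z| over sweep = %.4g", name, gap)
    return SweepResult(sigmas, profiles, curves)


@dataclass(frozen=True)
class OnsetResult:
    """Onset superhelix density of a region at a probability level."""

    sigma_c: float | None  # rounded to 3 decimals; None if no crossing
    sigma_c_raw: float | None
    level: float
    mode: str
    evaluations: int

    @property
    def found(self) -> bool:
        return self.sigma_c is not None


def onset_sigma(
    ctx_seq: SequenceContext,
    region: tuple[int, int],
    level: float = 0.8,
    mode: str = "mean_p",
    sigma_range: tuple[float, float] = (-0.12, 0.0),
    tol: float = 0.0005,
    params: SearchParams | None = None,
    constants: PhysicalConstants | None = None,
    table: DinucleotideEnergyTable | None = None,
) -> OnsetResult:
    """Superhelix density at which the region's Z-probability crosses ``level``.

    Bisection on sigma between ``sigma_range`` until |delta sigma| <= tol
    (0.0005 by default, i.e. 3-decimal onset reporting).  Returns an explicit
    "no onset" result when the curve does not cross the level in the range.
    """
    params = params or SearchParams()
    constants = constants or PhysicalConstants()
    cand = generate_candidates(ctx_seq.codes, True, params, table or default_table())
    lo, hi = min(sigma_range), max(sigma_range)
    evals = 0

    def prob(sg: float) -> float:
        nonlocal evals
        evals += 1
        result = _search(ctx_seq, sg, params, constants, cand)
        return region_probability(result, region, mode, ctx_seq.report_len)

    p_lo = prob(lo)
    p_hi = prob(hi)
    if not (p_lo >= level > p_hi):
        log.info(
            "no onset: P(%g)=%.4f, P(%g)=%.4f, level=%g", lo, p_lo, hi, p_hi, level
        )
        return OnsetResult(None, None, level, mode, evals)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if prob(mid) >= level:
            lo = mid  # crossing lies between mid and hi (less negative side)
        else:
            hi = mid
    sigma_c = 0.5 * (lo + hi)
    return OnsetResult(round(sigma_c, 3), sigma_c, level, mode, evals)


def call_z_regions(p: np.ndarray, level: float = 0.8) -> list[tuple[int, int]]:
    """Maximal segments where p exceeds ``level`` (0-based half-open)."""
    above = p > level
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


@dataclass
class AggregateResult:
    """Positional mean of aligned profiles plus per-sequence Z-region calls."""

    mean_p: np.ndarray
    anchor: int
    level: float
    calls: list[list[tuple[int, int]]]  # per profile
    window_counts: dict  # (lo, hi) relative to anchor -> n sequences with a call


def aggregate_profiles(
    profiles: list[np.ndarray] | list[TransitionProfile],
    anchor: int,
    level: float = 0.8,
    windows: list[tuple[int, int]] | None = None,
) -> AggregateResult:
    """Average aligned profiles and count Z-forming region calls near windows.

    All profiles must have equal length and share the anchor column.  A
    sequence is counted for a window (lo, hi) — positions anchor+lo to
    anchor+hi inclusive, both relative offsets — when at least one of its
    called regions (p > level) intersects the window.
    """
    arrs = [p.p if isinstance(p, TransitionProfile) else np.asarray(p) for p in profiles]
    if not arrs:
        raise ValueError("no profiles to aggregate")
    length = len(arrs[0])
    if any(len(a) != length for a in arrs):
        raise ValueError("profiles have ragged lengths; alignment requires equal length")
    if not 0 <= anchor < length:
        raise ValueError("anchor outside profile coordinates")
    mean = np.mean(np.stack(arrs), axis=0)
    calls = [call_z_regions(a, level) for a in arrs]
    counts = {}
    for lo, hi in windows or []:
        w_start = max(0, anchor + lo)
        w_end = min(length, anchor + hi + 1)
        n = sum(
            1
            for regs in calls
            if any(s < w_end and e > w_start for s, e in regs)
        )
        counts[(lo, hi)] = n
    return AggregateResult(mean, anchor, level, calls, counts)
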