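"""Superhelical topology bookkeeping.

A topological domain of N base pairs at superhelix density sigma carries a
linking difference alpha = sigma * N / A_B turns.  Flipping n_Z base pairs into
the left-handed Z-helix (A_Z = 12 bp/turn) in r runs changes the twist by
n_Z * (1/A_B + 1/A_Z) turns plus 2r * a turns of untwisting at the B-Z
junctions, leaving a residual linking difference alpha_r.  The residual stress
costs a quadratic free energy (K/2) * alpha_r**2 with K = C * R * T / N, and
each run additionally pays a nucleation energy of two B-Z junctions.

Defaults: A_B = 10.4 bp/turn, A_Z = 12 bp/turn, a = 0.4 turns/junction,
5.0 kcal/mol per B-Z junction (10 per run), C = 2200, T = 310 K.  All are
user-overridable; sigma is treated as constant during an analysis and Z-DNA is
treated as torsionally rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "PhysicalConstants",
    "TopologyContext",
    "StateGeometry",
    "residual_linking",
    "superhelical_energy",
    "state_free_energy",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the transition model (energies in kcal/mol)."""

    a_b: float = 10.4  # B-helix twist rate, bp/turn
    a_z: float = 12.0  # Z-helix twist magnitude, bp/turn (left-handed)
    junction_twist: float = 0.4  # untwisting per B-Z junction, turns
    junction_nucleation: float = 5.0  # kcal/mol per B-Z junction (2 per run)
    r_gas: float = 1.9872e-3  # kcal/(mol K)
    temperature: float = 310.0  # K
    c_quad: float = 2200.0  # K = c_quad * R * T / N

    def __post_init__(self):
        for name in ("a_b", "a_z", "junction_twist", "junction_nucleation",
                     "r_gas", "temperature", "c_quad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def rt(self) -> float:
        return self.r_gas * self.temperature

    @property
    def delta_twist(self) -> float:
        """Twist change per transformed bp, turns (1/A_B + 1/A_Z)."""
        return 1.0 / self.a_b + 1.0 / self.a_z

    @property
    def run_nucleation(self) -> float:
        """Nucleation energy per Z-run (two B-Z junctions)."""
        return 2.0 * self.junction_nucleation

    def quad_coeff(self, n_domain: int) -> float:
        """K = c_quad * R * T / N for a domain of n_domain bp."""
        if n_domain < 1:
            raise ValueError("domain length must be >= 1")
        return self.c_quad * self.rt / n_domain

    def with_overrides(self, **kwargs) -> "PhysicalConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TopologyContext:
    """A domain of N bp at superhelix density sigma (alpha in turns)."""

    n_domain: int
    sigma: float
    constants: PhysicalConstants = PhysicalConstants()

    def __post_init__(self):
        if self.n_domain < 1:
            raise ValueError("domain length must be >= 1")

    @property
    def alpha(self) -> float:
        """Linking difference, turns: alpha = sigma * N / A_B."""
        return self.sigma * self.n_domain / self.constants.a_b

    @property
    def k_coeff(self) -> float:
        return self.constants.quad_coeff(self.n_domain)


@dataclass(frozen=True)
class StateGeometry:
    """Composition of a state: n_z transformed bp in r runs."""

    n_z: int
    r: int

    def __post_init__(self):
        if self.n_z % 2:
            raise ValueError("n_z must be even (Z-DNA has a dinucleotide unit)")
        if self.n_z < 0 or self.r < 0 or (self.r == 0) != (self.n_z == 0):
            raise ValueError("inconsistent state geometry")


def residual_linking(ctx: TopologyContext, geom: StateGeometry) -> float:
    """Residual linking difference after transition, turns.

    alpha_r = alpha + n_z * (1/A_B + 1/A_Z) + 2 * r * a.  For alpha < 0 the
    transition moves alpha_r toward zero.
    """
    c = ctx.constants
    return ctx.alpha + geom.n_z * c.delta_twist + 2.0 * geom.r * c.junction_twist


def superhelical_energy(ctx: TopologyContext, alpha_r: float) -> float:
    """Quadratic stress free energy (K/2) * alpha_r**2, kcal/mol."""
    return 0.5 * ctx.k_coeff * alpha_r * alpha_r


def state_free_energy(
    ctx: TopologyContext,
    run_energies: list[float] | tuple[float, ...] = (),
    geom: StateGeometry | None = None,
) -> float:
    """Total free energy of a state, kcal/mol.

    G = sum of run transition energies + 2b * r (nucleation) +
    (K/2) * alpha_r(n_z, r)**2.  The untransformed state has G = (K/2) alpha**2.
    """
    if geom is None:
        geom = StateGeometry(0, 0)
    if len(run_energies) != geom.r:
        raise ValueError("one transition energy is required per run")
    c = ctx.constants
    g = float(sum(run_energies)) + c.run_nucleation * geom.r
    return g + superhelical_energy(ctx, residual_linking(ctx, geom))
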