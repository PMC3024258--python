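"""Onset superhelix density of an engineered insert.

Bisection on sigma for the density at which a (CG)16 insert's Z-probability
crosses 80% - the computational analogue of reading the transition midpoint
off a two-dimensional gel.  Also shows that doubling the nucleation energy
pushes the onset to more negative densities.
"""

from sibz import PhysicalConstants, make_context, onset_sigma
from sibz.fixtures import poly_t_with_insert

fx = poly_t_with_insert(2968, "CG" * 16, 300)
ctx = make_context(fx.sequence, circular=True)

onset = onset_sigma(ctx, fx.regions["insert"], level=0.8,
                    sigma_range=(-0.07, 0.0))
print(f"onset sigma at 80% (default constants): {onset.sigma_c}")
print(f"  ({onset.evaluations} profile evaluations, bisected to 0.0005)")

hard = PhysicalConstants(junction_nucleation=10.0)
onset2 = onset_sigma(ctx, fx.regions["insert"], level=0.8,
                     sigma_range=(-0.07, 0.0), constants=hard)
print(f"onset sigma with doubled nucleation:    {onset2.sigma_c}")
print("a costlier B-Z junction delays the transition, as expected")
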