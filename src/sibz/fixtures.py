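"""Deterministic synthetic sequences used throughout the tests and examples.

Thymidine backgrounds are maximally Z-resistant (the TT unit costs 3.9
kcal/mol per dinucleotide and 7.4 per junction), so an insert placed in a
poly-T circle is the only Z-susceptible site and its behaviour can be reasoned
about in closed form.  The insert fixtures mirror the classic engineered
plasmid experiments: a perfect (CG)16 insert, the same length with one GG
Z-Z junction ((CG)8(GC)8, +4.0 kcal/mol), and a 26-bp insert carrying one GA
and one TC unit (+6.8 kcal/mol relative to perfect alternation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES", "random_sequence",
           "poly_t_with_insert", "tss_cohort", "pbr322_derivative",
           "RESTRICTION_SITES"]

SEQ1_INSERT = "CG" * 16
SEQ2_INSERT = "CG" * 8 + "GC" * 8
SEQ3_INSERT = "CG" * 4 + "GA" + "CG" * 3 + "TC" + "CG" * 4

#: insert 1 of the two-site competition construct: short, perfect (CG)10.
#: It is longer than any junction-free block of insert 2 (so it is the single
#: cheapest site and transforms first) yet much shorter than insert 2.
COMPETITION_INSERT1 = "CG" * 10
#: insert 2: seven phase-alternating 14-bp blocks -> exactly six GG Z-Z
#: junctions over 98 bp.  Its full transition relieves ~18 turns of stress,
#: enough to revert insert 1 once it transforms.
COMPETITION_INSERT2 = "".join(("CG" * 7, "GC" * 7)[i % 2] for i in range(7))


@dataclass(frozen=True)
class Fixture:
    """A named synthetic sequence with its topology and regions of interest."""

    name: str
    sequence: str
    circular: bool
    regions: dict = field(default_factory=dict)  # name -> (start, end) 0-based half-open
    notes: str = ""


def poly_t_with_insert(background: int, insert: str, at: int, circular: bool = True,
                       name: str = "polyT_insert") -> Fixture:
    """A poly-T molecule of ``background`` T bp with ``insert`` placed after
    position ``at`` of the background."""
    seq = "T" * at + insert + "T" * (background - at)
    return Fixture(name, seq, circular, {"insert": (at, at + len(insert))})


def make_fixture(name: str) -> Fixture:
    """Built-in fixtures by name (see FIXTURE_NAMES)."""
    if name == "seq1_insert":
        return Fixture(name, SEQ1_INSERT, False, {"insert": (0, 32)},
                       "32-bp perfect alternating CG; the most Z-susceptible insert")
    if name == "seq2_insert":
        return Fixture(name, SEQ2_INSERT, False, {"insert": (0, 32)},
                       "32 bp with one GG Z-Z junction; +4.0 kcal/mol vs seq1")
    if name == "seq3_insert":
        return Fixture(name, SEQ3_INSERT, False, {"insert": (0, 26)},
                       "26 bp with one GA and one TC unit; +6.8 kcal/mol vs perfect CG")
    if name == "twin_islands60":
        seq = "T" * 10 + "CG" * 4 + "T" * 22 + "CG" * 4 + "T" * 12
        return Fixture(name, seq, True,
                       {"island1": (10, 18), "island2": (40, 48)},
                       "60-bp circle, two equidistant 8-bp CG islands; oracle fixture")
    if name == "competition5000":
        seq = ("T" * 1000 + COMPETITION_INSERT1 + "T" * 2500
               + COMPETITION_INSERT2 + "T" * 1500)
        i1 = (1000, 1000 + len(COMPETITION_INSERT1))
        i2_start = 1000 + len(COMPETITION_INSERT1) + 2500
        i2 = (i2_start, i2_start + len(COMPETITION_INSERT2))
        return Fixture(name, seq, True, {"insert1": i1, "insert2": i2},
                       "5000-bp poly-T circle with a short perfect CG insert and a "
                       "longer insert containing exactly six Z-Z junctions")
    raise ValueError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_NAMES)}")


FIXTURE_NAMES = ("seq1_insert", "seq2_insert", "seq3_insert", "twin_islands60",
                 "competition5000")


def random_sequence(length: int, seed: int, gc_patch: str | None = None,
                    patch_at: int | None = None) -> str:
    """Uniform random ACGT sequence; optionally overwrite a patch (e.g. a
    Z-susceptible island) at a given position.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    if gc_patch is not None:
        at = patch_at if patch_at is not None else length // 2
        seq[at:at + len(gc_patch)] = list(gc_patch)
    return "".join(seq)


def tss_cohort(n_sequences: int = 20, length: int = 2000, anchor: int = 1000,
               insert: str = "CG" * 12, offset: int = -100, seed: int = 0):
    """Synthetic transcription-start-site cohort for aggregation tests.

    Returns (list of Fixture, anchor).  Half the sequences (the even-indexed
    ones) carry ``insert`` ending ``-offset`` bp upstream of the anchor; all
    are poly-T otherwise, so the carriers are unambiguous.
    """
    out = []
    at = anchor + offset - len(insert) if offset < 0 else anchor + offset
    for i in range(n_sequences):
        if i % 2 == 0:
            seq = "T" * at + insert + "T" * (length - at - len(insert))
            regions = {"insert": (at, at + len(insert))}
        else:
            seq = "T" * length
            regions = {}
        out.append(Fixture(f"cohort_{i:02d}", seq, False, regions))
    return out, anchor


RESTRICTION_SITES = {
    # recognition motif and cut offset within it (top strand)
    "BamHI": ("GGATCC", 1),   # G^GATCC
    "PvuII": ("CAGCTG", 3),   # CAG^CTG (blunt)
}


def pbr322_derivative(plasmid: str, insert: str, site: str) -> Fixture:
    """Insert ``insert`` at a unique restriction site of a user-supplied
    plasmid sequence (circular), e.g. pBR322 from GenBank J01749.

    The recognition motif must occur exactly once on the given strand; the
    insert is placed at the enzyme's cut position.
    """
    if site not in RESTRICTION_SITES:
        raise ValueError(f"unknown restriction site {site!r}")
    motif, offset = RESTRICTION_SITES[site]
    plasmid = plasmid.upper()
    hits = []
    start = plasmid.find(motif)
    while start != -1:
        hits.append(start)
        start = plasmid.find(motif, start + 1)
    if len(hits) != 1:
        raise ValueError(
            f"{site} motif {motif} occurs {len(hits)} times; need exactly one"
        )
    cut = hits[0] + offset
    seq = plasmid[:cut] + insert + plasmid[cut:]
    return Fixture(
        f"derivative_{site}",
        seq,
        True,
        {"insert": (cut, cut + len(insert))},
        f"user plasmid with {len(insert)}-bp insert at the {site} cut site",
    )
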