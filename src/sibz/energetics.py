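"""Sequence-dependent energetics of the B-Z transition.

Z-DNA is built from dinucleotide repeat units in which one base pair adopts the
*syn* and the other the *anti* glycosidic conformation.  The free energy of
flipping a window of duplex DNA from B-form to Z-form is the sum of the unit
energies (which depend on whether the unit is 5'-anti-3'-syn, "AS", or
5'-syn-3'-anti, "SA") plus a Z-Z junction penalty wherever the syn/anti
alternation breaks between adjacent units.  The per-dinucleotide energies are
shipped as a plain-text table (``data/bz_energies.tsv``) and can be replaced by
the user.

The conformation of each base pair in a candidate Z-run is chosen by a fast
four-pass heuristic (purine->syn seed, triple-repeat removal, AASS/SSAA quartet
repair, and a final junction-minimizing fix-up of any invalid unit).  Because
the heuristic scans left to right, a window and its reverse complement can in
rare, energetically expensive patterns receive different assignments; run
energies are therefore evaluated in both orientations and the cheaper
assignment is kept, which makes window energies exactly reverse-complement
symmetric.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DinucleotideEnergyTable",
    "ConformationAssignment",
    "ZRunEnergy",
    "encode",
    "decode",
    "revcomp_codes",
    "assign_conformations",
    "run_transition_energy",
    "window_energies",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
A, C, G, T = 0, 1, 2, 3
ANTI, SYN = 0, 1

#: purine (A, G) base pairs seed as syn, pyrimidines (C, T) as anti
_PURINE = np.array([True, False, True, False])


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    seq = sequence.upper()
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(
            f"sequence contains non-ACGT symbols: {sorted(bad)}; "
            "degenerate bases must be resolved before analysis"
        )
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (A<->T is 0<->3, C<->G is 1<->2)."""
    return (3 - codes[::-1]).astype(np.uint8)


@dataclass(frozen=True)
class DinucleotideEnergyTable:
    """B-Z transition energies, kcal/mol, for all 16 dinucleotides.

    ``energy_as[i, j]`` is the cost of the doublet (i, j) as a 5'-anti-3'-syn
    Z unit, ``energy_sa`` the 5'-syn-3'-anti cost, and ``energy_zz`` the Z-Z
    junction penalty for the doublet spanning two out-of-phase units.
    Reverse-complement doublets share energies.
    """

    energy_as: np.ndarray
    energy_sa: np.ndarray
    energy_zz: np.ndarray
    source: str = field(default="builtin", compare=False)

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "DinucleotideEnergyTable":
        if path is None:
            ref = importlib.resources.files("sibz.data").joinpath("bz_energies.tsv")
            text = ref.read_text()
            source = "builtin"
        else:
            text = Path(path).read_text()
            source = str(path)
        e_as = np.full((4, 4), np.nan)
        e_sa = np.full((4, 4), np.nan)
        e_zz = np.full((4, 4), np.nan)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("dinucleotide"):
                continue
            cls_label, v_as, v_sa, v_zz = line.split("\t")
            for doublet in cls_label.split("="):
                i, j = _CODE[doublet[0]], _CODE[doublet[1]]
                e_as[i, j] = float(v_as)
                e_sa[i, j] = float(v_sa)
                e_zz[i, j] = float(v_zz)
        if np.isnan(e_as).any():
            missing = [
                BASES[i] + BASES[j] for i in range(4) for j in range(4) if np.isnan(e_as[i, j])
            ]
            raise ValueError(f"energy table is missing doublets: {missing}")
        if (e_as <= 0).any() or (e_sa <= 0).any() or (e_zz <= 0).any():
            raise ValueError("all B-Z transition energies must be strictly positive")
        for m in (e_as, e_sa, e_zz):
            m.setflags(write=False)
        return cls(e_as, e_sa, e_zz, source=source)

    def lookup(self, doublet: str, kind: str) -> float:
        """Energy of a two-base string; ``kind`` is ``"AS"``, ``"SA"`` or ``"ZZ"``."""
        i, j = _CODE[doublet[0].upper()], _CODE[doublet[1].upper()]
        return {"AS": self.energy_as, "SA": self.energy_sa, "ZZ": self.energy_zz}[kind][i, j]


_DEFAULT_TABLE: DinucleotideEnergyTable | None = None


def default_table() -> DinucleotideEnergyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = DinucleotideEnergyTable.from_tsv()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class ConformationAssignment:
    """Per-base-pair syn/anti labels for an even-length window."""

    labels: tuple[str, ...]  # "anti" | "syn"

    def __post_init__(self):
        if len(self.labels) % 2:
            raise ValueError("conformation assignments cover even-length windows only")

    @property
    def units(self) -> tuple[str, ...]:
        """Per-dinucleotide-unit pattern, "AS" or "SA"."""
        out = []
        for k in range(0, len(self.labels), 2):
            out.append("AS" if self.labels[k] == "anti" else "SA")
        return tuple(out)


@dataclass(frozen=True)
class ZRunEnergy:
    """Transition energy of one candidate Z-run, nucleation excluded."""

    total: float
    per_bp: tuple[float, ...]
    junction_count: int
    assignment: ConformationAssignment

    def __post_init__(self):
        if abs(self.total - sum(self.per_bp)) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("per-bp energy shares must sum to the run total")


def _assign_labels(bases: np.ndarray, table: DinucleotideEnergyTable) -> np.ndarray:
    """Vectorized four-pass syn/anti assignment.

    ``bases`` has shape (n_windows, L) with L even; returns labels of the same
    shape (0 = anti, 1 = syn).  The passes are applied left to right, matching
    the documented scan order.
    """
    n, L = bases.shape
    if L % 2 or L < 2:
        raise ValueError("window length must be even and >= 2")
    lab = _PURINE[bases].astype(np.uint8)

    # pass 2: flip any bp matching both nearest neighbours (kills runs > 2)
    for j in range(1, L - 1):
        m = (lab[:, j - 1] == lab[:, j]) & (lab[:, j] == lab[:, j + 1])
        lab[m, j] ^= 1

    # pass 3: AASS / SSAA quartets -> flip the central two
    for j in range(L - 3):
        m = (
            (lab[:, j] == lab[:, j + 1])
            & (lab[:, j + 2] == lab[:, j + 3])
            & (lab[:, j] != lab[:, j + 2])
        )
        lab[m, j + 1] ^= 1
        lab[m, j + 2] ^= 1

    # pass 4: repair units whose two bp share a label, choosing the flip with
    # the lower Z-Z junction cost against the current neighbours (tie: lower
    # unit energy, then flip the 3' bp)
    zz = table.energy_zz
    e_as = table.energy_as
    e_sa = table.energy_sa
    for k in range(L // 2):
        a, b = 2 * k, 2 * k + 1
        m = lab[:, a] == lab[:, b]
        if not m.any():
            continue
        idx = np.nonzero(m)[0]
        x = lab[idx, a].astype(np.int64)  # the shared label
        b0 = bases[idx, a].astype(np.int64)
        b1 = bases[idx, b].astype(np.int64)
        zz_a = np.zeros(len(idx))
        zz_b = np.zeros(len(idx))
        if a > 0:
            left_lab = lab[idx, a - 1].astype(np.int64)
            left_zz = zz[bases[idx, a - 1].astype(np.int64), b0]
            zz_a += np.where(left_lab == 1 - x, left_zz, 0.0)
            zz_b += np.where(left_lab == x, left_zz, 0.0)
        if b < L - 1:
            right_lab = lab[idx, b + 1].astype(np.int64)
            right_zz = zz[b1, bases[idx, b + 1].astype(np.int64)]
            zz_a += np.where(x == right_lab, right_zz, 0.0)
            zz_b += np.where(1 - x == right_lab, right_zz, 0.0)
        # option A = flip 5' bp -> labels (1-x, x); option B = flip 3' bp
        unit_a = np.where(x == 1, e_as[b0, b1], e_sa[b0, b1])
        unit_b = np.where(x == 1, e_sa[b0, b1], e_as[b0, b1])
        choose_a = (zz_a < zz_b - 1e-12) | (
            (np.abs(zz_a - zz_b) <= 1e-12) & (unit_a < unit_b - 1e-12)
        )
        ia = idx[choose_a]
        ib = idx[~choose_a]
        lab[ia, a] ^= 1
        lab[ib, b] ^= 1
    return lab


def _energies_from_labels(
    bases: np.ndarray, lab: np.ndarray, table: DinucleotideEnergyTable
) -> tuple[np.ndarray, np.ndarray]:
    """Total window energies and junction counts, shape (n_windows,)."""
    n, L = bases.shape
    b = bases.astype(np.int64)
    first = lab[:, 0::2]
    e_unit = np.where(
        first == ANTI,
        table.energy_as[b[:, 0::2], b[:, 1::2]],
        table.energy_sa[b[:, 0::2], b[:, 1::2]],
    )
    total = e_unit.sum(axis=1)
    n_junc = np.zeros(n, dtype=np.int64)
    if L >= 4:
        broken = lab[:, 1:-2:2] == lab[:, 2:-1:2]
        e_junc = table.energy_zz[b[:, 1:-2:2], b[:, 2:-1:2]]
        total = total + np.where(broken, e_junc, 0.0).sum(axis=1)
        n_junc = broken.sum(axis=1)
    return total, n_junc


def assign_conformations(
    window: str, table: DinucleotideEnergyTable | None = None
) -> ConformationAssignment:
    """Assign syn/anti conformations to an even-length window (forward scan).

    Applies, in order: purines->syn seed; removal of label repeats longer than
    two; AASS/SSAA quartet repair; and junction-minimizing repair of any unit
    whose base pairs share a label.
    """
    table = table or default_table()
    codes = encode(window)
    if len(codes) % 2 or len(codes) < 2:
        raise ValueError("window length must be even and >= 2")
    lab = _assign_labels(codes[None, :], table)[0]
    return ConformationAssignment(tuple("syn" if v else "anti" for v in lab))


def _scalar_energy(
    codes: np.ndarray, table: DinucleotideEnergyTable
) -> tuple[float, np.ndarray, int, np.ndarray]:
    """Energy, per-bp shares, junction count and labels of one window."""
    lab = _assign_labels(codes[None, :], table)[0]
    L = len(codes)
    b = codes.astype(np.int64)
    per_bp = np.zeros(L)
    n_junc = 0
    total = 0.0
    for k in range(L // 2):
        i, j = 2 * k, 2 * k + 1
        e = (
            table.energy_as[b[i], b[j]]
            if lab[i] == ANTI
            else table.energy_sa[b[i], b[j]]
        )
        per_bp[i] += e / 2
        per_bp[j] += e / 2
        total += e
    for k in range(L // 2 - 1):
        i, j = 2 * k + 1, 2 * k + 2
        if lab[i] == lab[j]:
            e = table.energy_zz[b[i], b[j]]
            per_bp[i] += e / 2
            per_bp[j] += e / 2
            total += e
            n_junc += 1
    return total, per_bp, n_junc, lab


def run_transition_energy(
    sequence: str | np.ndarray,
    start: int = 0,
    length: int | None = None,
    circular: bool = False,
    table: DinucleotideEnergyTable | None = None,
    min_len: int = 2,
    max_len: int | None = None,
) -> ZRunEnergy:
    """Transition energy of the window ``[start, start+length)`` of ``sequence``.

    The window is assigned conformations in both orientations and the cheaper
    assignment is kept, so the energy of a window always equals the energy of
    its reverse complement.  Nucleation is not included.
    """
    table = table or default_table()
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    n = len(codes)
    if length is None:
        length = n - start
    if length % 2 or length < max(2, min_len):
        raise ValueError(f"run length must be even and >= {max(2, min_len)}, got {length}")
    if max_len is not None and length > max_len:
        raise ValueError(f"run length {length} exceeds the maximum of {max_len}")
    if circular:
        window = codes[(start + np.arange(length)) % n]
    else:
        if start < 0 or start + length > n:
            raise ValueError("window falls off the end of a linear sequence")
        window = codes[start : start + length]

    tot_f, per_f, junc_f, lab_f = _scalar_energy(window, table)
    tot_r, per_r, junc_r, _ = _scalar_energy(revcomp_codes(window), table)
    if tot_r < tot_f - 1e-12:
        total, per_bp, n_junc = tot_r, per_r[::-1], junc_r
        # labels on the forward strand mirror the reverse-complement assignment
        lab = (1 - _assign_labels(revcomp_codes(window)[None, :], table)[0][::-1]).astype(np.uint8)
    else:
        total, per_bp, n_junc, lab = tot_f, per_f, junc_f, lab_f
    assignment = ConformationAssignment(tuple("syn" if v else "anti" for v in lab))
    return ZRunEnergy(float(total), tuple(per_bp), int(n_junc), assignment)


def window_energies(
    codes: np.ndarray,
    length: int,
    circular: bool,
    table: DinucleotideEnergyTable | None = None,
) -> np.ndarray:
    """Energies of every window of ``length`` bp, orientation-symmetrized.

    Returns an array indexed by window start: length N for circular sequences
    (windows may wrap) and N - length + 1 for linear ones.
    """
    table = table or default_table()
    n = len(codes)
    if length % 2 or length < 2 or length > n:
        raise ValueError("invalid window length")

    def forward(arr: np.ndarray) -> np.ndarray:
        if circular:
            ext = np.concatenate([arr, arr[: length - 1]])
            starts = n
        else:
            ext = arr
            starts = n - length + 1
        win = np.lib.stride_tricks.sliding_window_view(ext, length)[:starts]
        win = np.ascontiguousarray(win)
        lab = _assign_labels(win, table)
        tot, _ = _energies_from_labels(win, lab, table)
        return tot

    e_fwd = forward(codes)
    e_rc_seq = forward(revcomp_codes(codes))
    # window (s, L) of the forward strand is window (N - s - L) of the rc strand
    if circular:
        idx = (n - np.arange(n) - length) % n
    else:
        idx = n - length - np.arange(n - length + 1)
    return np.minimum(e_fwd, e_rc_seq[idx])
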