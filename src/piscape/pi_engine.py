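"""Protein net charge, isoelectric point, and amino-acid composition.

The charge model is the classic Henderson–Hasselbalch sum over ionizable
groups: for a protein with ``n_g`` instances of group ``g`` (the seven
ionizable side chains D, E, C, Y, H, K, R plus one N-terminal amine and one
C-terminal carboxyl),

    Z(pH) = sum_g  sign_g * n_g * f_g(pH)

where the ionized fraction is ``f = 1/(1 + 10^(pH - pKa))`` for positively
charged groups and ``f = 1/(1 + 10^(pKa - pH))`` for negatively charged
ones.  Z is strictly decreasing in pH whenever at least one group is
present, so the isoelectric point — the unique root of Z — is found by
bisection on [0, 14].

The default pKa table mirrors the EMBOSS Pepstats constants so that pI
values are directly comparable with surveys computed with that tool; the
Bjellqvist and IPC_protein tables ship as named alternatives because pI is
meaningful only relative to a pKa set.

Ambiguity codes (X, B, Z, J, U, O) contribute no charge and are excluded
from Mole% composition, numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .sequence_io import STANDARD_RESIDUES, ProteinRecord

# Ionizable group order used by all internal count vectors.
GROUPS = ("Nterm", "Cterm", "D", "E", "C", "Y", "H", "K", "R")
POSITIVE_GROUPS = frozenset({"Nterm", "H", "K", "R"})
NEGATIVE_GROUPS = frozenset({"Cterm", "D", "E", "C", "Y"})
_SIDE_CHAINS = "DECYHKR"


@dataclass(frozen=True)
class PkaSet:
    """A named table of pKa values and charge signs for ionizable groups."""

    name: str
    pka: Mapping[str, float]
    sign: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(GROUPS) - set(self.pka)
        if missing:
            raise ValidationError(f"PkaSet {self.name!r}: missing groups {sorted(missing)}")
        for g, v in self.pka.items():
            if not (0.0 < v < 14.0):
                raise ValidationError(f"PkaSet {self.name!r}: pKa[{g}]={v} outside (0, 14)")
        if not self.sign:
            object.__setattr__(
                self, "sign",
                {g: (+1 if g in POSITIVE_GROUPS else -1) for g in GROUPS},
            )
        for g in GROUPS:
            expected = +1 if g in POSITIVE_GROUPS else -1
            if self.sign[g] != expected:
                raise ValidationError(
                    f"PkaSet {self.name!r}: sign[{g}] must be {expected:+d}"
                )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pka = np.array([self.pka[g] for g in GROUPS])
        sign = np.array([self.sign[g] for g in GROUPS], dtype=float)
        return pka, sign


#: EMBOSS Pepstats constants (Epk.dat defaults).
EMBOSS = PkaSet("emboss", {
    "Nterm": 8.6, "Cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5,
})

#: Bjellqvist et al. constants (as used by ExPASy / Biopython ProtParam).
BJELLQVIST = PkaSet("bjellqvist", {
    "Nterm": 7.5, "Cterm": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0, "H": 5.98, "K": 10.0, "R": 12.0,
})

#: IPC_protein constants (Kozlowski 2016).
IPC_PROTEIN = PkaSet("ipc_protein", {
    "Nterm": 9.094, "Cterm": 2.869,
    "D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85, "H": 5.637,
    "K": 9.052, "R": 11.84,
})

PKA_SETS: dict[str, PkaSet] = {s.name: s for s in (EMBOSS, BJELLQVIST, IPC_PROTEIN)}


@dataclass(frozen=True)
class AaComposition:
    """Pooled Mole% over the 20 standard residues (ambiguity codes excluded)."""

    mole_percent: Mapping[str, float]
    n_residues: int


@dataclass(frozen=True)
class ChargeSummary:
    protein_id: str
    length: int
    pI: float
    acid_count: int          # D + E
    basic_count: int         # K + R + H
    net_charge_at_7: float


def group_counts(sequence: str, include_termini: bool = True) -> np.ndarray:
    """Counts of ionizable group instances in GROUPS order."""
    counts = np.zeros(len(GROUPS))
    if include_termini:
        counts[0] = 1.0
        counts[1] = 1.0
    for i, res in enumerate(_SIDE_CHAINS):
        counts[2 + i] = sequence.count(res)
    return counts


def _charge_from_counts(counts: np.ndarray, pH: float | np.ndarray,
                        pka_set: PkaSet) -> np.ndarray:
    """Z(pH) from a (..., 9) count array; broadcasts over pH arrays."""
    pka, sign = pka_set.as_arrays()
    pH = np.asarray(pH, dtype=float)
    # positive groups: f = 1/(1+10^(pH-pKa)); negative: f = 1/(1+10^(pKa-pH))
    delta = np.where(sign > 0, pH[..., None] - pka, pka - pH[..., None])
    frac = 1.0 / (1.0 + 10.0 ** delta)
    return (counts * sign * frac).sum(axis=-1)


def net_charge(sequence: str, pH: float, pka_set: PkaSet = EMBOSS,
               include_termini: bool = True) -> float:
    """Net charge (elementary charges) of a sequence at a given pH."""
    if not (0.0 <= pH <= 14.0):
        raise ValidationError(f"pH {pH} outside [0, 14]")
    counts = group_counts(sequence, include_termini)
    return float(_charge_from_counts(counts, pH, pka_set))


def _bisect_counts(counts: np.ndarray, pka_set: PkaSet,
                   tol: float) -> np.ndarray:
    """Vectorized bisection for pI over a (n, 9) count matrix.

    Rows with no ionizable group at all (possible only when termini are
    excluded) yield NaN.
    """
    counts = np.atleast_2d(counts)
    pka, sign = pka_set.as_arrays()
    lo = np.zeros(counts.shape[0])
    hi = np.full(counts.shape[0], 14.0)
    n_iter = int(np.ceil(np.log2(14.0 / tol)))
    weighted = counts * sign
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        delta = np.where(sign > 0, mid[:, None] - pka, pka - mid[:, None])
        z = (weighted / (1.0 + 10.0 ** delta)).sum(axis=1)
        above = z > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    pI = 0.5 * (lo + hi)
    degenerate = counts.sum(axis=1) == 0
    return np.where(degenerate, np.nan, pI)


def isoelectric_point(sequence: str, pka_set: PkaSet = EMBOSS,
                      tol: float = 1e-3, include_termini: bool = True) -> float:
    """The pH at which net charge crosses zero, by bisection to within tol."""
    if tol <= 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    counts = group_counts(sequence, include_termini)
    return float(_bisect_counts(counts, pka_set, tol)[0])


def isoelectric_points(sequences: Iterable[str], pka_set: PkaSet = EMBOSS,
                       tol: float = 1e-3,
                       include_termini: bool = True) -> np.ndarray:
    """Batch pI for many sequences (one vectorized bisection)."""
    counts = np.array([group_counts(s, include_termini) for s in sequences])
    if counts.size == 0:
        return np.empty(0)
    return _bisect_counts(counts, pka_set, tol)


def charge_summary(record: ProteinRecord, pka_set: PkaSet = EMBOSS,
                   tol: float = 1e-3) -> ChargeSummary:
    seq = record.sequence
    return ChargeSummary(
        protein_id=record.protein_id,
        length=len(seq),
        pI=isoelectric_point(seq, pka_set, tol),
        acid_count=seq.count("D") + seq.count("E"),
        basic_count=seq.count("K") + seq.count("R") + seq.count("H"),
        net_charge_at_7=net_charge(seq, 7.0, pka_set),
    )


def aa_composition(records: Sequence[ProteinRecord] | Sequence[str]) -> AaComposition:
    """Pooled Mole% of the 20 standard residues over one or more sequences."""
    counts = {r: 0 for r in STANDARD_RESIDUES}
    for rec in records:
        seq = rec.sequence if isinstance(rec, ProteinRecord) else rec
        for res in seq:
            if res in counts:
                counts[res] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no standard residues in input; Mole% undefined")
    return AaComposition(
        mole_percent={r: 100.0 * c / total for r, c in counts.items()},
        n_residues=total,
    )


def charged_fractions(comp: AaComposition) -> tuple[float, float, float]:
    """(acidic, basic, charged) Mole%: D+E, K+H+R, and their sum."""
    mp = comp.mole_percent
    acidic = mp["D"] + mp["E"]
    basic = mp["K"] + mp["H"] + mp["R"]
    return acidic, basic, acidic + basic
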