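"""Pairwise proteome comparison of phylogenetic neighbours.

Implements the protein-level half of a marine/freshwater genome-pair
comparison: all-vs-all local alignment with a k-mer prefilter, reciprocal
best hits (RBH), average amino-acid identity (AAI) over RBH pairs,
percentage of conserved proteins (POCP, conserved = e-value < 1e-5,
identity > 40%, alignable region > 50% of the query), a two-genome
core/flexible partition (core = member of an RBH pair), and per-category
and per-partition pI spectra with Mole% composition deltas.

Alignment is affine-gap Smith–Waterman with BLOSUM62 (gap open 11, extend
1) via Biopython's PairwiseAligner.  The e-value proxy follows the
Karlin–Altschul form E = K * m * n * exp(-lambda * S) with the standard
gapped BLOSUM62 constants (K = 0.041, lambda = 0.267) and n = the subject
proteome's residue count; it is a documented stand-in for a BLAST e-value,
used only for the POCP conserved-protein threshold.

Nucleotide ANI and 16S identity are not computed here; when reported by an
external tool they ride along as pass-through metadata in pair reports.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .localization import CATEGORIES, LocalizationCall
from .pi_engine import PkaSet, EMBOSS, aa_composition, isoelectric_points
from .sequence_io import ProteinRecord
from .spectrum import PiSpectrum, acid_neutral_basic, bin_spectrum

logger = logging.getLogger(__name__)

# Karlin-Altschul constants for gapped BLOSUM62 (open 11, extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 0.5
KMER_SIZE = 5
MIN_SHARED_KMERS = 2

_POCP_MAX_EVALUE = 1e-5
_POCP_MIN_IDENTITY = 40.0
_POCP_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignable_fraction_of_query: float
    score: float
    e_value_proxy: float


@dataclass(frozen=True)
class PairComparison:
    id_a: str
    id_b: str
    aai: float                      # NaN when no RBH pairs
    n_rbh_pairs: int
    pocp: float
    core_ids_a: tuple[str, ...]
    flexible_ids_a: tuple[str, ...]
    core_ids_b: tuple[str, ...]
    flexible_ids_b: tuple[str, ...]
    per_category_spectra: Mapping[str, Mapping[str, PiSpectrum]]
    partition_spectra: Mapping[str, Mapping[str, PiSpectrum]]
    composition_delta: Mapping[str, float]      # Mole% A - B per residue
    mean_pi: Mapping[str, Mapping[str, float]]  # genome -> category -> mean pI
    higher_acid_fraction: str                   # id of the more acid-shifted genome
    metadata: Mapping[str, float] = field(default_factory=dict)


_MATRIX = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = set(str(_MATRIX.alphabet))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _sanitize(seq: str) -> str:
    # J/U/O are absent from BLOSUM62; score them as X
    if set(seq) <= _MATRIX_ALPHABET:
        return seq
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in seq)


def _kmers(seq: str, k: int = KMER_SIZE) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def align_pair(query: str, subject: str,
               aligner: Align.PairwiseAligner | None = None
               ) -> tuple[float, float, float]:
    """Best local alignment of two sequences.

    Returns (percent_identity, alignable_fraction_of_query, raw_score);
    identity is counted over all alignment columns, gaps included.
    """
    if aligner is None:
        aligner = _make_aligner()
    alignments = aligner.align(_sanitize(query), _sanitize(subject))
    try:
        best = alignments[0]
    except IndexError:
        return 0.0, 0.0, 0.0
    counts = best.counts()
    aln_len = counts.gaps + counts.identities + counts.mismatches
    if aln_len == 0:
        return 0.0, 0.0, 0.0
    pident = 100.0 * counts.identities / aln_len
    qblocks = best.aligned[0]
    span = int(qblocks[-1][1] - qblocks[0][0])
    return pident, span / len(query), float(best.score)


def all_vs_all_hits(proteome_a: Sequence[ProteinRecord],
                    proteome_b: Sequence[ProteinRecord],
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_coverage: float = DEFAULT_MIN_COVERAGE) -> list[AlignmentHit]:
    """Filtered local-alignment hits of every A protein against B.

    Candidate subjects must share >= 2 exact 5-mers with the query (the
    prefilter that keeps all-vs-all cost desk-scale); hits below the
    identity/coverage thresholds are discarded.
    """
    if not proteome_a or not proteome_b:
        raise ValidationError("both proteomes must be non-empty")
    aligner = _make_aligner()
    db_residues = sum(len(r.sequence) for r in proteome_b)
    kmer_index: dict[str, list[int]] = {}
    for j, rec in enumerate(proteome_b):
        for kmer in _kmers(rec.sequence):
            kmer_index.setdefault(kmer, []).append(j)
    hits: list[AlignmentHit] = []
    for qrec in proteome_a:
        shared = Counter()
        for kmer in _kmers(qrec.sequence):
            for j in kmer_index.get(kmer, ()):
                shared[j] += 1
        for j, n_shared in shared.items():
            if n_shared < MIN_SHARED_KMERS:
                continue
            srec = proteome_b[j]
            pident, coverage, score = align_pair(qrec.sequence, srec.sequence,
                                                 aligner)
            if pident < min_identity or coverage < min_coverage:
                continue
            evalue = KA_K * len(qrec.sequence) * db_residues * math.exp(
                -KA_LAMBDA * score)
            hits.append(AlignmentHit(qrec.protein_id, srec.protein_id,
                                     pident, coverage, score, evalue))
    return hits


def _best_per_query(hits: Sequence[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best hit per query: highest score, ties to lexicographic subject id."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if (cur is None or hit.score > cur.score
                or (hit.score == cur.score and hit.subject_id < cur.subject_id)):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(hits_ab: Sequence[AlignmentHit],
                         hits_ba: Sequence[AlignmentHit]
                         ) -> list[tuple[AlignmentHit, AlignmentHit]]:
    best_ab = _best_per_query(hits_ab)
    best_ba = _best_per_query(hits_ba)
    pairs = []
    for a_id in sorted(best_ab):
        fwd = best_ab[a_id]
        rev = best_ba.get(fwd.subject_id)
        if rev is not None and rev.subject_id == a_id:
            pairs.append((fwd, rev))
    return pairs


def compute_aai(hits_ab: Sequence[AlignmentHit],
                hits_ba: Sequence[AlignmentHit]) -> tuple[float, int]:
    """AAI = unweighted mean identity over reciprocal best hit pairs.

    Each pair contributes the mean of its two directional identities, so
    AAI(a, b) == AAI(b, a) exactly.  Returns (NaN, 0) with a warning when
    there are no RBH pairs.
    """
    pairs = reciprocal_best_hits(hits_ab, hits_ba)
    if not pairs:
        logger.warning("no reciprocal best hits; AAI undefined")
        return float("nan"), 0
    idents = [0.5 * (f.percent_identity + r.percent_identity) for f, r in pairs]
    return float(np.mean(idents)), len(pairs)


def _conserved(hit: AlignmentHit) -> bool:
    return (hit.e_value_proxy < _POCP_MAX_EVALUE
            and hit.percent_identity > _POCP_MIN_IDENTITY
            and hit.alignable_fraction_of_query > _POCP_MIN_COVERAGE)


def compute_pocp(hits_ab: Sequence[AlignmentHit],
                 hits_ba: Sequence[AlignmentHit],
                 n_a: int, n_b: int) -> float:
    """POCP = 100 * (C_a + C_b) / (n_a + n_b).

    C_x counts proteins of proteome x with at least one hit passing the
    conserved-protein thresholds (e < 1e-5, identity > 40%, aligned > 50%
    of the query).
    """
    if n_a + n_b == 0:
        raise ValidationError("POCP undefined for two empty proteomes")
    c_a = len({h.query_id for h in hits_ab if _conserved(h)})
    c_b = len({h.query_id for h in hits_ba if _conserved(h)})
    return 100.0 * (c_a + c_b) / (n_a + n_b)


def core_flexible_partition(
    rbh_pairs: Sequence[tuple[AlignmentHit, AlignmentHit]],
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Two-genome core/flexible split: core = member of an RBH pair."""
    core_a = {f.query_id for f, _ in rbh_pairs}
    core_b = {f.subject_id for f, _ in rbh_pairs}
    ca = tuple(r.protein_id for r in proteome_a if r.protein_id in core_a)
    fa = tuple(r.protein_id for r in proteome_a if r.protein_id not in core_a)
    cb = tuple(r.protein_id for r in proteome_b if r.protein_id in core_b)
    fb = tuple(r.protein_id for r in proteome_b if r.protein_id not in core_b)
    return ca, fa, cb, fb


def _subset_spectrum(pis: Mapping[str, float], ids: Sequence[str],
                     bin_width: float, label: str) -> PiSpectrum:
    return bin_spectrum([pis[i] for i in ids], bin_width=bin_width, label=label)


def compare_pair(proteome_a: Sequence[ProteinRecord],
                 proteome_b: Sequence[ProteinRecord],
                 localizations: Mapping[str, LocalizationCall],
                 pka_set: PkaSet = EMBOSS,
                 bin_width: float = 0.25,
                 min_identity: float = DEFAULT_MIN_IDENTITY,
                 min_coverage: float = DEFAULT_MIN_COVERAGE,
                 metadata: Mapping[str, float] | None = None) -> PairComparison:
    """Full two-proteome report: AAI, POCP, partition, spectra, composition.

    ``localizations`` must cover every protein of both proteomes (imported
    or heuristic calls; see :mod:`piscape.localization`).
    """
    id_a = proteome_a[0].proteome_id
    id_b = proteome_b[0].proteome_id
    hits_ab = all_vs_all_hits(proteome_a, proteome_b, min_identity, min_coverage)
    hits_ba = all_vs_all_hits(proteome_b, proteome_a, min_identity, min_coverage)
    rbh = reciprocal_best_hits(hits_ab, hits_ba)
    aai, n_rbh = compute_aai(hits_ab, hits_ba)
    pocp = compute_pocp(hits_ab, hits_ba, len(proteome_a), len(proteome_b))
    core_a, flex_a, core_b, flex_b = core_flexible_partition(
        rbh, proteome_a, proteome_b)

    spectra: dict[str, dict[str, PiSpectrum]] = {}
    partition_spectra: dict[str, dict[str, PiSpectrum]] = {}
    mean_pi: dict[str, dict[str, float]] = {}
    for gid, records, core, flex in ((id_a, proteome_a, core_a, flex_a),
                                     (id_b, proteome_b, core_b, flex_b)):
        pis_arr = isoelectric_points([r.sequence for r in records], pka_set)
        pis = {r.protein_id: float(p) for r, p in zip(records, pis_arr)}
        by_cat: dict[str, dict[str, float]] = {c: {} for c in CATEGORIES}
        missing = [r.protein_id for r in records
                   if r.protein_id not in localizations]
        if missing:
            raise ValidationError(
                f"{gid}: {len(missing)} protein(s) without localization calls "
                f"(e.g. {missing[:3]})"
            )
        for rec in records:
            by_cat[localizations[rec.protein_id].category][rec.protein_id] = \
                pis[rec.protein_id]
        spectra[gid] = {"whole": bin_spectrum(list(pis.values()),
                                              bin_width=bin_width,
                                              label=f"{gid}:whole")}
        mean_pi[gid] = {"whole": float(np.mean(list(pis.values())))}
        for cat in CATEGORIES:
            vals = list(by_cat[cat].values())
            spectra[gid][cat] = bin_spectrum(vals, bin_width=bin_width,
                                             label=f"{gid}:{cat}")
            mean_pi[gid][cat] = float(np.mean(vals)) if vals else float("nan")
        partition_spectra[gid] = {
            "core": _subset_spectrum(pis, core, bin_width, f"{gid}:core"),
            "flexible": _subset_spectrum(pis, flex, bin_width, f"{gid}:flexible"),
        }

    comp_a = aa_composition(proteome_a).mole_percent
    comp_b = aa_composition(proteome_b).mole_percent
    delta = {res: comp_a[res] - comp_b[res] for res in comp_a}

    acid_a = acid_neutral_basic(spectra[id_a]["whole"]).acid_fraction
    acid_b = acid_neutral_basic(spectra[id_b]["whole"]).acid_fraction
    higher = id_a if acid_a >= acid_b else id_b

    return PairComparison(
        id_a=id_a, id_b=id_b, aai=aai, n_rbh_pairs=n_rbh, pocp=pocp,
        core_ids_a=core_a, flexible_ids_a=flex_a,
        core_ids_b=core_b, flexible_ids_b=flex_b,
        per_category_spectra=spectra, partition_spectra=partition_spectra,
        composition_delta=delta, mean_pi=mean_pi,
        higher_acid_fraction=higher,
        metadata=dict(metadata or {}),
    )
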