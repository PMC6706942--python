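"""Protein localization: secreted / transmembrane / cytoplasmic.

Two routes produce the same three-way partition:

* ``import_localization`` consumes a TSV of external predictions (e.g. from
  SignalP and Phobius runs) — the fidelity route when annotations exist.
* ``heuristic_localization`` is a deliberately simple, fully deterministic
  hydropathy stand-in so the pipeline runs with no external tools.  It is
  NOT a re-implementation of SignalP/Phobius and is labelled as heuristic
  evidence in every call it emits.

The heuristic scans Kyte–Doolittle hydropathy with a 19-residue window.  A
transmembrane (TM) segment is a run of at least 5 consecutive window
centers whose mean hydropathy reaches the threshold — i.e. a hydrophobic
region spanning at least 23 residues, about the span of a TM helix plus
its flanks; shorter runs are treated as sampling noise.  A
signal peptide needs a positively charged N-region (>= 1 K/R within the
first 5 residues) followed by a hydrophobic h-region (mean hydropathy >=
threshold over >= 8 residues) ending within the first ``sp_max_pos``
residues.  Precedence: any TM segment outside the signal-peptide region
makes the protein transmembrane; otherwise a signal peptide makes it
secreted; otherwise it is cytoplasmic/inner-membrane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

CATEGORIES = ("secreted", "transmembrane", "cytoplasmic")


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    category: str
    evidence: str                 # "imported" | "heuristic"
    n_tm_segments: int
    has_signal_peptide: bool
    flag: str | None = None


def _category(has_sp: bool, n_tm: int) -> str:
    if n_tm >= 1:
        return "transmembrane"
    if has_sp:
        return "secreted"
    return "cytoplasmic"


def _hydropathy(sequence: str) -> np.ndarray:
    # ambiguity codes are hydropathy-neutral
    return np.array([KYTE_DOOLITTLE.get(res, 0.0) for res in sequence])


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Means of every full window; length len(values) - window + 1."""
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return (csum[window:] - csum[:-window]) / window


def _passing_runs(passing: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of runs of True of length >= min_run."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(passing):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(passing) - start >= min_run:
        runs.append((start, len(passing) - 1))
    return runs


def heuristic_localization(record: ProteinRecord, window: int = 19,
                           tm_threshold: float = 1.6, sp_max_pos: int = 35,
                           tm_min_windows: int = 5,
                           sp_h_window: int = 8) -> LocalizationCall:
    """Hydropathy-based localization call (evidence = heuristic)."""
    seq = record.sequence
    if len(seq) < window:
        return LocalizationCall(record.protein_id, "cytoplasmic", "heuristic",
                                0, False, flag="shorter_than_window")
    hydro = _hydropathy(seq)

    means = _window_means(hydro, window)
    # each passing run of window centers is one candidate TM segment;
    # run start i covers residues [i, i + window - 1 + run_length - 1]
    runs = _passing_runs(means >= tm_threshold, tm_min_windows)
    segments = [(start, end + window - 1) for start, end in runs]

    # signal peptide: charged N-region then an early hydrophobic h-region
    has_sp = False
    if any(res in "KR" for res in seq[:5]):
        h_means = _window_means(hydro, sp_h_window)
        # h-region must end before sp_max_pos (0-based residue index)
        last_start = min(len(h_means), sp_max_pos - sp_h_window + 1)
        if last_start > 0 and np.any(h_means[:last_start] >= tm_threshold):
            has_sp = True

    if has_sp:
        # TM segments wholly inside the signal-peptide region are the
        # signal peptide's own h-region, not membrane anchors
        segments = [s for s in segments if s[1] >= sp_max_pos]

    n_tm = len(segments)
    return LocalizationCall(record.protein_id, _category(has_sp, n_tm),
                            "heuristic", n_tm, has_sp)


def import_localization(path: str | Path) -> list[LocalizationCall]:
    """Read external predictions (TSV: protein_id, has_signal_peptide, n_tm_segments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "has_signal_peptide", "n_tm_segments"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        has_sp = str(row.has_signal_peptide).strip().lower() in ("true", "1", "yes")
        n_tm = int(row.n_tm_segments)
        calls.append(LocalizationCall(str(row.protein_id),
                                      _category(has_sp, n_tm),
                                      "imported", n_tm, has_sp))
    return calls


def localize_proteome(records: Sequence[ProteinRecord],
                      imported: Mapping[str, LocalizationCall] | None = None,
                      **heuristic_kwargs) -> dict[str, LocalizationCall]:
    """One call per protein; imported calls take precedence when present."""
    calls: dict[str, LocalizationCall] = {}
    n_fallback = 0
    for rec in records:
        if imported is not None and rec.protein_id in imported:
            calls[rec.protein_id] = imported[rec.protein_id]
        else:
            if imported is not None:
                n_fallback += 1
            calls[rec.protein_id] = heuristic_localization(rec, **heuristic_kwargs)
    if n_fallback:
        logger.warning("%d protein(s) missing from annotations; "
                       "heuristic fallback used", n_fallback)
    return calls
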