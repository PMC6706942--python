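"""Protein FASTA and metadata I/O.

Proteomes are plain (optionally gzipped) protein FASTA files, one file per
proteome or metaproteome; the proteome identity is supplied by the caller
rather than parsed from headers, because header dialects vary wildly across
NCBI, Prokka and MAG pipelines.  Sequences are validated against the 20
standard residues plus the ambiguity codes that occur in MAG-derived protein
predictions (X, B, Z, J, U, O); a single terminal ``*`` (stop) is stripped,
while an internal ``*`` is rejected as a likely pseudogene or frameshift.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "XBZJUO"
_ALLOWED = frozenset(STANDARD_RESIDUES + AMBIGUITY_CODES)

HABITATS = ("freshwater", "brackish", "marine", "halophile")
LOCALIZATIONS = ("secreted", "transmembrane", "cytoplasmic")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its provenance and optional localization."""

    protein_id: str
    proteome_id: str
    sequence: str
    localization: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError(
                f"{self.protein_id}: empty sequence after stripping"
            )
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValidationError(
                f"{self.protein_id}: invalid residue(s) {sorted(bad)!r}; "
                f"allowed are the 20 standard residues plus {AMBIGUITY_CODES}"
            )
        if self.localization is not None and self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"{self.protein_id}: unknown localization {self.localization!r}; "
                f"allowed: {LOCALIZATIONS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteomeMeta:
    """Per-proteome metadata: habitat label and coarse taxon."""

    proteome_id: str
    habitat: str | None = None
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.habitat is not None and self.habitat not in HABITATS:
            raise SchemaError(
                f"{self.proteome_id}: unknown habitat {self.habitat!r}; "
                f"allowed labels: {HABITATS}"
            )


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def clean_sequence(raw: str, protein_id: str = "<seq>") -> str:
    """Uppercase, strip whitespace and a single terminal stop symbol.

    Internal ``*`` raises :class:`ValidationError`.
    """
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise ValidationError(
            f"{protein_id}: internal stop symbol '*' "
            "(likely pseudogene or frameshifted prediction)"
        )
    return seq


def read_proteome(path: str | Path, proteome_id: str) -> list[ProteinRecord]:
    """Read one proteome from (optionally gzipped) protein FASTA.

    Returns one :class:`ProteinRecord` per entry.  Duplicate ids within the
    file are rejected; an empty file yields an empty list with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        # SimpleFastaParser silently skips leading junk; detect it explicitly.
        head = handle.read(1)
        while head and head in "\r\n \t":
            head = handle.read(1)
        if head and head != ">":
            raise FastaParseError(
                f"{path}: not FASTA — first non-blank character is {head!r}, "
                "expected '>'"
            )
        handle.seek(0)
        for title, raw_seq in SimpleFastaParser(handle):
            protein_id = title.split()[0] if title.split() else ""
            if not protein_id:
                raise FastaParseError(f"{path}: FASTA entry with empty header")
            if protein_id in seen:
                raise ValidationError(
                    f"{path}: duplicate protein_id {protein_id!r}"
                )
            seen.add(protein_id)
            try:
                seq = clean_sequence(raw_seq, protein_id)
                records.append(
                    ProteinRecord(protein_id=protein_id,
                                  proteome_id=proteome_id,
                                  sequence=seq)
                )
            except ValidationError as exc:
                raise FastaParseError(f"{path}: entry {protein_id!r}: {exc}") from exc
    if not records:
        logger.warning("%s: no FASTA entries found (empty proteome)", path)
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path,
                   width: int = 60) -> None:
    """Write records as wrapped protein FASTA (gzipped if path ends in .gz)."""
    with (gzip.open(path, "wt", encoding="utf-8")
          if str(path).endswith(".gz")
          else open(path, "wt", encoding="utf-8")) as out:
        for rec in records:
            out.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


def read_metadata(path: str | Path) -> list[ProteomeMeta]:
    """Read the proteome metadata TSV (columns proteome_id, habitat, taxon)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"proteome_id", "habitat", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"expected {sorted(required)}"
        )
    dupes = df["proteome_id"][df["proteome_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicated proteome_id rows: {dupes}")
    metas = []
    for row in df.itertuples(index=False):
        habitat = None if pd.isna(row.habitat) else str(row.habitat)
        taxon = None if pd.isna(row.taxon) else str(row.taxon)
        metas.append(ProteomeMeta(proteome_id=str(row.proteome_id),
                                  habitat=habitat, taxon=taxon))
    return metas


def write_metadata(metas: Sequence[ProteomeMeta], path: str | Path) -> None:
    pd.DataFrame(
        {"proteome_id": [m.proteome_id for m in metas],
         "habitat": [m.habitat for m in metas],
         "taxon": [m.taxon for m in metas]}
    ).to_csv(path, sep="\t", index=False)
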