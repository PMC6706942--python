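"""End-to-end orchestration: cohort analysis and pair reports.

``run_cohort_analysis`` reproduces the cohort workflow — per-proteome pI
spectra, Bray–Curtis distance matrix, one-way PERMANOVA per factor, PCA,
and habitat aggregate statistics — from a single declarative config.
``run_pair_analysis`` produces the two-genome comparison report (AAI,
POCP, core/flexible partition, per-category spectra).

All numeric outputs are a pure function of (config, seed); every written
table carries a provenance header with the package version, the config
hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ValidationError
from .localization import LocalizationCall, import_localization, localize_proteome
from .pi_engine import PKA_SETS, isoelectric_points
from .sequence_io import ProteinRecord, ProteomeMeta, read_metadata, read_proteome
from .spectrum import (PiSpectrum, acid_neutral_basic, bin_spectrum,
                       group_aggregate_stats, spectrum_table)
from .stats import distance_matrix, pca_profiles, permanova
from .comparative import compare_pair

logger = logging.getLogger(__name__)

LOCALIZATION_MODES = ("heuristic", "imported", "merged")


@dataclass(frozen=True)
class RunConfig:
    """Declarative run description (YAML-loadable)."""

    fasta_paths: Mapping[str, str]          # proteome_id -> FASTA path
    metadata_path: str
    output_dir: str
    pka_set: str = "emboss"
    bin_width: float = 0.25
    permanova_factors: tuple[str, ...] = ("habitat",)
    n_permutations: int = 999
    seed: int = 0
    localization_mode: str = "heuristic"
    annotation_paths: Mapping[str, str] = field(default_factory=dict)
    pair_metadata: Mapping[str, float] = field(default_factory=dict)  # e.g. ANI, 16S

    def __post_init__(self) -> None:
        if self.pka_set not in PKA_SETS:
            raise ConfigurationError(
                f"unknown pka_set {self.pka_set!r}; available: {sorted(PKA_SETS)}")
        if self.localization_mode not in LOCALIZATION_MODES:
            raise ConfigurationError(
                f"unknown localization_mode {self.localization_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        raw["permanova_factors"] = tuple(raw.get("permanova_factors", ["habitat"]))
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = [p for p in [*self.fasta_paths.values(), self.metadata_path]
                   if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"missing input path(s): {missing}")

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> str:
    return (f"# piscape {__version__}  config={config.config_hash()}  "
            f"seed={config.seed}\n")


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 index: bool = False) -> None:
    with open(path, "w") as out:
        out.write(_provenance(config))
        df.to_csv(out, sep="\t", index=index, float_format="%.6g")


def _localizations_for(config: RunConfig, proteome_id: str,
                       records: Sequence[ProteinRecord]
                       ) -> dict[str, LocalizationCall]:
    mode = config.localization_mode
    if mode == "heuristic":
        return localize_proteome(records)
    path = config.annotation_paths.get(proteome_id)
    if path is None or not Path(path).exists():
        raise ConfigurationError(
            f"localization_mode={mode!r} but no annotation file for "
            f"{proteome_id!r}; refusing silent heuristic fallback")
    imported = {c.protein_id: c for c in import_localization(path)}
    if mode == "imported":
        missing = [r.protein_id for r in records
                   if r.protein_id not in imported]
        if missing:
            raise ValidationError(
                f"{proteome_id}: {len(missing)} protein(s) missing from "
                f"annotations in imported mode (e.g. {missing[:3]})")
        return {r.protein_id: imported[r.protein_id] for r in records}
    return localize_proteome(records, imported=imported)


def run_cohort_analysis(config: RunConfig) -> dict:
    """Spectra -> Bray-Curtis -> PERMANOVA -> PCA for a proteome cohort."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pka = PKA_SETS[config.pka_set]

    metas = {m.proteome_id: m for m in read_metadata(config.metadata_path)}
    unknown = sorted(set(config.fasta_paths) - set(metas))
    if unknown:
        raise ValidationError(f"proteome(s) without metadata: {unknown}")

    spectra: dict[str, PiSpectrum] = {}
    for pid in sorted(config.fasta_paths):
        records = read_proteome(config.fasta_paths[pid], pid)
        pis = isoelectric_points([r.sequence for r in records], pka)
        spec = bin_spectrum(pis, bin_width=config.bin_width, label=pid)
        spectra[pid] = spec
        _write_table(spectrum_table(spec), outdir / f"spectrum_{pid}.tsv", config)

    ids = sorted(spectra)
    results: dict = {"spectra": spectra, "n_proteomes": len(ids),
                     "seed": config.seed, "config_hash": config.config_hash()}

    aggregates = pd.DataFrame(
        [{"proteome_id": pid,
          "habitat": metas[pid].habitat,
          "taxon": metas[pid].taxon,
          **dataclasses.asdict(acid_neutral_basic(spectra[pid]))}
         for pid in ids])
    _write_table(aggregates, outdir / "aggregates.tsv", config)
    results["aggregates"] = aggregates

    habitats = [metas[pid].habitat for pid in ids]
    if all(h is not None for h in habitats):
        by_habitat = group_aggregate_stats([spectra[p] for p in ids], habitats)
        _write_table(by_habitat, outdir / "aggregate_stats_by_habitat.tsv",
                     config, index=True)
        results["aggregate_stats"] = by_habitat

    if len(ids) < 3:
        logger.warning("only %d proteome(s): distance statistics skipped",
                       len(ids))
        results["statistics_skipped"] = True
    else:
        profiles = np.vstack([spectra[pid].rel_freq for pid in ids])
        dm = distance_matrix(profiles, ids)
        _write_table(pd.DataFrame(dm.d, index=ids, columns=ids),
                     outdir / "bray_curtis.tsv", config, index=True)
        results["distance_matrix"] = dm

        results["permanova"] = {}
        for factor in config.permanova_factors:
            values = [getattr(metas[pid], factor) for pid in ids]
            if any(v is None for v in values):
                logger.warning("factor %r has missing values; skipped", factor)
                continue
            res = permanova(dm, values, config.n_permutations, config.seed)
            results["permanova"][factor] = res
            payload = {**dataclasses.asdict(res), "factor": factor,
                       "piscape_version": __version__,
                       "config_hash": config.config_hash()}
            (outdir / f"permanova_{factor}.json").write_text(
                json.dumps(payload, indent=2) + "\n")

        pca = pca_profiles(profiles, n_components=2)
        scores = pd.DataFrame(pca.scores, index=ids, columns=["PC1", "PC2"])
        scores["habitat"] = [metas[pid].habitat for pid in ids]
        _write_table(scores, outdir / "pca_scores.tsv", config, index=True)
        results["pca"] = pca

    manifest = {"piscape_version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(),
                "n_proteomes": len(ids),
                "statistics_skipped": results.get("statistics_skipped", False)}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results


def run_pair_analysis(config: RunConfig, pair: tuple[str, str]) -> dict:
    """Two-genome comparison bundle for proteome ids present in the manifest."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [pid for pid in pair if pid not in config.fasta_paths]
    if unknown:
        raise ValidationError(f"unknown proteome id(s): {unknown}")
    id_a, id_b = pair
    recs_a = read_proteome(config.fasta_paths[id_a], id_a)
    recs_b = read_proteome(config.fasta_paths[id_b], id_b)
    locs = {**_localizations_for(config, id_a, recs_a),
            **_localizations_for(config, id_b, recs_b)}
    pka = PKA_SETS[config.pka_set]
    comparison = compare_pair(recs_a, recs_b, locs, pka_set=pka,
                              bin_width=config.bin_width,
                              metadata=config.pair_metadata)

    report = {
        "piscape_version": __version__, "seed": config.seed,
        "config_hash": config.config_hash(),
        "proteome_a": id_a, "proteome_b": id_b,
        "aai": comparison.aai, "n_rbh_pairs": comparison.n_rbh_pairs,
        "pocp": comparison.pocp,
        "n_core_a": len(comparison.core_ids_a),
        "n_flexible_a": len(comparison.flexible_ids_a),
        "n_core_b": len(comparison.core_ids_b),
        "n_flexible_b": len(comparison.flexible_ids_b),
        "higher_acid_fraction": comparison.higher_acid_fraction,
        "mean_pi": comparison.mean_pi,
        "composition_delta_molepct": comparison.composition_delta,
        "external_metadata": dict(comparison.metadata),
    }
    (outdir / f"pair_{id_a}_vs_{id_b}.json").write_text(
        json.dumps(report, indent=2, default=float) + "\n")
    for gid, by_cat in comparison.per_category_spectra.items():
        for cat, spec in by_cat.items():
            _write_table(spectrum_table(spec),
                         outdir / f"pair_spectrum_{gid}_{cat}.tsv", config)
    return {"comparison": comparison, "report": report}
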