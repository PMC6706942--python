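"""Binned pI spectra and acid/neutral/basic habitat aggregates.

A proteome's pI spectrum is the relative-frequency histogram of its
per-protein isoelectric points, binned at 0.25 pH units over [2, 14] by
default.  Aggregates follow the three diagnostic ranges used for habitat
comparison — acid 3.25–6.25, neutral 6.75–7.25, basic 7.75–13.75 — with a
bin counted in a range when its center falls inside it (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .sequence_io import HABITATS

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.25
DEFAULT_RANGE = (2.0, 14.0)
ACID_RANGE = (3.25, 6.25)
NEUTRAL_RANGE = (6.75, 7.25)
BASIC_RANGE = (7.75, 13.75)


@dataclass(frozen=True)
class PiSpectrum:
    """Relative-frequency histogram of pI values."""

    bin_edges: np.ndarray        # length n_bins + 1, strictly increasing
    rel_freq: np.ndarray         # length n_bins, sums to 1 when n_proteins > 0
    n_proteins: int
    label: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_pi(self) -> float:
        """Histogram-based mean pI (mass at bin centers)."""
        if self.n_proteins == 0:
            return float("nan")
        return float(np.sum(self.bin_centers * self.rel_freq))


@dataclass(frozen=True)
class HabitatAggregate:
    """Fractions of proteome mass in the acid, neutral and basic pI ranges."""

    acid_fraction: float
    neutral_fraction: float
    basic_fraction: float

    def as_array(self) -> np.ndarray:
        return np.array([self.acid_fraction, self.neutral_fraction,
                         self.basic_fraction])


def bin_spectrum(pis: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH,
                 pi_range: tuple[float, float] = DEFAULT_RANGE,
                 label: str = "") -> PiSpectrum:
    """Bin pI values into half-open bins [lo, hi), last bin closed.

    Values outside the range are clipped into the terminal bins so that
    frequencies always sum to one over all proteins.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be > 0, got {bin_width}")
    lo, hi = pi_range
    n_bins = int(round((hi - lo) / bin_width))
    if n_bins < 1 or abs(lo + n_bins * bin_width - hi) > 1e-9:
        raise ConfigurationError(
            f"bin_width {bin_width} does not tile range {pi_range}"
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    pis = np.asarray(pis, dtype=float)
    if pis.size == 0:
        logger.warning("empty pI list for %r: all-zero spectrum", label)
        return PiSpectrum(edges, np.zeros(n_bins), 0, label)
    clipped = np.clip(pis, lo, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    return PiSpectrum(edges, counts / pis.size, int(pis.size), label)


def _range_mask(centers: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    eps = 1e-9
    return (centers >= rng[0] - eps) & (centers <= rng[1] + eps)


def acid_neutral_basic(spec: PiSpectrum) -> HabitatAggregate:
    """Sum spectrum mass over the acid/neutral/basic diagnostic ranges."""
    centers = spec.bin_centers
    fractions = []
    for rng in (ACID_RANGE, NEUTRAL_RANGE, BASIC_RANGE):
        mask = _range_mask(centers, rng)
        if not mask.any():
            raise ConfigurationError(
                f"no bin centers inside pI range {rng}; "
                "bin layout incompatible with aggregate ranges"
            )
        fractions.append(float(spec.rel_freq[mask].sum()))
    return HabitatAggregate(*fractions)


def group_aggregate_stats(specs: Sequence[PiSpectrum],
                          groups: Sequence[str]) -> pd.DataFrame:
    """Per-habitat mean and SD (ddof=1) of the aggregate components.

    Single-member groups report SD as NaN.
    """
    if len(specs) != len(groups):
        raise ValidationError("specs and groups must have equal length")
    unknown = sorted(set(groups) - set(HABITATS))
    if unknown:
        raise ValidationError(
            f"unknown habitat label(s) {unknown}; allowed: {HABITATS}"
        )
    rows = []
    for spec, grp in zip(specs, groups):
        agg = acid_neutral_basic(spec)
        rows.append({"group": grp, "acid": agg.acid_fraction,
                     "neutral": agg.neutral_fraction,
                     "basic": agg.basic_fraction})
    df = pd.DataFrame(rows)
    out = df.groupby("group").agg(["mean", "std"])
    out.columns = [f"{comp}_{stat}" for comp, stat in out.columns]
    return out


def peak_positions(spec: PiSpectrum, min_separation: float = 1.0,
                   min_rel_height: float = 0.1) -> list[float]:
    """Peaks of the smoothed spectrum, ranked by height.

    The spectrum is smoothed with a 3-bin moving average (zero-padded at
    the edges).  A peak is a plateau of equal smoothed values strictly
    higher than both neighbours (array boundaries count as lower); the
    plateau is reported at the bin holding the most unsmoothed mass, ties
    resolved to the lowest-pH bin.  Peaks closer than ``min_separation``
    to a higher-ranked peak are suppressed, as are sampling wiggles lower
    than ``min_rel_height`` times the highest peak.
    """
    if spec.n_proteins == 0:
        return []
    smoothed = np.convolve(spec.rel_freq, np.ones(3) / 3.0, mode="same")
    centers = spec.bin_centers
    candidates: list[tuple[float, float]] = []  # (height, center)
    i = 0
    n = len(smoothed)
    while i < n:
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1
        left_lower = i == 0 or smoothed[i - 1] < smoothed[i]
        right_lower = j == n - 1 or smoothed[j + 1] < smoothed[i]
        if left_lower and right_lower and smoothed[i] > 0:
            rep = i + int(np.argmax(spec.rel_freq[i:j + 1]))
            candidates.append((float(smoothed[i]), float(centers[rep])))
        i = j + 1
    # rank by height (desc), ties to lower pH; greedy suppression
    candidates.sort(key=lambda hc: (-hc[0], hc[1]))
    if candidates:
        floor = min_rel_height * candidates[0][0]
        candidates = [hc for hc in candidates if hc[0] >= floor]
    kept: list[float] = []
    for _, center in candidates:
        if all(abs(center - k) >= min_separation for k in kept):
            kept.append(center)
    return kept


def merge_spectra(specs: Sequence[PiSpectrum], label: str = "") -> PiSpectrum:
    """Count-weighted pooling of spectra sharing one bin layout."""
    if not specs:
        raise ValidationError("no spectra to merge")
    edges = specs[0].bin_edges
    for s in specs[1:]:
        if not np.array_equal(s.bin_edges, edges):
            raise ConfigurationError("cannot merge spectra with differing bins")
    total = sum(s.n_proteins for s in specs)
    if total == 0:
        return PiSpectrum(edges, np.zeros(len(edges) - 1), 0, label)
    pooled = sum(s.rel_freq * s.n_proteins for s in specs) / total
    return PiSpectrum(edges, pooled, total, label)


def spectrum_table(spec: PiSpectrum) -> pd.DataFrame:
    """One row per bin: lower edge, center, relative frequency."""
    return pd.DataFrame({
        "bin_lo": spec.bin_edges[:-1],
        "bin_center": spec.bin_centers,
        "rel_freq": spec.rel_freq,
    })


def aggregates_by_label(specs: Mapping[str, PiSpectrum]) -> pd.DataFrame:
    rows = []
    for label, spec in specs.items():
        agg = acid_neutral_basic(spec)
        rows.append({"label": label, "n_proteins": spec.n_proteins,
                     "acid_fraction": agg.acid_fraction,
                     "neutral_fraction": agg.neutral_fraction,
                     "basic_fraction": agg.basic_fraction,
                     "mean_pi": spec.mean_pi})
    return pd.DataFrame(rows).set_index("label")
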