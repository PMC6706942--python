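"""Distance-based statistics on pI profiles.

Implements the one-way, distance-based analysis used to separate habitat
from taxonomy effects: Bray–Curtis dissimilarities between per-proteome pI
relative-frequency profiles, one-way PERMANOVA (Anderson's formulation)
with a permutation p-value, a PCA of the profiles, and a nearest-centroid
habitat classifier on the (acid, neutral, basic) aggregate fractions.

PERMANOVA sums of squares, for N objects in a groups with sizes n_g:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within
    pseudo-F  = (SS_among / (a-1)) / (SS_within / (N-a))
    R^2       = SS_among / SS_total

The permutation p-value uses the (1 + b) / (1 + m) estimator, where b
counts permuted pseudo-F values >= the observed one, so it never returns
zero and has resolution 1/(m+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .spectrum import HabitatAggregate, PiSpectrum, acid_neutral_basic


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValidationError("d must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int
    ss_among: float
    ss_within: float
    ss_total: float


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray                    # (n_samples, n_components)
    explained_variance_ratio: np.ndarray  # per retained component
    components: np.ndarray                # (n_components, n_features)


def bray_curtis(p: Sequence[float], q: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity sum|p-q| / sum(p+q); 0 for two zero vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("Bray-Curtis requires non-negative entries")
    denom = float((p + q).sum())
    if denom == 0.0:
        return 0.0
    return float(np.abs(p - q).sum() / denom)


def distance_matrix(profiles: np.ndarray, labels: Sequence[str],
                    standardize: bool = False) -> DistanceMatrix:
    """All pairwise Bray–Curtis distances between profile rows.

    With ``standardize=True`` each row is divided by its total first
    (vegan's "total" standardization).  For profiles that are already
    relative frequencies this is a no-op, which is why the default is no
    extra normalization.
    """
    profiles = np.asarray(profiles, dtype=float)
    if standardize:
        sums = profiles.sum(axis=1, keepdims=True)
        profiles = np.divide(profiles, sums, out=np.zeros_like(profiles),
                             where=sums > 0)
    n = profiles.shape[0]
    if n != len(labels):
        raise ValidationError("profiles and labels must have equal length")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(profiles[i], profiles[j])
    return DistanceMatrix(tuple(labels), d)


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def permanova(dm: DistanceMatrix, groups: Sequence[str],
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA with seeded label permutations."""
    n = len(dm.labels)
    if len(groups) != n:
        raise ValidationError("groups must match distance-matrix labels")
    if n < 3:
        raise ValidationError("PERMANOVA requires at least 3 objects")
    uniq = sorted(set(groups))
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA requires >= 2 groups; "
                              "a single group equal to the whole set is invalid")
    codes = np.array([uniq.index(g) for g in groups])
    d2 = dm.d ** 2

    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, a)
    ss_among = ss_total - ss_within

    with np.errstate(divide="ignore"):
        if ss_within == 0.0:
            f_obs = np.inf
        else:
            f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))
    r_squared = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ssw_p = _ss_within(d2, perm, a)
        if ssw_p == 0.0:
            f_p = np.inf
        else:
            f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs:
            exceed += 1
    p_value = (1.0 + exceed) / (1.0 + n_permutations)

    return PermanovaResult(float(f_obs), float(r_squared), float(p_value),
                           n_permutations, seed, float(ss_among),
                           float(ss_within), float(ss_total))


def pca_profiles(profiles: np.ndarray, n_components: int = 2) -> PcaResult:
    """PCA of column-centered profiles via singular value decomposition.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude loading is
    positive.  Requests beyond the matrix rank are truncated with a
    warning.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 profiles")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(centered.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncated",
                      stacklevel=2)
        n_components = rank
    total_var = float((s ** 2).sum())
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else s[:n_components] * 0
    scores = u[:, :n_components] * s[:n_components]
    comps = vt[:n_components]
    for j in range(n_components):
        k = int(np.argmax(np.abs(comps[j])))
        if comps[j, k] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    return PcaResult(scores, evr, comps)


def classify_habitat(
    profile: PiSpectrum | HabitatAggregate,
    references: Mapping[str, Sequence[HabitatAggregate]],
) -> tuple[str, float]:
    """Nearest-centroid habitat call in (acid, neutral, basic) space.

    Returns the winning label and the margin (distance to runner-up minus
    distance to winner).  Equidistant centroids break ties to the
    lexicographically smaller label with margin 0.
    """
    if not references:
        raise ValidationError("empty reference set")
    agg = acid_neutral_basic(profile) if isinstance(profile, PiSpectrum) else profile
    x = agg.as_array()
    dists = []
    for label in sorted(references):
        exemplars = references[label]
        if not exemplars:
            raise ValidationError(f"no exemplars for label {label!r}")
        centroid = np.mean([e.as_array() for e in exemplars], axis=0)
        dists.append((float(np.linalg.norm(x - centroid)), label))
    dists.sort()  # by distance, then label — encodes the tie-break
    winner_dist, winner = dists[0]
    margin = (dists[1][0] - winner_dist) if len(dists) > 1 else float("inf")
    return winner, margin
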