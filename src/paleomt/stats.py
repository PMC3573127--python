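"""Population-genetic summary statistics for HVR-I haplotype samples.

Implements the 19-variable pooled haplogroup spectrum, Nei's corrected
haplotype diversity, AMOVA-based pairwise F_ST (the Arlequin-style
variance-component estimator), covariance PCA of haplogroup-frequency
matrices, and per-pool genetic distance profiles (Nei's standard distance by
default).
"""

from __future__ import annotations

import math
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplotypes import HvrHaplotype, PopulationSample

__all__ = [
    "POOLED_CLASSES",
    "HaplogroupSpectrum",
    "SummaryStatVector",
    "pooled_class",
    "percent",
    "haplogroup_spectrum",
    "haplotype_class_counts",
    "haplotype_diversity",
    "pairwise_fst",
    "fst_from_class_counts",
    "fst_from_site_counts",
    "PcaResult",
    "pca_spectra",
    "distance_profile",
]

#: The 19 pooled haplogroup variables used in frequency analyses.  'EAS'
#: pools the east-Eurasian haplogroups A, B, E, F, G and Y; 'misc' pools
#: low-frequency Eurasian haplogroups (L, M*, N*, U1, U6, U7, U8, ...).
POOLED_CLASSES = [
    "C", "D", "H", "HV", "I", "J", "K", "N1", "T", "U2", "U4",
    "U5a", "U5b", "V", "W", "X", "Z", "EAS", "misc",
]

_EAS_ROOTS = set("ABEFGY")
_NAMED_PREFIXES = ("U5a", "U5b", "HV", "N1", "U2", "U4")
_SINGLE_LETTER = set("CDHIJKTVWXZ")


def pooled_class(label: str) -> str:
    """Roll a haplogroup label up to its pooled 19-variable class.

    Sub-haplogroups roll up to their major class (C1, C*, C5 -> C; U4a1 ->
    U4; U5a1 -> U5a; Z1a -> Z; ...); east-Eurasian haplogroups pool into
    'EAS' and everything else into 'misc'.
    """
    lab = label.strip().rstrip("*")
    if not lab:
        return "misc"
    for cls in _NAMED_PREFIXES:
        if lab.startswith(cls):
            return cls
    if lab[0] in _EAS_ROOTS:
        return "EAS"
    if lab[0] in _SINGLE_LETTER:
        return lab[0]
    return "misc"


def percent(fraction: float) -> int:
    """Integer percentage with round-half-up, as used for printed frequencies."""
    return int(math.floor(fraction * 100 + 0.5))


@dataclass
class HaplogroupSpectrum:
    """Haplogroup frequencies of one population (pooled or raw labels)."""

    label: str
    freqs: "OrderedDict[str, float]"
    counts: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    n: int = 0

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum frequencies sum to {total}, expected 1")

    def as_array(self, variables: Sequence[str] | None = None) -> np.ndarray:
        names = list(variables) if variables is not None else list(self.freqs)
        return np.array([self.freqs.get(v, 0.0) for v in names])

    def percentages(self) -> "OrderedDict[str, int]":
        return OrderedDict((k, percent(v)) for k, v in self.freqs.items())


def haplogroup_spectrum(
    pop: PopulationSample, pooling: bool = True
) -> HaplogroupSpectrum:
    """Haplogroup frequency spectrum of a population sample.

    With ``pooling`` on, labels roll up to the 19 pooled variables and the
    returned frequency vector is ordered over :data:`POOLED_CLASSES`.
    """
    if pop.n == 0:
        raise ValueError(f"population {pop.label!r} is empty")
    labels = [hg for _, hg in pop.members]
    if pooling:
        counts = Counter(pooled_class(hg) for hg in labels)
        ordered = OrderedDict((c, counts.get(c, 0)) for c in POOLED_CLASSES)
    else:
        counts = Counter(labels)
        ordered = OrderedDict(sorted(counts.items()))
    n = pop.n
    freqs = OrderedDict((k, v / n) for k, v in ordered.items())
    return HaplogroupSpectrum(pop.label, freqs, ordered, n)


# ---------------------------------------------------------------------------
# Haplotype diversity and F_ST
# ---------------------------------------------------------------------------


def haplotype_class_counts(pop: PopulationSample) -> list[int]:
    """Counts of distinct haplotypes (resolved-variant equality)."""
    return sorted(Counter(h.resolved for h in pop.haplotypes).values(), reverse=True)


def haplotype_diversity(
    pop: PopulationSample | Sequence[int], corrected: bool = True
) -> float:
    """Haplotype (gene) diversity h = n/(n-1) * (1 - sum p_i^2).

    ``pop`` may be a population sample or a bare sequence of haplotype-class
    counts.  The uncorrected form 1 - sum p_i^2 is available for n < 2-free
    uses; the corrected (unbiased) form requires n >= 2.
    """
    counts = (
        haplotype_class_counts(pop)
        if isinstance(pop, PopulationSample)
        else [int(c) for c in pop]
    )
    n = sum(counts)
    if n == 0:
        raise ValueError("empty sample")
    sum_p2 = sum(c * c for c in counts) / (n * n)
    if not corrected:
        return 1.0 - sum_p2
    if n < 2:
        raise ValueError("corrected haplotype diversity requires n >= 2")
    return n / (n - 1) * (1.0 - sum_p2)


def _amova_fst_from_sums(
    sw1: float, sw2: float, st: float, n1: float, n2: float
) -> float:
    """Two-level AMOVA F_ST from ordered-pair squared-distance sums.

    ``sw1``/``sw2`` are the within-sample ordered-pair sums, ``st`` the sum
    over all ordered pairs of the combined sample.  When the total variance
    is zero (both samples fixed for one identical haplotype) F_ST is 0.
    """
    N = n1 + n2
    ssd_w = sw1 / (2 * n1) + sw2 / (2 * n2)
    ssd_t = st / (2 * N)
    ssd_a = ssd_t - ssd_w
    msd_a = ssd_a  # / (P - 1) with P = 2
    msd_w = ssd_w / (N - 2)
    n_c = N - (n1 * n1 + n2 * n2) / N  # / (P - 1)
    sigma_a = (msd_a - msd_w) / n_c
    sigma_w = msd_w
    total = sigma_a + sigma_w
    if abs(total) < 1e-15:
        return 0.0
    return sigma_a / total


def fst_from_class_counts(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    d2: np.ndarray | None = None,
) -> float:
    """AMOVA F_ST between two samples given shared haplotype-class counts.

    ``d2`` is the squared inter-class distance matrix; omitted, classes are
    compared 0/1 (haplotype-frequency mode).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the class axis")
    n1, n2 = float(a.sum()), float(b.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("empty population")
    t = a + b
    N = n1 + n2
    if d2 is None:
        sw1 = n1 * n1 - float(a @ a)
        sw2 = n2 * n2 - float(b @ b)
        st = N * N - float(t @ t)
    else:
        d2 = np.asarray(d2, dtype=float)
        sw1 = float(a @ d2 @ a)
        sw2 = float(b @ d2 @ b)
        st = float(t @ d2 @ t)
    return _amova_fst_from_sums(sw1, sw2, st, n1, n2)


def fst_from_site_counts(
    counts_a: np.ndarray, n_a: int, counts_b: np.ndarray, n_b: int
) -> float:
    """Pairwise-difference AMOVA F_ST from per-site base-count matrices.

    The Hamming distance between sequences decomposes per site, so the
    AMOVA sums reduce to sums over (sites x bases) count matrices — O(L)
    instead of O(n^2), which keeps sequence-level F_ST affordable inside
    simulation loops.
    """
    if n_a == 0 or n_b == 0:
        raise ValueError("empty population")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    sw1 = float((n_a * n_a - (a * a).sum(axis=1)).sum())
    sw2 = float((n_b * n_b - (b * b).sum(axis=1)).sum())
    cross = float((n_a * n_b - (a * b).sum(axis=1)).sum())
    st = sw1 + sw2 + 2 * cross
    return _amova_fst_from_sums(sw1, sw2, st, float(n_a), float(n_b))


def _resolved_states(
    hap: HvrHaplotype, lo: int, hi: int
) -> dict[int, str]:
    return {p: b for p, b in hap.resolved if lo <= p <= hi}


def _pairwise_diff(a: HvrHaplotype, b: HvrHaplotype) -> int:
    lo = max(a.range_start, b.range_start)
    hi = min(a.range_end, b.range_end)
    sa = _resolved_states(a, lo, hi)
    sb = _resolved_states(b, lo, hi)
    return sum(
        1 for pos in set(sa) | set(sb) if sa.get(pos) != sb.get(pos)
    )


def pairwise_fst(
    pop_a: PopulationSample,
    pop_b: PopulationSample,
    mode: str = "haplotype_freq",
) -> float:
    """Pairwise AMOVA F_ST between two population samples.

    ``mode`` selects the inter-haplotype distance: ``haplotype_freq`` scores
    any two distinct haplotypes 1 (the cheap form used for simulated data),
    ``pairwise_diff`` uses the count of resolved sequence differences.
    Negative estimates are reported as computed, not clamped.
    """
    if pop_a.n == 0 or pop_b.n == 0:
        raise ValueError("empty population")
    if mode not in ("haplotype_freq", "pairwise_diff"):
        raise ValueError(f"unknown F_ST mode {mode!r}")
    classes: dict[frozenset, int] = {}
    reps: list[HvrHaplotype] = []
    vectors = []
    for pop in (pop_a, pop_b):
        counts = Counter()
        for hap in pop.haplotypes:
            key = hap.resolved
            if key not in classes:
                classes[key] = len(classes)
                reps.append(hap)
            counts[classes[key]] += 1
        vec = np.zeros(len(classes))
        for k, c in counts.items():
            vec[k] = c
        vectors.append(vec)
    k = len(classes)
    va = np.zeros(k)
    vb = np.zeros(k)
    va[: len(vectors[0])] = vectors[0]
    vb[: len(vectors[1])] = vectors[1]
    d2 = None
    if mode == "pairwise_diff":
        d2 = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d2[i, j] = d2[j, i] = _pairwise_diff(reps[i], reps[j])
    return fst_from_class_counts(va, vb, d2)


@dataclass
class SummaryStatVector:
    """Named, ordered summary statistics (diversities and pairwise F_ST)."""

    entries: "OrderedDict[str, float]"

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        keys = list(names) if names is not None else self.names
        return np.array([self.entries[k] for k in keys], dtype=float)


# ---------------------------------------------------------------------------
# PCA of haplogroup-frequency matrices
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """Scores, loadings and variance fractions of a spectrum PCA."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    mean: np.ndarray
    row_labels: list[str]
    variables: list[str]


def _spectra_to_matrix(
    rows: Sequence[HaplogroupSpectrum] | np.ndarray,
) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(rows, np.ndarray):
        x = np.asarray(rows, dtype=float)
        return x, [str(i) for i in range(x.shape[0])], [
            str(j) for j in range(x.shape[1])
        ]
    variables = list(rows[0].freqs)
    for sp in rows[1:]:
        if list(sp.freqs) != variables:
            raise ValueError("spectra carry mismatched variable sets")
    x = np.vstack([sp.as_array(variables) for sp in rows])
    return x, [sp.label for sp in rows], variables


def pca_spectra(
    rows: Sequence[HaplogroupSpectrum] | np.ndarray,
    mode: str = "covariance",
) -> PcaResult:
    """PCA of a populations x haplogroup-frequency matrix.

    Column-centered, unscaled by default (covariance PCA, the behaviour of
    an unscaled ``prcomp``); ``mode='correlation'`` standardises columns.
    Component signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    x, row_labels, variables = _spectra_to_matrix(rows)
    n, p = x.shape
    if n < 3:
        raise ValueError("PCA requires at least 3 rows")
    mean = x.mean(axis=0)
    xc = x - mean
    if mode == "correlation":
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("correlation PCA undefined for zero-variance columns")
        xc = xc / sd
    elif mode != "covariance":
        raise ValueError(f"unknown PCA mode {mode!r}")
    cov = xc.T @ xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("zero-variance matrix")
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = xc @ eigvecs
    return PcaResult(
        scores=scores,
        loadings=eigvecs,
        variance_fractions=eigvals / total,
        mean=mean,
        row_labels=row_labels,
        variables=variables,
    )


# ---------------------------------------------------------------------------
# Genetic distance profiles
# ---------------------------------------------------------------------------


def _nei_distance(x: np.ndarray, y: np.ndarray) -> float:
    jxy = float(x @ y)
    jx = float(x @ x)
    jy = float(y @ y)
    if jxy <= 0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def distance_profile(
    ancient: HaplogroupSpectrum,
    pools: Sequence[HaplogroupSpectrum],
    metric: str = "nei",
) -> "OrderedDict[str, float]":
    """Genetic distance from one spectrum to each of a list of pools.

    Nei's standard genetic distance on haplogroup frequencies by default
    (D = -ln Jxy/sqrt(Jx Jy)); Euclidean distance as an alternative.
    """
    variables = list(ancient.freqs)
    out: "OrderedDict[str, float]" = OrderedDict()
    for pool in pools:
        if list(pool.freqs) != variables:
            raise ValueError(
                f"pool {pool.label!r} carries a mismatched variable set"
            )
        x = ancient.as_array(variables)
        y = pool.as_array(variables)
        if metric == "nei":
            out[pool.label] = _nei_distance(x, y)
        elif metric == "euclidean":
            out[pool.label] = float(np.linalg.norm(x - y))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out
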