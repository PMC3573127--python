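"""Serial (heterochronous) coalescent simulation with HVR-I mutation.

Simulates genealogies of samples taken at different past time points
(modern and ancient populations) under a haploid coalescent: the pairwise
coalescence rate in a deme of effective size Ne(t) is 1/Ne(t) per
generation, with Ne interpreted as the mtDNA gene-copy (haploid) effective
size.  Demes grow exponentially toward the present, anchored so that the
trajectory passes through an ancestral (Palaeolithic) size at a fixed time
in the past, beyond which the size is constant.  Demographic events are
processed backwards in time: a migration pulse moves each sink lineage to
the source deme independently with the stated probability (a mass
migration), and a divergence merges a derived deme into its ancestor.

Mutations are laid onto the genealogy as a Poisson process under a
finite-sites model: 354 sites, per-site gamma rate heterogeneity
(discretised, mean one), and a fixed transition/transversion ratio.
Recurrent and back mutation are permitted, as expected for HVR-I hotspots.
"""

from __future__ import annotations

import math
import random
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .haplotypes import HVR1_START, HvrHaplotype, VariantSite, reference_window
from .stats import (
    SummaryStatVector,
    fst_from_class_counts,
    fst_from_site_counts,
    haplotype_diversity,
)

__all__ = [
    "MutationModel",
    "SampleSpec",
    "DemeSpec",
    "MigrationPulse",
    "Divergence",
    "Genealogy",
    "simulate_genealogy",
    "mutate_sequences",
    "simulate_dataset",
]


@dataclass(frozen=True)
class MutationModel:
    """Finite-sites HVR-I substitution model.

    Defaults: 354 sites (np 16056-16409), 7.5e-6 substitutions/site/
    generation, transition:transversion ratio 0.9841, gamma shape 0.205
    discretised into 10 mean-one rate categories, 25-year generations.
    """

    length: int = 354
    mu: float = 7.5e-6
    titv: float = 0.9841
    gamma_shape: float = 0.205
    n_rate_categories: int = 10
    generation_years: float = 25.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.length <= 0 or self.n_rate_categories <= 0:
            raise ValueError("length and category count must be positive")

    def category_rates(self) -> np.ndarray:
        """Equal-probability discretised gamma rates, normalised to mean 1."""
        k = self.n_rate_categories
        if k == 1 or self.gamma_shape <= 0:
            return np.ones(max(k, 1))
        q = (2 * np.arange(k) + 1) / (2 * k)
        rates = _gamma_dist.ppf(q, a=self.gamma_shape, scale=1 / self.gamma_shape)
        return rates / rates.mean()


@dataclass(frozen=True)
class SampleSpec:
    """``size`` tips entering the process at ``age`` generations ago."""

    age: float
    size: int
    label: str

    def __post_init__(self) -> None:
        if self.age < 0 or self.size <= 0:
            raise ValueError("sample age must be >= 0 and size > 0")


@dataclass(frozen=True)
class DemeSpec:
    """One deme: size trajectory plus heterochronous sampling schedule.

    ``Ne(t) = ne_modern * exp(-growth_rate * t)`` backwards in time until
    ``ancient_time``, constant ``ancient_ne`` beyond.  Use
    :meth:`anchored` to derive the growth rate from a modern size and the
    ancestral anchor, or :meth:`constant` for a flat trajectory.
    """

    label: str
    ne_modern: float
    growth_rate: float = 0.0
    ancient_ne: float | None = None
    ancient_time: float | None = None
    samples: tuple[SampleSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.ne_modern <= 0:
            raise ValueError(f"deme {self.label!r}: non-positive Ne")
        if (self.ancient_ne is None) != (self.ancient_time is None):
            raise ValueError("ancient_ne and ancient_time go together")
        if self.ancient_ne is not None and self.ancient_ne <= 0:
            raise ValueError(f"deme {self.label!r}: non-positive ancestral Ne")

    @classmethod
    def anchored(
        cls,
        label: str,
        ne_modern: float,
        samples: Iterable[SampleSpec] = (),
        ancient_ne: float = 5000.0,
        ancient_time: float = 1500.0,
    ) -> "DemeSpec":
        """Exponential trajectory through (ancient_time, ancient_ne)."""
        rate = math.log(ne_modern / ancient_ne) / ancient_time
        return cls(label, ne_modern, rate, ancient_ne, ancient_time, tuple(samples))

    @classmethod
    def constant(
        cls, label: str, ne: float, samples: Iterable[SampleSpec] = ()
    ) -> "DemeSpec":
        return cls(label, ne, 0.0, samples=tuple(samples))

    # -- segment representation: (start_time, size_at_start, backward_rate) --
    def _segments(self) -> list[tuple[float, float, float]]:
        segs = [(0.0, self.ne_modern, self.growth_rate)]
        if self.ancient_time is not None:
            segs.append((self.ancient_time, float(self.ancient_ne), 0.0))
        return segs

    def size_at(self, t: float) -> float:
        segs = self._segments()
        for start, n0, r in reversed(segs):
            if t >= start:
                return n0 * math.exp(-r * (t - start))
        return segs[0][1]


def _draw_coal_time(
    segs: list[tuple[float, float, float]],
    t0: float,
    k: int,
    rng: random.Random,
) -> float:
    """First coalescence time after t0 among k lineages, or +inf.

    Inverts the cumulative pairwise hazard C(k,2)/Ne(t) across the
    piecewise-exponential size trajectory.
    """
    target = rng.expovariate(1.0)
    pairs = k * (k - 1) / 2.0
    t = t0
    for i, (start, n0, r) in enumerate(segs):
        end = segs[i + 1][0] if i + 1 < len(segs) else math.inf
        if end <= t:
            continue
        a = max(t, start)
        if r == 0.0:
            if math.isinf(end):
                return a + target * n0 / pairs
            hazard = pairs * (end - a) / n0
            if target <= hazard:
                return a + target * n0 / pairs
        else:
            ea = math.exp(r * (a - start))
            eb = math.exp(r * (end - start))
            hazard = pairs * (eb - ea) / (n0 * r)
            if target <= hazard:
                return start + math.log(ea + target * n0 * r / pairs) / r
        target -= hazard
    return math.inf


@dataclass(frozen=True)
class MigrationPulse:
    """Backward-time mass migration: each sink lineage moves to the source
    deme independently with probability ``fraction`` at ``time``."""

    time: float
    sink: str
    source: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("migrant fraction must be in [0, 1]")


@dataclass(frozen=True)
class Divergence:
    """Backward-time merge of ``derived`` into ``ancestral`` at ``time``."""

    time: float
    derived: str
    ancestral: str


@dataclass
class Genealogy:
    """A coalescent tree with aged tips; nodes 0..n_tips-1 are tips."""

    n_tips: int
    times: np.ndarray
    parent: np.ndarray
    children: list[list[int]]
    tip_labels: list[str]
    tip_demes: list[str]

    @property
    def root(self) -> int:
        return int(np.argmax(self.times))

    @property
    def tmrca(self) -> float:
        return float(self.times.max())

    @property
    def total_branch_length(self) -> float:
        mask = self.parent >= 0
        return float(np.sum(self.times[self.parent[mask]] - self.times[mask]))


def simulate_genealogy(
    demes: Sequence[DemeSpec],
    events: Sequence[MigrationPulse | Divergence] = (),
    rng: random.Random | int | None = None,
) -> Genealogy:
    """Simulate one serial-coalescent genealogy.

    Lineages sampled at age ``a`` enter the process at ``a``; between
    demographic events each deme coalesces independently at pairwise rate
    1/Ne(t); events are applied in backward time order.
    """
    if isinstance(rng, int) or rng is None:
        rng = random.Random(rng)
    deme_map = {d.label: d for d in demes}
    if len(deme_map) != len(demes):
        raise ValueError("duplicate deme labels")
    # validate that no sample postdates (in backward time) its deme's merge
    merge_time = {
        ev.derived: ev.time for ev in events if isinstance(ev, Divergence)
    }
    schedule = []
    for d in demes:
        for s in d.samples:
            if d.label in merge_time and s.age >= merge_time[d.label]:
                raise ValueError(
                    f"sample {s.label!r} at age {s.age} enters deme "
                    f"{d.label!r} after its divergence at {merge_time[d.label]}"
                )
            schedule.append((s.age, 0, d.label, s))
    if not schedule:
        raise ValueError("empty sampling schedule")
    for ev in events:
        kind = 1 if isinstance(ev, MigrationPulse) else 2
        for lab in (
            (ev.sink, ev.source) if kind == 1 else (ev.derived, ev.ancestral)
        ):
            if lab not in deme_map:
                raise ValueError(f"event references unknown deme {lab!r}")
        schedule.append((ev.time, kind, "", ev))
    schedule.sort(key=lambda item: (item[0], item[1]))

    segs = {d.label: d._segments() for d in demes}
    lineages: dict[str, list[int]] = {d.label: [] for d in demes}
    times: list[float] = []
    parent: list[int] = []
    children: list[list[int]] = []
    tip_labels: list[str] = []
    tip_demes: list[str] = []

    # tips first: allocate all tip nodes up front in schedule order
    tip_nodes: list[tuple[float, str, list[int]]] = []
    for age, kind, lab, payload in schedule:
        if kind == 0:
            ids = []
            for _ in range(payload.size):
                ids.append(len(times))
                times.append(age)
                parent.append(-1)
                children.append([])
                tip_labels.append(payload.label)
                tip_demes.append(lab)
            tip_nodes.append((age, lab, ids))
    n_tips = len(times)

    queue = schedule
    qi = 0
    tip_i = 0
    t = 0.0
    active = 0
    # Cached per-deme candidate coalescence times.  A candidate stays valid
    # until the deme's lineage count changes: deme intensities are
    # independent inhomogeneous Poisson processes in absolute time.
    cand: dict[str, float] = {lab: math.inf for lab in lineages}

    def _refresh(lab: str, now: float) -> None:
        k = len(lineages[lab])
        cand[lab] = (
            _draw_coal_time(segs[lab], now, k, rng) if k >= 2 else math.inf
        )

    while True:
        next_time = queue[qi][0] if qi < len(queue) else math.inf
        best_deme = None
        best_t = math.inf
        for lab, tc in cand.items():
            if tc < best_t:
                best_t = tc
                best_deme = lab
        if next_time <= best_t:
            if qi >= len(queue):
                if active > 1:
                    raise RuntimeError(
                        "lineages stranded in disconnected demes; add a divergence"
                    )
                break
            age, kind, lab, payload = queue[qi]
            qi += 1
            t = age
            if kind == 0:
                lineages[lab].extend(tip_nodes[tip_i][2])
                tip_i += 1
                active += payload.size
                _refresh(lab, t)
            elif kind == 1:
                sink = lineages[payload.sink]
                keep, moved = [], []
                for node in sink:
                    (moved if rng.random() < payload.fraction else keep).append(
                        node
                    )
                lineages[payload.sink] = keep
                lineages[payload.source].extend(moved)
                _refresh(payload.sink, t)
                _refresh(payload.source, t)
            else:
                lineages[payload.ancestral].extend(lineages[payload.derived])
                del lineages[payload.derived]
                del cand[payload.derived]
                _refresh(payload.ancestral, t)
        else:
            t = best_t
            lin = lineages[best_deme]
            i = rng.randrange(len(lin))
            a = lin[i]
            lin[i] = lin[-1]
            lin.pop()
            j = rng.randrange(len(lin))
            b = lin[j]
            node = len(times)
            times.append(t)
            parent.append(-1)
            children.append([a, b])
            parent[a] = node
            parent[b] = node
            lin[j] = node
            active -= 1
            _refresh(best_deme, t)
        if qi >= len(queue) and active <= 1:
            break

    return Genealogy(
        n_tips=n_tips,
        times=np.array(times),
        parent=np.array(parent, dtype=np.int64),
        children=children,
        tip_labels=tip_labels,
        tip_demes=tip_demes,
    )


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def _reference_indices(length: int) -> np.ndarray:
    ref = reference_window()
    if length == len(ref):
        return np.array([_BASE_IDX[b] for b in ref], dtype=np.int8)
    # shortened models (tests) reuse a prefix of the window
    return np.array([_BASE_IDX[b] for b in ref[:length]], dtype=np.int8)


def _draw_mutations(
    tree: Genealogy, model: MutationModel, nrng: np.random.Generator
) -> tuple[np.ndarray, list, np.ndarray, np.ndarray]:
    """Poisson mutation draws per branch: (offsets, sites, is_ts, tv_pick)."""
    k = model.n_rate_categories
    site_rates = model.category_rates()[
        nrng.integers(0, k, size=model.length)
    ]
    total_rate = model.mu * site_rates.sum()
    n_nodes = len(tree.times)
    blen = np.zeros(n_nodes)
    has_parent = tree.parent >= 0
    blen[has_parent] = (
        tree.times[tree.parent[has_parent]] - tree.times[has_parent]
    )
    counts = nrng.poisson(total_rate * blen)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    m_total = int(offsets[-1])
    if m_total:
        # inverse-CDF site sampling proportional to per-site rates
        cdf = np.cumsum(site_rates)
        sites = np.searchsorted(
            cdf, nrng.random(m_total) * cdf[-1], side="right"
        ).tolist()
        p_ts = model.titv / (1.0 + model.titv)
        is_ts = (nrng.random(m_total) < p_ts).tolist()
        tv_pick = nrng.integers(0, 2, size=m_total).tolist()
    else:
        sites = is_ts = tv_pick = []
    return offsets, sites, is_ts, tv_pick


def _mutate_keys(
    tree: Genealogy,
    model: MutationModel,
    nrng: np.random.Generator,
) -> list[frozenset[tuple[int, int]]]:
    """Per-tip haplotype keys as frozensets of (site, base index) vs root."""
    offsets, sites, is_ts, tv_pick = _draw_mutations(tree, model, nrng)
    ref = _reference_indices(model.length)
    state = ref.copy()
    diff: dict[int, int] = {}
    results: list[frozenset[tuple[int, int]] | None] = [None] * tree.n_tips
    root = tree.root
    stack: list[tuple[int, bool, list[tuple[int, int]] | None]] = [
        (root, False, None)
    ]
    while stack:
        node, done, applied = stack.pop()
        if done:
            for s, old in reversed(applied):  # type: ignore[arg-type]
                state[s] = old
                if old == ref[s]:
                    diff.pop(s, None)
                else:
                    diff[s] = old
            continue
        applied = []
        if node != root:
            for m in range(offsets[node], offsets[node + 1]):
                s = int(sites[m])
                old = int(state[s])
                if is_ts[m]:
                    new = old ^ 2
                else:
                    new = (1 - old % 2) + 2 * int(tv_pick[m])
                applied.append((s, old))
                state[s] = new
                if new == ref[s]:
                    diff.pop(s, None)
                else:
                    diff[s] = new
        if node < tree.n_tips:
            results[node] = frozenset(diff.items())
        stack.append((node, True, applied))
        for child in tree.children[node]:
            stack.append((child, False, None))
    return results  # type: ignore[return-value]


_ZOBRIST: list[list[int]] | None = None


def _zobrist_table(length: int) -> list[list[int]]:
    # fixed-seed 63-bit keys; identity of a variant set is its XOR digest
    global _ZOBRIST
    if _ZOBRIST is None or len(_ZOBRIST) < length:
        z = np.random.default_rng(0x5EED).integers(
            1, 2**63, size=(max(length, 354), 4)
        )
        _ZOBRIST = z.tolist()
    return _ZOBRIST


def _mutate_hash_keys(
    tree: Genealogy,
    model: MutationModel,
    nrng: np.random.Generator,
    collect_diffs: bool = False,
) -> tuple[list[int], list[dict[int, int]] | None]:
    """Per-tip haplotype equivalence keys as XOR digests of the variant set.

    Fast path for summary-statistic simulation: only haplotype identity is
    needed, so each tip is reduced to a 63-bit digest of its (site, base)
    differences from the root (collisions are vanishingly unlikely).  With
    ``collect_diffs`` the sparse per-tip {site: base} difference maps are
    returned too, for per-site statistics.
    """
    offsets, sites, is_ts, tv_pick = _draw_mutations(tree, model, nrng)
    ref = _reference_indices(model.length).tolist()
    state = list(ref)
    zob = _zobrist_table(model.length)
    h = 0
    diff: dict[int, int] = {}
    results = [0] * tree.n_tips
    diffs: list[dict[int, int]] | None = (
        [{}] * tree.n_tips if collect_diffs else None
    )
    root = tree.root
    n_tips = tree.n_tips
    children = tree.children
    stack: list[tuple[int, bool, list | None]] = [(root, False, None)]
    while stack:
        node, done, applied = stack.pop()
        if done:
            for s, old in reversed(applied):  # type: ignore[arg-type]
                cur = state[s]
                r = ref[s]
                if cur != r:
                    h ^= zob[s][cur]
                if old != r:
                    h ^= zob[s][old]
                    diff[s] = old
                else:
                    diff.pop(s, None)
                state[s] = old
            continue
        applied = []
        if node != root:
            for m in range(offsets[node], offsets[node + 1]):
                s = sites[m]
                old = state[s]
                new = old ^ 2 if is_ts[m] else (1 - old % 2) + 2 * tv_pick[m]
                applied.append((s, old))
                r = ref[s]
                if old != r:
                    h ^= zob[s][old]
                if new != r:
                    h ^= zob[s][new]
                    diff[s] = new
                else:
                    diff.pop(s, None)
                state[s] = new
        if node < n_tips:
            results[node] = h
            if diffs is not None and diff:
                diffs[node] = dict(diff)
        stack.append((node, True, applied))
        for child in children[node]:
            stack.append((child, False, None))
    return results, diffs


def mutate_sequences(
    tree: Genealogy,
    model: MutationModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[HvrHaplotype]:
    """Drop mutations on a genealogy; haplotypes as variant sets vs the root.

    Transition or transversion status of each realised variant is recorded
    from the actual base exchange against the reference window.
    """
    if model is None:
        model = MutationModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    keys = _mutate_keys(tree, model, rng)
    ref = _reference_indices(model.length)
    out = []
    for key in keys:
        variants = []
        for site, base in key:
            kind = "transition" if (base ^ int(ref[site])) == 2 else "transversion"
            variants.append(
                VariantSite(HVR1_START + site, _BASES[base], kind)
            )
        out.append(HvrHaplotype(frozenset(variants)))
    return out


# ---------------------------------------------------------------------------
# Simulated summary statistics
# ---------------------------------------------------------------------------


def simulate_dataset(
    demes: Sequence[DemeSpec],
    events: Sequence[MigrationPulse | Divergence] = (),
    model: MutationModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    stat_names: Sequence[str] | None = None,
    fst_mode: str = "pairwise_diff",
) -> SummaryStatVector:
    """One replicate: genealogy + mutations + per-sample summary statistics.

    Tips are grouped by sample label; the statistic vector holds corrected
    haplotype diversity ``h_<label>`` per sample and AMOVA F_ST
    ``fst_<a>_<b>`` per sample pair (labels in schedule order).  F_ST uses
    pairwise sequence differences by default, matching how the observed
    fixation indices are computed from sequence data; ``haplotype_freq``
    scores distinct haplotypes 0/1 instead.  Deterministic given the seed.
    """
    if model is None:
        model = MutationModel()
    if fst_mode not in ("pairwise_diff", "haplotype_freq"):
        raise ValueError(f"unknown F_ST mode {fst_mode!r}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    coal_seed, mut_seed = ss.spawn(2)
    tree = simulate_genealogy(
        demes, events, rng=random.Random(int(coal_seed.generate_state(1)[0]))
    )
    pairwise = fst_mode == "pairwise_diff"
    keys, diffs = _mutate_hash_keys(
        tree, model, np.random.default_rng(mut_seed), collect_diffs=pairwise
    )

    order: list[str] = []
    group_counts: dict[str, Counter] = {}
    group_dev: dict[str, tuple[list[int], list[int]]] = {}
    group_n: Counter = Counter()
    for i, (label, key) in enumerate(zip(tree.tip_labels, keys)):
        if label not in group_counts:
            group_counts[label] = Counter()
            order.append(label)
            if pairwise:
                group_dev[label] = ([], [])
        group_counts[label][key] += 1
        group_n[label] += 1
        if pairwise:
            d = diffs[i]  # type: ignore[index]
            sl, bl = group_dev[label]
            sl.extend(d.keys())
            bl.extend(d.values())

    group_sites: dict[str, np.ndarray] = {}
    if pairwise:
        # per-site base counts: deviations plus the reference-base remainder
        ref = _reference_indices(model.length)
        idx = np.arange(model.length)
        for label in order:
            sl, bl = group_dev[label]
            flat = np.bincount(
                np.array(sl, dtype=np.int64) * 4 + np.array(bl, dtype=np.int64),
                minlength=model.length * 4,
            )
            arr = flat.reshape(model.length, 4).astype(float)
            arr[idx, ref] += group_n[label] - arr.sum(axis=1)
            group_sites[label] = arr

    entries: "OrderedDict[str, float]" = OrderedDict()
    for label in order:
        entries[f"h_{label}"] = haplotype_diversity(
            list(group_counts[label].values())
        )
    for i, la in enumerate(order):
        for lb in order[i + 1 :]:
            if pairwise:
                entries[f"fst_{la}_{lb}"] = fst_from_site_counts(
                    group_sites[la], group_n[la], group_sites[lb], group_n[lb]
                )
            else:
                classes = sorted(
                    set(group_counts[la]) | set(group_counts[lb])
                )
                ca = [group_counts[la].get(c, 0) for c in classes]
                cb = [group_counts[lb].get(c, 0) for c in classes]
                entries[f"fst_{la}_{lb}"] = fst_from_class_counts(ca, cb)
    vec = SummaryStatVector(entries)
    if stat_names is not None:
        missing = [s for s in stat_names if s not in entries]
        if missing:
            raise ValueError(f"model does not produce statistics {missing}")
        vec = SummaryStatVector(
            OrderedDict((s, entries[s]) for s in stat_names)
        )
    return vec
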