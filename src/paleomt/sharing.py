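"""Haplotype sharing between ancient populations and comparative pools.

A comparative pool is a standardised collection of (by default) 500 modern
haplotypes, built by pooling geographically/linguistically related
populations and sub-sampling when the combined size exceeds the target.
Sharing is exact-match only: a pool member counts as shared when its
resolved variant set equals that of at least one distinct ancient haplotype
over the intersection of the sequenced windows.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .haplotypes import HvrHaplotype, PopulationSample, SITE_GROUPS

__all__ = [
    "HaplotypePool",
    "build_pool",
    "percent_shared",
    "shared_between_ancient",
    "dedupe_redundant",
]


@dataclass
class HaplotypePool:
    """A comparative haplotype pool with sub-sampling provenance."""

    label: str
    members: list[HvrHaplotype]
    source_populations: list[str] = field(default_factory=list)
    seed: int | None = None
    subsampled: bool = False

    @property
    def n(self) -> int:
        return len(self.members)


def build_pool(
    populations: Sequence[PopulationSample],
    target_size: int = 500,
    seed: int | None = None,
    label: str | None = None,
) -> HaplotypePool:
    """Pool populations and sub-sample to ``target_size`` without replacement.

    Populations smaller than the target are pooled first; a combined size
    above the target is reduced by uniform sampling without replacement,
    reproducible from the explicit ``seed``.  A combined size below the
    target is an error stating the shortfall.
    """
    if not populations:
        raise ValueError("no populations given")
    combined = [h for pop in populations for h in pop.haplotypes]
    sources = [pop.label for pop in populations]
    if len(combined) < target_size:
        raise ValueError(
            f"combined size {len(combined)} is {target_size - len(combined)} "
            f"short of the target {target_size}"
        )
    subsampled = len(combined) > target_size
    if subsampled:
        if seed is None:
            raise ValueError("sub-sampling requires an explicit seed")
        rng = random.Random(seed)
        combined = rng.sample(combined, target_size)
    return HaplotypePool(
        label=label if label is not None else "+".join(sources),
        members=combined,
        source_populations=sources,
        seed=seed,
        subsampled=subsampled,
    )


def _distinct(haplotypes: Sequence[HvrHaplotype]) -> list[HvrHaplotype]:
    seen = set()
    out = []
    for hap in haplotypes:
        key = hap.resolved
        if key not in seen:
            seen.add(key)
            out.append(hap)
    return out


def percent_shared(ancient: PopulationSample, pool: HaplotypePool) -> float:
    """Percentage of pool members exactly matching any ancient haplotype.

    Matching is against the distinct ancient haplotype set, so duplicated
    ancient haplotypes (possible kin) do not inflate the percentage; the
    divisor is the pool size.
    """
    if pool.n == 0:
        raise ValueError("empty pool")
    if ancient.n == 0:
        raise ValueError("empty ancient population")
    targets = _distinct(ancient.haplotypes)
    hits = sum(1 for m in pool.members if any(m.matches(t) for t in targets))
    return 100.0 * hits / pool.n


def shared_between_ancient(
    pop_a: PopulationSample, pop_b: PopulationSample
) -> float:
    """Percentage of ``pop_b`` members matching any ``pop_a`` haplotype.

    Directional: report both orders for an asymmetric sharing table.
    """
    if pop_a.n == 0 or pop_b.n == 0:
        raise ValueError("empty population")
    targets = _distinct(pop_a.haplotypes)
    hits = sum(1 for h in pop_b.haplotypes if any(h.matches(t) for t in targets))
    return 100.0 * hits / pop_b.n


def dedupe_redundant(pop: PopulationSample) -> PopulationSample:
    """Keep each haplotype once per burial-site group (kinship filtering).

    Identical haplotypes found in more than one individual at a given site
    may reflect maternal kinship and are counted only once.  Sites that are
    pooled for analysis (aUz + aPo) form one group.  Without site labels the
    whole sample is treated as one group.  Idempotent.
    """
    seen: set[tuple[str, frozenset]] = set()
    members: list[tuple[HvrHaplotype, str]] = []
    sites: list[str] | None = [] if pop.sites is not None else None
    for i, (hap, hg) in enumerate(pop.members):
        site = pop.sites[i] if pop.sites is not None else ""
        group = SITE_GROUPS.get(site, site)
        key = (group, hap.resolved)
        if key in seen:
            continue
        seen.add(key)
        members.append((hap, hg))
        if sites is not None:
            sites.append(site)
    return PopulationSample(
        label=pop.label,
        members=members,
        age_generations=pop.age_generations,
        sites=sites,
    )
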