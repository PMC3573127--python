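"""ABC rejection and AIC-based comparison of demographic models.

The model set confronts genetic continuity with migration for the ancient
North East European samples:

* H0 (continuity): a single population grows exponentially from a
  Palaeolithic size of Ne 5,000 at 1,500 generations ago to a modern size
  drawn from a uniform prior; ancient samples are taken from the same deme
  at their archaeological ages.  One free parameter (modern Ne).
* H1 (migration): the modern North East European population (sink) receives
  a pulse of migrants from Central Europe (source); sink and source sizes,
  migration time and divergence time are drawn from uniform priors, and the
  migrant percentage is fixed per model variant (10%, 50% or 75%).  Four
  free parameters.

Each model is fitted by rejection ABC: summary statistics (haplotype
diversities and pairwise F_ST, standardised by the simulated pool's
per-statistic standard deviation) are compared to the observed statistics
by Euclidean distance, the closest fraction of simulations is retained,
posterior point estimates (medians) replace the priors, and a final batch
of simulations at those estimates yields a likelihood estimate — the
fraction of final simulations falling within the stage-1 tolerance — from
which AIC and Akaike weights are computed.
"""

from __future__ import annotations

import csv
import math
import random
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .coalescent import (
    DemeSpec,
    Divergence,
    MigrationPulse,
    MutationModel,
    SampleSpec,
    simulate_dataset,
)
from .stats import SummaryStatVector

__all__ = [
    "DemographicModel",
    "AbcResult",
    "load_observed_stats",
    "observed_for_model",
    "preset_models",
    "abc_reject",
    "estimate_posterior",
    "model_fit",
    "akaike_weights",
    "run_model_comparison",
]

ANCHOR_NE = 5000.0
ANCHOR_TIME = 1500.0


@dataclass
class DemographicModel:
    """A demographic scenario with uniform priors and a sampling schedule."""

    name: str
    priors: "OrderedDict[str, tuple[float, float]]"
    fixed: Mapping[str, float]
    sample_labels: list[str]
    builder: Callable[[Mapping[str, float]], tuple[list[DemeSpec], list]]
    mutation_model: MutationModel = field(default_factory=MutationModel)
    fst_mode: str = "pairwise_diff"

    def __post_init__(self) -> None:
        for pname, (low, high) in self.priors.items():
            if not low < high:
                raise ValueError(
                    f"model {self.name}: prior for {pname!r} not well-ordered"
                )

    @property
    def k(self) -> int:
        """Count of free parameters (AIC penalty)."""
        return len(self.priors)

    @property
    def stat_names(self) -> list[str]:
        labels = self.sample_labels
        names = [f"h_{l}" for l in labels]
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                names.append(f"fst_{la}_{lb}")
        return names

    def draw_params(self, rng: random.Random) -> "OrderedDict[str, float]":
        params = OrderedDict(
            (p, rng.uniform(low, high)) for p, (low, high) in self.priors.items()
        )
        params.update(self.fixed)
        return params

    def simulate(
        self,
        params: Mapping[str, float],
        seed: int | np.random.SeedSequence | None,
    ) -> SummaryStatVector:
        demes, events = self.builder(params)
        return simulate_dataset(
            demes,
            events,
            model=self.mutation_model,
            seed=seed,
            stat_names=self.stat_names,
            fst_mode=self.fst_mode,
        )


# ---------------------------------------------------------------------------
# Observed statistics fixture
# ---------------------------------------------------------------------------


def _fixture(name: str) -> Path:
    return Path(resources.files("paleomt.data").joinpath(name))  # type: ignore[arg-type]


def _load_population_table() -> dict[str, dict[str, float]]:
    table = {}
    with open(_fixture("observed_populations.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["label"]] = {
                "n": int(row["sample_size"]),
                "age_min": float(row["age_min"]),
                "age_max": float(row["age_max"]),
                "h": float(row["haplotype_diversity"]),
            }
    return table


def _load_fst_table() -> dict[frozenset, float]:
    table = {}
    with open(_fixture("observed_fst.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            table[frozenset((row["pop_a"], row["pop_b"]))] = float(row["fst"])
    return table


def load_observed_stats(labels: Sequence[str]) -> SummaryStatVector:
    """Observed diversities and pairwise F_ST for the given populations.

    Values come from the packaged fixture of published population
    statistics; population pairs without a published F_ST are omitted.
    """
    pops = _load_population_table()
    fsts = _load_fst_table()
    entries: "OrderedDict[str, float]" = OrderedDict()
    for lab in labels:
        if lab not in pops:
            raise KeyError(f"no observed statistics for population {lab!r}")
        entries[f"h_{lab}"] = pops[lab]["h"]
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            key = frozenset((la, lb))
            if key in fsts:
                entries[f"fst_{la}_{lb}"] = fsts[key]
    return SummaryStatVector(entries)


def observed_for_model(model: DemographicModel) -> SummaryStatVector:
    """All applicable observed statistics for a model's sampled populations."""
    return load_observed_stats(model.sample_labels)


# ---------------------------------------------------------------------------
# Model presets
# ---------------------------------------------------------------------------


def _sample_specs(label: str, pops: Mapping[str, Mapping[str, float]]) -> list[SampleSpec]:
    info = pops[label]
    n = int(info["n"])
    lo, hi = info["age_min"], info["age_max"]
    if lo == hi:
        return [SampleSpec(lo, n, label)]
    # heterochronous series: tips spread evenly across the age range
    ages = np.linspace(lo, hi, n)
    return [SampleSpec(float(a), 1, label) for a in ages]


def _continuity_model(
    name: str,
    deme_label: str,
    sample_pops: Sequence[str],
    ne_prior: tuple[float, float],
    include_modern: bool,
) -> DemographicModel:
    pops = _load_population_table()
    specs: list[SampleSpec] = []
    labels: list[str] = []
    if include_modern:
        specs += _sample_specs(deme_label, pops)
        labels.append(deme_label)
    for lab in sample_pops:
        specs += _sample_specs(lab, pops)
        labels.append(lab)
    specs.sort(key=lambda s: s.age)
    labels.sort(key=lambda l: min(s.age for s in specs if s.label == l))

    def build(params: Mapping[str, float]):
        deme = DemeSpec.anchored(
            deme_label,
            params["ne_modern"],
            samples=specs,
            ancient_ne=ANCHOR_NE,
            ancient_time=ANCHOR_TIME,
        )
        return [deme], []

    return DemographicModel(
        name=name,
        priors=OrderedDict(ne_modern=ne_prior),
        fixed={},
        sample_labels=labels,
        builder=build,
    )


def _migration_model(
    name: str, ancient_label: str, migrant_fraction: float
) -> DemographicModel:
    pops = _load_population_table()
    sink_specs = _sample_specs("NEE", pops) + _sample_specs(ancient_label, pops)
    source_specs = _sample_specs("CE", pops)

    def build(params: Mapping[str, float]):
        sink = DemeSpec.anchored(
            "NEE",
            params["ne_sink"],
            samples=sink_specs,
            ancient_ne=ANCHOR_NE,
            ancient_time=ANCHOR_TIME,
        )
        source = DemeSpec.anchored(
            "CE",
            params["ne_source"],
            samples=source_specs,
            ancient_ne=ANCHOR_NE,
            ancient_time=ANCHOR_TIME,
        )
        events = [
            MigrationPulse(
                params["t_migration"], "NEE", "CE", params["migrant_fraction"]
            ),
            Divergence(params["t_divergence"], "CE", "NEE"),
        ]
        return [sink, source], events

    return DemographicModel(
        name=name,
        priors=OrderedDict(
            ne_sink=(1e5, 1.5e7),
            ne_source=(1e5, 1.5e7),
            t_migration=(2.0, 139.0),
            t_divergence=(620.0, 2600.0),
        ),
        fixed={"migrant_fraction": migrant_fraction},
        sample_labels=["NEE", "CE", ancient_label],
        builder=build,
    )


def preset_models() -> "OrderedDict[str, DemographicModel]":
    """The configured continuity (H0a-H0e) and migration (H1) presets.

    H1 variants are named ``H1a`` (aUzPo) and ``H1b`` (aBOO) with the
    migrant percentage as suffix, e.g. ``H1a-10``.
    """
    nee_prior = (1e5, 3e7)
    saa_prior = (1e3, 5e5)
    models = [
        _continuity_model("H0a", "NEE", ["aUzPo"], nee_prior, True),
        _continuity_model("H0b", "NEE", ["aBOO"], nee_prior, True),
        _continuity_model("H0c", "saa", ["aUzPo"], saa_prior, True),
        _continuity_model("H0d", "NEE", ["aHG", "aUzPo", "aPWC"], nee_prior, False),
        _continuity_model("H0e", "NEE", ["aHG", "aBOO", "aPWC"], nee_prior, False),
    ]
    for ancient, tag in (("aUzPo", "H1a"), ("aBOO", "H1b")):
        for pct in (10, 50, 75):
            models.append(
                _migration_model(f"{tag}-{pct}", ancient, pct / 100.0)
            )
    return OrderedDict((m.name, m) for m in models)


# ---------------------------------------------------------------------------
# Rejection, posterior, AIC
# ---------------------------------------------------------------------------


@dataclass
class AbcResult:
    """Outcome of the ABC pipeline for one demographic model."""

    model_name: str
    k: int
    n_sims: int
    stat_names: list[str]
    scale: np.ndarray
    retained_params: dict[str, np.ndarray]
    retained_distances: np.ndarray
    tolerance: float
    point_estimates: "OrderedDict[str, float]" = field(default_factory=OrderedDict)
    n_final: int = 0
    likelihood: float = float("nan")
    log_likelihood: float = float("nan")
    aic: float = float("nan")
    akaike_weight: float = float("nan")

    def summary(self) -> dict:
        return {
            "model": self.model_name,
            "k": self.k,
            "n_sims": self.n_sims,
            "tolerance": self.tolerance,
            "point_estimates": dict(self.point_estimates),
            "n_final": self.n_final,
            "likelihood": self.likelihood,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "akaike_weight": self.akaike_weight,
        }


def _standardised_distances(
    observed: SummaryStatVector,
    stats: np.ndarray,
    names: Sequence[str],
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    obs = observed.as_array(names)
    if scale is None:
        scale = stats.std(axis=0, ddof=0)
    keep = scale > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(
            f"statistic(s) {dropped} have zero simulated variance and were "
            "dropped from the ABC distance"
        )
    names = [n for n, k in zip(names, keep) if k]
    z = (stats[:, keep] - obs[keep]) / scale[keep]
    return np.sqrt((z * z).sum(axis=1)), scale, names


def abc_reject(
    observed: SummaryStatVector,
    sims: Sequence[tuple[Mapping[str, float], SummaryStatVector]],
    fraction: float = 0.01,
    model: DemographicModel | None = None,
) -> AbcResult:
    """Stage-1 rejection: retain the closest fraction of simulations.

    Distances are Euclidean over statistics standardised by the simulated
    pool's per-statistic standard deviation (diversities and F_ST live on
    different scales).  The recorded tolerance is the largest retained
    distance.
    """
    if len(sims) < 100:
        raise ValueError("rejection requires at least 100 simulations")
    names = list(observed.names)
    for _, vec in sims[:1]:
        if set(names) - set(vec.names):
            raise ValueError(
                "simulated statistics do not cover the observed vector"
            )
    stats = np.vstack([vec.as_array(names) for _, vec in sims])
    dists, scale, _ = _standardised_distances(observed, stats, names)
    n_keep = math.ceil(fraction * len(sims))
    order = np.argsort(dists, kind="stable")[:n_keep]
    param_names = list(sims[0][0])
    retained = {
        p: np.array([sims[i][0][p] for i in order]) for p in param_names
    }
    return AbcResult(
        model_name=model.name if model is not None else "",
        k=model.k if model is not None else 0,
        n_sims=len(sims),
        stat_names=names,
        scale=scale,
        retained_params=retained,
        retained_distances=dists[order],
        tolerance=float(dists[order[-1]]),
    )


def estimate_posterior(
    retained: Mapping[str, np.ndarray], method: str = "median"
) -> "OrderedDict[str, float]":
    """Posterior point estimates from retained draws (median by default).

    ``method='mode'`` uses a Gaussian KDE argmax, useful when the posterior
    is strongly skewed against a prior bound.
    """
    if not retained or any(len(v) == 0 for v in retained.values()):
        raise ValueError("empty retained set")
    out: "OrderedDict[str, float]" = OrderedDict()
    for name, draws in retained.items():
        draws = np.asarray(draws, dtype=float)
        if method == "median":
            out[name] = float(np.median(draws))
        elif method == "mode":
            if np.ptp(draws) == 0:
                out[name] = float(draws[0])
            else:
                from scipy.stats import gaussian_kde

                grid = np.linspace(draws.min(), draws.max(), 512)
                out[name] = float(grid[np.argmax(gaussian_kde(draws)(grid))])
        else:
            raise ValueError(f"unknown point-estimate method {method!r}")
    return out


def model_fit(
    model: DemographicModel,
    result: AbcResult,
    observed: SummaryStatVector,
    n_final: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    progress: bool = False,
    likelihood: str = "gaussian",
) -> AbcResult:
    """Final goodness-of-fit stage: likelihood estimate and AIC.

    Runs ``n_final`` simulations at the posterior point estimates and
    estimates the likelihood of the observed statistic vector under the
    model, with AIC = -2 ln L + 2k.  Two estimators are offered:

    * ``gaussian`` (default): the observed vector's density under a
      multivariate normal fitted (diagonal covariance) to the final
      simulated statistics.  This resolves likelihoods far into the tails,
      which is where heavily drifted observed statistics typically fall,
      and produces AIC magnitudes comparable across models.
    * ``fraction``: the fraction of final simulations whose
      stage-1-standardised distance falls within the stage-1 tolerance,
      floored at 1/(n_final + 1).  Coarse but assumption-free.
    """
    if n_final < 100:
        raise ValueError("n_final must be at least 100")
    if likelihood not in ("gaussian", "fraction"):
        raise ValueError(f"unknown likelihood estimator {likelihood!r}")
    if not result.point_estimates:
        result.point_estimates = estimate_posterior(result.retained_params)
    params = dict(model.fixed)
    params.update(result.point_estimates)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    names = result.stat_names
    sim_seeds = ss.spawn(n_final)
    iterator = range(n_final)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=f"{model.name} final", leave=False)
    stats = np.empty((n_final, len(names)))
    for i in iterator:
        vec = model.simulate(params, sim_seeds[i])
        stats[i] = vec.as_array(names)
    obs = observed.as_array(names)
    result.n_final = n_final
    if likelihood == "fraction":
        keep = result.scale > 0
        z = (stats[:, keep] - obs[keep]) / result.scale[keep]
        dists = np.sqrt((z * z).sum(axis=1))
        hits = int((dists <= result.tolerance).sum())
        lhat = max(hits / n_final, 1.0 / (n_final + 1))
        result.likelihood = lhat
        result.log_likelihood = math.log(lhat)
    else:
        result.log_likelihood = _gaussian_log_density(stats, obs)
        result.likelihood = (
            math.exp(result.log_likelihood)
            if result.log_likelihood > -700
            else 0.0
        )
    result.aic = -2.0 * result.log_likelihood + 2.0 * result.k
    return result


def _gaussian_log_density(stats: np.ndarray, obs: np.ndarray) -> float:
    """Log density of ``obs`` under a normal fitted to simulated statistics.

    Full covariance (simulated diversities and F_ST are strongly
    correlated), lightly ridge-regularised; falls back to independent
    normals if the covariance is numerically unusable.
    """
    mu = stats.mean(axis=0)
    if stats.shape[1] == 1:
        sd = max(float(stats.std(ddof=1)), 1e-12)
        z = (float(obs[0]) - float(mu[0])) / sd
        return -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * z * z
    cov = np.cov(stats.T)
    ridge = 1e-8 * float(np.trace(cov)) / cov.shape[0] + 1e-20
    cov = cov + ridge * np.eye(cov.shape[0])
    try:
        from scipy.stats import multivariate_normal

        return float(multivariate_normal(mean=mu, cov=cov).logpdf(obs))
    except (np.linalg.LinAlgError, ValueError):
        sd = np.maximum(stats.std(axis=0, ddof=1), 1e-12)
        return float(
            np.sum(
                -0.5 * math.log(2 * math.pi)
                - np.log(sd)
                - 0.5 * ((obs - mu) / sd) ** 2
            )
        )


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    if len(aics) == 0:
        raise ValueError("no AIC values given")
    a = np.asarray(aics, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def run_model_comparison(
    models: Sequence[DemographicModel],
    observed: SummaryStatVector | None = None,
    n_sims: int = 100_000,
    fraction: float = 0.01,
    n_final: int = 10_000,
    seed: int | None = None,
    progress: bool = False,
    likelihood: str = "gaussian",
) -> list[AbcResult]:
    """Full ABC pipeline per model; results ranked by Akaike weight.

    ``observed=None`` uses each model's applicable published statistics.
    Deterministic given the seed.
    """
    ss = np.random.SeedSequence(seed)
    model_seeds = ss.spawn(len(models))
    results: list[AbcResult] = []
    for model, mss in zip(models, model_seeds):
        if observed is None:
            obs = observed_for_model(model)
        else:
            # restrict to the statistics this model produces
            produced = set(model.stat_names)
            obs = SummaryStatVector(
                OrderedDict(
                    (k, v)
                    for k, v in observed.entries.items()
                    if k in produced
                )
            )
            if not obs.entries:
                raise ValueError(
                    f"model {model.name} shares no statistics with the "
                    "observed vector"
                )
        prior_ss, final_ss = mss.spawn(2)
        prng = random.Random(int(prior_ss.generate_state(1)[0]))
        sim_seeds = prior_ss.spawn(n_sims)
        iterator = range(n_sims)
        if progress:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=f"{model.name} prior", leave=False)
        sims = []
        for i in iterator:
            params = model.draw_params(prng)
            sims.append((params, model.simulate(params, sim_seeds[i])))
        result = abc_reject(obs, sims, fraction=fraction, model=model)
        result.point_estimates = estimate_posterior(result.retained_params)
        model_fit(
            model,
            result,
            obs,
            n_final=n_final,
            seed=final_ss,
            progress=progress,
            likelihood=likelihood,
        )
        results.append(result)
    weights = akaike_weights([r.aic for r in results])
    for r, w in zip(results, weights):
        r.akaike_weight = float(w)
    results.sort(key=lambda r: r.akaike_weight, reverse=True)
    return results
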