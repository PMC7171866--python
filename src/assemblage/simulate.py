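"""Synthetic metacommunities with known assembly regime.

The generator produces the statistical structure the inference machinery
assumes, with a known ground truth:

* a pure-birth (Yule) phylogeny of the regional species pool, scaled to
  unit depth;
* niche optima evolved along that tree by Brownian motion, so habitat
  preferences carry phylogenetic signal by construction;
* stations laid out on a 1-D transect (a cruise track) with an
  environmental gradient (linear, two-level step, or constant, plus noise);
* Gaussian environmental filtering of tunable strength acting on a
  log-series regional pool;
* exponentially distance-decaying immigration from each taxon's home
  station (finite dispersal length), or a well-mixed pool (infinite);
* local ecological drift: expected local relative abundances are perturbed
  by Sloan-style neutral sampling — a Dirichlet draw whose concentration is
  the effective number of immigrating individuals ``immigration`` (small
  values mean local abundances wander far from their expectation,
  ``math.inf`` disables drift);
* one multinomial draw of ``community_size`` individuals per station
  (sequencing/sampling noise).

Sampling weight of taxon ``i`` at station ``k``::

    weight = pool_i * exp(-d(k, home_i) / dispersal_length)
                    * exp(-selection * (E_k - mu_i)^2 / (2 * niche_breadth^2))

with the dispersal factor equal to 1 when ``dispersal_length`` is infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
import skbio

from .table import OtuTable, SampleMetadata
from ._utils import spawn_rngs

EARTH_KM_PER_DEGREE = 111.195  # mean great-circle km per degree at the equator


@dataclass
class SimulationConfig:
    """Knobs of the metacommunity generator.

    Units: ``sigma_bm`` is trait units per sqrt(unit branch length);
    ``niche_breadth`` and the environmental gradient share trait units
    (degrees C for the default temperature-like gradient);
    ``dispersal_length`` and ``station_spacing_km`` are km;
    ``community_size`` is individuals (reads) per station.
    """

    n_taxa: int = 300
    n_stations: int = 20
    birth_rate: float = 1.0
    sigma_bm: float = 5.0
    root_trait: float = 22.5
    niche_breadth: float = 3.0
    selection: float = 0.0
    dispersal_length: float = math.inf
    immigration: float = 1000.0
    community_size: int = 10_000
    station_spacing_km: float = 500.0
    coords: np.ndarray | None = None          # optional explicit (lat, lon) pairs
    gradient: str = "linear"                   # linear | step | constant
    env_range: tuple[float, float] = (15.0, 30.0)
    env_noise_sd: float = 0.25
    pool: str = "logseries"                    # logseries | uniform
    logseries_p: float = 0.9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        if self.community_size < 1:
            raise ValueError("community_size must be >= 1")
        if not (self.dispersal_length > 0):
            raise ValueError("dispersal_length must be > 0 (math.inf = unlimited)")
        if not (self.immigration > 0):
            raise ValueError("immigration must be > 0 (math.inf = no local drift)")
        for name in ("birth_rate", "sigma_bm", "niche_breadth", "selection"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gradient not in ("linear", "step", "constant"):
            raise ValueError(f"unknown gradient {self.gradient!r}")


@dataclass
class GroundTruth:
    """What the generator actually did: the quantities inference should recover."""

    niche_optima: pd.Series          # per taxon, trait units
    environment: pd.Series           # per station, trait units
    pool_abundance: pd.Series        # per taxon, relative abundance of the pool
    home_station: pd.Series | None   # per taxon, only under finite dispersal
    regime: str                      # drift | homogeneous_selection |
                                     # heterogeneous_selection | dispersal_limitation | mixed

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "niche_optimum": self.niche_optima,
            "pool_abundance": self.pool_abundance,
        })
        if self.home_station is not None:
            df["home_station"] = self.home_station
        return df


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int | None = None,
                  birth_rate: float = 1.0) -> skbio.TreeNode:
    """Pure-birth ultrametric tree with ``n_taxa`` tips, scaled to unit depth."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = skbio.TreeNode(name=None, length=0.0)
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = skbio.TreeNode(length=0.0)
            birth_time[id(child)] = t
            parent.append(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))  # terminal stem
    for node in root.traverse(include_self=False):
        end = birth_time.get(id(node.children[0])) if node.children else t
        node.length = end - birth_time[id(node)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i + 1:04d}"
    # scale to unit root-to-tip depth
    depth = next(root.tips()).accumulate_to_ancestor(root)
    for node in root.traverse(include_self=False):
        node.length /= depth
    root.length = 0.0
    return root


def evolve_niche(tree: skbio.TreeNode, sigma: float, root_value: float = 0.0,
                 seed: int | None = None) -> pd.Series:
    """Brownian-motion trait evolution: child = parent + N(0, sigma^2 * length)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    values = {id(tree): root_value}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, sigma * math.sqrt(node.length)) if node.length > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
    tips = {t.name: values[id(t)] for t in tree.tips()}
    return pd.Series(tips, name="niche_optimum")


# ---------------------------------------------------------------------------
# Stations and assembly
# ---------------------------------------------------------------------------

def _station_layout(config: SimulationConfig) -> pd.DataFrame:
    n = config.n_stations
    ids = [f"S{i + 1:03d}" for i in range(n)]
    if config.coords is not None:
        coords = np.asarray(config.coords, dtype=float)
        lat, lon = coords[:, 0], coords[:, 1]
    else:
        lat = np.zeros(n)
        lon = np.arange(n) * config.station_spacing_km / EARTH_KM_PER_DEGREE
        lon = lon - lon.mean()  # keep the transect within valid longitudes
    return pd.DataFrame({"latitude": lat, "longitude": lon,
                         "cruise_order": np.arange(1, n + 1)}, index=ids)


def _environment(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.env_range
    n = config.n_stations
    if config.gradient == "linear":
        base = np.linspace(lo, hi, n)
    elif config.gradient == "step":
        base = np.where(np.arange(n) < n // 2, lo, hi).astype(float)
    else:
        base = np.full(n, (lo + hi) / 2.0)
    return base + rng.normal(0.0, config.env_noise_sd, size=n)


def _pool_abundances(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.pool == "uniform":
        raw = np.ones(config.n_taxa)
    else:
        raw = scipy.stats.logser.rvs(config.logseries_p, size=config.n_taxa,
                                     random_state=rng).astype(float)
    return raw / raw.sum()


class AssemblyError(RuntimeError):
    pass


def assemble_communities(tree: skbio.TreeNode, truth: GroundTruth,
                         config: SimulationConfig,
                         seed: int | None = None) -> tuple[OtuTable, SampleMetadata]:
    """Draw one multinomial community per station from the fitness/dispersal kernel."""
    stations = _station_layout(config)
    taxa = list(truth.niche_optima.index)
    mu = truth.niche_optima.to_numpy()
    env = truth.environment.to_numpy()
    pool = truth.pool_abundance.to_numpy()
    n_st, n_tx = config.n_stations, len(taxa)

    # immigration kernel
    if math.isinf(config.dispersal_length):
        m = np.ones((n_st, n_tx))
    else:
        pos_km = stations["longitude"].to_numpy() * EARTH_KM_PER_DEGREE
        home_pos = pos_km[truth.home_station.to_numpy()]
        d = np.abs(pos_km[:, None] - home_pos[None, :])
        m = np.exp(-d / config.dispersal_length)

    tau2 = 2.0 * config.niche_breadth ** 2
    fitness = np.exp(-config.selection * (env[:, None] - mu[None, :]) ** 2 / tau2)
    weights = pool[None, :] * m * fitness

    rngs = spawn_rngs(seed, n_st)
    counts = np.zeros((n_st, n_tx), dtype=np.int64)
    for k in range(n_st):
        total = weights[k].sum()
        if total <= 0 or not np.isfinite(total):
            raise AssemblyError(
                f"all sampling weights vanish at station {stations.index[k]} "
                "(niche breadth too small for the environment)"
            )
        p = weights[k] / total
        if math.isfinite(config.immigration):
            # Sloan-style neutral sampling: finite immigration lets local
            # relative abundances drift around the expectation, with
            # var(p_i) ~ p_i (1 - p_i) / (I + 1).
            gamma = rngs[k].gamma(np.maximum(config.immigration * p, 1e-300))
            if gamma.sum() <= 0:
                raise AssemblyError(f"drift underflow at station {stations.index[k]}")
            p = gamma / gamma.sum()
        counts[k] = rngs[k].multinomial(config.community_size, p)

    table = OtuTable(list(stations.index), taxa, counts)
    meta = _default_metadata(stations, env, seed)
    return table, meta


def _default_metadata(stations: pd.DataFrame, env: np.ndarray,
                      seed) -> SampleMetadata:
    """Environmental covariates around the simulated temperature-like driver.

    Salinity, conductivity and oxygen covary with temperature (as they do in
    surface-ocean CTD casts); fluorescence is independent noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0xE07, abs(hash(seed)) % (2**31)])
                                if seed is not None else None)
    n = len(stations)
    df = stations.copy()
    df["temperature"] = env
    df["salinity"] = 35.0 + 0.08 * (env - env.mean()) + rng.normal(0, 0.1, n)
    df["conductivity"] = 4.0 + 0.1 * (env - env.mean()) + rng.normal(0, 0.05, n)
    df["fluorescence"] = np.abs(rng.normal(0.3, 0.1, n))
    df["oxygen"] = 6.0 - 0.05 * (env - env.mean()) + rng.normal(0, 0.1, n)
    half = n // 2
    df["basin"] = ["West" if i < half else "East" for i in range(n)]
    q = max(1, n // 4)
    df["province"] = [f"P{min(i // q + 1, 4)}" for i in range(n)]
    return SampleMetadata(df,
                          env_vars=["temperature", "salinity", "conductivity",
                                    "fluorescence", "oxygen"],
                          group_vars=["basin", "province"])


# ---------------------------------------------------------------------------
# End-to-end simulation and regime presets
# ---------------------------------------------------------------------------

def simulate_metacommunity(config: SimulationConfig,
                           regime_label: str = "mixed"
                           ) -> tuple[OtuTable, skbio.TreeNode, SampleMetadata, GroundTruth]:
    """Run the full generator: tree, niches, environment, communities."""
    seeds = np.random.SeedSequence(config.seed).generate_state(5) % (2 ** 31)
    tree = simulate_tree(config.n_taxa, seed=int(seeds[0]), birth_rate=config.birth_rate)
    niches = evolve_niche(tree, config.sigma_bm, config.root_trait, seed=int(seeds[1]))
    rng_env = np.random.default_rng(int(seeds[2]))
    stations = _station_layout(config)
    env = pd.Series(_environment(config, rng_env), index=stations.index, name="environment")
    pool = pd.Series(_pool_abundances(config, rng_env), index=niches.index,
                     name="pool_abundance")
    if math.isinf(config.dispersal_length):
        homes = None
    else:
        homes = pd.Series(
            np.random.default_rng(int(seeds[3])).integers(0, config.n_stations,
                                                          size=config.n_taxa),
            index=niches.index, name="home_station")
    truth = GroundTruth(niches, env, pool, homes, regime_label)
    table, meta = assemble_communities(tree, truth, config, seed=int(seeds[4]))
    return table, tree, meta, truth


REGIMES = ("drift", "homogeneous_selection", "heterogeneous_selection",
           "dispersal_limitation")


def regime_config(regime: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Preset configurations whose expected dominant assembly process is known.

    * ``drift`` - neutral, well-mixed: no selection, unlimited dispersal.
    * ``homogeneous_selection`` - strong narrow filtering, spatially uniform
      environment: communities converge on the same clade.
    * ``heterogeneous_selection`` - the same strong filtering on a steep
      linear gradient: different stations select different clades.
    * ``dispersal_limitation`` - neutral filtering but immigration decays
      on the scale of one station spacing.
    """
    base = dict(seed=seed)
    if regime == "drift":
        base.update(selection=0.0, dispersal_length=math.inf, immigration=1000.0)
    elif regime == "homogeneous_selection":
        # a uniform environment with strong filtering; local drift is the
        # source of the (phylogenetically constrained) compositional turnover
        base.update(selection=20.0, niche_breadth=2.0, gradient="constant",
                    env_noise_sd=0.0, dispersal_length=math.inf, immigration=100.0)
    elif regime == "heterogeneous_selection":
        base.update(selection=20.0, niche_breadth=2.0, gradient="linear",
                    dispersal_length=math.inf, immigration=1000.0)
    elif regime == "dispersal_limitation":
        base.update(selection=0.0, dispersal_length=500.0, immigration=1000.0)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    base.update(overrides)
    return SimulationConfig(**base)


def simulate_regime(regime: str, seed: int = 0, **overrides):
    config = regime_config(regime, seed=seed, **overrides)
    return simulate_metacommunity(config, regime_label=regime)
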