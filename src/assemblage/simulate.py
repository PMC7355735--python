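"""Synthetic metacommunities with known assembly processes.

This module emulates a paired DNA/RNA soil chronosequence: a Yule
phylogeny carries a Brownian-motion niche trait (so close relatives have
similar optima — the phylogenetic signal that licenses βNTI inference),
local communities are assembled from a regional pool through a Gaussian
environmental filter plus dispersal and drift, and the DNA fraction of
each sample mixes the current active (RNA) community with an
exponentially decaying *relic pool* of past communities, mimicking the
persistence of extracellular/dead-cell DNA in soil.

Ground truth (traits, realized environments, generating regime) is
returned alongside every table so downstream process inference can be
scored against what actually produced the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .containers import CommunityTable, MONTHS, STAGE_YEARS, SampleMetadata

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "evolve_trait",
    "assemble_community",
    "generate_chronosequence",
    "generate_regime",
    "generate",
]

REGIMES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "chronosequence",
)

#: selection_sd below this is treated as the deterministic (argmin) limit
_SELECTION_SD_FLOOR = 1e-8


@dataclass
class SimulationConfig:
    """Full parameterization of the generator.

    Defaults reproduce the chronosequence design at desk scale:
    5 successional stages sampled in 4 months with 3 replicate plots,
    paired DNA/RNA fractions (120 samples), 2000 individuals drawn from
    a 2000-taxon regional pool per local community, a monotone
    environmental gradient across stages and within-stage monthly
    fluctuations.
    """

    n_taxa: int = 2000
    tree_model: str = "yule"
    trait_sigma2: float = 4.0     # Brownian rate; tree height is 1
    n_stages: int = 5
    n_months: int = 4
    n_replicates: int = 3
    env_by_stage: Sequence[float] | None = None   # default: linspace(-2, 2)
    env_month_noise_sd: float = 1.0
    selection_sd: float | None = 0.5   # None = no selection (sd -> inf)
    migration_rate: float = 0.5        # m: weight of the regional pool
    taxon_availability: float = 0.3    # dispersal lottery: P(pool taxon reaches a site)
    lottery_alpha: float = 0.3         # gamma shape of neutral abundance lottery
    community_size: int = 2000
    relic_carryover: float = 0.5       # phi: DNA fraction drawn from relic pool
    relic_decay: float = 0.5           # per-month decay of the relic pool
    regime: str = "chronosequence"
    n_communities: int | None = None   # single-regime generators only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.community_size < 1:
            raise ValueError("community_size must be >= 1")
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValueError("migration_rate must lie in [0, 1]")
        if not (0.0 < self.taxon_availability <= 1.0):
            raise ValueError("taxon_availability must lie in (0, 1]")
        if self.lottery_alpha <= 0:
            raise ValueError("lottery_alpha must be positive")
        if not (0.0 <= self.relic_carryover < 1.0):
            raise ValueError("relic_carryover must lie in [0, 1)")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.tree_model != "yule":
            raise ValueError("only the yule tree model is supported")
        if self.n_stages < 1 or self.n_months < 1 or self.n_replicates < 1:
            raise ValueError("design dimensions must be >= 1")
        if self.n_stages > len(STAGE_YEARS):
            raise ValueError(f"n_stages must be <= {len(STAGE_YEARS)}")
        if self.n_months > len(MONTHS):
            raise ValueError(f"n_months must be <= {len(MONTHS)}")
        if self.env_by_stage is not None and len(self.env_by_stage) != self.n_stages:
            raise ValueError("env_by_stage length must equal n_stages")

    def stage_envs(self) -> np.ndarray:
        if self.env_by_stage is not None:
            return np.asarray(self.env_by_stage, dtype=float)
        if self.n_stages == 1:
            return np.zeros(1)
        return np.linspace(-2.0, 2.0, self.n_stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Latent values behind a simulated dataset."""

    regime: str
    traits: pd.Series                  # taxon -> niche optimum
    latent_env: pd.Series              # sample -> realized selective environment
    config: SimulationConfig

    def pair_regime(self, sample_a: str, sample_b: str) -> str:
        """Generating regime for a sample pair (uniform per simulation)."""
        return self.regime

    def to_frame(self) -> pd.DataFrame:
        env = self.latent_env.rename("latent_env").to_frame()
        env["regime"] = self.regime
        return env


# ---------------------------------------------------------------------------
# tree + traits
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int, height: float = 1.0) -> TreeNode:
    """Simulate an ultrametric Yule (pure-birth) tree with ``n_taxa`` tips.

    Lineages split at rate 1 each; the process is run until ``n_taxa``
    lineages exist, plus a terminal waiting time, and the tree is rescaled
    so the root-to-tip height equals ``height``. Tips are named
    ``t0001 ...`` in birth order.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)

    root = TreeNode(name=None)
    first = [TreeNode(), TreeNode()]
    for c in first:
        root.append(c)
    birth = {id(c): 0.0 for c in first}
    active: list[TreeNode] = list(first)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        parent.length = t - birth.pop(id(parent))
        kids = [TreeNode(), TreeNode()]
        for k in kids:
            parent.append(k)
            birth[id(k)] = t
            active.append(k)
    t_end = t + rng.exponential(1.0 / len(active))
    for i, tip in enumerate(active):
        tip.length = t_end - birth[id(tip)]
    # stable, seed-independent-of-construction-order naming: by depth order
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:04d}"
    scale = height / t_end
    for node in root.traverse(include_self=False):
        node.length *= scale
    return root


def evolve_trait(
    tree: TreeNode,
    sigma2: float,
    root_value: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Evolve a continuous trait along the tree by Brownian motion.

    Each branch adds an independent ``Normal(0, sigma2 * branch_length)``
    increment, so trait covariance between two tips equals ``sigma2`` times
    their shared path length — close relatives end up with similar niche
    optima.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): float(root_value)}
    tips: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        val = parent_val + rng.normal(0.0, math.sqrt(sigma2 * node.length))
        values[id(node)] = val
        if node.is_tip():
            tips[node.name] = val
    return pd.Series(tips, name="trait")


# ---------------------------------------------------------------------------
# local community assembly
# ---------------------------------------------------------------------------

def assemble_community(
    pool: np.ndarray,
    traits: np.ndarray,
    env: float,
    selection_sd: float | None,
    migration_rate: float,
    community_size: int,
    rng: np.random.Generator | int,
    local: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one local community of ``community_size`` individuals.

    Taxon weights are ``[m * pool + (1 - m) * local]`` (mass effects vs
    local dynamics) multiplied by a Gaussian fitness kernel
    ``exp(-(trait - env)^2 / (2 * selection_sd^2))``; the community is a
    multinomial draw from the renormalized weights. ``selection_sd=None``
    (or infinity) disables selection; a value below 1e-8 applies the
    deterministic limit where every individual belongs to the taxon whose
    trait is nearest ``env``.
    """
    pool = np.asarray(pool, dtype=float)
    if not math.isclose(pool.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("pool must sum to 1")
    if community_size < 1:
        raise ValueError("community_size must be >= 1")
    if selection_sd is not None and not math.isinf(selection_sd) and selection_sd <= 0:
        if selection_sd < 0:
            raise ValueError("selection_sd must be positive, infinite or None")
        selection_sd = 0.0  # exact zero -> argmin limit
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if local is None:
        local = pool
    local = np.asarray(local, dtype=float)
    m = migration_rate
    base = m * pool + (1.0 - m) * local

    no_selection = selection_sd is None or math.isinf(selection_sd)
    if not no_selection and selection_sd <= _SELECTION_SD_FLOOR:
        # deterministic limit: all mass on the best-matched available taxon
        candidates = np.flatnonzero(base > 0)
        winner = candidates[np.argmin(np.abs(traits[candidates] - env))]
        counts = np.zeros_like(pool, dtype=np.int64)
        counts[winner] = community_size
        return counts

    if no_selection:
        weights = base
    else:
        kernel = np.exp(-((traits - env) ** 2) / (2.0 * selection_sd**2))
        weights = base * kernel
    total = weights.sum()
    if total <= 0:
        # kernel underflow: fall back to the deterministic limit
        candidates = np.flatnonzero(base > 0)
        winner = candidates[np.argmin(np.abs(traits[candidates] - env))]
        counts = np.zeros_like(pool, dtype=np.int64)
        counts[winner] = community_size
        return counts
    return rng.multinomial(community_size, weights / total)


def _lognormal_pool(n_taxa: int, rng: np.random.Generator) -> np.ndarray:
    """Regional species-abundance distribution (lognormal, normalized)."""
    ab = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    return ab / ab.sum()


def _derive_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _env_columns(latent: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Map the latent gradient to named soil variables (monotone affine
    transforms plus small independent measurement noise)."""
    n = latent.shape[0]
    return {
        "pH": 8.2 - 0.6 * latent + rng.normal(0, 0.05, n),
        "sodium": 12.0 - 3.0 * latent + rng.normal(0, 0.25, n),
        "organic_carbon": 2.5 + 1.2 * latent + rng.normal(0, 0.08, n),
        "water_content": 0.25 + 0.05 * latent + rng.normal(0, 0.01, n),
    }


# ---------------------------------------------------------------------------
# full designs
# ---------------------------------------------------------------------------

def generate_chronosequence(
    config: SimulationConfig,
) -> tuple[CommunityTable, SampleMetadata, TreeNode, GroundTruth]:
    """Simulate the paired DNA/RNA chronosequence design.

    For every stage x replicate, months unfold sequentially: the active
    (RNA) community is assembled against that month's environment
    (stage baseline + shared monthly fluctuation) with migration from the
    regional pool and inheritance from the previous month; the DNA sample
    mixes the current RNA composition with the replicate's relic pool
    (``relic_carryover`` mass) and is multinomially resampled. The relic
    pool is an exponentially decaying running mixture of past RNA
    compositions, seeded with the regional pool (pre-existing relic DNA).
    """
    if config.regime != "chronosequence":
        raise ValueError("generate_chronosequence requires regime='chronosequence'")
    seeds = _derive_seeds(config.seed, 5)
    tree = simulate_tree(config.n_taxa, seeds[0])
    traits = evolve_trait(tree, config.trait_sigma2, 0.0, seeds[1])
    taxa = list(traits.index)
    trait_arr = traits.to_numpy()
    rng_env = np.random.default_rng(seeds[2])
    rng_comm = np.random.default_rng(seeds[3])
    rng_meta = np.random.default_rng(seeds[4])

    pool = _lognormal_pool(config.n_taxa, rng_comm)
    stage_base = config.stage_envs()
    years = STAGE_YEARS[: config.n_stages]
    months = MONTHS[: config.n_months]

    # month-level environmental fluctuation shared by replicates & fractions
    env_sm = {
        (s, mi): stage_base[s] + rng_env.normal(0.0, config.env_month_noise_sd)
        for s in range(config.n_stages)
        for mi in range(config.n_months)
    }

    rows, ids, meta_rows, latent = [], [], [], []
    phi = config.relic_carryover
    decay_w = math.exp(-config.relic_decay)
    for s in range(config.n_stages):
        for rep in range(1, config.n_replicates + 1):
            # the plot's accessible colonist pool: a dispersal lottery on
            # taxon identities, drawn once per site
            mask = rng_comm.random(config.n_taxa) < config.taxon_availability
            site_pool = pool * mask
            if site_pool.sum() == 0:
                site_pool = pool.copy()
            site_pool = site_pool / site_pool.sum()
            # pre-study state: the site's community under the stage's
            # baseline environment; relic DNA accumulates *filtered*
            # material, not the raw regional pool
            init = assemble_community(
                site_pool, trait_arr, float(stage_base[s]),
                config.selection_sd, config.migration_rate,
                config.community_size, rng_comm,
            )
            local = init / init.sum()
            relic_u = local.copy()  # unnormalized decaying accumulator
            for mi, month in enumerate(months):
                env = env_sm[(s, mi)]
                rna = assemble_community(
                    site_pool, trait_arr, env, config.selection_sd,
                    config.migration_rate, config.community_size,
                    rng_comm, local=local,
                )
                rna_comp = rna / rna.sum()
                relic = relic_u / relic_u.sum()
                dna_mix = (1.0 - phi) * rna_comp + phi * relic
                dna = rng_comm.multinomial(config.community_size, dna_mix)
                for ds, counts in (("RNA", rna), ("DNA", dna)):
                    sid = f"{ds}_y{years[s]}_{month}_r{rep}"
                    ids.append(sid)
                    rows.append(counts)
                    meta_rows.append((sid, ds, years[s], month, rep))
                    latent.append(env)
                relic_u = decay_w * relic_u + rna_comp
                local = rna_comp
    counts = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="sample_id"), columns=taxa
    )
    table = CommunityTable(counts)

    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "dataset", "stage_year", "month", "replicate"]
    ).set_index("sample_id")
    latent_arr = np.asarray(latent)
    for name, vals in _env_columns(latent_arr, rng_meta).items():
        meta[name] = vals
    metadata = SampleMetadata(meta)
    truth = GroundTruth(
        regime="chronosequence",
        traits=traits,
        latent_env=pd.Series(latent_arr, index=counts.index, name="latent_env"),
        config=config,
    )
    return table, metadata, tree, truth


def generate_regime(
    config: SimulationConfig,
) -> tuple[CommunityTable, SampleMetadata, TreeNode, GroundTruth]:
    """Simulate a set of communities under one named assembly regime.

    ``n_communities`` (default ``n_stages * n_replicates``) local
    communities are produced:

    * ``variable_selection`` — each community filtered (narrow Gaussian
      kernel) toward its own environment, spread widely across the trait
      range.
    * ``homogeneous_selection`` — all communities filtered toward one
      shared environment.
    * ``dispersal_limitation`` — no selection; each community founded by a
      small random subset of the pool (founder effect) and amplified, so
      isolated communities diverge far beyond a random-assembly
      expectation.
    * ``homogenizing_dispersal`` — no selection, full mass effects: every
      community is a fresh multinomial draw from the shared pool, so
      communities are *more* similar than random assemblies.
    * ``drift`` — no selection, weak migration; communities wander by a
      few Wright-Fisher resampling generations around the pool.
    """
    if config.regime == "chronosequence":
        raise ValueError("use generate_chronosequence for the chronosequence regime")
    k = config.n_communities or (config.n_stages * config.n_replicates)
    seeds = _derive_seeds(config.seed, 4)
    tree = simulate_tree(config.n_taxa, seeds[0])
    traits = evolve_trait(tree, config.trait_sigma2, 0.0, seeds[1])
    trait_arr = traits.to_numpy()
    rng = np.random.default_rng(seeds[2])
    rng_meta = np.random.default_rng(seeds[3])
    pool = _lognormal_pool(config.n_taxa, rng)
    N = config.community_size

    def filtered_draw(env: float) -> np.ndarray:
        """Gaussian filter + dispersal lottery on taxon identities."""
        mask = rng.random(config.n_taxa) < config.taxon_availability
        w = pool * mask
        if config.selection_sd is not None:
            w = w * np.exp(
                -((trait_arr - env) ** 2) / (2.0 * config.selection_sd**2)
            )
        if w.sum() == 0:
            w = pool * (np.abs(trait_arr - env) == np.abs(trait_arr - env).min())
        return rng.multinomial(N, w / w.sum())

    if config.regime == "variable_selection":
        # widely spread environments, each community filtered to its own
        lo, hi = np.quantile(trait_arr, [0.01, 0.99])
        envs = np.linspace(lo, hi, k)
        comms = [filtered_draw(e) for e in envs]
    elif config.regime == "homogeneous_selection":
        # one stringent shared filter; a realistic selective environment
        # sits in the tail of the regional trait distribution
        envs = np.full(k, np.quantile(trait_arr, 0.9))
        comms = [filtered_draw(envs[0]) for _ in range(k)]
    elif config.regime == "dispersal_limitation":
        # no selection: isolated sites receive idiosyncratic colonist
        # subsets (identity lottery) with idiosyncratic abundances
        envs = np.zeros(k)
        comms = []
        for _ in range(k):
            mask = rng.random(config.n_taxa) < config.taxon_availability
            w = pool * mask * rng.gamma(
                config.lottery_alpha, 1.0 / config.lottery_alpha, config.n_taxa
            )
            if w.sum() == 0:
                w = pool
            comms.append(rng.multinomial(N, w / w.sum()))
    elif config.regime == "homogenizing_dispersal":
        # mass effects homogenize everything around one shared community
        # state that drift has moved away from the pool average
        envs = np.zeros(k)
        state = pool.copy()
        ne = max(N // 20, 50)
        for _ in range(10):
            state = rng.multinomial(ne, state) / ne
        base = 0.9 * state + 0.1 * pool
        comms = [rng.multinomial(N, base) for _ in range(k)]
    elif config.regime == "drift":
        # independent multinomial sampling drift around the shared pool
        envs = np.zeros(k)
        comms = [rng.multinomial(N, pool) for _ in range(k)]
    else:  # pragma: no cover
        raise ValueError(f"unknown regime {config.regime!r}")

    ids = [f"C{i + 1:03d}" for i in range(k)]
    counts = pd.DataFrame(
        np.vstack(comms), index=pd.Index(ids, name="sample_id"),
        columns=list(traits.index),
    )
    table = CommunityTable(counts)
    # design factors are placeholders for single-regime sets
    meta = pd.DataFrame(
        {
            "dataset": "DNA",
            "stage_year": 0,
            "month": "May",
            "replicate": np.arange(1, k + 1),
        },
        index=counts.index,
    )
    for name, vals in _env_columns(envs, rng_meta).items():
        meta[name] = vals
    metadata = SampleMetadata(meta)
    truth = GroundTruth(
        regime=config.regime,
        traits=traits,
        latent_env=pd.Series(envs, index=counts.index, name="latent_env"),
        config=config,
    )
    return table, metadata, tree, truth


def generate(
    config: SimulationConfig,
) -> tuple[CommunityTable, SampleMetadata, TreeNode, GroundTruth]:
    """Dispatch on ``config.regime``."""
    if config.regime == "chronosequence":
        return generate_chronosequence(config)
    return generate_regime(config)
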