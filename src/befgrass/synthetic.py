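"""Synthetic grassland datasets with known ground truth.

The generator emulates the sampling design of a large alpine-grassland
survey: 118 sites of five 1 m^2 quadrats (nine quadrats lost, leaving 581),
a regional pool of 719 species on an ultrametric tree, quadrat richness
between 3 and 37 species, individual densities up to ~2,250/m^2, and four
log-normal traits (SLA, leaf size, plant height, seed mass). Community
assembly can be neutral (uniform draws from the pool), environmentally
filtered (trait-clustered) or shaped by limiting similarity
(trait-overdispersed). Quadrat-level aboveground biomass follows a
continuous broken-line law on the log10 scale,

    log10 B = a + b1 log10 S + (b2 - b1)(log10 S - psi)_+ + N(0, sigma),

whose parameters (psi = 1.05, b1 = 0.04, b2 = 1.16 by default) are the
ground truth the regression stage is meant to recover; sigma defaults to the
value that puts the law's population R^2 at 0.31.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .data_model import TRAIT_COLUMNS, CommunityTable, TraitTable

__all__ = [
    "SyntheticConfig",
    "generate_tree",
    "generate_traits",
    "assemble_communities",
    "apply_biomass_law",
    "generate_dataset",
    "sigma_for_target_r2",
]

#: per-trait (log10 location, log10 scale) of the raw measurement scales:
#: SLA mm^2/mg, leaf size cm^2, height cm, seed mass mg
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "SLA": (1.2, 0.25),
    "leaf_size": (0.5, 0.5),
    "height": (1.0, 0.4),
    "seed_mass": (0.0, 0.5),
}


@dataclass(frozen=True)
class SyntheticConfig:
    pool_size: int = 719
    n_sites: int = 118
    quadrats_per_site: int = 5
    n_missing_quadrats: int = 9  # field losses; 118*5 - 9 = 581
    richness_range: tuple[int, int] = (3, 37)
    max_density: float = 2252.0  # individuals per m^2
    trait_model: str = "brownian"  # or "independent"
    trait_signal: dict[str, bool] = field(default_factory=dict)  # per-trait override
    assembly: str = "random"  # random | filtered | limiting
    assembly_strength: float = 0.0
    abundance_correlation: float = 0.7  # shared latent across biomass/cover/density
    biomass_intercept: float = 1.5
    biomass_psi: float = 1.05  # breakpoint on log10 richness
    biomass_b1: float = 0.04
    biomass_b2: float = 1.16
    biomass_sigma: float | None = None  # None -> solve for target_r2
    target_r2: float = 0.31
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.richness_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid richness range")
        if self.n_missing_quadrats >= self.n_sites * self.quadrats_per_site:
            raise ValueError("cannot lose every quadrat")
        if hi > self.pool_size:
            raise ValueError("richness range exceeds pool size")
        if self.assembly not in ("random", "filtered", "limiting"):
            raise ValueError(f"unknown assembly mode {self.assembly!r}")
        if self.assembly != "random" and self.assembly_strength < 0:
            raise ValueError("assembly_strength must be non-negative")
        lo_x, hi_x = np.log10(lo), np.log10(hi)
        if not lo_x < self.biomass_psi < hi_x:
            raise ValueError("biomass_psi must lie inside the log10 richness range")


def _sub_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(master))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_tree(pool_size: int, seed: int | None = None) -> dendropy.Tree:
    """Yule (pure-birth) tree on the species pool, scaled to root age 1."""
    if pool_size < 2:
        raise ValueError("pool must have at least 2 species")
    rng = _random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=pool_size, rng=rng
    )
    width = len(str(pool_size))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:0{width}d}"
    root_age = tree.max_distance_from_root()
    if root_age <= 0:  # two starting lineages and no events: unit cherry
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
        root_age = 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / root_age
    return tree


def _brownian_tips(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    vals: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = vals[id(node.parent_node)]
        step = rng.normal(0.0, np.sqrt(max(node.edge.length or 0.0, 0.0)))
        vals[id(node)] = parent + step
        if node.is_leaf():
            out[node.taxon.label] = vals[id(node)]
    return out


def generate_traits(
    tree: dendropy.Tree,
    model: str = "brownian",
    seed: int | None = None,
    trait_signal: dict[str, bool] | None = None,
) -> TraitTable:
    """Four traits on the tips, Brownian (phylogenetic signal, K near 1) or
    tree-independent (no signal), exponentiated to realistic raw scales."""
    if model not in ("brownian", "independent"):
        raise ValueError(f"unknown trait model {model!r}")
    trait_signal = trait_signal or {}
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    seeds = _sub_seeds(seed if seed is not None else 0, len(TRAIT_COLUMNS))
    cols = {}
    for trait, s in zip(TRAIT_COLUMNS, seeds):
        rng = np.random.default_rng(s)
        use_bm = trait_signal.get(trait, model == "brownian")
        if use_bm:
            tips = _brownian_tips(tree, rng)
            z = np.array([tips[sp] for sp in species])
        else:
            z = rng.normal(size=len(species))
        z = (z - z.mean()) / z.std(ddof=1)
        mu, sd = TRAIT_SCALES[trait]
        cols[trait] = np.power(10.0, mu + sd * z)
    df = pd.DataFrame(cols, index=pd.Index(species, name="species"))
    return TraitTable(data=df)


def _trait_z(traits: TraitTable) -> tuple[list[str], np.ndarray]:
    species = traits.complete_species()
    logt = np.log10(traits.data.loc[species, list(TRAIT_COLUMNS)].to_numpy(float))
    z = (logt - logt.mean(axis=0)) / logt.std(axis=0, ddof=1)
    return species, z


def _select_species(
    mode: str, strength: float, z: np.ndarray, S: int, rng: np.random.Generator
) -> np.ndarray:
    n = z.shape[0]
    if mode == "random" or strength == 0:
        return rng.choice(n, size=S, replace=False)
    if mode == "filtered":
        opt = z[rng.integers(n)]  # a random species defines the local optimum
        logw = -strength * ((z - opt) ** 2).sum(axis=1)
        gumbel = rng.gumbel(size=n)
        return np.argsort(logw + gumbel)[-S:]
    # limiting similarity: sequentially favour the species farthest (in trait
    # space) from everything already present
    chosen = [int(rng.integers(n))]
    avail = np.ones(n, dtype=bool)
    avail[chosen[0]] = False
    min_d = np.sqrt(((z - z[chosen[0]]) ** 2).sum(axis=1))
    while len(chosen) < S:
        logw = strength * min_d[avail]
        logw = logw - logw.max()
        w = np.exp(logw)
        pick_idx = rng.choice(np.flatnonzero(avail), p=w / w.sum())
        chosen.append(int(pick_idx))
        avail[pick_idx] = False
        min_d = np.minimum(min_d, np.sqrt(((z - z[pick_idx]) ** 2).sum(axis=1)))
    return np.array(chosen)


def assemble_communities(
    config: SyntheticConfig,
    tree: dendropy.Tree,
    traits: TraitTable,
    rng: np.random.Generator | None = None,
) -> CommunityTable:
    """Draw quadrat communities from the pool under the configured assembly
    mode and assign correlated lognormal abundance components."""
    if rng is None:
        rng = np.random.default_rng(_sub_seeds(config.seed, 3)[1])
    species, z = _trait_z(traits)
    species = np.array(species)
    lo, hi = config.richness_range
    rho = config.abundance_correlation

    n_quadrats = config.n_sites * config.quadrats_per_site
    drop = set(
        rng.choice(n_quadrats, size=config.n_missing_quadrats, replace=False).tolist()
    )
    rows = []
    meta_rows = []
    q = 0
    for si in range(config.n_sites):
        site_id = f"S{si + 1:03d}"
        for _ in range(config.quadrats_per_site):
            q += 1
            if (q - 1) in drop:
                continue
            qid = f"Q{q:04d}"
            S = int(rng.integers(lo, hi + 1))
            idx = _select_species(config.assembly, config.assembly_strength, z, S, rng)
            latent = rng.normal(size=S)

            def mix(scale_sd: float) -> np.ndarray:
                eps = rng.normal(size=S)
                return scale_sd * (rho * latent + np.sqrt(1 - rho**2) * eps)

            density = np.power(10.0, 1.0 + mix(0.8))
            density = np.clip(density, 0.5, config.max_density)
            biomass = np.power(10.0, 0.5 + mix(0.6))
            cover_rel = np.power(10.0, mix(0.4))
            total_cover = rng.uniform(0.6, 0.95)
            cover = cover_rel / cover_rel.sum() * total_cover
            for j, sp_i in enumerate(idx):
                rows.append(
                    {
                        "quadrat_id": qid,
                        "site_id": site_id,
                        "species": species[sp_i],
                        "biomass": float(biomass[j]),
                        "cover": float(cover[j]),
                        "density": float(density[j]),
                    }
                )
            meta_rows.append({"quadrat_id": qid, "site_id": site_id})
    data = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows).set_index("quadrat_id")
    return CommunityTable(data=data, quadrat_meta=meta)


def sigma_for_target_r2(config: SyntheticConfig) -> float:
    """Noise SD that sets the biomass law's population R^2 to the target,
    for richness uniform over the configured range."""
    lo, hi = config.richness_range
    s_vals = np.arange(lo, hi + 1)
    x = np.log10(s_vals)
    f = (
        config.biomass_b1 * x
        + (config.biomass_b2 - config.biomass_b1) * np.clip(x - config.biomass_psi, 0, None)
    )
    var_f = float(np.var(f))
    r2 = config.target_r2
    return float(np.sqrt(var_f * (1 - r2) / r2))


def apply_biomass_law(
    communities: CommunityTable,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> CommunityTable:
    """Redraw quadrat total biomass from the broken-line law and rescale the
    species biomasses to match, preserving relative abundances."""
    if rng is None:
        rng = np.random.default_rng(_sub_seeds(config.seed, 3)[2])
    sigma = config.biomass_sigma
    if sigma is None:
        sigma = sigma_for_target_r2(config)
    data = communities.data.copy()
    for qid, sub in data.groupby("quadrat_id", sort=True):
        S = sub["species"].nunique()
        x = np.log10(S)
        log_b = (
            config.biomass_intercept
            + config.biomass_b1 * x
            + (config.biomass_b2 - config.biomass_b1) * max(x - config.biomass_psi, 0.0)
            + rng.normal(0.0, sigma)
        )
        total = 10.0**log_b
        cur = sub["biomass"].sum()
        data.loc[sub.index, "biomass"] = sub["biomass"] / cur * total
    return CommunityTable(data=data, quadrat_meta=communities.quadrat_meta.copy())


def sample_richness_biomass(
    config: SyntheticConfig, n_quadrats: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal draw of (richness, log10 biomass) pairs under the generator's
    richness distribution and biomass law — the regression stage's ground
    truth without the community bookkeeping."""
    lo, hi = config.richness_range
    sigma = config.biomass_sigma
    if sigma is None:
        sigma = sigma_for_target_r2(config)
    S = rng.integers(lo, hi + 1, n_quadrats)
    x = np.log10(S)
    log_b = (
        config.biomass_intercept
        + config.biomass_b1 * x
        + (config.biomass_b2 - config.biomass_b1) * np.clip(x - config.biomass_psi, 0, None)
        + rng.normal(0.0, sigma, n_quadrats)
    )
    return S, log_b


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[CommunityTable, TraitTable, dendropy.Tree]:
    """Full synthetic dataset (communities, traits, tree) from one config."""
    config = config or SyntheticConfig()
    tree_seed, _, _ = _sub_seeds(config.seed, 3)
    tree = generate_tree(config.pool_size, seed=tree_seed)
    traits = generate_traits(
        tree, model=config.trait_model, seed=config.seed, trait_signal=config.trait_signal
    )
    communities = assemble_communities(config, tree, traits)
    communities = apply_biomass_law(communities, config)
    return communities, traits, tree
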