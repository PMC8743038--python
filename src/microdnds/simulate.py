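"""Synthetic divergence tables with known ground truth.

The generator emits gene-level substitution-count tables whose pooled dN/dS
follows the saturating purifying-selection curve, with pathway constraints
correlated across species through an Ornstein-Uhlenbeck process on a random
coalescent tree. Ground truth (per-cell selected fractions, species offsets,
the tree, decay rate) is returned for parameter-recovery tests.

Generative model, per gene of pathway p in species s for lineage pair t:

    dS_t       ~ truncated lognormal (pair-level neutral divergence)
    s_diff     ~ Binomial(s_opp, dS_t)
    n_diff     ~ Binomial(n_opp, dS_t * curve(dS_t; f_sel[s,p], d_star)
                                * offset_s * noise_gene)

so the expected pooled dN/dS of a (species, pathway) cell is the dS-weighted
average of the curve, times the species offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .pathways import PathwayMap

logger = logging.getLogger(__name__)

_P_CAP = 0.745  # binomial success probabilities are clipped below the JC singularity


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic divergence generator (all rates/scales > 0)."""

    n_species: int = 40
    n_pathways: int = 20
    genes_per_pathway: int = 25
    pairs_per_species: int = 30
    n_opp: int = 700
    s_opp: int = 250
    # pair-level neutral dS: lognormal(median, sigma_log) truncated to [ds_min, ds_max]
    ds_median: float = 0.01
    ds_sigma_log: float = 1.0
    ds_min: float = 1e-4
    ds_max: float = 0.1
    # constraint field: pathway baselines + OU evolution across the tree
    f_sel_min: float = 0.5
    f_sel_max: float = 0.99
    sigma_ou: float = 0.12
    lambda_ou: float = 3.0
    d_star: float = 0.01
    gene_noise_sigma: float = 0.2
    species_offset_sigma: float = 0.0
    cv_target: float | None = None
    force_f_sel: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "n_pathways", "genes_per_pathway", "pairs_per_species",
                     "n_opp", "s_opp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("ds_median", "ds_sigma_log", "ds_min", "ds_max", "d_star", "lambda_ou"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma_ou < 0 or self.gene_noise_sigma < 0 or self.species_offset_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.f_sel_min <= self.f_sel_max <= 1:
            raise ValueError("need 0 <= f_sel_min <= f_sel_max <= 1")
        if self.force_f_sel is not None and not 0 <= self.force_f_sel <= 1:
            raise ValueError("force_f_sel must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneratorTruth:
    """Ground truth emitted alongside a simulated table."""

    f_sel: pd.DataFrame = field(repr=False)  # species x pathway, values actually used
    d_star: float = 0.01
    species_offsets: pd.Series = field(default=None, repr=False)
    cell_multipliers: pd.DataFrame = field(default=None, repr=False)
    tree_newick: str = ""
    decay_rate: float | None = None
    cv_target: float | None = None
    pathway_baselines: pd.Series = field(default=None, repr=False)
    n_prob_clipped: int = 0
    config: dict = field(default_factory=dict)


def _species_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Random Kingman-coalescent tree, max tip-to-tip distance scaled to 1."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    labels = _species_labels(n_species)
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        node.age = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = t
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = t - child.age
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    scale = 1.0 / (2.0 * t)  # ultrametric: deepest tip pair spans twice the root age
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def simulate_constraints(
    tree: dendropy.Tree,
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-(species, pathway) selected fractions evolved by OU along the tree.

    Each pathway draws a baseline in [f_sel_min, f_sel_max] and evolves
    independently under a stationary Ornstein-Uhlenbeck process (sd
    ``sigma_ou``, reversion rate ``lambda_ou``), so the expected cross-species
    correlation of constraint decays as exp(-lambda_ou * distance). Tip values
    are clipped to [0, 1] with the clip count logged.
    """
    if config.lambda_ou <= 0:
        raise ValueError("lambda_ou must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_pw = config.n_pathways
    baselines = rng.uniform(config.f_sel_min, config.f_sel_max, size=n_pw)
    lam, sigma = config.lambda_ou, config.sigma_ou

    values: dict[int, np.ndarray] = {}
    root = tree.seed_node
    values[id(root)] = baselines + sigma * rng.standard_normal(n_pw)
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            x = values[id(root)]
        else:
            parent_x = values[id(node.parent_node)]
            decay = np.exp(-lam * node.edge.length)
            sd = sigma * np.sqrt(max(0.0, 1.0 - decay**2))
            x = baselines + (parent_x - baselines) * decay + sd * rng.standard_normal(n_pw)
            values[id(node)] = x
        if node.is_leaf():
            tips[node.taxon.label] = x

    species = sorted(tips)
    raw = np.vstack([tips[s] for s in species])
    n_clipped = int(np.sum((raw < 0) | (raw > 1)))
    if n_clipped:
        logger.info("simulate_constraints: %d tip values clipped to [0, 1]", n_clipped)
    f = pd.DataFrame(
        np.clip(raw, 0.0, 1.0),
        index=species,
        columns=[f"P{j + 1:02d}" for j in range(n_pw)],
    )
    truth = {
        "baselines": pd.Series(baselines, index=f.columns),
        "decay_rate": lam,
        "stationary_sd": sigma,
        "n_clipped": n_clipped,
    }
    return f, truth


def _curve(ds: np.ndarray, f: np.ndarray, d_star: float) -> np.ndarray:
    """Vectorized purifying-selection curve with elementwise f_sel."""
    x = np.asarray(ds, dtype=float) / d_star
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(x > 0, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0)
    return (1.0 - f) + f * sat


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float, size
) -> np.ndarray:
    out = rng.lognormal(np.log(median), sigma, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.lognormal(np.log(median), sigma, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _constant_cv_factors(rng: np.random.Generator, shape: tuple[int, int], cv: float) -> np.ndarray:
    """IID positive mean-one factors, rescaled so the median per-column sample
    CV equals ``cv`` exactly.

    Independence across columns (pathways) keeps per-pathway sample CVs
    scattering naturally around the target, so downstream mean-variance
    regressions see honest residuals rather than a degenerate exact power law.
    """
    if cv == 0:
        return np.ones(shape)
    s2 = np.log1p(cv**2)
    x = rng.lognormal(-0.5 * s2, np.sqrt(s2), size=shape)
    col_cv = x.std(axis=0, ddof=1) / x.mean(axis=0)
    med = float(np.median(col_cv))
    if med > 0:
        x = 1.0 + (x - 1.0) * (cv / med)
    return np.clip(x, 0.02, None)


def simulate_curve_points(
    n: int,
    f_sel: float,
    d_star: float,
    noise_sigma: float = 0.2,
    seed: int = 0,
    ds_min: float = 1e-4,
    ds_max: float = 0.1,
) -> pd.DataFrame:
    """(dS, dN/dS) points on the model curve with multiplicative lognormal noise.

    Noise has median 1 so points are unbiased in log space, matching the
    log-space fit objective. dS is log-uniform over [ds_min, ds_max].
    """
    rng = np.random.default_rng(seed)
    ds = np.exp(rng.uniform(np.log(ds_min), np.log(ds_max), size=n))
    y = _curve(ds, np.full(n, f_sel), d_star) * rng.lognormal(0.0, noise_sigma, size=n)
    return pd.DataFrame({"dS": ds, "dNdS": y})


def simulate_divergence_table(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, PathwayMap, dendropy.Tree, GeneratorTruth]:
    """Full synthetic dataset: records table, pathway map, tree, ground truth.

    Deterministic given ``config.seed`` (byte-identical tables on re-run).
    When ``cv_target`` is set, pathway constraints are rebuilt so every
    pathway's across-species coefficient of variation of expected dN/dS
    equals the target (constant-CV regime, Taylor slope 2); otherwise the OU
    constraint field is used. ``force_f_sel`` overrides both (e.g. 0 for the
    neutral null).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seed_tree, seed_constraints, seed_table = (int(s.generate_state(1)[0]) for s in ss.spawn(3))

    tree = simulate_tree(cfg.n_species, seed=seed_tree)
    species = _species_labels(cfg.n_species)
    pathways = [f"P{j + 1:02d}" for j in range(cfg.n_pathways)]
    rng = np.random.default_rng(seed_table)

    # pair-level neutral synonymous divergence
    ds_pair = _truncated_lognormal(
        rng, cfg.ds_median, cfg.ds_sigma_log, cfg.ds_min, cfg.ds_max,
        size=(cfg.n_species, cfg.pairs_per_species),
    )

    baselines = None
    decay_rate = None
    offsets = np.ones(cfg.n_species)
    cell_mult = None  # per-(species, pathway) multiplier on expected dN/dS
    if cfg.force_f_sel is not None:
        f_matrix = pd.DataFrame(cfg.force_f_sel, index=species, columns=pathways)
    elif cfg.cv_target is not None:
        # constant-CV regime: each pathway's expected dN/dS is a pathway level
        # times an iid mean-one factor with coefficient of variation cv_target.
        # Constraints are chosen per species so that the dS-weighted curve
        # average hits the pathway level exactly, removing the coupling between
        # a species' dS draws and its cell values.
        x = np.asarray(ds_pair / cfg.d_star)
        g = np.where(x > 0, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0)
        g_s = (ds_pair * g).sum(axis=1) / ds_pair.sum(axis=1)  # dS-weighted curve tail
        g_bar = float(g_s.mean())
        fbar = rng.uniform(cfg.f_sel_min, cfg.f_sel_max, size=cfg.n_pathways)
        b_level = (1.0 - fbar) + fbar * g_bar  # target pathway-level dN/dS
        f_cells = (1.0 - b_level[None, :]) / (1.0 - g_s[:, None])
        n_clip = int(np.sum((f_cells < 0) | (f_cells > 1)))
        if n_clip:
            logger.info("cv_target mode: %d constraint cells clipped to [0, 1]", n_clip)
        f_matrix = pd.DataFrame(np.clip(f_cells, 0.0, 1.0), index=species, columns=pathways)
        cell_mult = _constant_cv_factors(rng, (cfg.n_species, cfg.n_pathways), cfg.cv_target)
        baselines = pd.Series(fbar, index=pathways)
    else:
        f_matrix, ou_truth = simulate_constraints(tree, cfg, seed=seed_constraints)
        baselines = ou_truth["baselines"]
        decay_rate = ou_truth["decay_rate"]
        if cfg.species_offset_sigma > 0:
            offsets = rng.lognormal(
                -0.5 * cfg.species_offset_sigma**2, cfg.species_offset_sigma, cfg.n_species
            )
    if cell_mult is None:
        cell_mult = np.broadcast_to(offsets[:, None], (cfg.n_species, cfg.n_pathways))

    genes_per_species = cfg.n_pathways * cfg.genes_per_pathway
    gene_ids = np.array(
        [f"{pw}_g{k + 1:03d}" for pw in pathways for k in range(cfg.genes_per_pathway)]
    )
    gene_pathway = np.repeat(np.arange(cfg.n_pathways), cfg.genes_per_pathway)

    n_rows = cfg.n_species * cfg.pairs_per_species * genes_per_species
    sp_idx = np.repeat(np.arange(cfg.n_species), cfg.pairs_per_species * genes_per_species)
    pair_idx = np.tile(
        np.repeat(np.arange(cfg.pairs_per_species), genes_per_species), cfg.n_species
    )
    gene_idx = np.tile(np.arange(genes_per_species), cfg.n_species * cfg.pairs_per_species)
    pw_idx = gene_pathway[gene_idx]

    ds_row = ds_pair[sp_idx, pair_idx]
    f_row = f_matrix.to_numpy()[sp_idx, pw_idx]
    expected = _curve(ds_row, f_row, cfg.d_star) * cell_mult[sp_idx, pw_idx]
    if cfg.gene_noise_sigma > 0:
        # mean-one multiplicative gene noise keeps pooled dN/dS unbiased
        expected = expected * rng.lognormal(
            -0.5 * cfg.gene_noise_sigma**2, cfg.gene_noise_sigma, size=n_rows
        )
    p_n = ds_row * expected
    clipped = p_n > _P_CAP
    n_prob_clipped = int(clipped.sum())
    if n_prob_clipped > 0.01 * n_rows:
        raise ValueError(
            f"{n_prob_clipped}/{n_rows} nonsynonymous success probabilities >= {_P_CAP}; "
            "rescale ds_max, d_star or noise parameters"
        )
    if n_prob_clipped:
        logger.info("simulate_divergence_table: %d probabilities clipped at %.3f",
                    n_prob_clipped, _P_CAP)
        p_n = np.minimum(p_n, _P_CAP)

    s_diff = rng.binomial(cfg.s_opp, ds_row)
    n_diff = rng.binomial(cfg.n_opp, p_n)

    pair_width = max(3, len(str(cfg.pairs_per_species)))
    species_arr = np.array(species)
    pair_labels = np.array([f"pair{j + 1:0{pair_width}d}" for j in range(cfg.pairs_per_species)])
    table = pd.DataFrame(
        {
            "species_id": species_arr[sp_idx],
            "pair_id": pair_labels[pair_idx],
            "gene_id": gene_ids[gene_idx],
            "pathway_id": np.array(pathways)[pw_idx],
            "n_diff": n_diff,
            "n_opp": cfg.n_opp,
            "s_diff": s_diff,
            "s_opp": cfg.s_opp,
        }
    )
    pmap = PathwayMap(
        entries={g: pathways[p] for g, p in zip(gene_ids, gene_pathway)},
        pathway_names={p: f"pathway {p}" for p in pathways},
    )
    truth = GeneratorTruth(
        f_sel=f_matrix,
        d_star=cfg.d_star,
        species_offsets=pd.Series(offsets, index=species),
        cell_multipliers=pd.DataFrame(np.array(cell_mult), index=species, columns=pathways),
        tree_newick=tree.as_string(schema="newick").strip(),
        decay_rate=decay_rate,
        cv_target=cfg.cv_target,
        pathway_baselines=baselines,
        n_prob_clipped=n_prob_clipped,
        config=cfg.to_dict(),
    )
    return table, pmap, tree, truth
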