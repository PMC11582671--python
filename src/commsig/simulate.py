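"""Synthetic community generator with recorded ground truth.

Emulates the statistical structure of a multi-habitat amplicon survey:
a handful of sample groups (habitats), a heavy-tailed ("rare biosphere")
taxon abundance distribution, planted high-index signature taxa per group,
controllable phylogenetic assembly (clustered / overdispersed / random)
within groups, group-structured environmental covariates, and spatially
clustered station coordinates.  Everything is deterministic given the seed,
and the planted truth is returned so recovery can be scored.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .containers import AbundanceTable, SampleMetadata
from .phylo import patristic_distances

__all__ = ["SimulationConfig", "PlantedTruth", "simulate_tree", "simulate_community"]

ASSEMBLY_MODES = ("clustered", "overdispersed", "random")

# Beaufort-Sea-like station cluster centres (decimal degrees), a few hundred
# to ~1500 km apart so distance-decay is estimable.
DEFAULT_CENTERS = [
    (71.3, -156.8),
    (70.5, -138.9),
    (73.5, -150.0),
    (74.6, -146.0),
    (69.8, -133.0),
    (72.0, -127.0),
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a desk-scale 4-habitat survey."""

    n_taxa: int = 200
    n_samples_per_group: int = 6
    n_groups: int = 4
    n_signatures_per_group: int = 10
    signature_effect: float = 20.0       # multiplicative boost within the group
    log_abundance_mean: float = 0.0      # natural-log baseline abundance
    log_abundance_sd: float = 4.0        # heavy tail: ~83% of taxa below 0.01%
                                         # of the grand total, as in an 18S survey
    depth: int = 5000                    # sequences per sample (~25 reads/taxon,
                                         # the depth-to-richness regime of a
                                         # rarefied 18S survey)
    assembly_modes: tuple[str, ...] | None = None  # per group; None = all random
    pool_size: int = 40                  # active non-signature taxa for non-random modes
    signature_min_share: float = 1e-4    # plant signatures among non-rare taxa
                                         # (expected study-wide share >= this)
    n_env: int = 6
    env_offset: float = 2.0              # group-mean shift in sd units
    spatial_spread_km: float = 50.0
    overdispersion: float = 0.0          # >0 adds Gamma noise to expected proportions
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_taxa, self.n_samples_per_group, self.n_groups, self.depth) < 1:
            raise ValueError("counts must be positive")
        if self.signature_effect <= 0:
            raise ValueError("signature_effect must be > 0")
        if self.n_signatures_per_group * self.n_groups > self.n_taxa:
            raise ValueError("more signatures requested than taxa")
        if self.assembly_modes is not None:
            if len(self.assembly_modes) != self.n_groups:
                raise ValueError("need one assembly mode per group")
            bad = set(self.assembly_modes) - set(ASSEMBLY_MODES)
            if bad:
                raise ValueError(f"invalid assembly modes: {sorted(bad)}")

    @property
    def modes(self) -> tuple[str, ...]:
        return self.assembly_modes or ("random",) * self.n_groups

    @property
    def group_names(self) -> list[str]:
        return [f"G{g + 1}" for g in range(self.n_groups)]


@dataclass
class PlantedTruth:
    """Ground truth recorded by :func:`simulate_community`."""

    signatures: dict[str, list[str]]     # group -> planted signature taxa
    assembly_modes: dict[str, str]
    env_means: dict[str, list[float]]
    centers: dict[str, tuple[float, float]]
    active_taxa: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        d["centers"] = {k: tuple(v) for k, v in d["centers"].items()}
        return cls(**d)


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Rooted Yule (pure-birth) tree with exponential branch lengths.

    Leaves are labelled ``ASV_1 .. ASV_n``; deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = _random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, rng=rng
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"ASV_{i}"
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    sk = TreeNode.read([newick])
    for node in sk.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    sk.length = 0.0  # a root edge carries no information
    return sk


def _greedy_max_dispersion(D: np.ndarray, candidates: np.ndarray, k: int) -> list[int]:
    """Greedily pick k tips spread across the tree (maximin dispersion).

    Starts from the most distant pair, then repeatedly adds the tip whose
    minimum patristic distance to the chosen set is largest.  A maximin
    objective avoids the close sister pairs that a summed-distance greedy
    leaves at the extremes of two clades, so the pool is overdispersed
    pairwise, not just on average.
    """
    cand = list(candidates)
    if k >= len(cand):
        return cand
    sub = D[np.ix_(cand, cand)]
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    chosen = [cand[i], cand[j]]
    remaining = [c for c in cand if c not in chosen]
    while len(chosen) < k:
        gains = [D[c, chosen].min() for c in remaining]
        best = int(np.argmax(gains))
        chosen.append(remaining.pop(best))
    return chosen


def _clade_pool(
    tree: TreeNode, taxa: list[str], exclude: set[int], k: int, rng: np.random.Generator
) -> list[int]:
    """Pick one clade's tips (smallest clade with >= k eligible tips)."""
    col = {t: i for i, t in enumerate(taxa)}
    best: list[int] | None = None
    clades = []
    for node in tree.non_tips(include_self=True):
        idx = [col[t.name] for t in node.tips() if col[t.name] not in exclude]
        if len(idx) >= k:
            clades.append(idx)
    if not clades:
        raise ValueError("no clade large enough for the requested pool")
    sizes = np.array([len(c) for c in clades])
    # smallest adequate clade = most phylogenetically concentrated choice
    best = clades[int(np.argmin(sizes))]
    if len(best) > k:
        best = list(rng.choice(best, size=k, replace=False))
    return best


def simulate_community(
    config: SimulationConfig, tree: TreeNode
) -> tuple[AbundanceTable, SampleMetadata, PlantedTruth]:
    """Draw a multi-group community with planted signature taxa.

    Per taxon a log-normal baseline abundance is drawn; each group gets
    disjoint planted signature taxa whose baseline is multiplied by
    ``signature_effect`` in that group's samples.  Counts are
    Multinomial(depth, p) per sample (optionally Gamma-perturbed for
    overdispersion).  Metadata carries group labels, group-shifted
    environmental variables and jittered station coordinates.
    """
    cfg = config
    taxa = [t.name for t in tree.tips()]
    if len(taxa) < cfg.n_taxa:
        raise ValueError("tree has fewer leaves than requested taxa")
    taxa = taxa[: cfg.n_taxa]
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa
    q = cfg.n_groups

    baseline = np.exp(rng.normal(cfg.log_abundance_mean, cfg.log_abundance_sd, size=n))

    # disjoint planted signature sets, drawn from the expected non-rare pool:
    # habitat-characteristic taxa are detectable within their habitat, and in
    # real surveys the signature taxa sit above the rare-biosphere cutoff
    n_sig_total = cfg.n_signatures_per_group * q
    share = baseline / baseline.sum()
    eligible = np.flatnonzero(share >= cfg.signature_min_share)
    if len(eligible) < n_sig_total:
        # fall back to the top taxa by baseline abundance
        eligible = np.argsort(baseline)[::-1][:n_sig_total]
    order = rng.permutation(eligible)
    sig_idx = {
        g: [int(i) for i in
            order[g * cfg.n_signatures_per_group : (g + 1) * cfg.n_signatures_per_group]]
        for g in range(q)
    }
    planted: set[int] = {i for idx in sig_idx.values() for i in idx}

    modes = cfg.modes
    need_patristic = any(m == "overdispersed" for m in modes)
    D = patristic_distances(tree, taxa) if need_patristic else None

    # active non-signature pool per group
    active_idx: dict[int, list[int]] = {}
    for g in range(q):
        mode = modes[g]
        non_sig = np.array(sorted(set(range(n)) - set(sig_idx[g])))
        if mode == "random":
            active_idx[g] = list(non_sig)
        elif mode == "clustered":
            pool = _clade_pool(tree, taxa, set(sig_idx[g]), cfg.pool_size, rng)
            active_idx[g] = pool
        else:  # overdispersed
            eligible = np.array(sorted(set(non_sig) - planted))
            active_idx[g] = _greedy_max_dispersion(D, eligible, cfg.pool_size)

    # expected relative abundances per group
    counts = np.zeros((n, q * cfg.n_samples_per_group), dtype=float)
    sample_ids, group_labels = [], []
    names = cfg.group_names
    for g in range(q):
        lam = np.zeros(n)
        act = active_idx[g]
        lam[act] = baseline[act]
        if modes[g] == "overdispersed":
            # competitive exclusion among dominants: the most abundant pool
            # members are the most mutually distant (maximin pick order),
            # so abundance-weighted MPD genuinely exceeds the null
            lam[act] = np.sort(baseline[act])[::-1]
        lam[sig_idx[g]] = baseline[sig_idx[g]] * cfg.signature_effect
        for s in range(cfg.n_samples_per_group):
            w = lam.copy()
            if cfg.overdispersion > 0:
                shape = 1.0 / cfg.overdispersion
                w = w * rng.gamma(shape, 1.0 / shape, size=n)
            p = w / w.sum()
            col = g * cfg.n_samples_per_group + s
            counts[:, col] = rng.multinomial(cfg.depth, p)
            sample_ids.append(f"{names[g]}_S{s + 1}")
            group_labels.append(names[g])

    table = AbundanceTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))

    # metadata: env variables and coordinates
    env_means = {}
    centers = {}
    rows = []
    for g in range(q):
        mu = np.zeros(cfg.n_env)
        # each group shifts a distinct (cyclic) pair of variables
        for v in range(cfg.n_env):
            if v % q == g:
                mu[v] = cfg.env_offset
        env_means[names[g]] = list(mu)
        centers[names[g]] = DEFAULT_CENTERS[g % len(DEFAULT_CENTERS)]
    lat_jitter = cfg.spatial_spread_km / 111.195
    for col, sid in enumerate(sample_ids):
        g = col // cfg.n_samples_per_group
        mu = np.array(env_means[names[g]])
        env = mu + rng.normal(0.0, 1.0, size=cfg.n_env)
        lat0, lon0 = centers[names[g]]
        lat = lat0 + rng.normal(0.0, lat_jitter)
        lon = lon0 + rng.normal(0.0, lat_jitter / np.cos(np.radians(lat0)))
        rows.append([group_labels[col], lat, lon, *env])
    meta = pd.DataFrame(
        rows,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["group", "latitude", "longitude"]
        + [f"env_{v + 1}" for v in range(cfg.n_env)],
    )
    metadata = SampleMetadata(meta)

    truth = PlantedTruth(
        signatures={names[g]: [taxa[i] for i in sig_idx[g]] for g in range(q)},
        assembly_modes={names[g]: modes[g] for g in range(q)},
        env_means={k: list(v) for k, v in env_means.items()},
        centers=centers,
        active_taxa={names[g]: [taxa[i] for i in active_idx[g]] for g in range(q)},
    )
    return table, metadata, truth
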