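"""Synthetic trees, trait tables and FA profiles with the assumed structure.

The generator emulates the statistical shape of the study data: an
ultrametric phylogeny of ~54 mammal species (Yule process, optionally
degraded with polytomies), a three-level environment factor assigned with
phylogenetic clustering, latitudes spanning the sampled band, log-normal
hair densities for semi-aquatic species, and continuous indices generated as
fixed effects plus λ-scaled Brownian residuals — exactly the generative model
PGLS assumes.  FA composition profiles are constructed to hit prescribed
index values, so the whole pipeline round-trips without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .fa import DELTA9_MUFAS, DELTA9_SFAS, FAProfile, ProfileError
from .models import ENV_LEVELS, MAIN_SUITE, ModelSpec, build_design_matrix
from .phylo import PhyloTree, apply_lambda

__all__ = ["SimulationConfig", "simulate_tree", "simulate_traits", "simulate_fa_profiles"]

#: fixed 12-FA panel: the 8 index FAs plus four common dietary PUFAs
FA_PANEL = (*DELTA9_SFAS, *DELTA9_MUFAS, "18:2ω6", "20:4ω6", "20:5ω3", "22:6ω3")
_PUFA_BONDS = {"18:2ω6": 2, "20:4ω6": 4, "20:5ω3": 5, "22:6ω3": 6}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study's composition.

    54 tips split 15 terrestrial / 25 semi-aquatic / 14 fully-aquatic,
    latitudes uniform on 0–80°, Pagel's λ = 0.5 and regression coefficients
    taken from the fitted per-environment desaturation-vs-latitude lines
    (intercepts 2.27 / −1.34 / 1.62 and slopes 0.02 / 0.06 / −0.01 for
    fully-aquatic / semi-aquatic / terrestrial).  σ² is the Brownian rate per
    unit branch length; on a Yule tree of height ≈ ln(n_tips) the default
    gives a tip-level residual SD near 1.1.  Hair densities (hairs/mm²) are
    log-normal across the observed range from sparsely furred pinnipeds to
    dense-furred otters and rodents.
    """

    seed: int = 0
    n_tips: int = 54
    birth_rate: float = 1.0
    env_proportions: tuple[float, float, float] = (15 / 54, 25 / 54, 14 / 54)
    latitude_range: tuple[float, float] = (0.0, 80.0)
    true_lambda: float = 0.5
    sigma2: float = 0.3
    true_beta: tuple[float, ...] | None = None  # on the model spec's columns
    model: ModelSpec = MAIN_SUITE[0]  # interaction model
    polytomy_fraction: float = 0.0
    clade_biased_environments: bool = True
    hair_density_lognormal: tuple[float, float] = (4.0, 1.5)  # (meanlog, sdlog)

    def __post_init__(self) -> None:
        if abs(sum(self.env_proportions) - 1.0) > 1e-9:
            raise ValueError("environment proportions must sum to 1")
        if not 0.0 <= self.true_lambda <= 1.0:
            raise ValueError("true_lambda must lie in [0, 1]")
        if self.sigma2 < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive")


#: interaction-model coefficients on columns
#: [intercept, latitude, env[terrestrial], env[semi_aquatic],
#:  latitude:env[terrestrial], latitude:env[semi_aquatic]]
#: reference level fully-aquatic; values from the per-environment lines above
DEFAULT_INTERACTION_BETA = (2.27, 0.02, 1.62 - 2.27, -1.34 - 2.27, -0.01 - 0.02, 0.06 - 0.02)


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with ``n_tips`` extant species.

    Lineages split at exponential waiting times (rate = birth_rate × number
    alive); after the last split the clock runs one more waiting interval so
    tips have positive terminal branches.  ``polytomy_fraction`` of the
    internal non-root edges are then collapsed (child merged into parent) to
    create multifurcations.  Bit-reproducible from ``config.seed``.
    """
    if config.n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    root.birth_time = 0.0
    active = []
    t = 0.0
    for _ in range(2):
        c = tree.node_factory()
        c.birth_time = 0.0
        root.add_child(c)
        active.append(c)
    while len(active) < config.n_tips:
        t += rng.exponential(1.0 / (config.birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.split_time = t
        for _ in range(2):
            c = tree.node_factory()
            c.birth_time = t
            node.add_child(c)
            active.append(c)
    t += rng.exponential(1.0 / (config.birth_rate * len(active)))
    ns = tree.taxon_namespace
    for i, leaf in enumerate(active):
        leaf.taxon = ns.new_taxon(label=f"sp{i+1:03d}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        end = getattr(node, "split_time", t)
        node.edge.length = end - node.birth_time
    out = PhyloTree(tree)
    if config.polytomy_fraction > 0:
        out = _collapse_edges(out, config.polytomy_fraction, rng)
    return out


def _collapse_edges(tree: PhyloTree, fraction: float, rng: np.random.Generator) -> PhyloTree:
    out = tree.copy()
    internal = [
        nd
        for nd in out._tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    k = int(round(fraction * len(internal)))
    if k == 0:
        return out
    chosen = rng.choice(len(internal), size=min(k, len(internal)), replace=False)
    for idx in sorted(chosen, reverse=True):
        node = internal[idx]
        parent = node.parent_node
        if parent is None:
            continue
        length = node.edge.length or 0.0
        for child in list(node.child_nodes()):
            node.remove_child(child)
            child.edge.length = (child.edge.length or 0.0) + length
            parent.add_child(child)
        parent.remove_child(node)
    return PhyloTree(out._tree)


def _assign_environments(
    tip_order: Sequence[str], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Environment per tip; contiguous blocks of the tree's leaf order when
    clade-biased (related species share environments), i.i.d. otherwise."""
    n = len(tip_order)
    counts = [int(round(p * n)) for p in config.env_proportions]
    counts[-1] = n - sum(counts[:-1])
    if min(counts) < 1:
        raise ValueError("every environment level needs at least one species")
    labels = [lv for lv, c in zip(ENV_LEVELS, counts) for _ in range(c)]
    if not config.clade_biased_environments:
        labels = list(rng.permutation(labels))
    return dict(zip(tip_order, labels))


def simulate_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    response: str = "delta9_di",
) -> tuple[pd.DataFrame, dict]:
    """Trait table with the response drawn from the PGLS generative model.

    y = Xβ + ε with ε ~ MVN(0, σ²·V(λ)), drawn through the Cholesky factor
    of the λ-transformed VCV.  Returns (records, truth) where ``truth``
    records the generating β, λ, σ² and per-column names for recovery tests.
    Trees with polytomies must be resolved before simulation.
    """
    if not tree.is_binary:
        raise ValueError("resolve polytomies before simulating traits")
    rng = np.random.default_rng(config.seed + 1)
    taxa = tree.tip_labels
    n = len(taxa)
    env = _assign_environments(taxa, config, rng)
    lat = rng.uniform(*config.latitude_range, size=n)
    records = pd.DataFrame(
        {
            "species": taxa,
            "environment": [env[t] for t in taxa],
            "latitude": lat,
        }
    )
    meanlog, sdlog = config.hair_density_lognormal
    hair = np.where(
        records["environment"] == "semi_aquatic",
        rng.lognormal(meanlog, sdlog, size=n),
        np.nan,
    )
    records["hair_density"] = hair
    records["log_hair_density"] = np.log(hair)
    # pinnipeds stand in for the sparsely furred semi-aquatic species
    records["pinniped"] = (records["environment"] == "semi_aquatic") & (
        records["hair_density"] < np.exp(meanlog)
    )
    records["blubber_section"] = np.where(
        records["environment"] == "terrestrial", "white_adipose", "outer"
    )

    X, names = build_design_matrix(records, config.model)
    beta = np.asarray(
        config.true_beta
        if config.true_beta is not None
        else DEFAULT_INTERACTION_BETA[: X.shape[1]],
        dtype=float,
    )
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"true_beta has {beta.shape[0]} entries but the design has "
            f"{X.shape[1]} columns ({names})"
        )
    _, V = tree.vcv(order=taxa)
    Vl = apply_lambda(V, config.true_lambda)
    if config.sigma2 > 0:
        L = linalg.cholesky(config.sigma2 * Vl, lower=True)
        eps = L @ rng.standard_normal(n)
    else:
        eps = np.zeros(n)
    records[response] = X @ beta + eps
    truth = {
        "beta": dict(zip(names, beta.tolist())),
        "lambda": config.true_lambda,
        "sigma2": config.sigma2,
        "model": config.model.name,
        "response": response,
        "seed": config.seed,
    }
    return records, truth


def simulate_fa_profiles(
    records: pd.DataFrame, config: SimulationConfig
) -> list[FAProfile]:
    """FA composition profiles whose indices equal each record's targets.

    Mass (summing to 100 wt%) is split into the three index SFAs, the five
    index MUFAs and a PUFA block; the SFA/MUFA split fixes the Δ9-DI exactly
    (it is their ratio), Dirichlet noise inside each block leaves both
    indices untouched (all MUFAs carry one double bond, all SFAs none), and
    the PUFA block is apportioned between a 2-double-bond and a high-bond FA
    to land the DBI exactly.  Raises :class:`ProfileError` with the feasible
    DBI range when a (Δ9-DI, DBI) pair cannot be realised on the panel.
    """
    rng = np.random.default_rng(config.seed + 2)
    profiles: list[FAProfile] = []
    for rec in records.itertuples():
        di = float(rec.delta9_di)
        dbi = float(rec.dbi)
        if di < 0:
            raise ProfileError(f"{rec.species}: target Δ9-DI must be ≥ 0, got {di}")
        solution = None
        for pufa_total in np.linspace(5.0, 60.0, 56):
            sfa_total = (100.0 - pufa_total) / (1.0 + di)
            mufa_total = di * sfa_total
            needed = 100.0 * dbi - mufa_total  # double bonds owed by PUFAs
            lo, hi = 2.0 * pufa_total, 6.0 * pufa_total
            if lo - 1e-9 <= needed <= hi + 1e-9:
                f = float(np.clip((needed - lo) / (hi - lo), 0.0, 1.0))
                solution = (sfa_total, mufa_total, pufa_total, f)
                break
        if solution is None:
            raise ProfileError(
                f"{rec.species}: no FA composition on the panel gives Δ9-DI={di:g} "
                f"with DBI={dbi:g}; with PUFA mass P ∈ [5, 60] the feasible DBI range "
                f"is [(Δ9-DI·S + 2P)/100, (Δ9-DI·S + 6P)/100] with S = (100−P)/(1+Δ9-DI)"
            )
        sfa_total, mufa_total, pufa_total, f = solution
        weights: dict[str, float] = {}
        sfa_split = rng.dirichlet(np.full(len(DELTA9_SFAS), 3.0))
        for lab, w in zip(DELTA9_SFAS, sfa_split):
            weights[lab] = sfa_total * w
        mufa_split = rng.dirichlet(np.full(len(DELTA9_MUFAS), 2.0))
        for lab, w in zip(DELTA9_MUFAS, mufa_split):
            weights[lab] = mufa_total * w
        # PUFA block: mix 18:2ω6 (x=2) and 22:6ω3 (x=6) to hit the DBI;
        # the other panel PUFAs stay at zero mass so the DBI is exact
        weights["18:2ω6"] = pufa_total * (1.0 - f)
        weights["22:6ω3"] = pufa_total * f
        weights["20:4ω6"] = 0.0
        weights["20:5ω3"] = 0.0
        profiles.append(
            FAProfile(
                species=str(rec.species),
                weights=weights,
                section=getattr(rec, "blubber_section", "unknown"),
            )
        )
    return profiles
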