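"""Seeded generators for pathway networks, profiles and pseudo-score tables.

Everything here is synthetic plumbing: it lets the whole pipeline be
exercised and validated without any external pathway database or
expression dataset. Generated networks are layered (genes -> complexes ->
abstracts) and therefore acyclic by construction, which keeps planted
ground truth unambiguous; an optional flag adds feedback edges for solver
stress tests. Generation is a pure function of the spec: the same spec
always produces byte-identical serialisations (integer-state RNG, no
float-ordering dependence). No attempt is made to mimic curated pathway
degree distributions.

The module also ships the small Wnt planar-cell-polarity toy pathway (two
ligand/receptor component-complexes, WNT5A/FZD7 and WNT3A/FZD1, both
activating one signalling abstract) together with its three canonical
expression scenarios, used throughout the examples and tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .boolean_ilp import ModelConfig, OPTIMAL, brute_force_min
from .expression_io import ExpressionProfile
from .pathway_io import (
    ABSTRACT,
    COMPLEX,
    GENE,
    Entity,
    Interaction,
    PathwayNetwork,
)

__all__ = [
    "SyntheticSpec",
    "PlantedFixture",
    "generate_network",
    "generate_profiles",
    "plant_essential",
    "generate_scores",
    "toy_pathway",
    "toy_profiles",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scenario.

    expressed_fraction defaults to 0.7: most genes detected as expressed,
    as is typical of binarised bulk expression over pathway genes.
    """

    seed: int = 0
    n_genes: int = 6
    n_complexes: int = 3
    n_abstracts: int = 2
    p_member: float = 0.3
    p_inhibition: float = 0.1
    expressed_fraction: float = 0.7
    n_samples: int = 5

    def __post_init__(self) -> None:
        for name in ("p_member", "p_inhibition", "expressed_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_complexes > 0 and self.n_genes < 2:
            raise ValueError("complexes need at least 2 genes to draw from")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def generate_network(
    spec: SyntheticSpec,
    name: str | None = None,
    with_cycles: bool = False,
) -> PathwayNetwork:
    """Generate a layered random pathway.

    Genes feed complexes through 2-4 component edges; abstracts draw 1-4
    parents from the gene+complex pool, the first guaranteed to be a
    member or activation edge so every abstract is reachable from at least
    one gene. ``with_cycles`` adds activation back-edges between abstracts
    (no ground-truth claims are made for cyclic networks).
    """
    rng = random.Random(spec.seed)
    genes = [f"G{j:03d}" for j in range(1, spec.n_genes + 1)]
    complexes = [f"CPX{j:02d}" for j in range(1, spec.n_complexes + 1)]
    abstracts = [f"ABS{j:02d}" for j in range(1, spec.n_abstracts + 1)]

    entities = (
        [Entity(g, GENE) for g in genes]
        + [Entity(c, COMPLEX) for c in complexes]
        + [Entity(a, ABSTRACT) for a in abstracts]
    )
    interactions: list[Interaction] = []
    for cpx in complexes:
        k = rng.randint(2, min(4, spec.n_genes))
        for g in rng.sample(genes, k):
            interactions.append(Interaction(g, cpx, "component"))
    pool = genes + complexes
    for abstract in abstracts:
        k = rng.randint(1, min(4, len(pool)))
        parents = rng.sample(pool, k)
        for j, parent in enumerate(parents):
            if rng.random() < spec.p_member:
                relation = "member"
            elif rng.random() < spec.p_inhibition:
                relation = "inhibition"
            else:
                relation = "activation"
            if j == 0 and relation == "inhibition":
                relation = "activation"  # keep the abstract activatable
            interactions.append(Interaction(parent, abstract, relation))
    if with_cycles and len(abstracts) >= 2:
        for a, b in zip(abstracts, abstracts[1:] + abstracts[:1]):
            interactions.append(Interaction(a, b, "activation"))
    return PathwayNetwork(name or f"synthetic_{spec.seed}", entities, interactions)


def generate_profiles(
    spec: SyntheticSpec, network: PathwayNetwork
) -> list[ExpressionProfile]:
    """One binary profile per sample; each gene expressed independently."""
    rng = random.Random(spec.seed * 1_000_003 + 17)
    profiles = []
    for s in range(1, spec.n_samples + 1):
        status = {
            g: int(rng.random() < spec.expressed_fraction) for g in network.genes
        }
        profiles.append(ExpressionProfile(f"S{s:03d}", status))
    return profiles


@dataclass(frozen=True)
class PlantedFixture:
    """A network + profile with a provably essential planted gene."""

    network: PathwayNetwork
    profile: ExpressionProfile
    gene: str
    target_active: str
    expected_delta: int


def plant_essential(
    k_alternative_cost: int,
    decoy: bool = True,
    name: str = "planted",
    config: ModelConfig = ModelConfig(),
) -> PlantedFixture:
    """Construct a fixture whose planted gene is essential with known cost.

    Two routes activate the output abstract: route A is a complex whose
    sole component is the planted expressed gene; route B is a complex
    requiring ``k_alternative_cost`` lowly expressed genes (plus, when
    ``decoy`` is set, one expressed decoy gene whose own knockout is
    harmless because route A remains). Knocking out the planted gene
    therefore raises the minimum from 0 to exactly ``k_alternative_cost``
    for the abstract. The expected delta is confirmed against the
    enumeration oracle before the fixture is returned.
    """
    if k_alternative_cost < 1:
        raise ValueError("k_alternative_cost must be >= 1")
    k = k_alternative_cost
    target = "TARGET"
    lows = [f"LOW{j:02d}" for j in range(1, k + 1)]
    genes = [target] + lows + (["DECOY"] if decoy else [])
    entities = (
        [Entity(g, GENE) for g in genes]
        + [Entity("ROUTE_A", COMPLEX), Entity("ROUTE_B", COMPLEX)]
        + [Entity("OUTPUT", ABSTRACT)]
    )
    interactions = [Interaction(target, "ROUTE_A", "component")]
    for g in lows + (["DECOY"] if decoy else []):
        interactions.append(Interaction(g, "ROUTE_B", "component"))
    interactions += [
        Interaction("ROUTE_A", "OUTPUT", "activation"),
        Interaction("ROUTE_B", "OUTPUT", "activation"),
    ]
    network = PathwayNetwork(name, entities, interactions)
    status = {target: 1, **{g: 0 for g in lows}}
    if decoy:
        status["DECOY"] = 1
    profile = ExpressionProfile(f"{name}_sample", status)

    # confirm the planted delta with the independent enumeration oracle
    lowly = frozenset(lows)
    wild = brute_force_min(network, lowly, "OUTPUT", None, config)
    knocked = brute_force_min(network, lowly, "OUTPUT", target, config)
    assert wild.status == OPTIMAL and knocked.status == OPTIMAL
    delta = knocked.objective_value - wild.objective_value
    if delta != k:
        raise AssertionError(
            f"planted fixture delta {delta} does not match requested {k}"
        )
    return PlantedFixture(network, profile, target, "OUTPUT", k)


def generate_scores(
    calls: pd.DataFrame, noise: float, seed: int
) -> pd.DataFrame:
    """Pseudo dependency scores matched to binary calls.

    ``calls`` is a tidy (gene, sample, c) table. Essential pairs draw from
    a normal centred at -1.0, non-essential at 0.0, both with the given
    noise SD, so the conventional -0.5 ground-truth cutoff separates the
    groups exactly when noise is 0. Synthetic stand-in for an external
    dependency screen; lower = more essential.
    """
    rng = np.random.default_rng(seed)
    centre = np.where(calls["c"].astype(int) == 1, -1.0, 0.0)
    score = centre + rng.normal(0.0, noise, size=len(calls)) if noise > 0 else centre
    return pd.DataFrame(
        {
            "gene": calls["gene"].to_numpy(),
            "sample": calls["sample"].to_numpy(),
            "score": score,
        }
    )


# -- the Wnt toy fixture ---------------------------------------------------

TOY_PATHWAY_NAME = "wnt_pcp_toy"

_TOY_TEXT = """\
gene\tWNT5A
gene\tFZD7
gene\tWNT3A
gene\tFZD1
complex\tWNT5A/FZD7
complex\tWNT3A/FZD1
abstract\tWNT_PCP_PATHWAY
WNT5A\tWNT5A/FZD7\tcomponent>
FZD7\tWNT5A/FZD7\tcomponent>
WNT3A\tWNT3A/FZD1\tcomponent>
FZD1\tWNT3A/FZD1\tcomponent>
WNT5A/FZD7\tWNT_PCP_PATHWAY\t-a>
WNT3A/FZD1\tWNT_PCP_PATHWAY\t-a>
"""

#: gene expression of the three canonical scenarios (FZD7/FZD1 always expressed)
_TOY_SCENARIOS: Mapping[str, Mapping[str, int]] = {
    "A": {"WNT5A": 0, "FZD7": 1, "WNT3A": 0, "FZD1": 1},
    "B": {"WNT5A": 0, "FZD7": 1, "WNT3A": 1, "FZD1": 1},
    "C": {"WNT5A": 1, "FZD7": 1, "WNT3A": 0, "FZD1": 1},
}


def toy_pathway() -> PathwayNetwork:
    """The Wnt planar-cell-polarity toy pathway (7 entities, 6 interactions)."""
    from .pathway_io import parse_pathway

    return parse_pathway(_TOY_TEXT, name=TOY_PATHWAY_NAME)


def toy_profiles() -> dict[str, ExpressionProfile]:
    """The three canonical scenarios: A (both WNTs low), B (WNT3A expressed), C (WNT5A expressed)."""
    return {
        label: ExpressionProfile(f"scenario_{label}", dict(status))
        for label, status in _TOY_SCENARIOS.items()
    }
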