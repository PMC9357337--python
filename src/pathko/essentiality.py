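"""The knockout-screening pipeline and the Essentiality Congruity Score.

For one sample and one pathway the screen proceeds per forced active *a*
(every complex and abstract of the pathway): solve the wild-type instance
to obtain ``S_a_wild`` — the minimum number of lowly expressed genes that
must be active to sustain *a* — then fix each expressed gene *g* to zero in
turn and re-solve for ``S_a_g``. Gene *g* is called essential for (p, a)
when ``S_a_g > S_a_wild`` (an infeasible knockout counts as infinity: the
active cannot be sustained at any cost). Lowly expressed genes are never
knockout candidates. Actives whose wild-type instance is already
infeasible yield no calls.

Binary calls aggregate by maximum: a gene is essential for a pathway if it
is essential for any of its actives, and essential overall if essential in
any pathway containing it. The Essentiality Congruity Score (ECS) softens
this max into the fraction of essentiality predictions that called the
gene essential, over the actives that produced at least one essentiality
prediction, across all pathways containing the gene; it lives in [0, 1]
and is 1 exactly when every such prediction was essential.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .boolean_ilp import INFEASIBLE, OPTIMAL, IlpSolution, ModelConfig, build_problem, solve
from .expression_io import ExpressionProfile, partition_genes
from .pathway_io import PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EssentialityCall",
    "scan_pathway",
    "scan_pathways",
    "aggregate_gene",
    "compute_ecs",
    "ecs_table",
    "threshold_ecs",
    "classify_global",
    "calls_to_frame",
    "write_calls",
    "read_calls",
]

INF_TOKEN = "Inf"

DenominatorMode = Literal["predicted", "literal"]
ActivesMode = Literal["all_genes", "per_gene"]


@dataclass(frozen=True)
class EssentialityCall:
    """One (gene, pathway, active) knockout outcome.

    ``c = 1`` iff the knockout objective strictly exceeds the wild-type
    objective (infinity exceeds any finite value).
    """

    gene: str
    pathway: str
    active: str
    s_wild: float
    s_knockout: float
    c: int

    def __post_init__(self) -> None:
        if self.s_knockout < self.s_wild:
            raise ValueError(
                f"knockout objective {self.s_knockout} below wild-type "
                f"{self.s_wild} for {self.gene} in {self.pathway}/{self.active}"
            )
        expected = int(self.s_knockout > self.s_wild)
        if self.c != expected:
            raise ValueError(
                f"inconsistent call c={self.c} for s_wild={self.s_wild}, "
                f"s_knockout={self.s_knockout}"
            )


def _objective(solution: IlpSolution) -> float:
    return math.inf if solution.status == INFEASIBLE else float(solution.objective_value)


def scan_pathway(
    network: PathwayNetwork,
    profile: ExpressionProfile,
    config: ModelConfig = ModelConfig(),
) -> list[EssentialityCall]:
    """Exhaustive single-gene knockout screen of one pathway for one sample."""
    expressed, lowly = partition_genes(profile, network)
    calls: list[EssentialityCall] = []
    for active in network.actives:
        wild = solve(build_problem(network, lowly, active, None, config))
        if wild.status != OPTIMAL:
            logger.info(
                "%s/%s: wild-type infeasible, no calls emitted",
                network.name,
                active,
            )
            continue
        s_wild = float(wild.objective_value)
        for gene in sorted(expressed):
            sol = solve(build_problem(network, lowly, active, gene, config))
            s_ko = _objective(sol)
            calls.append(
                EssentialityCall(
                    gene=gene,
                    pathway=network.name,
                    active=active,
                    s_wild=s_wild,
                    s_knockout=s_ko,
                    c=int(s_ko > s_wild),
                )
            )
    return calls


def scan_pathways(
    networks: Iterable[PathwayNetwork],
    profile: ExpressionProfile,
    config: ModelConfig = ModelConfig(),
) -> list[EssentialityCall]:
    """Screen every pathway independently and concatenate the calls."""
    calls: list[EssentialityCall] = []
    for network in networks:
        calls.extend(scan_pathway(network, profile, config))
    return calls


def aggregate_gene(
    calls: Sequence[EssentialityCall], gene: str
) -> tuple[dict[str, int], int]:
    """Per-pathway and overall binary essentiality of one gene (max over calls).

    A gene with zero calls aggregates to 0.
    """
    per_pathway: dict[str, int] = {}
    for call in calls:
        if call.gene != gene:
            continue
        per_pathway[call.pathway] = max(per_pathway.get(call.pathway, 0), call.c)
    c_g = max(per_pathway.values(), default=0)
    return per_pathway, c_g


def _predicted_actives(
    calls: Sequence[EssentialityCall], gene: str | None
) -> dict[str, set[str]]:
    """Per pathway, the actives with >= 1 essentiality prediction.

    With ``gene=None`` a prediction by any gene counts (all-genes reading);
    otherwise only the named gene's own essential calls count.
    """
    bar: dict[str, set[str]] = {}
    for call in calls:
        if call.c == 1 and (gene is None or call.gene == gene):
            bar.setdefault(call.pathway, set()).add(call.active)
    return bar


def compute_ecs(
    calls: Sequence[EssentialityCall],
    gene: str,
    denominator: DenominatorMode = "predicted",
    actives_mode: ActivesMode = "all_genes",
) -> float:
    """Essentiality Congruity Score of one gene from one sample's calls.

    The numerator counts the gene's essential calls over actives with at
    least one essentiality prediction, summed over the pathways containing
    the gene. With ``denominator="predicted"`` (default) the denominator is
    the total count of those predicted actives, so a gene essential in
    every prediction scores exactly 1; ``"literal"`` divides by the total
    number of screened actives instead. ``actives_mode`` selects whether an
    active counts as predicted when any gene was essential there
    (``"all_genes"``, default) or only the scored gene (``"per_gene"``).
    Returns 0 when the denominator is empty.
    """
    own = [c for c in calls if c.gene == gene]
    if not own:
        return 0.0
    pathways = {c.pathway for c in own}
    bar = _predicted_actives(calls, None if actives_mode == "all_genes" else gene)
    numerator = sum(
        c.c for c in own if c.active in bar.get(c.pathway, set())
    )
    if denominator == "predicted":
        denom = sum(len(bar.get(p, set())) for p in pathways)
    elif denominator == "literal":
        all_actives: dict[str, set[str]] = {}
        for c in calls:
            all_actives.setdefault(c.pathway, set()).add(c.active)
        denom = sum(len(all_actives.get(p, set())) for p in pathways)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return numerator / denom if denom else 0.0


def ecs_table(
    calls: Sequence[EssentialityCall],
    sample_id: str,
    denominator: DenominatorMode = "predicted",
    actives_mode: ActivesMode = "all_genes",
) -> pd.DataFrame:
    """Per-gene ECS, binary call and prediction count for one sample.

    Columns: gene, ecs, c_g, n_predictions; one row per knockout candidate
    observed in the calls, sorted by gene.
    """
    genes = sorted({c.gene for c in calls})
    rows = []
    for gene in genes:
        _, c_g = aggregate_gene(calls, gene)
        ecs = compute_ecs(calls, gene, denominator, actives_mode)
        n_pred = sum(1 for c in calls if c.gene == gene)
        rows.append((gene, ecs, c_g, n_pred))
    frame = pd.DataFrame(rows, columns=["gene", "ecs", "c_g", "n_predictions"])
    frame.insert(0, "sample", sample_id)
    return frame


def threshold_ecs(table: pd.DataFrame, th: float) -> pd.Series:
    """Binary essentiality calls at an ECS threshold: ``c = 1`` iff ecs > th.

    At ``th = 0`` this reproduces the plain max aggregation.
    """
    if not 0.0 <= th < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {th}")
    calls = (table["ecs"] > th).astype(int)
    calls.index = pd.Index(table["gene"], name="gene")
    calls.name = "c"
    return calls


def classify_global(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Classify genes across samples from a tidy (gene, sample, c) table.

    A gene absent from a sample's calls counts as not essential there.
    Returns a frame (gene, label) with labels ``globally_essential``
    (c = 1 in every sample), ``globally_not_essential`` (c = 0 in every
    sample) or ``context_dependent``; the first two classes are the ones
    conventionally excluded from downstream comparisons.
    """
    required = {"gene", "sample", "c"}
    if not required.issubset(per_sample.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    wide = (
        per_sample.pivot_table(index="gene", columns="sample", values="c", fill_value=0)
        .astype(int)
    )
    labels = []
    for gene, row in wide.iterrows():
        if (row == 1).all():
            label = "globally_essential"
        elif (row == 0).all():
            label = "globally_not_essential"
        else:
            label = "context_dependent"
        labels.append((gene, label))
    return pd.DataFrame(labels, columns=["gene", "label"])


# -- serialisation ---------------------------------------------------------


def calls_to_frame(
    calls: Sequence[EssentialityCall], sample_id: str
) -> pd.DataFrame:
    """Tidy call table (sample, pathway, active, gene, s_wild, s_knockout, c)."""
    rows = [
        (sample_id, c.pathway, c.active, c.gene, c.s_wild, c.s_knockout, c.c)
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "pathway", "active", "gene", "s_wild", "s_knockout", "c"],
    )


def _fmt_objective(value: float) -> str:
    return INF_TOKEN if math.isinf(value) else str(int(value))


def write_calls(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a call table as CSV with infinity serialised as ``Inf``."""
    out = frame.copy()
    for col in ("s_wild", "s_knockout"):
        out[col] = out[col].map(_fmt_objective)
    out.to_csv(path, index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    frame = pd.read_csv(path, dtype={"s_wild": str, "s_knockout": str})
    for col in ("s_wild", "s_knockout"):
        frame[col] = frame[col].map(
            lambda v: math.inf if v == INF_TOKEN else float(v)
        )
    return frame
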