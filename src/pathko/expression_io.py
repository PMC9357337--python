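"""Binary expression profiles and the expressed / lowly-expressed partition.

The essentiality model consumes *pre-binarized* expression: each measured
gene is either expressed (1) or lowly expressed (0) in a sample. Genes that
appear in a pathway but are not measured in the profile are treated as
expressed — they impose no cost on the optimisation and remain knockout
candidates. Continuous expression is rejected; discretisation is an
upstream modelling choice, though :func:`binarize_expression` offers a
simple cutoff utility for convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .pathway_io import PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "ExpressionFormatError",
    "read_expression",
    "write_expression",
    "profiles_to_frame",
    "partition_genes",
    "invert_profile",
    "binarize_expression",
]

_INVERSION_SUFFIX = ":inverted"


class ExpressionFormatError(ValueError):
    """The expression table violates the binary gene x sample contract."""


@dataclass(frozen=True)
class ExpressionProfile:
    """Binary expressed/lowly-expressed status of measured genes in one sample.

    ``status[g] == 1`` means expressed, ``0`` lowly expressed. Genes absent
    from ``status`` are unmeasured and default to expressed downstream.
    """

    sample_id: str
    status: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.status.items():
            if value not in (0, 1):
                raise ExpressionFormatError(
                    f"sample {self.sample_id!r}, gene {gene!r}: "
                    f"status must be 0 or 1, got {value!r}"
                )

    @property
    def expressed(self) -> frozenset[str]:
        return frozenset(g for g, v in self.status.items() if v == 1)

    @property
    def lowly_expressed(self) -> frozenset[str]:
        return frozenset(g for g, v in self.status.items() if v == 0)

    def __len__(self) -> int:
        return len(self.status)


def read_expression(source: str | Path) -> list[ExpressionProfile]:
    """Read a tab-separated binary gene x sample matrix.

    First column holds gene symbols, header row holds sample ids, cells are
    0/1. Empty cells and NA tokens mark unmeasured genes (they are dropped
    from the profile, with a logged count). Gzip input is handled
    transparently by pandas. Raises :class:`ExpressionFormatError` on
    non-binary cells (with coordinates) and on duplicate gene rows.
    """
    df = pd.read_csv(source, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ExpressionFormatError(f"duplicate gene rows: {sorted(set(dup))}")
    profiles = []
    for sample in df.columns:
        col = df[sample]
        measured = col.dropna()
        n_missing = len(col) - len(measured)
        if n_missing:
            logger.info(
                "sample %s: %d unmeasured genes (treated as expressed)",
                sample,
                n_missing,
            )
        status: dict[str, int] = {}
        for gene, value in measured.items():
            if value not in (0, 1):
                raise ExpressionFormatError(
                    f"non-binary value {value!r} at gene {gene!r}, "
                    f"sample {sample!r}"
                )
            status[str(gene)] = int(value)
        profiles.append(ExpressionProfile(str(sample), status))
    return profiles


def profiles_to_frame(profiles: Iterable[ExpressionProfile]) -> pd.DataFrame:
    """Assemble profiles into a gene x sample matrix (NA = unmeasured)."""
    cols = {p.sample_id: pd.Series(dict(p.status), dtype="float") for p in profiles}
    frame = pd.DataFrame(cols).sort_index()
    return frame.astype("Int64")


def write_expression(profiles: Iterable[ExpressionProfile], path: str | Path) -> None:
    """Write profiles as a tab-separated binary matrix."""
    profiles_to_frame(profiles).to_csv(path, sep="\t")


def partition_genes(
    profile: ExpressionProfile, network: PathwayNetwork
) -> tuple[frozenset[str], frozenset[str]]:
    """Split a pathway's gene entities into expressed (G) and lowly expressed (L).

    Unmeasured genes fall into G; G is exactly the knockout-candidate set.
    The partition is exhaustive and disjoint over the network's genes.
    """
    lowly = frozenset(
        g for g in network.genes if profile.status.get(g, 1) == 0
    )
    expressed = frozenset(network.genes) - lowly
    return expressed, lowly


def invert_profile(profile: ExpressionProfile) -> ExpressionProfile:
    """Flip every status 0<->1 ("nonsense data" control experiment).

    The sample id is suffixed to mark the inversion; inverting twice
    restores the original profile (involution).
    """
    if profile.sample_id.endswith(_INVERSION_SUFFIX):
        sample_id = profile.sample_id[: -len(_INVERSION_SUFFIX)]
    else:
        sample_id = profile.sample_id + _INVERSION_SUFFIX
    return ExpressionProfile(
        sample_id, {g: 1 - v for g, v in profile.status.items()}
    )


def binarize_expression(values: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Threshold a continuous gene x sample matrix: value > cutoff -> 1.

    Off by default in every pipeline entry point; binarisation strategy is a
    consequential upstream choice best made with a dedicated method.
    """
    return (values > cutoff).astype(int)
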