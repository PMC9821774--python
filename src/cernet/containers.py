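"""Core in-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: The three RNA classes of the tripartite network.
RNA_CLASSES = ("circRNA", "miRNA", "mRNA")


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of raw counts for one RNA class in one tissue.

    Parameters
    ----------
    counts
        DataFrame with unique feature IDs as the index and unique sample IDs
        as columns; values must be nonnegative integers.
    rna_class
        One of ``circRNA``, ``miRNA``, ``mRNA``.
    tissue
        Tissue label the samples were taken from.
    """

    counts: pd.DataFrame
    rna_class: str
    tissue: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ConfigurationError(
                f"unknown rna_class {self.rna_class!r}; expected one of {RNA_CLASSES}"
            )
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ConfigurationError(f"duplicate feature ID {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ConfigurationError(f"duplicate sample ID {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ConfigurationError("counts must be numeric")
        if (values < 0).any():
            raise ConfigurationError("counts must be nonnegative")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ConfigurationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GroundTruth:
    """Ledger of planted structure written by the simulator.

    ``planted_de`` holds ``(rna_class, feature_id, direction)`` triples,
    ``planted_triads`` holds ``(circ_id, mirna_id, mrna_id)`` triples, and
    ``planted_interactions`` the miRNA->target edges that carry true
    regulation (two per triad).
    """

    planted_de: set[tuple[str, str, str]] = field(default_factory=set)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    planted_interactions: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        de_keys = {(cls, fid) for cls, fid, _ in self.planted_de}
        inter = set(self.planted_interactions)
        for circ, mi, mrna in self.planted_triads:
            if ("circRNA", circ) not in de_keys or ("mRNA", mrna) not in de_keys:
                raise ConfigurationError(
                    f"triad ({circ}, {mi}, {mrna}) members missing from planted_de"
                )
            if (mi, circ, "circRNA") not in inter or (mi, mrna, "mRNA") not in inter:
                raise ConfigurationError(
                    f"triad ({circ}, {mi}, {mrna}) edges missing from planted_interactions"
                )

    def to_dict(self) -> dict:
        return {
            "planted_de": sorted(list(t) for t in self.planted_de),
            "planted_triads": [list(t) for t in self.planted_triads],
            "planted_interactions": [list(t) for t in self.planted_interactions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_de={tuple(t) for t in d.get("planted_de", [])},
            planted_triads=[tuple(t) for t in d.get("planted_triads", [])],
            planted_interactions=[tuple(t) for t in d.get("planted_interactions", [])],
        )
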