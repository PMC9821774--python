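"""Study design: tissues x two conditions x replicates.

The default design mirrors a three-tissue (hypothalamus, pituitary,
mammary gland), two-condition (non-heat-stress NHS vs heat-stress HS)
experiment with three biological replicates per condition, i.e. 18
libraries in total. Sample identifiers follow the
``<condition>_<tissue-initial><replicate>`` convention (``NHS_H1`` ...
``HS_M3``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidDesignError

DEFAULT_TISSUES = ("hypothalamus", "pituitary", "mammary_gland")
DEFAULT_CONDITIONS = ("NHS", "HS")


@dataclass(frozen=True)
class StudyDesign:
    """Immutable description of the sample layout.

    ``conditions`` lists the control condition first; fold changes are
    reported as treatment over control.
    """

    tissues: tuple[str, ...]
    conditions: tuple[str, str]
    replicates_per_condition: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tissues) == 0:
            raise InvalidDesignError("at least one tissue is required")
        if len(set(self.tissues)) != len(self.tissues):
            raise InvalidDesignError("tissue labels must be unique")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise InvalidDesignError("exactly two distinct conditions are required")
        if self.replicates_per_condition < 2:
            raise InvalidDesignError(
                f"replicates_per_condition must be >= 2, got {self.replicates_per_condition}"
            )

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * 2 * self.replicates_per_condition

    def tissue_codes(self) -> dict[str, str]:
        """Short per-tissue codes used in sample IDs.

        The first letter (upper-cased) of each tissue label; if two tissues
        collide on their initial the full capitalized label is used instead.
        """
        initials = [t[0].upper() for t in self.tissues]
        codes = {}
        for tissue, initial in zip(self.tissues, initials):
            codes[tissue] = initial if initials.count(initial) == 1 else tissue.capitalize()
        return codes

    def samples(self, tissue: str) -> pd.DataFrame:
        """Sample metadata table for one tissue.

        Columns: ``sample_id``, ``tissue``, ``condition``, ``replicate``.
        Control samples come first, replicates in ascending order.
        """
        if tissue not in self.tissues:
            raise InvalidDesignError(f"unknown tissue {tissue!r}")
        code = self.tissue_codes()[tissue]
        rows = [
            {
                "sample_id": f"{cond}_{code}{rep}",
                "tissue": tissue,
                "condition": cond,
                "replicate": rep,
            }
            for cond in self.conditions
            for rep in range(1, self.replicates_per_condition + 1)
        ]
        return pd.DataFrame(rows)

    def sample_table(self) -> pd.DataFrame:
        """Metadata for every sample in the design, all tissues stacked."""
        return pd.concat([self.samples(t) for t in self.tissues], ignore_index=True)

    def condition_of(self, sample_ids) -> pd.Series:
        """Map sample IDs to their condition labels."""
        table = self.sample_table().set_index("sample_id")["condition"]
        missing = [s for s in sample_ids if s not in table.index]
        if missing:
            raise InvalidDesignError(f"samples not in design: {missing[:5]}")
        return table.loc[list(sample_ids)]


@dataclass
class MetadataDesign:
    """Design adapter backed by an explicit sample-metadata table.

    Used when inputs come from files rather than the simulator; provides
    the same grouping interface (``control``, ``treatment``,
    ``condition_of``) the DE functions need, without requiring a balanced
    replicate grid.
    """

    metadata: pd.DataFrame
    conditions: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise InvalidDesignError("exactly two distinct conditions are required")
        present = set(self.metadata["condition"])
        missing = set(self.conditions) - present
        if missing:
            raise InvalidDesignError(f"conditions {sorted(missing)} absent from metadata")

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.metadata["tissue"]))

    def condition_of(self, sample_ids) -> pd.Series:
        table = self.metadata.set_index("sample_id")["condition"]
        missing = [s for s in sample_ids if s not in table.index]
        if missing:
            raise InvalidDesignError(f"samples not in metadata: {missing[:5]}")
        return table.loc[list(sample_ids)]


def generate_design(
    tissues=DEFAULT_TISSUES,
    conditions=DEFAULT_CONDITIONS,
    replicates: int = 3,
    seed: int = 0,
) -> StudyDesign:
    """Build a :class:`StudyDesign`; deterministic given its arguments."""
    return StudyDesign(
        tissues=tuple(tissues),
        conditions=tuple(conditions),
        replicates_per_condition=int(replicates),
        seed=int(seed),
    )
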