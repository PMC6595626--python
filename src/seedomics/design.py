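"""Sample/stage design shared by the expression and metabolite tables.

A germination time course covers six stages: dry seed (1), rapid imbibition
(2), slow water uptake (3), hypocotyl extension (4), cotyledon unfolding (5)
and true-leaf unfolding (6). Samples are named ``S<stage>R<replicate>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

N_STAGES = 6

_SAMPLE_RE = re.compile(r"^S(\d+)R(\d+)$")


class DesignError(ValueError):
    """Raised when a sample design violates the time-course layout."""


@dataclass(frozen=True)
class StageDesign:
    """Mapping of sample ids to germination stages.

    Parameters
    ----------
    stage_of_sample:
        Ordered mapping ``sample id -> stage index`` (1-based).
    """

    stage_of_sample: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.stage_of_sample)) != len(self.stage_of_sample):
            raise DesignError("sample ids must be unique")
        for stage in range(1, N_STAGES + 1):
            if len(self.samples_for_stage(stage)) < 2:
                raise DesignError(
                    f"stage {stage} has fewer than 2 replicates"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.stage_of_sample)

    @property
    def stages(self) -> list[int]:
        return sorted(set(self.stage_of_sample.values()))

    def samples_for_stage(self, stage: int) -> list[str]:
        return [s for s, g in self.stage_of_sample.items() if g == stage]

    @property
    def n_samples(self) -> int:
        return len(self.stage_of_sample)

    @classmethod
    def balanced(cls, replicates_per_stage: int) -> "StageDesign":
        """Six-stage balanced design with ``replicates_per_stage`` each."""
        if replicates_per_stage < 2:
            raise DesignError("replicates_per_stage must be >= 2")
        mapping = {
            f"S{stage}R{rep}": stage
            for stage in range(1, N_STAGES + 1)
            for rep in range(1, replicates_per_stage + 1)
        }
        return cls(mapping)

    @classmethod
    def from_sample_ids(cls, sample_ids: list[str]) -> "StageDesign":
        """Parse a design from ``S<stage>R<rep>`` column names."""
        mapping: dict[str, int] = {}
        for sid in sample_ids:
            m = _SAMPLE_RE.match(sid)
            if m is None:
                raise DesignError(f"cannot parse stage from sample id {sid!r}")
            mapping[sid] = int(m.group(1))
        return cls(mapping)
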