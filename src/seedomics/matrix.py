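"""Omics table containers: expression and metabolite matrices plus design."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import DesignError, StageDesign


@dataclass
class ExpressionMatrix:
    """FPKM-scale gene x sample abundance table with its stage design.

    ``data`` rows are genes, columns are sample ids; all values must be
    non-negative (FPKM is a normalized fragment count).
    """

    data: pd.DataFrame
    design: StageDesign

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if list(self.data.columns) != self.design.samples:
            raise DesignError("sample columns do not match design")
        if (self.data.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def stage_means(self) -> pd.DataFrame:
        """Per-gene arithmetic mean per stage (original scale), 6 columns."""
        cols = {
            stage: self.data[self.design.samples_for_stage(stage)].mean(axis=1)
            for stage in self.design.stages
        }
        return pd.DataFrame(cols)


@dataclass
class MetaboliteTable:
    """Metabolite x sample abundances plus pathway wiring and enzyme roles.

    ``enzyme_map`` has columns gene_id, metabolite_id, role
    (synthesis/decomposition); ``pathway_edges`` lists unordered pairs of
    pathway-adjacent metabolites.
    """

    data: pd.DataFrame
    design: StageDesign
    enzyme_map: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "metabolite_id", "role"]
        )
    )
    pathway_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("metabolite ids must be unique")
        if list(self.data.columns) != self.design.samples:
            raise DesignError("sample columns do not match design")
        if (self.data.values <= 0).any():
            raise ValueError("metabolite abundances must be positive")
        known = set(self.data.index)
        for a, b in self.pathway_edges:
            if a not in known or b not in known:
                raise ValueError(f"pathway edge ({a}, {b}) references unknown metabolite")

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.index)

    def stage_means(self) -> pd.DataFrame:
        cols = {
            stage: self.data[self.design.samples_for_stage(stage)].mean(axis=1)
            for stage in self.design.stages
        }
        return pd.DataFrame(cols)
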