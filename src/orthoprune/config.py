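"""Per-dataset cutoff presets and run configuration.

The three presets carry the published cutoff sets of the example
datasets they are named after: a deeply diverged invertebrate dataset
(MIL-like, divergences beyond 400 Ma), an intermediate insect dataset
(HYM-like), and a recently diverged plant dataset analysed on coding
sequence (GRP-like).  Deeper datasets tolerate longer branches before
a cut, hence the larger cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .homolog_refine import RefinementConfig
from .ortholog_prune import PruneConfig

__all__ = ["DatasetPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class DatasetPreset:
    """Every numeric knob of the pipeline for one dataset style."""

    name: str
    char_type: str  # "aa" | "nt"
    # similarity filtering / clustering
    hit_fraction: float = 0.4
    evalue_cutoff: float = 1e-5
    min_seq_length: int = 40
    min_taxa: int = 8
    # homolog refinement
    internal_branch_cutoff: float = 1.0
    tip_absolute_cutoff: float = 0.6
    tip_relative_factor: float = 10.0
    # MI-stage remainder trimming (stricter tip cutoff)
    mi_tip_absolute_cutoff: float = 0.3
    # ortholog extraction
    min_ingroup_taxa: Optional[int] = None
    # alignment trimming / matrix filters
    homolog_clean: float = 0.1
    ortholog_clean: float = 0.3
    min_locus_length: int = 100
    max_missing_taxa: int = 0
    # jackknife designs used in the published analyses
    jackknife_replicates: int = 200
    jackknife_proportions: tuple[float, ...] = (0.1, 0.3)
    jackknife_count: int = 20

    def refinement(self) -> RefinementConfig:
        return RefinementConfig(
            internal_branch_cutoff=self.internal_branch_cutoff,
            tip_absolute_cutoff=self.tip_absolute_cutoff,
            tip_relative_factor=self.tip_relative_factor,
            min_subtree_taxa=self.min_taxa,
        )

    def mi_tip_trim(self) -> RefinementConfig:
        return replace(
            self.refinement(), tip_absolute_cutoff=self.mi_tip_absolute_cutoff
        )

    def pruning(self) -> PruneConfig:
        return PruneConfig(
            min_taxa=self.min_taxa,
            min_ingroup_taxa=self.min_ingroup_taxa,
            mi_tip_trim=self.mi_tip_trim(),
        )


PRESETS: dict[str, DatasetPreset] = {
    "MIL-like": DatasetPreset(
        name="MIL-like",
        char_type="aa",
        internal_branch_cutoff=1.5,
        tip_absolute_cutoff=0.75,
        mi_tip_absolute_cutoff=0.4,
        min_ingroup_taxa=6,
        min_locus_length=100,
        max_missing_taxa=1,
    ),
    "HYM-like": DatasetPreset(
        name="HYM-like",
        char_type="aa",
        internal_branch_cutoff=1.0,
        tip_absolute_cutoff=0.6,
        mi_tip_absolute_cutoff=0.3,
        min_locus_length=100,
        max_missing_taxa=0,
    ),
    "GRP-like": DatasetPreset(
        name="GRP-like",
        char_type="nt",
        internal_branch_cutoff=0.3,
        tip_absolute_cutoff=0.1,
        mi_tip_absolute_cutoff=0.1,
        min_locus_length=300,
        max_missing_taxa=0,
    ),
}


def get_preset(name: str, **overrides) -> DatasetPreset:
    """Fetch a preset by name (``custom`` starts from neutral defaults)."""
    if name == "custom":
        base = DatasetPreset(name="custom", char_type="aa")
    else:
        try:
            base = PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; choose from "
                f"{sorted(PRESETS) + ['custom']}"
            ) from None
    return replace(base, **overrides) if overrides else base
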