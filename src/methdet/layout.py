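"""Physical layout of the 56-gene CpG-island methylation array.

Each slide carries three identical 8x8 subarrays. Within a subarray,
56 spots are gene CpG-island probes, 3 carry positive-control DNA,
2 carry hybridization-control DNA (nonspecific-binding reference) and
3 positions are left empty to measure background fluorescence.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Optional, Tuple


class SpotRole(str, Enum):
    GENE = "gene_probe"
    POSITIVE = "positive_control"
    HYB = "hybridization_control"
    EMPTY = "empty"


#: Canonical gene set: the 21 differentially-methylated genes plus placeholder
#: names for the remaining probes of the 56-gene panel (their identities are
#: defined by the assay design, not by this analysis).
def default_gene_ids() -> Tuple[str, ...]:
    from .tables import TABLE1_GENES  # local import avoids a cycle

    nulls = tuple(f"PROBE{i:02d}" for i in range(len(TABLE1_GENES) + 1, 57))
    return tuple(TABLE1_GENES) + nulls


@dataclass(frozen=True)
class ArrayLayout:
    """Spot-role map shared by all subarrays of a slide.

    Roles are assigned in row-major order within a subarray: gene probes
    first, then positive controls, hybridization controls, and empty spots
    filling the remainder of the grid.
    """

    genes: Tuple[str, ...]
    n_subarrays: int = 3
    n_rows: int = 8
    n_cols: int = 8
    n_positive: int = 3
    n_hyb: int = 2

    def __post_init__(self) -> None:
        per_sub = self.n_rows * self.n_cols
        reserved = self.n_positive + self.n_hyb
        if len(self.genes) + reserved >= per_sub:
            raise ValueError(
                f"layout capacity exceeded: {len(self.genes)} gene probes plus "
                f"{reserved} control spots do not leave an empty spot in a "
                f"{self.n_rows}x{self.n_cols} subarray"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in layout")

    @property
    def spots_per_subarray(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_spots(self) -> int:
        return self.n_subarrays * self.spots_per_subarray

    @property
    def n_empty(self) -> int:
        return self.spots_per_subarray - len(self.genes) - self.n_positive - self.n_hyb

    def spot_role(self, index: int) -> Tuple[SpotRole, Optional[str]]:
        """Role of the row-major position ``index`` within one subarray."""
        if not 0 <= index < self.spots_per_subarray:
            raise IndexError(index)
        n_g = len(self.genes)
        if index < n_g:
            return SpotRole.GENE, self.genes[index]
        if index < n_g + self.n_positive:
            return SpotRole.POSITIVE, None
        if index < n_g + self.n_positive + self.n_hyb:
            return SpotRole.HYB, None
        return SpotRole.EMPTY, None

    def iter_spots(self) -> Iterator[Tuple[int, int, int, SpotRole, Optional[str]]]:
        """Yield (subarray, row, col, role, gene_id) over the whole slide."""
        for sub in range(self.n_subarrays):
            for idx in range(self.spots_per_subarray):
                role, gene = self.spot_role(idx)
                yield sub, idx // self.n_cols, idx % self.n_cols, role, gene

    def role_counts(self) -> dict:
        """Per-subarray role composition."""
        return {
            SpotRole.GENE: len(self.genes),
            SpotRole.POSITIVE: self.n_positive,
            SpotRole.HYB: self.n_hyb,
            SpotRole.EMPTY: self.n_empty,
        }


def default_layout(genes: Optional[Tuple[str, ...]] = None) -> ArrayLayout:
    """The 3 x (8 x 8) slide with 56 gene probes per subarray."""
    return ArrayLayout(genes=tuple(genes) if genes is not None else default_gene_ids())
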