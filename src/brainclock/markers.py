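"""Cell-type marker sets and their overlap with age-regulated genes.

Marker lists (e.g. top-100 cell-type-enriched genes) are inputs, one list
per cell type. Astrocyte, oligodendrocyte, and microglia sets pool into a
single glial category; overlaps with the age up/down gene sets are reported
as Venn partition counts plus an upper-tail hypergeometric enrichment p
(the test is an addition on top of the descriptive counts). The background
universe is the set of genes tested in the age screen, not the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import scipy.stats

__all__ = [
    "MarkerSet",
    "OverlapResult",
    "combine_glial",
    "venn_counts",
    "overlap_test",
    "read_marker_dir",
]

GLIAL_TYPES = ("astrocyte", "oligodendrocyte", "microglia")


@dataclass(frozen=True)
class MarkerSet:
    """A labeled set of marker gene IDs (duplicates collapse)."""

    label: str
    genes: frozenset

    @classmethod
    def from_list(cls, label: str, genes) -> "MarkerSet":
        return cls(label, frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    size_a: int
    size_b: int
    intersection: int
    background: int
    p: float


def combine_glial(sets: dict[str, MarkerSet]) -> MarkerSet:
    """Union of the astrocyte, oligodendrocyte and microglia marker sets."""
    missing = [t for t in GLIAL_TYPES if t not in sets]
    if missing:
        raise KeyError(f"missing marker sets: {missing}")
    genes = frozenset().union(*(sets[t].genes for t in GLIAL_TYPES))
    return MarkerSet("glial", genes)


def venn_counts(set_a, set_b) -> tuple[int, int, int]:
    """(only-A, intersection, only-B) partition counts."""
    a = set_a.genes if isinstance(set_a, MarkerSet) else frozenset(set_a)
    b = set_b.genes if isinstance(set_b, MarkerSet) else frozenset(set_b)
    inter = len(a & b)
    return len(a) - inter, inter, len(b) - inter


def overlap_test(set_a, set_b, background) -> OverlapResult:
    """Upper-tail hypergeometric p for an intersection at least this large.

    Both sets must be subsets of the background universe. The p-value is
    P(X >= k) for X hypergeometric(|background|, |A|, |B|).
    """
    a = set_a.genes if isinstance(set_a, MarkerSet) else frozenset(set_a)
    b = set_b.genes if isinstance(set_b, MarkerSet) else frozenset(set_b)
    bg = frozenset(background)
    if not a <= bg or not b <= bg:
        raise ValueError("marker/age sets must be subsets of the background")
    k = len(a & b)
    p = float(scipy.stats.hypergeom.sf(k - 1, len(bg), len(a), len(b)))
    return OverlapResult(len(a), len(b), k, len(bg), min(p, 1.0))


def read_marker_dir(path) -> dict[str, MarkerSet]:
    """Read ``<celltype>.txt`` files (one gene ID per line) from a directory."""
    path = Path(path)
    sets: dict[str, MarkerSet] = {}
    for f in sorted(path.glob("*.txt")):
        genes = [line.strip() for line in f.read_text().splitlines() if line.strip()]
        sets[f.stem] = MarkerSet.from_list(f.stem, genes)
    if not sets:
        raise FileNotFoundError(f"no marker files (*.txt) in {path}")
    return sets
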