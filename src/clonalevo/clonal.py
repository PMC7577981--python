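"""Clonal composition, diversity and evolution-pattern classification.

A subclone is a distinct cellular population carrying at least one mutation:
a tree node with assigned cells, labeled by the set of events on its root
path.  Wild-type cells (attached at the root) are excluded from subclone
fractions.  Diversity is the Shannon index in bits over subclone fractions.
Evolution patterns follow the usual single-cell AML reading: a tree whose
surviving events form a single path — allowing one terminal fork whose
children are all leaves — is linear; anything else is branching; a branching
tree with two functionally redundant events (same gene, or same pathway under
a supplied map) on disjoint branches is additionally convergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylogeny import AttachmentPosterior
from .tree import MutationTree, ROOT

# Driver-gene -> pathway groupings customary for AML amplicon panels.
DEFAULT_PATHWAY_MAP = {
    "NPM1": "nucleophosmin",
    "DNMT3A": "DNA methylation", "TET2": "DNA methylation",
    "IDH1": "DNA methylation", "IDH2": "DNA methylation",
    "FLT3": "RTK/RAS/MAPK", "FLT3-ITD": "RTK/RAS/MAPK",
    "NRAS": "RTK/RAS/MAPK", "KRAS": "RTK/RAS/MAPK",
    "PTPN11": "RTK/RAS/MAPK", "KIT": "RTK/RAS/MAPK", "MYC": "RTK/RAS/MAPK",
    "JAK2": "JAK-STAT",
    "RUNX1": "transcription factor", "GATA2": "transcription factor",
    "ETV6": "transcription factor", "CEBPA": "transcription factor",
    "WT1": "transcription factor",
    "ASXL1": "chromatin/cohesin", "EZH2": "chromatin/cohesin",
    "STAG2": "chromatin/cohesin", "BCOR": "chromatin/cohesin",
    "SRSF2": "splicing", "SF3B1": "splicing", "U2AF1": "splicing",
    "ZRSR2": "splicing",
    "TP53": "apoptosis", "PPM1D": "apoptosis",
}


@dataclass
class Subclone:
    node: int
    mutations: tuple[str, ...]
    cell_count: float
    fraction: float  # among mutated cells
    ci_low: float
    ci_high: float
    below_threshold: bool


@dataclass
class ClonalComposition:
    """Subclones of one sample (per timepoint), wild-type cells excluded."""

    subclones: list[Subclone]
    wt_cell_count: float
    min_clone_fraction: float
    timepoint: str | None = None
    tree: MutationTree | None = None

    @property
    def n_subclones(self) -> int:
        return len(self.subclones)

    def fractions(self, include_flagged: bool = True) -> np.ndarray:
        fr = np.array([
            s.fraction for s in self.subclones
            if include_flagged or not s.below_threshold
        ])
        return fr

    def surviving_events(self) -> set[int]:
        """Events carried by at least one (unflagged) subclone."""
        out: set[int] = set()
        for s in self.subclones:
            if not s.below_threshold and self.tree is not None:
                out.update(self.tree.root_path(s.node))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "clone_id": f"clone{s.node}",
                "mutations": ",".join(s.mutations),
                "cell_count": s.cell_count,
                "fraction": s.fraction,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "below_threshold": s.below_threshold,
            }
            for s in self.subclones
        ])


@dataclass
class EvolutionCall:
    pattern: str  # "linear" | "branching"
    convergent: bool
    branch_points: tuple[int, ...] = ()
    convergent_units: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pattern not in ("linear", "branching"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.convergent and self.pattern != "branching":
            raise ValueError("convergent evolution implies a branching pattern")


def compose_clones(
    attachment: AttachmentPosterior,
    threshold: float = 0.01,
) -> ClonalComposition:
    """Clonal composition from an attachment posterior.

    Each tree node with assigned cells becomes a subclone whose mutation set
    is the node's root path in the reporting (MAP) tree.  Fractions are among
    mutated cells; credible intervals come from the per-draw assigned-cell
    counts.  Subclones below ``threshold`` are retained but flagged (they are
    excluded from downstream association analysis).
    """
    tree = attachment.tree
    point = attachment.point
    n_mutated = float(point[1:].sum())
    subclones = []
    for v in range(1, len(point)):
        if point[v] <= 0:
            continue
        frac = point[v] / n_mutated
        subclones.append(Subclone(
            node=v,
            mutations=tuple(tree.labels[u - 1] for u in tree.root_path(v)),
            cell_count=float(point[v]),
            fraction=float(frac),
            ci_low=float(attachment.ci_low[v]),
            ci_high=float(attachment.ci_high[v]),
            below_threshold=bool(frac < threshold),
        ))
    return ClonalComposition(
        subclones=subclones,
        wt_cell_count=float(point[0]),
        min_clone_fraction=threshold,
        timepoint=attachment.timepoint,
        tree=tree,
    )


def shannon_index(composition: ClonalComposition | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i log2 p_i over subclone fractions (bits).

    Fractions are renormalized to sum to 1; a single clone gives exactly 0 and
    k equal clones give exactly log2 k.
    """
    if isinstance(composition, ClonalComposition):
        fr = composition.fractions()
    else:
        fr = np.asarray(composition, dtype=float)
    fr = fr[fr > 0]
    if fr.size == 0:
        raise ValueError("empty clonal composition")
    p = fr / fr.sum()
    return float(-(p * np.log2(p)).sum())


def _gene_of(label: str) -> str:
    """Gene symbol from an event label like 'IDH1 p.R132H' or 'RUNX1:LOH'."""
    return label.split(":")[0].split()[0].split("_")[0]


def classify_evolution(
    tree: MutationTree,
    composition: ClonalComposition | None = None,
    pathway_map: dict[str, str] | None = None,
    strict_linear: bool = False,
) -> EvolutionCall:
    """Classify the evolution pattern of a clonal tree.

    The tree is first restricted to events carried by at least one surviving
    subclone (when a composition is given).  The pattern is linear iff the
    restricted tree has at most one branch point and — unless
    ``strict_linear`` — all of that branch point's children are leaves (a
    terminal fork); otherwise branching.  A branching tree is additionally
    convergent when two events hitting the same gene (or, with
    ``pathway_map``, the same pathway) sit on disjoint branches, i.e. neither
    is an ancestor of the other.
    """
    if tree.n_events < 1:
        raise ValueError("tree must carry at least one event")
    if composition is not None and composition.tree is not None:
        keep = composition.surviving_events()
    else:
        keep = set(range(1, tree.n_events + 1))
    if not keep:
        raise ValueError("no surviving events to classify")

    # contract the tree onto the kept events: each kept event's parent is its
    # nearest kept ancestor (or the root)
    def kept_parent(v: int) -> int:
        u = tree.parent[v - 1]
        while u != ROOT and u not in keep:
            u = tree.parent[u - 1]
        return u

    children: dict[int, list[int]] = {ROOT: []}
    for v in sorted(keep):
        children.setdefault(v, [])
        children.setdefault(kept_parent(v), []).append(v)

    branch_points = [v for v, ch in children.items() if len(ch) >= 2]
    if len(branch_points) == 0:
        pattern = "linear"
    elif len(branch_points) == 1 and not strict_linear:
        bp = branch_points[0]
        terminal = all(len(children[c]) == 0 for c in children[bp])
        pattern = "linear" if terminal else "branching"
    else:
        pattern = "branching"

    convergent = False
    units: list[str] = []
    if pattern == "branching":
        unit_of = {}
        for v in keep:
            gene = _gene_of(tree.labels[v - 1])
            unit_of[v] = (pathway_map or {}).get(gene, gene) if pathway_map else gene
        by_unit: dict[str, list[int]] = {}
        for v, u in unit_of.items():
            by_unit.setdefault(u, []).append(v)
        for unit, nodes in by_unit.items():
            for a in range(len(nodes)):
                for b in range(a + 1, len(nodes)):
                    u, v = nodes[a], nodes[b]
                    if not tree.is_ancestor(u, v) and not tree.is_ancestor(v, u):
                        convergent = True
                        units.append(unit)
        units = sorted(set(units))
    return EvolutionCall(
        pattern=pattern,
        convergent=convergent,
        branch_points=tuple(sorted(branch_points)),
        convergent_units=tuple(units),
    )


def prevalence_matrix(
    compositions: dict[str, ClonalComposition]
) -> pd.DataFrame:
    """Timepoints x clones prevalence table (fishplot-ready)."""
    clones = sorted({
        s.node for comp in compositions.values() for s in comp.subclones
    })
    rows = {}
    for label, comp in compositions.items():
        frac = {s.node: s.fraction for s in comp.subclones}
        rows[label] = [frac.get(c, 0.0) for c in clones]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"clone{c}" for c in clones]
    )
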