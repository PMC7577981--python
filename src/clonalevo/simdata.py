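"""Synthetic single-cell genotype data with the error structure of targeted
amplicon scDNA-seq.

The generator produces a ground-truth clonal tree, per-clone prevalences,
true per-cell genotypes, and two layers of observation: noisy genotype calls
(false positives, allele dropout, missing entries, optional doublets) and raw
read counts (negative-binomial depth, allele-level dropout, base errors).
Defaults mirror a typical AML amplicon panel run: a handful to a few dozen
driver loci, thousands of cells, ~5.8% allele dropout, 1% false-positive rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import GenotypeMatrix, ReadCountMatrix, WT, HET, HOM, MISSING
from .tree import MutationTree

# Cohort-scale defaults: median per-amplicon-per-cell coverage ~48x, median
# allele dropout 5.8%, sequencing false-positive rate ~1%.
DEFAULT_MEAN_DEPTH = 48.0
DEFAULT_ADO = 0.058
DEFAULT_FPR = 0.01

LOH_SUFFIX = ":LOH"


@dataclass
class SimulationTruth:
    """Ground truth of one simulated sample (or longitudinal series)."""

    tree: MutationTree
    clone_fractions: np.ndarray  # (n_timepoints, n_nodes), node 0 = wild type
    error_params: dict = field(default_factory=dict)
    loh_events: tuple[tuple[int, int], ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.clone_fractions = np.atleast_2d(np.asarray(self.clone_fractions, dtype=float))
        if self.clone_fractions.shape[1] != self.tree.n_nodes:
            raise ValueError("clone_fractions must cover every node incl. root")
        if not np.allclose(self.clone_fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("clone fractions must sum to 1 per timepoint")
        for locus, node in self.loh_events:
            _check_loh_event(self.tree, locus, node)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "parent": list(self.tree.parent),
            "labels": list(self.tree.labels),
            "clone_fractions": self.clone_fractions.tolist(),
            "error_params": self.error_params,
            "loh_events": [list(e) for e in self.loh_events],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            tree=MutationTree(tuple(doc["parent"]), tuple(doc["labels"])),
            clone_fractions=np.asarray(doc["clone_fractions"]),
            error_params=doc["error_params"],
            loh_events=tuple((int(a), int(b)) for a, b in doc["loh_events"]),
            seed=doc["seed"],
        )


def _check_loh_event(tree: MutationTree, locus: int, node: int) -> None:
    if not (1 <= locus <= tree.n_events and 1 <= node <= tree.n_events):
        raise ValueError("loh event indices out of range")
    if node == locus or not tree.is_ancestor(locus, node):
        raise ValueError(
            f"LOH node {node} must be a strict descendant of the node carrying "
            f"the heterozygous mutation ({locus})"
        )


def simulate_tree(n_mutations: int, seed: int | None = None) -> MutationTree:
    """Draw a random recursive tree over ``n_mutations`` events.

    Node j's parent is uniform on {root, 1, ..., j-1}; mutation labels are
    then assigned to nodes by a uniform permutation so the law is
    label-exchangeable.  This gives a simple null with closed-form topology
    probabilities: for two events the fork has probability 1/2 and each of
    the two chains 1/4.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    parent = [int(rng.integers(0, j)) for j in range(1, n_mutations + 1)]
    sigma = [0] + list(1 + rng.permutation(n_mutations))
    permuted = [0] * n_mutations
    for v in range(1, n_mutations + 1):
        permuted[sigma[v] - 1] = sigma[parent[v - 1]]
    return MutationTree(tuple(permuted))


def add_loh_node(
    tree: MutationTree, locus: int, parent_node: int
) -> tuple[MutationTree, tuple[int, int]]:
    """Append a dedicated LOH node for ``locus`` below ``parent_node``.

    The new node carries no new mutation; cells at or below it are homozygous
    at ``locus``.  ``parent_node`` must be the node carrying the heterozygous
    mutation or one of its descendants, so that the het state strictly
    precedes the hom state.
    """
    if parent_node != locus and not tree.is_ancestor(locus, parent_node):
        raise ValueError("LOH must arise at or below the heterozygous mutation node")
    new_parent = tree.parent + (parent_node,)
    new_labels = tree.labels + (f"{tree.labels[locus - 1]}{LOH_SUFFIX}",)
    new_tree = MutationTree(new_parent, new_labels)
    event = (locus, new_tree.n_events)
    _check_loh_event(new_tree, *event)
    return new_tree, event


def locus_nodes(tree: MutationTree) -> list[int]:
    """Event nodes that carry a mutation of their own (excludes LOH nodes)."""
    return [
        j for j in range(1, tree.n_events + 1)
        if not tree.labels[j - 1].endswith(LOH_SUFFIX)
    ]


def simulate_clone_fractions(
    tree: MutationTree,
    dirichlet_alpha: float = 1.0,
    wt_fraction: float = 0.05,
    n_timepoints: int = 1,
    drift: float = 0.0,
    seed: int | None = None,
    selection_strength: float = 1.0,
) -> np.ndarray:
    """Clone prevalences per node and timepoint, summing to 1 per timepoint.

    Mutated-node masses are a symmetric Dirichlet(``dirichlet_alpha``) draw
    rescaled to ``1 - wt_fraction``.  ``selection_strength`` > 1 weights each
    clone's mass by ``s ** depth``, emulating cumulative fitness gains of
    successive drivers (deep clones expand); at the default 1 the draw is
    neutral.  Successive timepoints are perturbed by logistic-normal noise of
    scale ``drift`` (``drift = 0`` replicates the first timepoint).
    """
    if not 0 <= wt_fraction < 1:
        raise ValueError("wt_fraction must be in [0, 1)")
    if dirichlet_alpha <= 0 or drift < 0 or selection_strength <= 0:
        raise ValueError("invalid dirichlet_alpha, drift or selection_strength")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    n = tree.n_events
    mass = rng.gamma(dirichlet_alpha, size=n)
    mass *= selection_strength ** tree.node_depths()[1:]
    mass = mass / mass.sum() * (1.0 - wt_fraction)
    base = np.concatenate([[wt_fraction], mass])

    out = np.empty((n_timepoints, n + 1))
    out[0] = base
    for t in range(1, n_timepoints):
        if drift == 0:
            out[t] = out[t - 1]
            continue
        logm = np.log(np.clip(out[t - 1], 1e-300, None))
        logm += rng.normal(0.0, drift, size=n + 1)
        w = np.exp(logm - logm.max())
        out[t] = w / w.sum()
    return out


def genotypes_from_tree(
    tree: MutationTree,
    fractions: np.ndarray,
    n_cells: int,
    loh_events: Sequence[tuple[int, int]] = (),
    seed: int | None = None,
    return_assignments: bool = False,
):
    """True genotypes of ``n_cells`` cells sampled from the clonal tree.

    Each cell is attached multinomially to a node by ``fractions`` (one row of
    prevalences over all nodes incl. root).  Its genotype at a locus is HET iff
    the mutation node is an ancestor-or-self of its attachment and no LOH event
    for that locus is, HOM iff an LOH event node is ancestor-or-self, else WT.
    No missing codes are produced.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (tree.n_nodes,):
        raise ValueError("fractions must give one prevalence per node")
    for locus, node in loh_events:
        _check_loh_event(tree, locus, node)
    rng = np.random.default_rng(seed)
    nodes = rng.choice(tree.n_nodes, size=n_cells, p=fractions / fractions.sum())

    A = tree.ancestor_matrix()  # (nodes, events)
    loci = locus_nodes(tree)
    codes = np.where(A[:, [j - 1 for j in loci]], HET, WT).astype(np.int8)
    for locus, node in loh_events:
        col = loci.index(locus)
        hom_nodes = A[:, node - 1]  # nodes at/below the LOH event
        codes[hom_nodes, col] = HOM
    matrix = GenotypeMatrix(
        codes[nodes], locus_ids=tuple(tree.labels[j - 1] for j in loci)
    )
    if return_assignments:
        return matrix, nodes
    return matrix


def _per_locus(rate, n_loci: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(rate, dtype=float), (n_loci,)).copy()
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def add_observation_noise(
    truth: GenotypeMatrix,
    fpr: float = DEFAULT_FPR,
    fnr=DEFAULT_ADO,
    missing_rate=0.0,
    doublet_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Overlay genotype-level observation noise on a true matrix.

    Binary mode (no HOM codes): true 0 flips to 1 with probability ``fpr``;
    true 1 flips to 0 with the per-locus ``fnr``.  Zygosity mode (HOM codes
    present): a heterozygous call loses one allele with total probability
    ``fnr`` — half the time the alternate allele (observed WT), half the time
    the reference (observed HOM); homozygous calls carry two alternate copies
    and are left intact.  Entries are then set to missing independently with
    the per-locus ``missing_rate``.  With probability ``doublet_rate`` a cell
    is a multiplet: its true row is replaced by the elementwise maximum of its
    own and another random cell's row before noise.
    """
    if not 0 <= fpr <= 1 or not 0 <= doublet_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    fnr_j = _per_locus(fnr, truth.n_loci, "fnr")
    miss_j = _per_locus(missing_rate, truth.n_loci, "missing_rate")
    rng = np.random.default_rng(seed)

    codes = truth.codes.copy()
    if doublet_rate > 0:
        is_doublet = rng.random(truth.n_cells) < doublet_rate
        partners = rng.integers(0, truth.n_cells, size=truth.n_cells)
        codes[is_doublet] = np.maximum(codes[is_doublet], truth.codes[partners[is_doublet]])

    u = rng.random(codes.shape)
    out = codes.copy()
    out[(codes == WT) & (u < fpr)] = HET
    if truth.binary_view:
        out[(codes == HET) & (u < fnr_j)] = WT
    else:
        half = fnr_j / 2.0
        het = codes == HET
        out[het & (u < half)] = WT
        out[het & (u >= half) & (u < fnr_j)] = HOM
    out[rng.random(codes.shape) < miss_j] = MISSING
    return GenotypeMatrix(
        out, cell_ids=truth.cell_ids, locus_ids=truth.locus_ids,
        sample_id=truth.sample_id, timepoint=truth.timepoint,
    )


def per_allele_dropout(ado: np.ndarray | float) -> np.ndarray | float:
    """Per-allele dropout probability d matching a platform-style ADO rate.

    Each allele of a heterozygous site drops independently with probability d;
    the site then looks homozygous when exactly one allele remains, i.e. with
    probability 2d(1-d) / (1-d^2) = 2d/(1+d) among non-missing calls.  Solving
    for d gives d = ado / (2 - ado).
    """
    return np.asarray(ado) / (2.0 - np.asarray(ado))


def simulate_read_counts(
    truth: GenotypeMatrix,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    depth_dispersion: float = 5.0,
    ado=DEFAULT_ADO,
    base_error: float = 0.003,
    seed: int | None = None,
    locus_class: Sequence[str] | None = None,
) -> ReadCountMatrix:
    """Raw depth / alt counts consistent with the true genotypes.

    Depth is negative-binomial with the given mean and dispersion (gamma shape
    ``depth_dispersion``; smaller = more overdispersed).  For heterozygous
    entries, each allele drops independently with the per-allele probability
    derived from the target ADO; if both drop the entry has zero depth
    (missing).  Alternate reads are binomial with success probability 0.5
    (both alleles), 1 - base_error (hom, or het with the reference allele
    dropped) or base_error (wt, or het with the alternate allele dropped).
    """
    if mean_depth <= 0 or depth_dispersion <= 0:
        raise ValueError("mean_depth and depth_dispersion must be positive")
    if not 0 <= base_error < 0.5:
        raise ValueError("base_error must lie in [0, 0.5)")
    ado_j = _per_locus(ado, truth.n_loci, "ado")
    d_j = per_allele_dropout(ado_j)
    rng = np.random.default_rng(seed)
    shape = truth.codes.shape

    r = depth_dispersion
    depth = rng.negative_binomial(r, r / (r + mean_depth), size=shape)

    p_alt = np.full(shape, base_error)
    p_alt[truth.codes == HOM] = 1.0 - base_error
    het = truth.codes == HET
    drop_ref = rng.random(shape) < d_j
    drop_alt = rng.random(shape) < d_j
    p_alt[het & ~drop_ref & ~drop_alt] = 0.5
    p_alt[het & drop_ref & ~drop_alt] = 1.0 - base_error
    # het with alt dropped keeps base_error; both dropped -> no template
    depth[het & drop_ref & drop_alt] = 0
    alt = rng.binomial(depth, p_alt)
    return ReadCountMatrix(
        depth, alt, cell_ids=truth.cell_ids, locus_ids=truth.locus_ids,
        locus_class=locus_class, sample_id=truth.sample_id,
    )


def simulate_sample(
    n_mutations: int = 8,
    n_cells: int = 3000,
    dirichlet_alpha: float = 10.0,
    wt_fraction: float = 0.05,
    fpr: float = DEFAULT_FPR,
    ado: float = DEFAULT_ADO,
    missing_rate: float = 0.0,
    doublet_rate: float = 0.0,
    n_timepoints: int = 1,
    drift: float = 0.0,
    seed: int | None = None,
):
    """One-call generator: tree, fractions, true and observed genotypes.

    Returns ``(truth, observed)`` where observed is a list of GenotypeMatrix,
    one per timepoint, and ``truth`` records the tree, prevalences, error
    rates, seed, and per-timepoint node assignments (``truth.error_params``
    holds the rates; assignments are stored on the returned matrices via
    ``truth`` for recovery tests).
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=2 + 2 * n_timepoints)
    tree = simulate_tree(n_mutations, seed=int(child_seeds[0]))
    fractions = simulate_clone_fractions(
        tree, dirichlet_alpha=dirichlet_alpha, wt_fraction=wt_fraction,
        n_timepoints=n_timepoints, drift=drift, seed=int(child_seeds[1]),
    )
    truth = SimulationTruth(
        tree=tree, clone_fractions=fractions,
        error_params={"fpr": fpr, "fnr": ado, "missing_rate": missing_rate,
                      "doublet_rate": doublet_rate},
        seed=seed,
    )
    observed, assignments = [], []
    for t in range(n_timepoints):
        true_gt, nodes = genotypes_from_tree(
            tree, fractions[t], n_cells, seed=int(child_seeds[2 + 2 * t]),
            return_assignments=True,
        )
        obs = add_observation_noise(
            true_gt, fpr=fpr, fnr=ado, missing_rate=missing_rate,
            doublet_rate=doublet_rate, seed=int(child_seeds[3 + 2 * t]),
        )
        obs.timepoint = f"t{t}"
        observed.append(obs)
        assignments.append(nodes)
    truth.error_params["assignments"] = [a.tolist() for a in assignments]
    return truth, observed
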