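"""Bayesian mutation-tree inference from noisy single-cell genotypes.

The observation model is the classic single-cell mutation-tree likelihood:
given a rooted tree T over mutation events and a cell attached at node v, the
cell truly carries exactly the events on the root path of v.  An observed
mutant call at a truly wild-type locus occurs with the false-positive rate
alpha; an observed wild-type call at a truly mutant locus occurs with the
false-negative rate beta_j (allele dropout, optionally locus-specific);
missing entries contribute no likelihood factor.  Cells attach with a uniform
prior over the E + 1 nodes and are marginalized out:

    P(D | T) = prod_c  (1 / (E+1)) * sum_v  prod_j  P(D_cj | E_j(v))

Inference is Metropolis-Hastings over trees (prune-and-reattach, node label
swap, subtree swap) with a uniform tree prior, optionally jointly over the
error rate beta (uniform prior, reflected Gaussian random walk) or over
locus-specific rates beta_j (Gaussian prior centred on the sample-level ADO
estimate, SD 0.002, truncated to [0, 1]).

Four standard model configurations are supported: (1) all cells, beta
learned; (2) all cells, beta fixed to the platform/sample ADO; (3) cells with
complete genotypes only, beta learned; (4) complete cells, beta fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import GenotypeMatrix, WT, HET, HOM, MISSING
from .tree import MutationTree, ROOT, enumerate_parent_vectors

_EPS = 1e-12


@dataclass
class ErrorModel:
    """False-positive / false-negative rates of the genotype observations."""

    fpr: float = 0.01
    fnr: float | np.ndarray = 0.058
    learn_fnr: bool = False
    locus_specific: bool = False
    prior_mean: float | None = None  # sample ADO estimate; default = fnr
    prior_sd: float = 0.002

    def __post_init__(self) -> None:
        fnr = np.asarray(self.fnr, dtype=float)
        if not 0 <= self.fpr <= 1 or ((fnr < 0) | (fnr > 1)).any():
            raise ValueError("error rates must lie in [0, 1]")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.prior_mean is None:
            self.prior_mean = float(np.mean(fnr))

    def fnr_vector(self, n_loci: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.fnr, dtype=float), (n_loci,)).copy()


@dataclass
class McmcConfig:
    """Chain settings for mutation-tree MCMC."""

    chain_length: int = 200_000
    burn_in: float = 0.25
    thinning: int = 10
    n_chains: int = 3
    seed: int | None = None
    model_id: int = 2
    # prune-and-reattach, label swap, subtree swap, error-rate update
    move_weights: tuple[float, float, float, float] = (0.5, 0.2, 0.2, 0.1)
    beta_proposal_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError(f"model_id must be 1-4, got {self.model_id}")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be a fraction in [0, 1)")
        if self.chain_length < 10 or self.thinning < 1 or self.n_chains < 1:
            raise ValueError("invalid chain settings")
        w = np.asarray(self.move_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("move weights must be non-negative and sum > 0")
        self.move_weights = tuple(w / w.sum())

    @property
    def learn_beta(self) -> bool:
        return self.model_id in (1, 3)

    @property
    def complete_cells_only(self) -> bool:
        return self.model_id in (3, 4)


@dataclass
class TreePosterior:
    """Thinned post-burn-in MCMC samples and the MAP tree."""

    trees: list[tuple[int, ...]]
    betas: np.ndarray  # (n_samples, n_loci)
    loglik_trace: np.ndarray
    map_tree: MutationTree
    map_loglik: float
    locus_ids: tuple[str, ...]
    errors: ErrorModel
    config: McmcConfig
    acceptance: dict = field(default_factory=dict)
    psrf: float = float("nan")
    constraints: tuple[tuple[int, int], ...] = ()
    visit_counts: dict | None = None

    @property
    def n_samples(self) -> int:
        return len(self.trees)

    def posterior_mean_beta(self) -> np.ndarray:
        return self.betas.mean(axis=0)


@dataclass
class AttachmentPosterior:
    """Per-cell attachment distributions and subclone-size credible intervals."""

    probs: np.ndarray        # (n_cells, n_nodes) posterior mean attachment
    counts_draws: np.ndarray  # (n_draws, n_nodes) sampled cell counts
    point: np.ndarray        # posterior mean cell count per node
    ci_low: np.ndarray       # 2.5 percentile of counts per node
    ci_high: np.ndarray      # 97.5 percentile
    cell_ids: tuple[str, ...]
    node_labels: tuple[str, ...]  # "root" + event labels
    tree: MutationTree       # MAP tree used for reporting mutation sets
    uninformative_cells: np.ndarray  # all-missing cells (prior attachment)
    timepoint: str | None = None

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]

    def fractions(self, among_mutated: bool = True) -> np.ndarray:
        """Point-estimate node fractions, optionally among mutated cells."""
        pt = self.point.copy()
        total = pt[1:].sum() if among_mutated else pt.sum()
        if total == 0:
            raise ValueError("no mutated cells")
        out = pt / total
        if among_mutated:
            out[0] = 0.0
        return out


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

def _logsumexp(S: np.ndarray) -> np.ndarray:
    m = S.max(axis=1)
    return m + np.log(np.exp(S - m[:, None]).sum(axis=1))


def _ancestor_matrix(parent: tuple[int, ...] | list[int]) -> np.ndarray:
    n = len(parent)
    A = np.zeros((n + 1, n), dtype=float)
    for v in range(1, n + 1):
        path_v, u = [], v
        while u != ROOT:
            path_v.append(u - 1)
            u = parent[u - 1]
        A[v, path_v] = 1.0
    return A


class _LikelihoodEngine:
    """Vectorized tree likelihood with duplicate-row collapsing and per-tree
    memoization (valid while beta is unchanged)."""

    def __init__(self, codes: np.ndarray, alpha: float, marginalize: bool = True):
        if (codes == HOM).any():
            raise ValueError(
                "homozygous codes present: collapse with to_binary() or use "
                "encode_zygosity() for LOH-aware inference"
            )
        self.n_cells, self.n_loci = codes.shape
        rows, self.row_of_cell, counts = np.unique(
            codes, axis=0, return_inverse=True, return_counts=True
        )
        self.counts = counts.astype(float)
        self.is1 = rows == HET
        self.is0 = rows == WT
        self.alpha = float(np.clip(alpha, _EPS, 1 - _EPS))
        self.marginalize = marginalize
        self.log_prior_attach = -math.log(self.n_loci + 1)
        self._memo: dict[tuple[int, ...], float] = {}
        self.beta = None
        self.W = None
        self.const = None

    def set_beta(self, beta_j: np.ndarray) -> None:
        b = np.clip(np.asarray(beta_j, dtype=float), _EPS, 1 - _EPS)
        la, l1a = math.log(self.alpha), math.log1p(-self.alpha)
        lb, l1b = np.log(b), np.log1p(-b)
        self.W = self.is1 * (l1b - la) + self.is0 * (lb - l1a)
        self.const = (self.is1 * la + self.is0 * l1a).sum(axis=1)
        self.beta = b
        self._memo.clear()

    def scores(self, parent) -> np.ndarray:
        """(rows, nodes) per-attachment log-likelihoods."""
        A = _ancestor_matrix(parent)
        return self.const[:, None] + self.W @ A.T

    def cell_scores(self, parent) -> np.ndarray:
        return self.scores(parent)[self.row_of_cell]

    def loglik(self, parent) -> float:
        key = tuple(parent)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        S = self.scores(parent)
        per_row = S.max(axis=1) if not self.marginalize else _logsumexp(S)
        val = float(self.counts @ (per_row + self.log_prior_attach))
        self._memo[key] = val
        return val


def tree_log_likelihood(
    matrix: GenotypeMatrix,
    tree: MutationTree,
    errors: ErrorModel,
    marginalize: bool = True,
) -> float:
    """Log-likelihood of a genotype matrix under a mutation tree.

    Cells attach to the E + 1 nodes with a uniform prior; by default the
    attachment is marginalized (fully Bayesian); ``marginalize=False`` scores
    each cell at its best attachment instead.
    """
    if tree.n_events != matrix.n_loci:
        raise ValueError("tree events must cover all loci")
    engine = _LikelihoodEngine(matrix.codes, errors.fpr, marginalize)
    engine.set_beta(errors.fnr_vector(matrix.n_loci))
    return engine.loglik(tree.parent)


def exhaustive_map(
    matrix: GenotypeMatrix, errors: ErrorModel
) -> tuple[MutationTree, float]:
    """Global MAP tree by exhaustive enumeration (feasible up to ~6 events)."""
    engine = _LikelihoodEngine(matrix.codes, errors.fpr)
    engine.set_beta(errors.fnr_vector(matrix.n_loci))
    best, best_parent = -math.inf, None
    for parent in enumerate_parent_vectors(matrix.n_loci):
        ll = engine.loglik(parent)
        if ll > best + 1e-9 or (abs(ll - best) <= 1e-9 and parent < best_parent):
            best, best_parent = ll, parent
    return MutationTree(best_parent, matrix.locus_ids), best


def enumerate_posterior(
    matrix: GenotypeMatrix, errors: ErrorModel
) -> dict[tuple[int, ...], float]:
    """Exact tree posterior (uniform prior) by enumeration; small E only."""
    engine = _LikelihoodEngine(matrix.codes, errors.fpr)
    engine.set_beta(errors.fnr_vector(matrix.n_loci))
    lls = {p: engine.loglik(p) for p in enumerate_parent_vectors(matrix.n_loci)}
    m = max(lls.values())
    w = {p: math.exp(v - m) for p, v in lls.items()}
    z = sum(w.values())
    return {p: v / z for p, v in w.items()}


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _descendant_set(parent, i) -> set[int]:
    n = len(parent)
    desc = {i}
    # nodes whose root path passes through i
    for v in range(1, n + 1):
        u, path = v, []
        while u != ROOT:
            if u in desc:
                desc.update(path + [v])
                break
            path.append(u)
            u = parent[u - 1]
    return desc


def _is_proper_ancestor(parent, a: int, b: int) -> bool:
    u = parent[b - 1]
    while u != ROOT:
        if u == a:
            return True
        u = parent[u - 1]
    return False


def _satisfies(parent, constraints) -> bool:
    return all(_is_proper_ancestor(parent, m, l) for m, l in constraints)


def _initial_tree(E: int, constraints, rng) -> list[int]:
    parent = [int(rng.integers(0, j)) for j in range(1, E + 1)]
    for m, l in constraints:
        parent[l - 1] = m
        # guard against cycles introduced by constraint rewiring
        if _is_proper_ancestor(parent, l, m):
            parent[m - 1] = ROOT
    if not _satisfies(parent, constraints):
        # fall back: star tree with constrained events chained below their mate
        parent = [ROOT] * E
        for m, l in constraints:
            parent[l - 1] = m
    return parent


def _reflect01(x: float) -> float:
    while x < 0 or x > 1:
        x = -x if x < 0 else 2 - x
    return x


def _chain(engine, E, errors, config, constraints, rng, record_visits):
    parent = _initial_tree(E, constraints, rng)
    beta = errors.fnr_vector(E)
    engine.set_beta(beta)
    cur_ll = engine.loglik(parent)

    learn = config.learn_beta
    w = np.asarray(config.move_weights, dtype=float)
    if not learn:
        w = w.copy()
        w[3] = 0.0
    w = np.cumsum(w / w.sum())

    prior_mu, prior_sd = errors.prior_mean, errors.prior_sd
    burn = int(config.burn_in * config.chain_length)
    trees, betas, trace = [], [], []
    visits: dict[tuple[int, ...], int] = {} if record_visits else None
    best_ll, best_parent = cur_ll, tuple(parent)
    n_prop = np.zeros(4, dtype=int)
    n_acc = np.zeros(4, dtype=int)

    for it in range(config.chain_length):
        u = rng.random()
        kind = int(np.searchsorted(w, u, side="right"))
        n_prop[kind] += 1
        if kind == 3:  # error-rate update
            if errors.locus_specific:
                j = int(rng.integers(0, E))
                prop = beta.copy()
                prop[j] = _reflect01(beta[j] + rng.normal(0, 2 * prior_sd))
                dprior = (
                    (beta[j] - prior_mu) ** 2 - (prop[j] - prior_mu) ** 2
                ) / (2 * prior_sd**2)
            else:
                b = _reflect01(float(beta[0]) + rng.normal(0, config.beta_proposal_sd))
                prop = np.full(E, b)
                dprior = 0.0  # uniform prior on [0, 1]
            engine.set_beta(prop)
            new_ll = engine.loglik(parent)
            if math.log(rng.random() + _EPS) < new_ll - cur_ll + dprior:
                beta, cur_ll = prop, new_ll
                n_acc[3] += 1
            else:
                engine.set_beta(beta)
        else:
            new_parent = None
            if kind == 0:  # prune-and-reattach
                i = int(rng.integers(1, E + 1))
                desc = _descendant_set(parent, i)
                cands = [v for v in range(E + 1) if v not in desc]
                new_parent = parent.copy()
                new_parent[i - 1] = cands[int(rng.integers(0, len(cands)))]
            elif kind == 1 and E >= 2:  # node label swap
                i = int(rng.integers(1, E + 1))
                j = int(rng.integers(1, E))
                j += j >= i
                sigma = list(range(E + 1))
                sigma[i], sigma[j] = j, i
                new_parent = [0] * E
                for v in range(1, E + 1):
                    new_parent[sigma[v] - 1] = sigma[parent[v - 1]]
            elif kind == 2 and E >= 2:  # subtree swap of two non-nested nodes
                i = int(rng.integers(1, E + 1))
                j = int(rng.integers(1, E))
                j += j >= i
                if not (
                    _is_proper_ancestor(parent, i, j)
                    or _is_proper_ancestor(parent, j, i)
                ):
                    new_parent = parent.copy()
                    new_parent[i - 1], new_parent[j - 1] = parent[j - 1], parent[i - 1]
            if new_parent is not None and (
                not constraints or _satisfies(new_parent, constraints)
            ):
                new_ll = engine.loglik(new_parent)
                if math.log(rng.random() + _EPS) < new_ll - cur_ll:
                    parent, cur_ll = new_parent, new_ll
                    n_acc[kind] += 1

        if cur_ll > best_ll + 1e-9 or (
            abs(cur_ll - best_ll) <= 1e-9 and tuple(parent) < best_parent
        ):
            best_ll, best_parent = cur_ll, tuple(parent)
        if it >= burn:
            if visits is not None:
                key = tuple(parent)
                visits[key] = visits.get(key, 0) + 1
            if (it - burn) % config.thinning == 0:
                trees.append(tuple(parent))
                betas.append(beta.copy())
                trace.append(cur_ll)

    rates = {
        name: (n_acc[k] / n_prop[k] if n_prop[k] else float("nan"))
        for k, name in enumerate(
            ["prune_reattach", "label_swap", "subtree_swap", "beta_update"]
        )
    }
    return trees, betas, trace, best_ll, best_parent, rates, visits


def _psrf(traces: list[np.ndarray]) -> float:
    """Potential scale reduction factor on the log-likelihood, split-chain."""
    halves = []
    for t in traces:
        t = np.asarray(t, dtype=float)
        h = len(t) // 2
        if h >= 2:
            halves.extend([t[:h], t[h : 2 * h]])
    if len(halves) < 2:
        return float("nan")
    n = min(len(h) for h in halves)
    chains = np.array([h[:n] for h in halves])
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    return float(math.sqrt((n - 1) / n + B / (n * W)))


def mcmc_infer(
    matrix: GenotypeMatrix,
    errors: ErrorModel | None = None,
    config: McmcConfig | None = None,
    constraints: tuple[tuple[int, int], ...] = (),
    record_visits: bool = False,
) -> TreePosterior:
    """Posterior over mutation trees by Metropolis-Hastings.

    ``constraints`` is a set of (ancestor_event, descendant_event) pairs that
    every sampled tree must respect (used for het-before-hom LOH ordering);
    proposals violating a constraint are rejected.  ``record_visits`` keeps
    per-iteration (unthinned) tree visit counts for diagnostics.
    """
    errors = errors or ErrorModel()
    config = config or McmcConfig()
    matrix = matrix.to_binary() if not matrix.binary_view else matrix
    if config.complete_cells_only:
        matrix = matrix.complete_cells()

    all_missing = (matrix.codes == MISSING).all(axis=0)
    if all_missing.any():
        if constraints:
            raise ValueError(
                "cannot drop uninformative loci while ordering constraints "
                "reference fixed event indices; filter the matrix first"
            )
        dropped = [matrix.locus_ids[j] for j in np.flatnonzero(all_missing)]
        warnings.warn(f"dropping loci with no informative calls: {dropped}")
        keep = ~all_missing
        matrix = GenotypeMatrix(
            matrix.codes[:, keep],
            cell_ids=matrix.cell_ids,
            locus_ids=tuple(np.asarray(matrix.locus_ids, dtype=object)[keep]),
            sample_id=matrix.sample_id,
            timepoint=matrix.timepoint,
        )

    E = matrix.n_loci
    errors = replace(errors, learn_fnr=config.learn_beta)
    rng = np.random.default_rng(config.seed)
    engine = _LikelihoodEngine(matrix.codes, errors.fpr)

    all_trees, all_betas, traces = [], [], []
    best_ll, best_parent = -math.inf, None
    rates_acc, visits_total = [], {}
    for _ in range(config.n_chains):
        chain_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        trees, betas, trace, bll, bp, rates, visits = _chain(
            engine, E, errors, config, tuple(constraints), chain_rng, record_visits
        )
        all_trees.extend(trees)
        all_betas.extend(betas)
        traces.append(np.asarray(trace))
        rates_acc.append(rates)
        if visits:
            for k, v in visits.items():
                visits_total[k] = visits_total.get(k, 0) + v
        if bll > best_ll + 1e-9 or (
            abs(bll - best_ll) <= 1e-9 and (best_parent is None or bp < best_parent)
        ):
            best_ll, best_parent = bll, bp

    acceptance = {}
    for k in rates_acc[0]:
        vals = [r[k] for r in rates_acc if not math.isnan(r[k])]
        acceptance[k] = float(np.mean(vals)) if vals else float("nan")
    return TreePosterior(
        trees=all_trees,
        betas=np.asarray(all_betas),
        loglik_trace=np.concatenate(traces),
        map_tree=MutationTree(best_parent, matrix.locus_ids),
        map_loglik=best_ll,
        locus_ids=matrix.locus_ids,
        errors=errors,
        config=config,
        acceptance=acceptance,
        psrf=_psrf(traces),
        constraints=tuple(constraints),
        visit_counts=visits_total if record_visits else None,
    )


# ---------------------------------------------------------------------------
# Zygosity (LOH) encoding
# ---------------------------------------------------------------------------

def encode_zygosity(
    matrix: GenotypeMatrix, min_hom_fraction: float = 0.0
) -> tuple[GenotypeMatrix, tuple[tuple[int, int], ...]]:
    """Split loci with homozygous calls into mutation + LOH event rows.

    For each locus with at least one homozygous (code 2) call, two binary
    events are created: the mutation event M (observed 1 iff code in {1, 2})
    and the LOH event L (observed 1 iff code == 2); missing propagates to
    both.  Returns the binary matrix and the ordering constraints
    (M_index, L_index), 1-based event indices, requiring M to be a proper
    ancestor of L in every tree.

    ``min_hom_fraction`` optionally suppresses LOH events at loci whose
    homozygous-call fraction (among non-missing calls) is below the given
    value — useful because sporadic dropout produces rare spurious
    homozygous calls at a rate of about half the ADO.
    """
    cols, labels, constraints = [], [], []
    for j in range(matrix.n_loci):
        col = matrix.codes[:, j]
        m = np.where(col == MISSING, MISSING, ((col == HET) | (col == HOM)).astype(np.int8))
        cols.append(m)
        labels.append(matrix.locus_ids[j])
        informative = max(int((col != MISSING).sum()), 1)
        if (col == HOM).any() and (col == HOM).sum() / informative >= min_hom_fraction:
            l = np.where(col == MISSING, MISSING, (col == HOM).astype(np.int8))
            constraints.append((len(cols), len(cols) + 1))
            cols.append(l)
            labels.append(f"{matrix.locus_ids[j]}:LOH")
    binary = GenotypeMatrix(
        np.column_stack(cols), cell_ids=matrix.cell_ids, locus_ids=tuple(labels),
        sample_id=matrix.sample_id, timepoint=matrix.timepoint,
    )
    return binary, tuple(constraints)


# ---------------------------------------------------------------------------
# Cell attachment and longitudinal restriction
# ---------------------------------------------------------------------------

def _allowed_nodes(parent, allowed_events: set[int] | None, E: int) -> np.ndarray:
    """Boolean mask over nodes; a node is allowed iff no event on its root
    path (inclusive) lies outside ``allowed_events``.  Root always allowed."""
    ok = np.ones(E + 1, dtype=bool)
    if allowed_events is None:
        return ok
    for v in range(1, E + 1):
        u = v
        while u != ROOT:
            if u not in allowed_events:
                ok[v] = False
                break
            u = parent[u - 1]
    return ok


def attach_cells(
    posterior: TreePosterior,
    matrix: GenotypeMatrix,
    seed: int | None = None,
    allowed_events: set[int] | None = None,
    timepoint: str | None = None,
    max_draws: int = 500,
    prior: str = "empirical",
    gibbs_sweeps: int = 30,
    dirichlet_alpha: float = 1.0,
) -> AttachmentPosterior:
    """Cell-to-node attachment posterior with subclone-size credible intervals.

    For each posterior draw (tree, beta), cells are assigned to nodes and the
    assigned-cell counts per node form one draw of the subclone sizes; the
    point estimate is the posterior mean and the 95% credible interval the
    2.5/97.5 percentiles over draws.

    With the default ``prior="empirical"`` the attachment prior over nodes is
    itself learned per draw under a symmetric Dirichlet(``dirichlet_alpha``)
    hyperprior by a short collapsed Gibbs sweep (alternating node assignments
    and mixture weights).  This removes the systematic pull of
    dropout-affected cells toward ancestral nodes that a fixed uniform prior
    produces, and propagates the weight uncertainty into the credible
    intervals.  ``prior="uniform"`` assigns each cell with probability
    proportional to its attachment likelihood alone.

    Cells with all-missing genotypes attach by the prior and are flagged.
    ``allowed_events`` restricts attachments to nodes whose root path only
    uses those events (longitudinal restriction); disallowed nodes get exactly
    zero mass.
    """
    if posterior.n_samples == 0:
        raise ValueError("empty posterior")
    if prior not in ("empirical", "uniform"):
        raise ValueError("prior must be 'empirical' or 'uniform'")
    matrix = matrix.to_binary() if not matrix.binary_view else matrix
    if matrix.n_loci != len(posterior.locus_ids):
        raise ValueError("matrix loci do not match the posterior's panel")
    E = matrix.n_loci
    rng = np.random.default_rng(seed)
    engine = _LikelihoodEngine(matrix.codes, posterior.errors.fpr)

    idx = np.arange(posterior.n_samples)
    if posterior.n_samples > max_draws:
        idx = np.linspace(0, posterior.n_samples - 1, max_draws).astype(int)
    n = matrix.n_cells
    row_of_cell = engine.row_of_cell
    row_counts = engine.counts.astype(int)
    R = len(row_counts)
    mean_probs = np.zeros((n, E + 1))
    counts = np.zeros((len(idx), E + 1))
    for k, s in enumerate(idx):
        engine.set_beta(posterior.betas[s])
        S = engine.scores(posterior.trees[s])  # (rows, nodes)
        mask = _allowed_nodes(posterior.trees[s], allowed_events, E)
        S = np.where(mask[None, :], S, -np.inf)
        L = np.exp(S - S.max(axis=1, keepdims=True))
        if prior == "uniform":
            P = L / L.sum(axis=1, keepdims=True)
            c = np.zeros(E + 1)
            for r in range(R):
                c += rng.multinomial(row_counts[r], P[r])
        else:
            pi = mask / mask.sum()
            for _ in range(gibbs_sweeps):
                P = L * pi
                P /= P.sum(axis=1, keepdims=True)
                c = np.zeros(E + 1)
                for r in range(R):
                    c += rng.multinomial(row_counts[r], P[r])
                pi = np.zeros(E + 1)
                pi[mask] = np.maximum(
                    rng.dirichlet(dirichlet_alpha + c[mask]), 1e-300
                )
        counts[k] = c
        mean_probs += P[row_of_cell]
    mean_probs /= len(idx)

    uninformative = (matrix.codes == MISSING).all(axis=1)
    return AttachmentPosterior(
        probs=mean_probs,
        counts_draws=counts,
        point=counts.mean(axis=0),
        ci_low=np.percentile(counts, 2.5, axis=0),
        ci_high=np.percentile(counts, 97.5, axis=0),
        cell_ids=matrix.cell_ids,
        node_labels=("root",) + tuple(posterior.map_tree.labels),
        tree=posterior.map_tree,
        uninformative_cells=uninformative,
        timepoint=timepoint,
    )


def observed_events(
    matrix: GenotypeMatrix, min_fraction: float = 0.02
) -> set[int]:
    """Events considered observed at a timepoint: loci whose mutant-call
    fraction (among non-missing calls) exceeds ``min_fraction``.

    The default threshold sits above the ~1% sequencing false-positive rate so
    that spurious calls do not mark an absent mutation as present.
    """
    codes = matrix.codes
    informative = (codes != MISSING).sum(axis=0)
    mutant = ((codes == HET) | (codes == HOM)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(informative > 0, mutant / np.maximum(informative, 1), 0.0)
    return {j + 1 for j in range(matrix.n_loci) if frac[j] > min_fraction}


def longitudinal_infer(
    matrices: list[GenotypeMatrix],
    errors: ErrorModel | None = None,
    config: McmcConfig | None = None,
    observed: dict[str, set[int]] | None = None,
    min_observed_fraction: float = 0.02,
    seed: int | None = None,
) -> tuple[TreePosterior, dict[str, AttachmentPosterior]]:
    """One tree from pooled timepoints; per-timepoint restricted attachments.

    All timepoints must share the locus panel.  A cell sampled at timepoint t
    cannot attach at or below any event whose mutation is unobserved at t
    (zero, renormalized, attachment mass), so a subclone may legitimately have
    0% prevalence at some timepoint without implying extinction.  ``observed``
    optionally gives the per-timepoint observed event sets (1-based locus
    indices); by default they are derived from the per-timepoint mutant-call
    fractions.
    """
    if len(matrices) < 2:
        raise ValueError("longitudinal inference needs >= 2 timepoints")
    panel = matrices[0].locus_ids
    for m in matrices[1:]:
        if m.locus_ids != panel:
            raise ValueError("timepoints must share an identical locus panel")
    labels = [m.timepoint or f"t{i}" for i, m in enumerate(matrices)]

    pooled = GenotypeMatrix(
        np.vstack([m.codes for m in matrices]),
        cell_ids=tuple(
            f"{lab}:{cid}" for lab, m in zip(labels, matrices) for cid in m.cell_ids
        ),
        locus_ids=panel,
        sample_id=matrices[0].sample_id,
    )
    posterior = mcmc_infer(pooled, errors, config)
    rng = np.random.default_rng(seed)
    attachments = {}
    for lab, m in zip(labels, matrices):
        allowed = (
            observed[lab] if observed is not None
            else observed_events(m, min_observed_fraction)
        )
        attachments[lab] = attach_cells(
            posterior, m, seed=int(rng.integers(0, 2**31 - 1)),
            allowed_events=allowed, timepoint=lab,
        )
    return posterior, attachments


# ---------------------------------------------------------------------------
# Model consensus
# ---------------------------------------------------------------------------

def consensus_across_models(
    matrix: GenotypeMatrix,
    errors: ErrorModel | None = None,
    config: McmcConfig | None = None,
) -> dict:
    """Run the four standard model configurations and compare MAP trees.

    Reports the six pairwise tree equalities, a parent-vector agreement
    fraction, and whether all four MAP trees are identical ("consistent").
    """
    errors = errors or ErrorModel()
    config = config or McmcConfig()
    maps = {}
    for model_id in (1, 2, 3, 4):
        cfg = replace(config, model_id=model_id)
        maps[model_id] = mcmc_infer(matrix, errors, cfg).map_tree.parent
    pairs = {}
    agree = []
    ids = sorted(maps)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            pa, pb = maps[ids[a]], maps[ids[b]]
            frac = float(np.mean(np.asarray(pa) == np.asarray(pb)))
            pairs[(ids[a], ids[b])] = {"equal": pa == pb, "agreement": frac}
            agree.append(frac)
    return {
        "map_trees": maps,
        "pairwise": pairs,
        "agreement_fraction": float(np.mean(agree)),
        "consistent": all(p["equal"] for p in pairs.values()),
    }
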