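"""Pairwise mutation co-occurrence and mutual exclusivity.

Three analysis levels share one 2x2-table machinery:

* cell level — units are cells of one sample; cells missing at either locus
  are excluded pairwise; log2 odds ratio with Haldane correction, two-sided
  Fisher exact p, Benjamini-Hochberg q across the sample's pairs.
* patient (bulk) level — units are patients, presence/absence per gene;
  natural-log Haldane odds ratio, G-test of independence (chi-squared, 1 df),
  BH q.
* clone level — units are subclones pooled across samples, restricted to
  clones above a prevalence threshold; same statistics as the bulk level.

The Haldane correction (+0.5 to every table cell) keeps the odds ratio finite
for tables with zeros; the G statistic is computed on the uncorrected counts
with the convention 0 * ln(0 / E) = 0.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix, HET, HOM, MISSING
from .clonal import ClonalComposition, _gene_of


def haldane_log_odds(a: float, b: float, c: float, d: float, base: float = math.e) -> float:
    """Haldane-corrected log odds ratio of the table [[a, b], [c, d]]."""
    return math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))) / math.log(base)


def g_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """G statistic (2 sum O ln(O/E)) and chi-squared (1 df) p value.

    Expected counts come from the table margins; zero observed cells
    contribute nothing.  Degenerate margins give G = 0, p = 1.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    expected = np.outer(rows, cols) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    return g, float(stats.chi2.sf(g, df=1))


def _bh(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["q_value"] = np.nan
    ok = frame["p_value"].notna()
    if ok.any():
        frame.loc[ok, "q_value"] = multipletests(
            frame.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return frame


def _pairwise_frame(records: list[dict], level: str) -> pd.DataFrame:
    cols = ["mutation_a", "mutation_b", "a", "b", "c", "d",
            "log_or", "log_base", "p_value", "level"]
    frame = pd.DataFrame(records, columns=cols)
    frame["level"] = level
    return _bh(frame)


def cell_cooccurrence(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Cell-level pairwise association within one sample.

    For every locus pair, cells missing at either locus are excluded; the
    2x2 mutant/wild-type table yields a Haldane-corrected log2 odds ratio and
    a two-sided Fisher exact p value, BH-adjusted across the sample's pairs.
    Pairs with zero informative cells carry NaN statistics and are excluded
    from the adjustment.
    """
    if matrix.n_loci < 2:
        raise ValueError("need at least two loci")
    mutant = (matrix.codes == HET) | (matrix.codes == HOM)
    informative = matrix.codes != MISSING
    records = []
    for i, j in combinations(range(matrix.n_loci), 2):
        ok = informative[:, i] & informative[:, j]
        mi, mj = mutant[ok, i], mutant[ok, j]
        a = int((mi & mj).sum())
        b = int((mi & ~mj).sum())
        c = int((~mi & mj).sum())
        d = int((~mi & ~mj).sum())
        rec = {"mutation_a": matrix.locus_ids[i], "mutation_b": matrix.locus_ids[j],
               "a": a, "b": b, "c": c, "d": d, "log_base": 2.0}
        if a + b + c + d == 0:
            rec.update({"log_or": np.nan, "p_value": np.nan})
        else:
            rec["log_or"] = haldane_log_odds(a, b, c, d, base=2.0)
            rec["p_value"] = float(
                stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            )
        records.append(rec)
    return _pairwise_frame(records, level="cell")


def _presence_cooccurrence(
    presence: pd.DataFrame, level: str
) -> pd.DataFrame:
    presence = presence.astype(bool)
    keep = presence.any(axis=0)
    dropped = [g for g, k in keep.items() if not k]
    if dropped:
        import warnings

        warnings.warn(f"genes absent in every unit excluded: {dropped}")
    presence = presence.loc[:, keep]
    if presence.shape[1] < 2:
        raise ValueError("need at least two genes present in some unit")
    records = []
    for ga, gb in combinations(presence.columns, 2):
        x, y = presence[ga].to_numpy(), presence[gb].to_numpy()
        a = int((x & y).sum())
        b = int((x & ~y).sum())
        c = int((~x & y).sum())
        d = int((~x & ~y).sum())
        g, p = g_test(a, b, c, d)
        records.append({
            "mutation_a": ga, "mutation_b": gb, "a": a, "b": b, "c": c, "d": d,
            "log_or": haldane_log_odds(a, b, c, d), "log_base": math.e,
            "p_value": p, "g_statistic": g,
        })
    frame = _pairwise_frame(records, level=level)
    frame["g_statistic"] = [r["g_statistic"] for r in records]
    return frame


def bulk_cooccurrence(presence: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level association over a patients x genes presence matrix."""
    if presence.shape[0] < 2 or presence.shape[1] < 2:
        raise ValueError("need >= 2 patients and >= 2 genes")
    return _presence_cooccurrence(presence, level="patient_bulk")


def clone_cooccurrence(
    compositions: list[ClonalComposition],
    min_fraction: float = 0.01,
    by_gene: bool = True,
) -> pd.DataFrame:
    """Clone-level association pooled across samples.

    Units are subclones with fraction >= ``min_fraction`` of their sample's
    tumor (mutated) cells; each clone's mutation set is reduced to gene
    symbols when ``by_gene``.  Statistics as at the bulk level.
    """
    rows = []
    for k, comp in enumerate(compositions):
        for s in comp.subclones:
            if s.fraction >= min_fraction:
                muts = {_gene_of(m) for m in s.mutations} if by_gene else set(s.mutations)
                rows.append((f"s{k}:clone{s.node}", muts))
    if not rows:
        return _pairwise_frame([], level="clone")
    genes = sorted(set().union(*(m for _, m in rows)))
    presence = pd.DataFrame(
        [[g in muts for g in genes] for _, muts in rows],
        index=[cid for cid, _ in rows], columns=genes,
    )
    if presence.shape[1] < 2:
        return _pairwise_frame([], level="clone")
    return _presence_cooccurrence(presence, level="clone")


def log_or_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric matrix of log odds ratios from a long-format table."""
    names = sorted(set(results["mutation_a"]) | set(results["mutation_b"]))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for _, r in results.iterrows():
        mat.loc[r["mutation_a"], r["mutation_b"]] = r["log_or"]
        mat.loc[r["mutation_b"], r["mutation_a"]] = r["log_or"]
    return mat
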