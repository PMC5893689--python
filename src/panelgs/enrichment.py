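"""GO-term functional enrichment of marker-predicted effects.

Each SNP inside a gene inherits all GO terms of that gene; the SNPs matching
a term form its GO cluster.  For every cluster, a one-sided two-sample
Kolmogorov-Smirnov test asks whether the absolute marker effects in the
cluster are stochastically larger than those of all remaining markers
(including non-genic ones); Benjamini-Hochberg controls the FDR across
terms.  No GO-graph propagation is performed: a SNP carries exactly the
terms directly annotated to its genes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, exp

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synthetic import GeneAnnotation

EXACT_ENUM_LIMIT = 100_000  # max number of splits for exact permutation p


def assign_snps_to_genes(markers: pd.DataFrame, annotation: GeneAnnotation):
    """Per-SNP GO term sets via interval lookup.

    A SNP at position p receives the union of the GO terms of every gene with
    start <= p <= end on its chromosome (both endpoints inclusive; GFF3 and
    VCF coordinates are both 1-based, so no conversion applies).  SNPs inside
    no annotated gene get the empty set.  Chromosomes present in the marker
    map but absent from a non-empty annotation raise.
    """
    genes = annotation.genes
    if len(genes):
        unmatched = sorted(set(markers["chrom"]) - set(genes["chrom"]))
        if unmatched:
            raise ValueError(f"chromosomes absent from annotation: {unmatched}")

    # per-chromosome lookup structures: a sorted-interval bisection table for
    # non-overlapping genes (the common case), an interval tree otherwise
    sorted_tables, trees = {}, {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        terms = [frozenset(annotation.gene_to_go.get(g, set()))
                 for g in grp["id"]]
        if len(grp) < 2 or np.all(starts[1:] > ends[:-1]):
            sorted_tables[chrom] = (starts, ends, terms)
        else:
            t = IntervalTree()
            # interval ends are exclusive in intervaltree; genes are inclusive
            for s, e, tm in zip(starts, ends, terms):
                t[s:e + 1] = tm
            trees[chrom] = t

    out = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        if chrom in sorted_tables:
            starts, ends, terms = sorted_tables[chrom]
            idx = np.searchsorted(starts, pos, side="right") - 1
            hit = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
            chunk = [set(terms[i]) if h else set() for i, h in zip(idx, hit)]
        elif chrom in trees:
            tree = trees[chrom]
            chunk = []
            for p in pos:
                acc = set()
                for iv in tree[int(p)]:
                    acc |= iv.data
                chunk.append(acc)
        else:
            chunk = [set() for _ in pos]
        out.append(pd.Series(chunk, index=grp.index))
    if not out:
        return []
    return pd.concat(out).sort_index().tolist()


def build_go_clusters(assignments):
    """Invert per-SNP term sets into term -> SNP index set."""
    clusters = {}
    for i, terms in enumerate(assignments):
        for t in terms:
            clusters.setdefault(t, set()).add(i)
    return clusters


def ks_one_sided(cluster_vals, rest_vals, exact: str = "auto",
                 n_perm: int = 2000, seed: int = 0):
    """One-sided two-sample KS test: is the cluster stochastically larger?

    D = sup_x [F_rest(x) - F_cluster(x)], clipped at 0.  The p value is the
    asymptotic one-sided bound exp(-2 D^2 mn/(m+n)); when the number of
    possible splits is small (min sample <= 10 and C(m+n, min) within the
    enumeration limit) an exact permutation p over all splits of the pooled
    sample is used instead.  ``exact`` in {"auto", "always", "never", "mc"};
    "mc" draws ``n_perm`` random splits instead of enumerating.
    """
    a = np.asarray(cluster_vals, dtype=float)
    b = np.asarray(rest_vals, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")

    d_obs = _d_one_sided(a, b)
    m, n = a.size, b.size
    if exact == "mc":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 1  # the observed split counts (permutation-test convention)
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _d_one_sided(perm[:m], perm[m:]) >= d_obs - 1e-12:
                count += 1
        return float(d_obs), count / (n_perm + 1)
    use_exact = exact == "always" or (
        exact == "auto" and min(m, n) <= 10
        and comb(m + n, min(m, n)) <= EXACT_ENUM_LIMIT)
    if use_exact:
        total = m + n
        n_splits = comb(total, m)
        if n_splits > EXACT_ENUM_LIMIT:
            raise ValueError("too many splits for exact enumeration")
        pooled = np.sort(np.concatenate([a, b]))
        if m == 1:
            # singleton cluster {x}: D = #{rest < x} / n; enumerate all
            # choices of x from the pooled sample in one vectorized pass
            n_less = np.searchsorted(pooled, pooled, side="left")
            d_all = n_less / n
            count = int(np.sum(d_all >= d_obs - 1e-12))
            p = count / n_splits
        else:
            # evaluate the ECDF difference at the last index of each tie run
            is_last = np.r_[pooled[1:] != pooled[:-1], True]
            eval_idx = np.where(is_last)[0]
            rank = np.arange(1, total + 1)[eval_idx]
            count = 0
            ind = np.zeros(total)
            for cluster_pos in combinations(range(total), m):
                ind[:] = 0.0
                ind[list(cluster_pos)] = 1.0
                cum_a = np.cumsum(ind)[eval_idx]
                d = np.max((rank - cum_a) / n - cum_a / m)
                if max(d, 0.0) >= d_obs - 1e-12:
                    count += 1
            p = count / n_splits
    else:
        p = min(1.0, exp(-2.0 * d_obs ** 2 * m * n / (m + n)))
    return float(d_obs), float(p)


def _d_one_sided(a, b):
    """sup_x [F_b(x) - F_a(x)] over the pooled sample points, clipped at 0."""
    pooled = np.concatenate([a, b])
    pooled.sort()
    fa = np.searchsorted(np.sort(a), pooled, side="right") / a.size
    fb = np.searchsorted(np.sort(b), pooled, side="right") / b.size
    return max(0.0, float(np.max(fb - fa)))


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted p values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def enrich_effects(effects, markers: pd.DataFrame, annotation: GeneAnnotation,
                   alpha: float = 0.01, exact: str = "auto") -> pd.DataFrame:
    """Full enrichment analysis of one marker-effect vector.

    For every GO cluster, the absolute effects of its SNPs are compared with
    the absolute effects of *all remaining* markers (genic or not) by the
    one-sided KS test; BH adjustment is applied across all tested terms and
    terms with adjusted p < ``alpha`` are flagged.  Returns a table sorted by
    adjusted p with columns term, n_snps, D, p, p_adj, significant.
    """
    eff = effects.effects if hasattr(effects, "effects") else np.asarray(effects, float)
    eff = np.abs(np.asarray(eff, dtype=float))
    if len(eff) != len(markers):
        raise ValueError("effects do not align with the marker map")
    assignments = assign_snps_to_genes(markers, annotation)
    clusters = build_go_clusters(assignments)
    if not clusters:
        import warnings

        warnings.warn("no GO clusters; returning empty enrichment table")
        return pd.DataFrame(columns=["term", "n_snps", "D", "p", "p_adj",
                                     "significant"])

    all_idx = np.arange(len(eff))
    rows = []
    for term in sorted(clusters):
        idx = np.fromiter(clusters[term], dtype=int)
        rest = np.setdiff1d(all_idx, idx, assume_unique=False)
        if rest.size == 0:
            raise ValueError(f"cluster {term} contains every marker; "
                             "no complement to test against")
        d, p = ks_one_sided(eff[idx], eff[rest], exact=exact)
        rows.append((term, idx.size, d, p))
    table = pd.DataFrame(rows, columns=["term", "n_snps", "D", "p"])
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p_adj", "p", "term"]).reset_index(drop=True)
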