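"""Population structure: windowed LD pruning, PCA, and the Evanno delta-K
summary of externally supplied admixture log-likelihoods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import DosageMatrix


@dataclass
class PcaResult:
    scores: np.ndarray             # lines x components, column means zero
    variance_explained: np.ndarray  # per-component fraction of total variance
    loadings: np.ndarray           # markers x components


@dataclass
class DeltaKTable:
    table: pd.DataFrame  # columns: K, mean_loglik, sd_loglik, delta_k
    best_k: int


def ld_prune(g: DosageMatrix, r2_max: float = 0.20,
             window_bp: int = 2_000_000):
    """Greedy left-to-right LD pruning per chromosome.

    A marker is kept iff its squared Pearson correlation with every
    already-kept marker within ``window_bp`` upstream is <= ``r2_max``.
    Keep-first (leftmost retained) makes the scan deterministic.  Monomorphic
    markers (zero variance) have undefined r2 and are treated as
    uncorrelated, hence kept.

    Returns ``(pruned DosageMatrix, kept ids, removed ids)``.
    """
    g.require_state("final")
    pos = g.markers["pos"].to_numpy()
    chrom = g.markers["chrom"].to_numpy()
    for _, grp in g.markers.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError("marker map must be sorted within chromosome")

    x = g.values.astype(float)
    x = x - x.mean(axis=0)
    norms = np.sqrt((x ** 2).sum(axis=0))

    keep = []
    kept_by_chrom = {}
    for j in range(g.n_markers):
        c = chrom[j]
        kept = kept_by_chrom.setdefault(c, [])
        ok = True
        if norms[j] > 0:
            for k in reversed(kept):
                if pos[j] - pos[k] > window_bp:
                    break
                if norms[k] == 0:
                    continue
                r = float(x[:, j] @ x[:, k]) / (norms[j] * norms[k])
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(j)
            keep.append(j)
    keep = np.array(keep, dtype=int)
    ids = g.markers["id"]
    removed = ids[~ids.index.isin(keep)].tolist()
    return g.take_markers(keep), ids.iloc[keep].tolist(), removed


def pca(g: DosageMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the column-centred marker matrix by SVD.

    Scores are the line projections; per-component signs are fixed by making
    the largest-|loading| entry of each component positive, so results are
    deterministic.
    """
    g.require_state("final")
    if g.n_lines < 2:
        raise ValueError("PCA needs at least 2 lines")
    if n_components > min(g.n_lines, g.n_markers):
        raise ValueError("n_components exceeds min(lines, markers)")
    x = g.values.astype(float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: largest-|loading| entry positive
    for k in range(n_components):
        i = np.argmax(np.abs(vt[k]))
        if vt[k, i] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    total = (x ** 2).sum()
    var_exp = (s ** 2) / total if total > 0 else np.zeros(n_components)
    return PcaResult(scores=scores, variance_explained=var_exp, loadings=vt.T)


def evanno_delta_k(loglik: pd.DataFrame) -> DeltaKTable:
    """Evanno second-difference summary of per-K admixture log-likelihoods.

    ``loglik`` is a table of independent runs (rows) by K (columns, named by
    integer K); delta K(K) = |m(K+1) - 2 m(K) + m(K-1)| / s(K) with m, s the
    across-run mean and sample sd.  K values with zero sd are flagged
    (delta K = NaN) and excluded from the argmax.
    """
    ks = sorted(int(k) for k in loglik.columns)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    cols = {int(k): loglik[k].dropna().to_numpy(dtype=float) for k in loglik.columns}
    if any(len(v) < 2 for v in cols.values()):
        raise ValueError("need at least 2 runs per K (sample sd undefined otherwise)")

    means = {k: float(np.mean(cols[k])) for k in ks}
    sds = {k: float(np.std(cols[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        elif sds[k] == 0:
            dk = np.nan
        else:
            dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
        rows.append((k, means[k], sds[k], dk))
    table = pd.DataFrame(rows, columns=["K", "mean_loglik", "sd_loglik", "delta_k"])
    valid = table.dropna(subset=["delta_k"])
    if valid.empty:
        raise ValueError("delta K undefined for every interior K")
    best_k = int(valid.loc[valid["delta_k"].idxmax(), "K"])
    return DeltaKTable(table=table, best_k=best_k)
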