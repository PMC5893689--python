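"""Genotype quality control: marker statistics, heterozygosity filtering,
window nearest-neighbour imputation, MAF filtering and -1/+1 recoding.

The pipeline order is raw -> (het filter) -> impute -> MAF filter -> final
recode, enforced through ``DosageMatrix.coding_state``.  Imputation follows
the window nearest-neighbour idea used for inbred GBS panels: a missing call
is filled with the allele of the line most similar to the target over a
window of flanking markers, with the window size chosen by self-masking
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import HOM_ALT, HOM_REF, HET, MISSING, DosageMatrix


@dataclass
class MarkerStats:
    """Per-marker and per-line QC statistics computed over called genotypes."""

    het_frac: np.ndarray       # heterozygous fraction among called genotypes
    missing_frac: np.ndarray   # missing fraction per marker
    line_missing_frac: np.ndarray
    maf: np.ndarray            # minor allele frequency among called alleles
    undefined: np.ndarray      # markers with zero called genotypes

    def to_frame(self, markers: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({
            "id": markers["id"].to_numpy(),
            "het_frac": self.het_frac,
            "missing_frac": self.missing_frac,
            "maf": self.maf,
            "undefined": self.undefined,
        })


def compute_marker_stats(g: DosageMatrix) -> MarkerStats:
    """Heterozygosity, missingness and MAF per marker, missingness per line.

    Statistics are over called genotypes only.  Markers where every call is
    missing are flagged ``undefined`` and carry NaN statistics rather than
    raising.
    """
    g.require_state("raw", "imputed")
    v = g.values
    called = v != MISSING
    n_called = called.sum(axis=0)
    undefined = n_called == 0

    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0,
                       (v == HET).sum(axis=0) / np.maximum(n_called, 1), np.nan)
        miss = 1.0 - n_called / v.shape[0]
        # allele counts among called genotypes: ref = 2*homRef + het
        ref_alleles = 2 * (v == HOM_REF).sum(axis=0) + (v == HET).sum(axis=0)
        tot_alleles = 2 * n_called
        p_ref = np.where(tot_alleles > 0,
                         ref_alleles / np.maximum(tot_alleles, 1), np.nan)
        maf = np.minimum(p_ref, 1.0 - p_ref)
    het[undefined] = np.nan
    maf[undefined] = np.nan
    line_miss = (~called).sum(axis=1) / v.shape[1]
    return MarkerStats(het_frac=het, missing_frac=miss,
                       line_missing_frac=line_miss, maf=maf, undefined=undefined)


def filter_het_markers(g: DosageMatrix, stats: MarkerStats,
                       max_het: float = 0.10) -> DosageMatrix:
    """Drop markers whose heterozygous fraction exceeds ``max_het`` and set
    the surviving heterozygous calls to missing (inbred-line assumption);
    artifact loci from duplicated regions show up as high-het columns."""
    g.require_state("raw")
    keep = ~(stats.het_frac > max_het)  # NaN (undefined) markers are kept here
    out = g.take_markers(np.where(keep)[0])
    out.values[out.values == HET] = MISSING
    return out


def impute_npute_style(g: DosageMatrix, window_candidates=(5, 11, 21),
                       mask_fraction: float = 0.1, seed: int = 0):
    """Fill every missing call with its nearest-neighbour line's allele.

    For window size W, the donor for a missing call (line i, marker j) is the
    line minimizing the mismatch count with line i over the mutually observed
    entries among the W markers centred on j (windows never cross chromosome
    boundaries and shrink near chromosome ends).  Ties are broken by the
    majority call among tied donors, then by the panel-wide major allele.
    W is chosen from ``window_candidates`` by self-masking cross-validation:
    a fraction of observed calls is masked, each W imputes them, and the W
    with the highest recovery rate wins.

    Returns ``(imputed DosageMatrix, chosen W, recovery table)``.

    Raises if a marker has no observed call (no donor exists) or if
    ``window_candidates`` is empty.
    """
    g.require_state("raw")
    if len(window_candidates) == 0:
        raise ValueError("window_candidates must be non-empty")
    if any(w % 2 == 0 or w < 1 for w in window_candidates):
        raise ValueError("window sizes must be odd positive integers")
    if g.n_lines < 2:
        raise ValueError("imputation needs at least 2 lines")
    if np.any(g.values == HET):
        raise ValueError("resolve heterozygous calls to missing before imputing")

    v = g.values
    all_missing = np.where((v == MISSING).all(axis=0))[0]
    if all_missing.size:
        bad = g.markers["id"].iloc[all_missing[0]]
        raise ValueError(f"marker {bad!r} has no observed call; cannot impute")

    chrom_codes = pd.factorize(g.markers["chrom"])[0]

    recovery = {}
    best_w, best_rate = None, -1.0
    if np.any(v == MISSING) and len(window_candidates) > 1:
        rng = np.random.default_rng(seed)
        obs_i, obs_j = np.where(v != MISSING)
        k = max(1, int(mask_fraction * obs_i.size))
        pick = rng.choice(obs_i.size, size=k, replace=False)
        masked = v.copy()
        masked[obs_i[pick], obs_j[pick]] = MISSING
        # a fully-masked column has no donor; unmask one entry if needed
        dead = np.where((masked == MISSING).all(axis=0))[0]
        for j in dead:
            i = np.where(v[:, j] != MISSING)[0][0]
            masked[i, j] = v[i, j]
        truth = v[obs_i[pick], obs_j[pick]]
        for w in window_candidates:
            filled = _impute_all(masked, chrom_codes, w)
            rate = float(np.mean(filled[obs_i[pick], obs_j[pick]] == truth))
            recovery[w] = rate
            if rate > best_rate:
                best_w, best_rate = w, rate
    else:
        best_w = window_candidates[0]
        recovery = {w: np.nan for w in window_candidates}

    out = g.copy()
    out.values = _impute_all(v, chrom_codes, best_w)
    out.coding_state = "imputed"
    table = pd.DataFrame({"window": list(recovery), "recovery": list(recovery.values())})
    return out, best_w, table


def _impute_all(v: np.ndarray, chrom_codes: np.ndarray, w: int) -> np.ndarray:
    """Impute every missing entry of ``v`` with window size ``w``."""
    out = v.copy()
    half = w // 2
    n, p = v.shape
    # panel-wide major allele per marker (final tie-break)
    ref_ct = (v == HOM_REF).sum(axis=0)
    alt_ct = (v == HOM_ALT).sum(axis=0)
    major = np.where(alt_ct > ref_ct, HOM_ALT, HOM_REF)

    miss_cols = np.where((v == MISSING).any(axis=0))[0]
    for j in miss_cols:
        lo = j - half
        hi = j + half + 1
        # clip to this chromosome
        c = chrom_codes[j]
        while lo < 0 or chrom_codes[lo] != c:
            lo += 1
        while hi > p or chrom_codes[hi - 1] != c:
            hi -= 1
        block = v[:, lo:hi]
        obs_block = block != MISSING
        targets = np.where(v[:, j] == MISSING)[0]
        donors_ok = v[:, j] != MISSING
        tb = block[targets]                       # (t, W)
        tobs = obs_block[targets]                 # (t, W)
        both = tobs[:, None, :] & obs_block[None, :, :]
        mism = ((tb[:, None, :] != block[None, :, :]) & both).sum(axis=2)
        mism = np.where(donors_ok[None, :], mism, np.iinfo(np.int32).max)
        for t_idx, i in enumerate(targets):
            row = mism[t_idx]
            best = row.min()
            tied = np.where(row == best)[0]
            calls = v[tied, j]
            n_ref = int((calls == HOM_REF).sum())
            n_alt = int((calls == HOM_ALT).sum())
            if n_ref > n_alt:
                out[i, j] = HOM_REF
            elif n_alt > n_ref:
                out[i, j] = HOM_ALT
            else:
                out[i, j] = major[j]
    return out


def impute_majority(g: DosageMatrix) -> DosageMatrix:
    """Baseline imputation: fill missing calls with the per-marker major
    allele (ties -> reference).  Used as the floor that the nearest-neighbour
    imputer must beat on LD data."""
    g.require_state("raw")
    v = g.values.copy()
    ref_ct = (g.values == HOM_REF).sum(axis=0)
    alt_ct = (g.values == HOM_ALT).sum(axis=0)
    if np.any(ref_ct + alt_ct == 0):
        raise ValueError("marker with no observed call")
    major = np.where(alt_ct > ref_ct, HOM_ALT, HOM_REF).astype(v.dtype)
    miss = v == MISSING
    v[miss] = np.broadcast_to(major, v.shape)[miss]
    if np.any(v == HET):
        raise ValueError("resolve heterozygous calls before imputing")
    out = g.copy()
    out.values = v
    out.coding_state = "imputed"
    return out


def filter_maf(g: DosageMatrix, min_maf: float = 0.05) -> DosageMatrix:
    """Drop markers with MAF strictly below ``min_maf`` (a marker at exactly
    the threshold is retained)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    g.require_state("imputed")
    if np.any(g.values == MISSING):
        raise ValueError("filter_maf requires a fully imputed matrix")
    v = g.values
    n = v.shape[0]
    p_ref = (2 * (v == HOM_REF).sum(axis=0) + (v == HET).sum(axis=0)) / (2 * n)
    maf = np.minimum(p_ref, 1 - p_ref)
    keep = np.where(maf >= min_maf)[0]
    return g.take_markers(keep)


def recode_final(g: DosageMatrix) -> DosageMatrix:
    """Recode homozygous calls to the final -1/+1 coding.

    Convention: homozygous reference -> +1, homozygous alternate -> -1.
    Requires an imputed matrix with no residual heterozygous or missing call;
    a final-coded input raises (the recode is not idempotent by contract).
    """
    g.require_state("imputed")
    v = g.values
    if np.any(v == MISSING):
        raise ValueError("residual missing call; impute before recoding")
    if np.any(v == HET):
        raise ValueError("residual heterozygous call; resolve before recoding")
    out = g.copy()
    out.values = np.where(v == HOM_REF, 1, -1).astype(np.int8)
    out.coding_state = "final"
    return out


def run_qc_pipeline(g: DosageMatrix, max_het: float = 0.10, min_maf: float = 0.05,
                    window_candidates=(5, 11, 21), seed: int = 0):
    """Convenience wrapper: het filter -> impute -> MAF filter -> recode.

    Returns ``(final DosageMatrix, dict of stage summaries)``.
    """
    stats = compute_marker_stats(g)
    g1 = filter_het_markers(g, stats, max_het=max_het)
    g2, best_w, rec = impute_npute_style(g1, window_candidates, seed=seed)
    g3 = filter_maf(g2, min_maf=min_maf)
    g4 = recode_final(g3)
    summary = {
        "n_markers_raw": g.n_markers,
        "n_markers_post_het": g1.n_markers,
        "n_markers_post_maf": g3.n_markers,
        "chosen_window": best_w,
        "window_recovery": rec,
        "mean_missing": float(np.nanmean(stats.missing_frac)),
        "mean_het": float(np.nanmean(stats.het_frac)),
    }
    return g4, summary
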