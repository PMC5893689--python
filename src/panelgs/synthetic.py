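"""Synthetic panel generator.

Emulates the statistical structure of a two sub-panel inbred sorghum diversity
panel genotyped by GBS and phenotyped in lattice field trials, so the whole
pipeline (QC, imputation, structure, REML, genomic prediction, enrichment)
runs offline:

* genotypes: founder-haplotype mosaics within each sub-panel, with sub-panel
  allele frequencies drawn from a Balding-Nichols divergence model, giving
  both local LD (for imputation and pruning) and a PC1 split between panels;
* GBS corruption: per-marker missing rates with a right-skewed distribution
  (target mean ~34.6%, median below the mean) and heterozygous-call artifacts
  concentrated on a small subset of loci, mimicking spurious polymorphisms
  from duplicated regions;
* trait architecture: additive QTL effects, optionally amplified inside genes
  annotated with "planted" GO terms so enrichment detection has ground truth;
* field trials: a resolvable lattice (blocks nested in replicates nested in
  years) with crop-stand and days-to-flowering covariates, genotype main and
  genotype-by-year effects and independent residuals;
* annotation: non-overlapping gene intervals plus a gene -> GO map whose
  cluster sizes are long-tailed (singletons up to hundreds of SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dosage import HOM_ALT, HOM_REF, HET, MISSING, DosageMatrix, marker_table


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the emulated
    panel: 2 x 100 inbred lines, 10 chromosomes, GBS-like missingness (mean
    0.346) and heterozygosity artifacts (mean 0.042), a 10 x 10 lattice with
    three replicates."""

    seed: int = 0
    n_lines_per_panel: int = 100
    n_panels: int = 2
    n_chrom: int = 10
    chrom_length_bp: int = 60_000_000
    n_markers: int = 2000
    fst: float = 0.25
    n_founder_haplotypes: int = 4
    recomb_rate: float = 0.5  # expected crossovers per chromosome per line
    missing_rate_mean: float = 0.346
    het_artifact_rate: float = 0.042
    het_artifact_marker_fraction: float = 0.02
    n_qtl: int = 200
    qtl_effect_dist: str = "normal"  # or "gamma"
    qtl_effect_scale: float = 1.0
    qtl_effect_shape: float = 1.5  # gamma shape when qtl_effect_dist == "gamma"
    # (sigma_g^2, sigma_ga^2, sigma_rep^2, sigma_block^2, sigma_e^2)
    variance_components: tuple = (4.0, 1.0, 0.5, 0.5, 3.0)
    n_years: int = 2
    n_reps: int = 3
    n_blocks: int = 10
    mu: float = 50.0
    beta_stand: float = 0.3
    gamma_flowering: float = 0.1
    stand_mean: float = 40.0
    flowering_cor: float = 0.4  # genetic correlation of flowering with the trait
    gene_fraction: float = 0.30
    mean_gene_length_bp: int = 3000
    n_go_terms: int = 150
    terms_per_gene_mean: float = 2.3  # gene carries 1 + Poisson(this) terms, <= 40
    planted_terms: tuple = ()  # ((term_id, effect multiplier), ...)

    def __post_init__(self):
        for name in ("missing_rate_mean", "het_artifact_rate", "gene_fraction",
                     "het_artifact_marker_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if any(v < 0 for v in self.variance_components):
            raise ValueError("variance components must be non-negative")
        if self.n_markers < self.n_qtl:
            raise ValueError("n_markers must be >= n_qtl")
        if self.n_markers < self.n_chrom:
            raise ValueError("n_markers must be >= n_chrom")
        if self.qtl_effect_dist not in ("normal", "gamma"):
            raise ValueError("qtl_effect_dist must be 'normal' or 'gamma'")

    @property
    def n_lines(self) -> int:
        return self.n_lines_per_panel * self.n_panels


@dataclass
class TruePanelState:
    """Ground truth carried alongside the synthetic genotypes."""

    panel_labels: np.ndarray  # per-line sub-panel index (0-based)
    true_effects: Optional[np.ndarray] = None  # per-marker additive effect
    true_breeding_values: Optional[np.ndarray] = None  # g_i = sum_j m_ij alpha_j
    qtl_index: Optional[np.ndarray] = None
    planted_terms: tuple = ()


@dataclass
class GeneAnnotation:
    """Gene models (1-based inclusive coordinates) plus gene -> GO term map."""

    genes: pd.DataFrame  # columns: id, chrom, start, end, strand
    gene_to_go: dict = field(default_factory=dict)  # gene id -> set of term ids

    def __post_init__(self):
        if len(self.genes) and (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")

    @property
    def all_terms(self) -> set:
        out = set()
        for terms in self.gene_to_go.values():
            out |= set(terms)
        return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _marker_positions(rng, cfg):
    """Sorted distinct positions per chromosome, markers split evenly."""
    per_chrom = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per_chrom[: cfg.n_markers % cfg.n_chrom] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chrom):
        k = per_chrom[c]
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=k, replace=False)) + 1
        chroms.append(np.full(k, f"chr{c + 1:02d}"))
        positions.append(pos)
    return np.concatenate(chroms), np.concatenate(positions), per_chrom


def simulate_panel_genotypes(cfg: SimulationConfig):
    """Simulate fully observed homozygous genotypes for a structured panel.

    Sub-panel allele frequencies follow a Balding-Nichols model: for ancestral
    frequency p and divergence F, each sub-panel draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F).  Each inbred line is a mosaic of the
    sub-panel's founder haplotypes with Poisson(recomb_rate) switch points per
    chromosome, which creates local LD decaying with distance.

    Returns
    -------
    (DosageMatrix, TruePanelState)
        Raw-coded (but fully observed, fully homozygous) genotypes and the
        per-line sub-panel labels.  Effects are filled in later by
        :func:`simulate_qtl_architecture`.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, per_chrom = _marker_positions(rng, cfg)
    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_markers)

    geno = np.empty((cfg.n_lines, cfg.n_markers), dtype=np.int8)
    labels = np.repeat(np.arange(cfg.n_panels), cfg.n_lines_per_panel)
    chrom_slices = np.concatenate([[0], np.cumsum(per_chrom)])

    # with zero divergence the sub-panels share one founder pool, so lines
    # are exchangeable; with fst > 0 each sub-panel gets Balding-Nichols
    # frequencies and its own founders
    shared_founders = None
    if cfg.fst == 0:
        shared_founders = (
            rng.random((cfg.n_founder_haplotypes, cfg.n_markers)) < p_anc
        ).astype(np.int8)

    for panel in range(cfg.n_panels):
        if cfg.fst > 0:
            a = p_anc * (1 - cfg.fst) / cfg.fst
            b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
            freq = rng.beta(a, b)
            # founder haplotypes of this sub-panel: 1 = alternate allele
            founders = (
                rng.random((cfg.n_founder_haplotypes, cfg.n_markers)) < freq
            ).astype(np.int8)
        else:
            founders = shared_founders
        rows = np.where(labels == panel)[0]
        for i in rows:
            hap = np.empty(cfg.n_markers, dtype=np.int8)
            for c in range(cfg.n_chrom):
                lo, hi = chrom_slices[c], chrom_slices[c + 1]
                k = hi - lo
                switch = rng.random(k) < cfg.recomb_rate / max(k - 1, 1)
                switch[0] = True  # fresh founder at chromosome start
                donor = -1
                for j in range(k):
                    if switch[j]:
                        donor = rng.integers(cfg.n_founder_haplotypes)
                    hap[lo + j] = founders[donor, lo + j]
            geno[i] = np.where(hap == 1, HOM_ALT, HOM_REF)

    markers = marker_table(chroms, positions)
    dm = DosageMatrix(geno, markers, lines=[f"L{i + 1:03d}" for i in range(cfg.n_lines)],
                      coding_state="raw")
    return dm, TruePanelState(panel_labels=labels)


def corrupt_genotypes(g: DosageMatrix, cfg: SimulationConfig) -> DosageMatrix:
    """Inject GBS-style missingness and heterozygous-call artifacts.

    Per-marker missing rates are Beta-distributed with mean
    ``cfg.missing_rate_mean`` and shape chosen right-skewed (median < mean, as
    observed for GBS SNPs).  Heterozygous artifacts are concentrated: a small
    subset of markers (fraction ``het_artifact_marker_fraction``) receives het
    rates in [0.5, 0.95], the rest a low background rate, so the pooled het
    fraction is about ``het_artifact_rate`` while a few loci look like
    duplicated-region artifacts.
    """
    g.require_state("raw")
    if np.any(g.values == MISSING) or np.any(g.values == HET):
        raise ValueError("corrupt_genotypes expects fully observed homozygous input")
    rng = np.random.default_rng(cfg.seed + 1)
    out = g.copy()
    n, p = out.values.shape

    if cfg.het_artifact_rate > 0:
        n_art = max(1, int(round(cfg.het_artifact_marker_fraction * p)))
        art = rng.choice(p, size=n_art, replace=False)
        het_rate = np.full(p, 0.0)
        # background so that the pooled mean matches the configured target
        art_mean = 0.725
        bg = max(
            0.0,
            (cfg.het_artifact_rate - art_mean * n_art / p) / max(1 - n_art / p, 1e-12),
        )
        het_rate[:] = rng.exponential(bg, size=p).clip(max=0.45) if bg > 0 else 0.0
        het_rate[art] = rng.uniform(0.5, 0.95, size=n_art)
        het_mask = rng.random((n, p)) < het_rate[None, :]
        out.values[het_mask] = HET

    if cfg.missing_rate_mean > 0:
        a = 1.2
        b = a * (1 - cfg.missing_rate_mean) / cfg.missing_rate_mean
        miss_rate = rng.beta(a, b, size=p)
        miss_mask = rng.random((n, p)) < miss_rate[None, :]
        out.values[miss_mask] = MISSING

    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_gene_annotation(cfg: SimulationConfig) -> GeneAnnotation:
    """Lay out non-overlapping genes covering ~``gene_fraction`` of the genome
    and attach GO terms with Zipf-weighted popularity (long-tailed cluster
    sizes) to each gene; a gene carries 1 + Poisson(terms_per_gene_mean)
    terms, capped at 40."""
    if cfg.gene_fraction >= 1.0:
        raise ValueError("gene_fraction must be < 1")
    rng = np.random.default_rng(cfg.seed + 2)
    genes = []
    if cfg.gene_fraction > 0:
        mean_gap = cfg.mean_gene_length_bp * (1 - cfg.gene_fraction) / cfg.gene_fraction
        gid = 0
        for c in range(cfg.n_chrom):
            pos = 1
            chrom = f"chr{c + 1:02d}"
            while True:
                pos += int(rng.exponential(mean_gap)) + 1
                length = max(200, int(rng.lognormal(
                    np.log(cfg.mean_gene_length_bp), 0.6)))
                end = pos + length - 1
                if end > cfg.chrom_length_bp:
                    break
                gid += 1
                genes.append((f"gene{gid:05d}", chrom, pos, end,
                              "+" if rng.random() < 0.5 else "-"))
                pos = end
    gene_df = pd.DataFrame(genes, columns=["id", "chrom", "start", "end", "strand"])

    gene_to_go = {}
    if len(gene_df) and cfg.n_go_terms > 0:
        term_ids = [f"GO:{7_000_000 + t:07d}" for t in range(cfg.n_go_terms)]
        weights = 1.0 / np.arange(1, cfg.n_go_terms + 1) ** 1.2
        weights /= weights.sum()
        for gene_id in gene_df["id"]:
            k = int(min(40, 1 + rng.poisson(cfg.terms_per_gene_mean)))
            k = min(k, cfg.n_go_terms)
            picks = rng.choice(cfg.n_go_terms, size=k, replace=False, p=weights)
            gene_to_go[gene_id] = {term_ids[t] for t in picks}
    return GeneAnnotation(genes=gene_df, gene_to_go=gene_to_go)


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------

def _genic_marker_mask_for_terms(g: DosageMatrix, annotation: GeneAnnotation,
                                 terms: set) -> np.ndarray:
    """Boolean mask of markers lying inside any gene annotated with a term."""
    from .enrichment import assign_snps_to_genes

    assignments = assign_snps_to_genes(g.markers, annotation)
    return np.array([bool(t & terms) for t in assignments])


def simulate_qtl_architecture(g: DosageMatrix, annotation: Optional[GeneAnnotation],
                              cfg: SimulationConfig,
                              state: Optional[TruePanelState] = None) -> TruePanelState:
    """Sample QTL, draw their additive effects and compute true breeding values.

    Effects are N(0, scale^2) or sign-randomized Gamma(shape, scale).  Markers
    inside genes carrying a planted GO term get their |effect| multiplied by
    the configured factor, creating known enrichment for validation.  Breeding
    values are the exact dosage x effect product in -1/+1 coding (het/missing
    calls, if present, count as 0).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    p = g.n_markers
    qtl = np.sort(rng.choice(p, size=cfg.n_qtl, replace=False))
    effects = np.zeros(p)
    if cfg.qtl_effect_dist == "normal":
        effects[qtl] = rng.normal(0.0, cfg.qtl_effect_scale, size=cfg.n_qtl)
    else:
        mag = rng.gamma(cfg.qtl_effect_shape, cfg.qtl_effect_scale, size=cfg.n_qtl)
        effects[qtl] = mag * rng.choice([-1.0, 1.0], size=cfg.n_qtl)

    if cfg.planted_terms:
        if annotation is None:
            raise ValueError("planted terms require a gene annotation")
        available = annotation.all_terms
        for term, mult in cfg.planted_terms:
            if term not in available:
                raise ValueError(f"planted term {term!r} absent from annotation")
            mask = _genic_marker_mask_for_terms(g, annotation, {term})
            effects[mask] *= mult

    dosage = _signed_dosage(g)
    gvals = dosage @ effects
    labels = state.panel_labels if state is not None else np.zeros(g.n_lines, int)
    return TruePanelState(
        panel_labels=labels,
        true_effects=effects,
        true_breeding_values=gvals,
        qtl_index=qtl,
        planted_terms=tuple(cfg.planted_terms),
    )


def _signed_dosage(g: DosageMatrix) -> np.ndarray:
    """-1/+1 view of any coding; het or missing contribute 0."""
    if g.coding_state == "final":
        return g.values.astype(float)
    v = g.values
    out = np.zeros(v.shape, dtype=float)
    out[v == HOM_REF] = 1.0
    out[v == HOM_ALT] = -1.0
    return out


# ---------------------------------------------------------------------------
# field trials
# ---------------------------------------------------------------------------

def simulate_trials(state: TruePanelState, cfg: SimulationConfig,
                    line_ids=None, trait: str = "trait",
                    scale_g: bool = True) -> pd.DataFrame:
    """Generate lattice field-trial observations for the lines in ``state``.

    The generative model per plot is
    ``y = mu + beta*stand + gamma*flowering + year + rep(year) + block(rep, year)
    + g_i + (gy)_iy + e`` with independent normal random effects at the
    configured variances; with a single year the year and interaction terms
    drop out.  Crop stand is a truncated-Poisson plant count; days to
    flowering is a line-level covariate genetically correlated with the trait
    (correlation ``flowering_cor``) plus small plot noise, so the covariate
    adjustment in downstream model fitting is non-trivial.
    """
    if state.true_breeding_values is None:
        raise ValueError("state has no breeding values; run simulate_qtl_architecture")
    sg2, sga2, srep2, sblock2, se2 = cfg.variance_components
    if min(sg2, sga2, srep2, sblock2, se2) < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(cfg.seed + 4)

    gvals = np.asarray(state.true_breeding_values, dtype=float)
    n = len(gvals)
    if line_ids is None:
        line_ids = [f"L{i + 1:03d}" for i in range(n)]
    # rescale true breeding values to the configured genetic variance;
    # scale_g=False uses them as-is (callers simulating several sub-panel
    # trials scale once on the full panel so between-panel differences are
    # kept on a common scale)
    sd = gvals.std()
    gshift = (gvals - gvals.mean()) / (sd if sd > 0 else 1.0)
    g_effect = gshift * np.sqrt(sg2) if scale_g else gvals

    # line-level flowering covariate, genetically correlated with the trait
    rho = cfg.flowering_cor
    flowering_line = 70 + 8 * (rho * gshift
                               + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n))

    n_blocks = cfg.n_blocks
    block_of_line_base = np.arange(n) % n_blocks

    rows = []
    for year in range(1, cfg.n_years + 1):
        a_m = 5.0 * (year - 1)  # fixed year effect
        gy = rng.normal(0.0, np.sqrt(sga2), size=n) if cfg.n_years > 1 else np.zeros(n)
        for rep in range(1, cfg.n_reps + 1):
            r_km = rng.normal(0.0, np.sqrt(srep2))
            b_eff = rng.normal(0.0, np.sqrt(sblock2), size=n_blocks)
            perm = rng.permutation(n)  # resolvable: re-randomize lines to blocks
            block_of_line = block_of_line_base[np.argsort(perm)]
            for i in range(n):
                blk = block_of_line[i]
                stand = max(1, rng.poisson(cfg.stand_mean))
                flow = flowering_line[i] + rng.normal(0.0, 1.0)
                y = (cfg.mu + cfg.beta_stand * stand + cfg.gamma_flowering * flow
                     + a_m + r_km + b_eff[blk] + g_effect[i] + gy[i]
                     + rng.normal(0.0, np.sqrt(se2)))
                rows.append((line_ids[i], year, rep, blk + 1, stand, flow, y))

    return pd.DataFrame(
        rows, columns=["genotype", "year", "rep", "block", "stand", "flowering", trait]
    )


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def pick_plantable_term(g: DosageMatrix, annotation: GeneAnnotation,
                        min_snps: int = 20) -> str:
    """Return a GO term whose SNP cluster has at least ``min_snps`` markers."""
    from .enrichment import assign_snps_to_genes, build_go_clusters

    clusters = build_go_clusters(assign_snps_to_genes(g.markers, annotation))
    for term, idx in sorted(clusters.items(), key=lambda kv: -len(kv[1])):
        if len(idx) >= min_snps:
            return term
    raise ValueError(f"no GO term with >= {min_snps} SNPs in this annotation")
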