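"""Per-SNP likelihood-ratio genome scan for allometric QTLs.

At each biallelic RIL SNP the progenies split into the two homozygous
genotype classes.  Under the alternative each class has its own power-law
mean curve per density, alpha_jd * x_i(t)**beta_jd, evaluated at that
progeny's own predictor trajectory; under the null the classes share one
curve per density.  Residuals across the stacked (high; low) week grids
follow the two-density SAD(1) covariance with parameters (phi1, phi2,
sigma2).  The scan statistic is LR = -2 (logL0 - logL1), converted to
LOD = LR / (2 ln 10); genome-wide significance comes from a permutation
null that shuffles whole progenies (both densities together) against the
genotype matrix and records the per-permutation maximum LR.

A second, nested test per SNP asks whether the QTL's allometric curves
differ between planting densities (genotype-by-environment interaction):
its null constrains alpha_jh = alpha_jl and beta_jh = beta_jl per genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .datatypes import (
    MISSING,
    GenotypeMatrix,
    LongitudinalTraitSet,
    MeanModelParams,
    TraitPair,
    TraitPairData,
)
from .sad import SadParams, assemble_joint_covariance, log_density

logger = logging.getLogger(__name__)

LOD_PER_LR = 1.0 / (2.0 * np.log(10.0))

HYPOTHESES = ("H0-pooled", "H1", "H0-density-equal")


@dataclass
class ScanConfig:
    """Tuning knobs of the scan; defaults follow the study design."""

    n_perm: int = 1000
    level: float = 0.01
    min_group: int = 5
    n_starts: int = 3
    fatol: float = 1e-9   # on the profiled objective ~ 2x logL scale
    xatol: float = 1e-6
    maxiter: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.level <= 1.0:
            raise ValueError("level must lie in (0, 1]")
        if self.n_perm < 1.0 / self.level:
            raise ValueError("n_perm must be at least 1/level")


@dataclass
class FitResult:
    hypothesis: str
    mean_params: MeanModelParams
    sad_params: SadParams
    loglik: float
    converged: bool = True


@dataclass
class ScanRecord:
    snp_id: str
    chrom: str
    pos: int
    logl0: float = np.nan
    logl1: float = np.nan
    lr: float = np.nan
    lod: float = np.nan
    mean_params: MeanModelParams | None = None
    sad_params: SadParams | None = None
    n_group: tuple[int, int] = (0, 0)
    n_excluded: int = 0
    skipped: bool = False
    converged: bool = True
    significant: bool | None = None
    interaction_lr: float | None = None


class PairDesign:
    """Arrays of one trait pair laid out for the likelihood kernels.

    Weeks where either member of the pair is missing (or the predictor is
    non-positive) are masked for that progeny; the SAD(1) likelihood then
    marginalizes them exactly.
    """

    def __init__(self, data: TraitPairData):
        self.data = data
        self.times = {}
        self.y = {}
        self.logx = {}
        self.logy = {}
        for d in ("high", "low"):
            t = np.ascontiguousarray(data.times[d], dtype=np.float64)
            x = np.array(data.x[d], dtype=np.float64)
            y = np.array(data.y[d], dtype=np.float64)
            bad = ~np.isfinite(x) | ~np.isfinite(y) | (x <= 0)
            x = np.where(bad, np.nan, x)
            y = np.where(bad, np.nan, y)
            with np.errstate(invalid="ignore", divide="ignore"):
                ly = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)
            self.times[d] = t
            self.y[d] = np.ascontiguousarray(y)
            self.logx[d] = np.ascontiguousarray(np.log(x))
            self.logy[d] = np.ascontiguousarray(ly)

    @property
    def n_progeny(self) -> int:
        return self.data.n_progeny

    def kernel_args(self):
        return (
            self.y["high"], self.logx["high"], self.logy["high"], self.times["high"],
            self.y["low"], self.logx["low"], self.logy["low"], self.times["low"],
        )


def _unpack_params(hypothesis: str, params: np.ndarray, alphas: np.ndarray,
                   sigma2: float) -> tuple[MeanModelParams, SadParams]:
    beta_of = _engine.BETA_OF[hypothesis]
    n_beta = _engine.N_GROUPS[hypothesis]
    mp = MeanModelParams()
    for j in (0, 1):
        mp.alpha[j] = {}
        mp.beta[j] = {}
        for di, d in enumerate(("high", "low")):
            g = beta_of[j, di]
            mp.alpha[j][d] = float(max(alphas[g], 1e-12))
            mp.beta[j][d] = float(params[g])
    sp = SadParams(
        phi_high=float(params[n_beta]),
        phi_low=float(params[n_beta + 1]),
        sigma2=float(max(sigma2, 1e-300)),
    )
    return mp, sp


def fit_model(
    design: PairDesign | TraitPairData,
    grouping: np.ndarray,
    hypothesis: str = "H1",
    config: ScanConfig | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one hypothesis for one genotype grouping.

    ``grouping`` holds a genotype in {0, 1} per progeny, or -1 to exclude.
    Initialization is the per-group log-log OLS slope with lag-scale
    multi-starts on (phi_high, phi_low); alpha and sigma2 are profiled.
    """
    if isinstance(design, TraitPairData):
        design = PairDesign(design)
    config = config or ScanConfig()
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    geno = np.asarray(grouping, dtype=np.int64)
    if geno.shape[0] != design.n_progeny:
        raise ValueError("grouping length must equal number of progenies")
    beta_of = _engine.BETA_OF[hypothesis]
    n_beta = _engine.N_GROUPS[hypothesis]
    y_h, lx_h, ly_h, t_h, y_l, lx_l, ly_l, t_l = design.kernel_args()
    x, f, n_eval = _engine._fit_hypothesis(
        beta_of, n_beta, y_h, lx_h, ly_h, t_h, y_l, lx_l, ly_l, t_l,
        geno, config.fatol, config.xatol, config.maxiter, config.n_starts,
    )
    if not np.isfinite(f) or f >= _engine._BIG:
        raise RuntimeError(
            f"all optimizer starts failed for {hypothesis} (n_eval={n_eval})"
        )
    logl, alphas, sigma2 = _engine._loglik_from_objective(
        x, beta_of, n_beta, y_h, lx_h, t_h, y_l, lx_l, t_l, geno
    )
    mp, sp = _unpack_params(hypothesis, x, alphas, sigma2)
    return FitResult(
        hypothesis=hypothesis, mean_params=mp, sad_params=sp,
        loglik=float(logl), converged=n_eval < 3 * config.maxiter,
    )


def model_loglik(
    data: TraitPairData,
    grouping: np.ndarray,
    mean_params: MeanModelParams,
    sad_params: SadParams,
) -> float:
    """Joint log-likelihood via the dense covariance path (reference route).

    Builds each progeny's stacked mean vector and the full Sigma explicitly
    (sad module), deleting rows/columns for missing weeks.  The fast
    whitened kernel in ``_engine`` must agree with this to numerical
    precision; tests assert it.
    """
    geno = np.asarray(grouping, dtype=int)
    if geno.shape[0] != data.n_progeny:
        raise ValueError("grouping length must equal number of progenies")
    assembly = assemble_joint_covariance(data.times["high"], data.times["low"], sad_params)
    total = 0.0
    n_excluded = 0
    for i in range(data.n_progeny):
        j = geno[i]
        if j < 0:
            n_excluded += 1
            continue
        resid = []
        observed = []
        for d in ("high", "low"):
            x = data.x[d][i]
            y = data.y[d][i]
            ok = np.isfinite(x) & np.isfinite(y) & (x > 0)
            mu = mean_params.mean_curve(x[ok], j, d)
            resid.append(y[ok] - mu)
            observed.append(ok)
        total += log_density(
            np.concatenate(resid), assembly, observed=np.concatenate(observed)
        )
    if n_excluded:
        logger.debug("model_loglik: %d progenies excluded (missing genotype)", n_excluded)
    return float(total)


def lr_test(
    design: PairDesign | TraitPairData,
    snp_codes: np.ndarray,
    snp_id: str = "",
    chrom: str = "",
    pos: int = 0,
    h0_fit: FitResult | None = None,
    config: ScanConfig | None = None,
) -> ScanRecord:
    """QTL existence test at one SNP: H1 (genotype curves) vs pooled H0."""
    if isinstance(design, TraitPairData):
        design = PairDesign(design)
    config = config or ScanConfig()
    geno = np.asarray(snp_codes, dtype=np.int64)
    n0 = int(np.sum(geno == 0))
    n1 = int(np.sum(geno == 1))
    rec = ScanRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, n_group=(n0, n1),
        n_excluded=int(np.sum(geno == MISSING)),
    )
    if n0 < config.min_group or n1 < config.min_group:
        rec.skipped = True
        return rec
    if h0_fit is None or rec.n_excluded > 0:
        # L0 must be computed on the same progeny subset as L1
        h0_group = np.where(geno == MISSING, -1, 0)
        h0_fit = fit_model(design, h0_group, "H0-pooled", config)
    h1_fit = fit_model(design, geno, "H1", config)
    rec.logl0 = h0_fit.loglik
    rec.logl1 = h1_fit.loglik
    rec.lr = max(-2.0 * (rec.logl0 - rec.logl1), 0.0)
    rec.lod = rec.lr * LOD_PER_LR
    rec.mean_params = h1_fit.mean_params
    rec.sad_params = h1_fit.sad_params
    rec.converged = h0_fit.converged and h1_fit.converged
    return rec


def align_progenies(
    genotypes: GenotypeMatrix, phenotypes: LongitudinalTraitSet
) -> tuple[np.ndarray, LongitudinalTraitSet]:
    """Match progeny columns of the genotype matrix to phenotype rows.

    Returns the genotype code matrix reordered to the shared progeny set
    (phenotype order) and the phenotype subset.  Errors when no progenies
    are shared.
    """
    gidx = {p: i for i, p in enumerate(genotypes.progeny_ids)}
    shared = [p for p in phenotypes.progeny_ids if p in gidx]
    if not shared:
        raise ValueError("genotype and phenotype sets share no progeny ids")
    if len(shared) < len(phenotypes.progeny_ids) or len(shared) < len(genotypes.progeny_ids):
        logger.info("aligning on %d shared progenies", len(shared))
    pheno_idx = [phenotypes.progeny_ids.index(p) for p in shared]
    codes = genotypes.codes[:, [gidx[p] for p in shared]]
    return codes, phenotypes.subset_progeny(np.asarray(pheno_idx))


def genome_scan(
    genotypes: GenotypeMatrix,
    phenotypes: LongitudinalTraitSet,
    pair: TraitPair,
    config: ScanConfig | None = None,
) -> list[ScanRecord]:
    """LR/LOD at every SNP for one allometric trait pair."""
    config = config or ScanConfig()
    if genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    codes, pheno = align_progenies(genotypes, phenotypes)
    design = PairDesign(TraitPairData.from_traits(pheno, pair))
    h0_fit = fit_model(design, np.zeros(design.n_progeny, dtype=np.int64),
                       "H0-pooled", config)
    logger.info("scanning %d SNPs x %d progenies for pair %s",
                genotypes.n_snps, design.n_progeny, pair.label)
    has_missing = (codes == MISSING).any(axis=1)
    records: list[ScanRecord] = []
    if not has_missing.any():
        # fast path: one kernel call over all SNPs, shared H0
        logl1, params, alphas, sigma2s = _engine._scan_h1(
            np.ascontiguousarray(codes), _engine.BETA_OF["H1"],
            *design.kernel_args(), config.min_group,
            config.fatol, config.xatol, config.maxiter, config.n_starts,
        )
        for s in range(genotypes.n_snps):
            geno = codes[s]
            rec = ScanRecord(
                snp_id=str(genotypes.snp_ids[s]), chrom=str(genotypes.chrom[s]),
                pos=int(genotypes.pos[s]),
                n_group=(int(np.sum(geno == 0)), int(np.sum(geno == 1))),
            )
            if np.isnan(logl1[s]):
                rec.skipped = True
            else:
                rec.logl0 = h0_fit.loglik
                rec.logl1 = float(logl1[s])
                rec.lr = max(-2.0 * (rec.logl0 - rec.logl1), 0.0)
                rec.lod = rec.lr * LOD_PER_LR
                mp, sp = _unpack_params("H1", params[s], alphas[s], sigma2s[s])
                rec.mean_params, rec.sad_params = mp, sp
            records.append(rec)
    else:
        for s in range(genotypes.n_snps):
            records.append(
                lr_test(design, codes[s], snp_id=str(genotypes.snp_ids[s]),
                        chrom=str(genotypes.chrom[s]), pos=int(genotypes.pos[s]),
                        h0_fit=h0_fit, config=config)
            )
    n_skip = sum(r.skipped for r in records)
    if n_skip:
        logger.info("%d SNPs skipped (genotype group below %d)", n_skip, config.min_group)
    return records


@dataclass
class PermutationResult:
    lr_threshold: float
    lod_threshold: float
    max_lr: np.ndarray = field(repr=False)
    level: float = 0.05
    n_perm: int = 0


def permutation_threshold(
    genotypes: GenotypeMatrix,
    phenotypes: LongitudinalTraitSet,
    pair: TraitPair,
    n_perm: int,
    level: float,
    seed: int,
    config: ScanConfig | None = None,
) -> PermutationResult:
    """Genome-wide LR threshold from progeny-level permutations.

    Each permutation reassigns whole progenies (their high- and low-density
    series together) to genotype columns, preserving the joint covariance
    under the null; the (1 - level) empirical quantile of the per-permutation
    maximum LR is the threshold.
    """
    config = config or ScanConfig(n_perm=n_perm, level=level)
    if n_perm < 1.0 / level:
        raise ValueError("n_perm must be at least 1/level")
    codes, pheno = align_progenies(genotypes, phenotypes)
    design = PairDesign(TraitPairData.from_traits(pheno, pair))
    if (codes == MISSING).any():
        raise NotImplementedError(
            "permutation thresholds require complete genotypes; "
            "drop or impute missing calls first"
        )
    h0 = fit_model(design, np.zeros(design.n_progeny, dtype=np.int64),
                   "H0-pooled", config)
    rng = np.random.default_rng(seed)
    kargs = design.kernel_args()
    max_lr = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(design.n_progeny)
        best_l1 = _engine._max_logl1(
            np.ascontiguousarray(codes[:, perm]), _engine.BETA_OF["H1"], *kargs,
            config.min_group, config.fatol, config.xatol, config.maxiter,
            config.n_starts,
        )
        max_lr[p] = max(-2.0 * (h0.loglik - best_l1), 0.0)
    thr = float(np.quantile(max_lr, 1.0 - level, method="higher"))
    return PermutationResult(
        lr_threshold=thr, lod_threshold=thr * LOD_PER_LR,
        max_lr=max_lr, level=level, n_perm=n_perm,
    )


def density_interaction_test(
    design: PairDesign | TraitPairData,
    snp_codes: np.ndarray,
    h1_fit: FitResult | None = None,
    config: ScanConfig | None = None,
) -> float:
    """G x E test: are the genotype allometric curves density-specific?

    The null shares (alpha_j, beta_j) across densities per genotype while
    the SAD(1) covariance keeps its density-specific phis; LR is against
    the unconstrained H1 (reused from the main scan when provided).
    """
    if isinstance(design, TraitPairData):
        design = PairDesign(design)
    config = config or ScanConfig()
    geno = np.asarray(snp_codes, dtype=np.int64)
    if h1_fit is None:
        h1_fit = fit_model(design, geno, "H1", config)
    h0_fit = fit_model(design, geno, "H0-density-equal", config)
    return max(-2.0 * (h0_fit.loglik - h1_fit.loglik), 0.0)
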