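"""Synthetic RIL genotypes and two-density longitudinal leaf traits.

The generator reproduces the statistical structure the likelihood assumes,
at the motivating study's design scale: 84 recombinant inbred progenies,
5 chromosomes, weekly measurements over 7 weeks at high planting density
and 8 at low density.  Petiole length P follows an S-shaped (logistic)
growth curve with progeny-level lognormal variation; leaf length L is
generated from P through the petiole-leaf power law and leaf area A from L
through the leaf-area power law, each with SAD(1)-structured residuals.
Causal SNPs act by giving the two homozygous genotype classes their own
(alpha, beta) per density.

All randomness flows from one seed through named ``numpy`` SeedSequence
substreams, so e.g. changing the SNP count leaves the phenotype draws
untouched.  Causal genotype columns are drawn from their own substream and
the flanking markers are extended outward from the causal anchor, keeping
both the causal column stable and the local linkage structure intact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, LongitudinalTraitSet, MISSING
from .sad import SadParams, assemble_joint_covariance

# Trait floor: SAD residuals are unbounded below, so on rare draws a trait
# could dip non-positive early in growth; measurements are clipped here.
TRAIT_FLOOR = 0.02


@dataclass
class LogisticSpec:
    """K / (1 + exp(-r (t - t0))): asymptote K, rate r, inflection week t0."""

    K: float
    r: float
    t0: float

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.K / (1.0 + np.exp(-self.r * (t - self.t0)))


@dataclass
class GrowthSpec:
    """Density-specific logistic growth with progeny-level variation.

    ``sd_logK`` / ``sd_logr`` are the standard deviations of lognormal
    progeny multipliers applied to K and r; the same progeny draws act in
    both densities (the progeny's identity travels with it).
    """

    high: LogisticSpec
    low: LogisticSpec
    sd_logK: float = 0.10
    sd_logr: float = 0.06

    def __post_init__(self) -> None:
        for spec in (self.high, self.low):
            if spec.K <= 0 or spec.r <= 0:
                raise ValueError("logistic growth needs K > 0 and r > 0")


@dataclass
class PairBaseline:
    """Baseline (no-QTL) allometry alpha/beta per density for one pair."""

    alpha: dict[str, float]
    beta: dict[str, float]


@dataclass
class QtlEffect:
    """One causal SNP: genotype- and density-specific allometry parameters.

    ``alpha[j][d]`` / ``beta[j][d]`` for genotype j in {0,1} and density d;
    this mirrors the alternative-hypothesis parameterization directly.
    """

    snp_index: int
    pair: str  # "LA" or "PL"
    alpha: dict[int, dict[str, float]]
    beta: dict[int, dict[str, float]]


# Defaults emulate the study conditions: high density overtakes low density
# mid-experiment, with mean-curve crossovers near week 3.2 (P), 3.7 (L) and
# 4.1 (A).  Constants frozen from a one-off root-finding calibration.
DEFAULT_GROWTH = GrowthSpec(
    high=LogisticSpec(K=3.10, r=1.20, t0=3.085),
    low=LogisticSpec(K=2.30, r=1.30, t0=2.45),
)
DEFAULT_PL_BASELINE = PairBaseline(
    alpha={"high": 1.9273, "low": 2.0754}, beta={"high": 0.90, "low": 0.90}
)
DEFAULT_LA_BASELINE = PairBaseline(
    alpha={"high": 0.4284, "low": 0.4727}, beta={"high": 1.80, "low": 1.80}
)
DEFAULT_SAD = {
    "PL": SadParams(phi_high=0.85, phi_low=0.80, sigma2=0.010),
    "LA": SadParams(phi_high=0.85, phi_low=0.80, sigma2=0.040),
}


@dataclass
class SimDesign:
    """Design constants of a simulated mapping experiment."""

    n_progeny: int = 84
    n_chrom: int = 5
    snps_per_chrom: int = 400
    recomb_fraction: float = 0.02
    snp_spacing: int = 75_000
    times_high: np.ndarray = field(default_factory=lambda: np.arange(1.0, 8.0))
    times_low: np.ndarray = field(default_factory=lambda: np.arange(1.0, 9.0))
    growth: GrowthSpec = field(default_factory=lambda: DEFAULT_GROWTH)
    baselines: dict = field(
        default_factory=lambda: {"PL": DEFAULT_PL_BASELINE, "LA": DEFAULT_LA_BASELINE}
    )
    sad: dict = field(default_factory=lambda: dict(DEFAULT_SAD))
    qtls: list[QtlEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 2:
            raise ValueError("need at least 2 progenies")
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ValueError("recombination fraction must lie in [0, 0.5]")

    @property
    def n_snps(self) -> int:
        return self.n_chrom * self.snps_per_chrom


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("genotypes", "causal", "growth", "noise_PL", "noise_LA")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def simulate_ril_genotypes(
    design: SimDesign, rng: np.random.Generator | None = None,
    anchors: dict[int, np.ndarray] | None = None,
) -> GenotypeMatrix:
    """Fully homozygous RIL genotypes via a Markov chain along each chromosome.

    Adjacent SNPs switch parental class with probability equal to the
    inter-SNP recombination fraction; marginal class frequencies are 0.5.
    ``anchors`` optionally pins given (global SNP index -> genotype column)
    values — the chain is then extended outward from the anchor, which
    preserves both the pinned column and the linkage decay around it
    (the chain is reversible with uniform marginals).
    """
    if rng is None:
        rng = _streams(design.seed)["genotypes"]
    anchors = anchors or {}
    n, r = design.n_progeny, design.recomb_fraction
    codes = np.empty((design.n_snps, n), dtype=np.int8)
    snp_ids, chroms, pos = [], [], []
    for c in range(design.n_chrom):
        lo = c * design.snps_per_chrom
        hi = lo + design.snps_per_chrom
        chrom_anchors = sorted(k for k in anchors if lo <= k < hi)
        start = chrom_anchors[0] if chrom_anchors else lo
        if start in anchors:
            codes[start] = anchors[start]
        else:
            codes[start] = (rng.random(n) < 0.5).astype(np.int8)
        for s in range(start + 1, hi):  # rightward extension
            flip = rng.random(n) < r
            codes[s] = np.where(flip, 1 - codes[s - 1], codes[s - 1])
        for s in range(start - 1, lo - 1, -1):  # leftward extension
            flip = rng.random(n) < r
            codes[s] = np.where(flip, 1 - codes[s + 1], codes[s + 1])
        for s in range(lo, hi):
            snp_ids.append(f"snp_c{c + 1}_{s - lo + 1}")
            chroms.append(str(c + 1))
            pos.append((s - lo + 1) * design.snp_spacing)
    return GenotypeMatrix(
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos),
        codes=codes,
        progeny_ids=[f"RIL{i + 1:03d}" for i in range(n)],
    )


def simulate_predictor_growth(
    design: SimDesign, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Logistic petiole-length trajectories per density, (n_progeny, T_d).

    Progeny-level lognormal multipliers on (K, r) are shared between the two
    densities; trajectories are strictly positive and increasing in t.
    """
    if rng is None:
        rng = _streams(design.seed)["growth"]
    g = design.growth
    mult_K = np.exp(g.sd_logK * rng.standard_normal(design.n_progeny))
    mult_r = np.exp(g.sd_logr * rng.standard_normal(design.n_progeny))
    out = {}
    for d, spec, times in (
        ("high", g.high, design.times_high),
        ("low", g.low, design.times_low),
    ):
        K = spec.K * mult_K
        r = spec.r * mult_r
        t = np.asarray(times, dtype=float)
        out[d] = K[:, None] / (1.0 + np.exp(-r[:, None] * (t[None, :] - spec.t0)))
    return out


def simulate_response_from_allometry(
    x: dict[str, np.ndarray],
    genotypes: np.ndarray,
    alpha: dict[int, dict[str, float]],
    beta: dict[int, dict[str, float]],
    sad: SadParams,
    rng: np.random.Generator,
    times: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Response trajectories y = alpha_jd * x**beta_jd + SAD(1) residuals.

    ``genotypes`` assigns each progeny its class at the causal SNP (all
    zeros for a no-QTL baseline).  ``sad.sigma2 == 0`` yields the exact
    power law with no residual.
    """
    for d in x:
        if np.any(np.asarray(x[d]) <= 0):
            raise ValueError("predictor trajectories must be strictly positive")
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    out = {}
    if sad.sigma2 > 0:
        assembly = assemble_joint_covariance(times["high"], times["low"], sad)
        chol = assembly.cholesky
        noise = (chol @ rng.standard_normal((assembly.dim, n))).T
    else:
        noise = np.zeros((n, len(times["high"]) + len(times["low"])))
    th = len(times["high"])
    for d, sl in (("high", slice(0, th)), ("low", slice(th, None))):
        a = np.array([alpha[int(j)][d] for j in genotypes])
        b = np.array([beta[int(j)][d] for j in genotypes])
        out[d] = a[:, None] * np.power(x[d], b[:, None]) + noise[:, sl]
    return out


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)


def truth_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _qtl_from_baseline(
    snp_index: int, pair: str, base: PairBaseline, alpha_effect: float,
    beta_effect: float = 0.0,
) -> QtlEffect:
    """Symmetric genotype effect around the baseline: alpha_j = base * exp(+-h)."""
    alpha = {
        j: {d: base.alpha[d] * np.exp(s * alpha_effect) for d in ("high", "low")}
        for j, s in ((0, -0.5), (1, 0.5))
    }
    beta = {
        j: {d: base.beta[d] + s * beta_effect for d in ("high", "low")}
        for j, s in ((0, -0.5), (1, 0.5))
    }
    return QtlEffect(snp_index=snp_index, pair=pair, alpha=alpha, beta=beta)


# log-scale alpha separations giving each causal locus a generating PVE
# near 1.5% (the headline QTLs explain 0.99-1.91% of phenotypic variance)
DEFAULT_ALPHA_EFFECTS = {"PL": 0.028, "LA": 0.059}


def default_qtls(
    design: SimDesign, alpha_effect: float | dict[str, float] | None = None
) -> list[QtlEffect]:
    """Two causal SNPs: a positionQTL (P-L) on chromosome 1, a shapeQTL
    (L-A) on chromosome 2, each mid-chromosome."""
    if alpha_effect is None:
        alpha_effect = DEFAULT_ALPHA_EFFECTS
    if not isinstance(alpha_effect, dict):
        alpha_effect = {"PL": alpha_effect, "LA": alpha_effect}
    spc = design.snps_per_chrom
    return [
        _qtl_from_baseline(spc // 2, "PL", design.baselines["PL"], alpha_effect["PL"]),
        _qtl_from_baseline(spc + spc // 2, "LA", design.baselines["LA"], alpha_effect["LA"]),
    ]


def simulate_dataset(
    design: SimDesign,
) -> tuple[GenotypeMatrix, LongitudinalTraitSet, dict]:
    """Genotypes, phenotypes and the truth record for one design."""
    streams = _streams(design.seed)
    n = design.n_progeny
    anchors = {
        q.snp_index: (streams["causal"].random(n) < 0.5).astype(np.int8)
        for q in design.qtls
    }
    gm = simulate_ril_genotypes(design, rng=streams["genotypes"], anchors=anchors)
    times = {"high": np.asarray(design.times_high, float),
             "low": np.asarray(design.times_low, float)}
    P = simulate_predictor_growth(design, rng=streams["growth"])

    def params_for(pair: str):
        base = design.baselines[pair]
        for q in design.qtls:
            if q.pair == pair:
                return q.alpha, q.beta, anchors[q.snp_index].astype(int)
        shared_a = {j: dict(base.alpha) for j in (0, 1)}
        shared_b = {j: dict(base.beta) for j in (0, 1)}
        return shared_a, shared_b, np.zeros(n, dtype=int)

    a_pl, b_pl, g_pl = params_for("PL")
    L = simulate_response_from_allometry(
        P, g_pl, a_pl, b_pl, design.sad["PL"], streams["noise_PL"], times
    )
    L = {d: np.maximum(L[d], TRAIT_FLOOR) for d in L}
    a_la, b_la, g_la = params_for("LA")
    A = simulate_response_from_allometry(
        L, g_la, a_la, b_la, design.sad["LA"], streams["noise_LA"], times
    )
    A = {d: np.maximum(A[d], TRAIT_FLOOR) for d in A}

    values = {
        d: np.stack([P[d], L[d], A[d]], axis=1) for d in ("high", "low")
    }
    traits = LongitudinalTraitSet(
        progeny_ids=list(gm.progeny_ids), times=times, values=values
    )
    truth = {
        "seed": design.seed,
        "n_progeny": n,
        "n_snps": design.n_snps,
        "recomb_fraction": design.recomb_fraction,
        "growth": asdict(design.growth),
        "baselines": {p: asdict(design.baselines[p]) for p in design.baselines},
        "sad": {p: asdict(design.sad[p]) for p in design.sad},
        "qtls": [
            {
                "snp_id": str(gm.snp_ids[q.snp_index]),
                "snp_index": q.snp_index,
                "pair": q.pair,
                "alpha": {str(j): q.alpha[j] for j in q.alpha},
                "beta": {str(j): q.beta[j] for j in q.beta},
            }
            for q in design.qtls
        ],
    }
    return gm, traits, truth


def make_paper_like_dataset(
    seed: int,
    snps_per_chrom: int = 400,
    alpha_effect: float | dict[str, float] | None = None,
    design: SimDesign | None = None,
) -> tuple[GenotypeMatrix, LongitudinalTraitSet, dict]:
    """Default study-scale dataset: 84 progenies, 5 chromosomes, 7/8 weeks.

    ``alpha_effect`` is the log-scale separation of the two genotype
    classes' alpha at the two causal SNPs (one per allometric pair).
    """
    if design is None:
        design = SimDesign(seed=seed, snps_per_chrom=snps_per_chrom)
        design.qtls = default_qtls(design, alpha_effect=alpha_effect)
    else:
        design.seed = seed
    return simulate_dataset(design)
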