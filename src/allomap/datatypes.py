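"""Core data containers for the allometric functional-mapping pipeline.

A recombinant inbred line (RIL) population carries two homozygous genotype
classes at every biallelic SNP, coded 0/1 (missing = -1).  Phenotypes are
longitudinal measurements of three leaf traits — petiole length P (cm),
leaf length L (cm) and leaf area A (cm²) — taken weekly under two planting
densities with possibly different numbers of timepoints per density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

DENSITIES = ("high", "low")
TRAITS = ("P", "L", "A")

TRAIT_UNITS = {"P": "cm", "L": "cm", "A": "cm^2"}


class DataError(ValueError):
    """Raised when an input table or container violates its contract."""


@dataclass
class GenotypeMatrix:
    """SNP x progeny genotype codes with a genomic map.

    ``codes`` is an int8 array with entries in {0, 1, MISSING}; 0 and 1 are
    the two homozygous parental classes.  Heterozygous calls do not occur in
    a fully selfed RIL model and are recoded to missing upstream.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    codes: np.ndarray
    progeny_ids: list[str]

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise DataError("codes must be a 2-D SNP x progeny array")
        n_snp = self.codes.shape[0]
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == n_snp):
            raise DataError("snp_ids, chrom, pos and codes rows must agree")
        if self.codes.shape[1] != len(self.progeny_ids):
            raise DataError("codes columns must match progeny_ids")
        bad = ~np.isin(self.codes, (0, 1, MISSING))
        if bad.any():
            raise DataError("genotype codes must be 0, 1 or missing (-1)")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return self.codes.shape[0]

    @property
    def n_progeny(self) -> int:
        return self.codes.shape[1]

    def minor_genotype_frequency(self) -> np.ndarray:
        """Per-SNP frequency of the rarer homozygous class among called progenies."""
        called = self.codes != MISSING
        n_called = called.sum(axis=1)
        n_one = (self.codes == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(n_called > 0, n_one / np.maximum(n_called, 1), 0.0)
        return np.minimum(f1, 1.0 - f1)

    def missing_fraction(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            codes=self.codes[mask],
            progeny_ids=list(self.progeny_ids),
        )


@dataclass
class LongitudinalTraitSet:
    """Per-progeny, per-density weekly time series of the three leaf traits.

    ``times[d]`` is the strictly increasing week grid for density ``d`` and
    ``values[d]`` an (n_progeny, n_traits, T_d) array of progeny means;
    NaN marks a missing week.  The two grids may differ in length
    (7 high-density vs 8 low-density weeks in the motivating design).
    """

    progeny_ids: list[str]
    times: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        for d in self.times:
            if d not in DENSITIES:
                raise DataError(f"unknown density label {d!r}")
            self.times[d] = np.asarray(self.times[d], dtype=float)
            self.values[d] = np.asarray(self.values[d], dtype=float)
            if np.any(np.diff(self.times[d]) <= 0):
                raise DataError(f"times for density {d!r} not strictly increasing")
            v = self.values[d]
            if v.shape != (len(self.progeny_ids), len(self.traits), len(self.times[d])):
                raise DataError(
                    f"values[{d!r}] shape {v.shape} inconsistent with "
                    f"(n_progeny, n_traits, T)"
                )
            if v.size and np.any(v[np.isfinite(v)] < 0):
                raise DataError("trait values must be non-negative")

    @property
    def densities(self) -> tuple[str, ...]:
        return tuple(d for d in DENSITIES if d in self.times)

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)

    def trait_matrix(self, density: str, trait: str) -> np.ndarray:
        """(n_progeny, T) matrix for one trait under one density."""
        return self.values[density][:, self.traits.index(trait), :]

    def subset_progeny(self, idx: np.ndarray) -> "LongitudinalTraitSet":
        return LongitudinalTraitSet(
            progeny_ids=[self.progeny_ids[i] for i in idx],
            times={d: self.times[d].copy() for d in self.times},
            values={d: self.values[d][idx] for d in self.values},
            traits=self.traits,
        )


@dataclass(frozen=True)
class TraitPair:
    """Predictor/response roles in one allometric relationship."""

    predictor: str
    response: str

    def __post_init__(self) -> None:
        if self.predictor == self.response:
            raise DataError("predictor and response traits must differ")

    @property
    def label(self) -> str:
        return f"{self.predictor}-{self.response}"


#: leaf length -> leaf area allometry ("shape" relation)
PAIR_LA = TraitPair("L", "A")
#: petiole length -> leaf length allometry ("position" relation)
PAIR_PL = TraitPair("P", "L")
#: petiole length -> leaf area (weak; kept for goodness-of-fit reporting)
PAIR_PA = TraitPair("P", "A")

PAIRS = {"LA": PAIR_LA, "PL": PAIR_PL, "PA": PAIR_PA}


@dataclass
class TraitPairData:
    """Predictor/response arrays for one pair, ready for the likelihood.

    ``x[d]`` and ``y[d]`` are (n_progeny, T_d); rows align with
    ``progeny_ids``.  NaNs in either member mark a missing week for that
    progeny (the likelihood drops the corresponding covariance rows).
    """

    progeny_ids: list[str]
    pair: TraitPair
    times: dict[str, np.ndarray]
    x: dict[str, np.ndarray]
    y: dict[str, np.ndarray]

    @classmethod
    def from_traits(cls, traits: LongitudinalTraitSet, pair: TraitPair) -> "TraitPairData":
        return cls(
            progeny_ids=list(traits.progeny_ids),
            pair=pair,
            times={d: traits.times[d] for d in traits.densities},
            x={d: traits.trait_matrix(d, pair.predictor) for d in traits.densities},
            y={d: traits.trait_matrix(d, pair.response) for d in traits.densities},
        )

    @property
    def densities(self) -> tuple[str, ...]:
        return tuple(d for d in DENSITIES if d in self.times)

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)


@dataclass
class MeanModelParams:
    """Power-law mean parameters per genotype class and density.

    ``alpha[j][d]`` and ``beta[j][d]`` give the allometric scale and
    exponent for genotype j in {0, 1} and density d in {"high", "low"}.
    Under the pooled null the two genotype entries coincide.
    """

    alpha: dict[int, dict[str, float]] = field(default_factory=dict)
    beta: dict[int, dict[str, float]] = field(default_factory=dict)

    def mean_curve(self, x: np.ndarray, genotype: int, density: str) -> np.ndarray:
        return self.alpha[genotype][density] * np.power(x, self.beta[genotype][density])
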