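"""Readers and writers for the tabular formats the pipeline touches.

Genotypes come either as a delimited table (snp_id, chrom, pos, one column
per progeny; codes 0/1, missing as NA/./empty) or as a VCF whose GT field
is collapsed to the two homozygous RIL classes (0/0 -> 0, 1/1 -> 1,
heterozygous or unknown -> missing).  On read, SNPs with minor genotype
frequency below 5% or with at least half the progenies missing are dropped,
matching the upstream variant-screening rules.

Phenotypes are a long table (progeny, density, trait, week, value);
replicate rows for the same cell are averaged into progeny means.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DENSITIES,
    MISSING,
    TRAITS,
    DataError,
    GenotypeMatrix,
    LongitudinalTraitSet,
)

logger = logging.getLogger(__name__)

MIN_GENOTYPE_FREQ = 0.05
MAX_MISSING_FRACTION = 0.50

_MISSING_TOKENS = {"", "na", "nan", ".", "-1", "./.", "none"}


def apply_snp_filters(
    gm: GenotypeMatrix,
    min_freq: float = MIN_GENOTYPE_FREQ,
    max_missing: float = MAX_MISSING_FRACTION,
) -> GenotypeMatrix:
    """Drop SNPs failing the frequency or missing-rate screen.

    The two filters act on independent per-SNP statistics, so their order
    is immaterial.  Raises when nothing survives.
    """
    freq_ok = gm.minor_genotype_frequency() >= min_freq
    miss_ok = gm.missing_fraction() < max_missing
    keep = freq_ok & miss_ok
    logger.info(
        "SNP filters: %d/%d kept (%d low-frequency, %d high-missing)",
        int(keep.sum()), gm.n_snps, int((~freq_ok).sum()), int((~miss_ok).sum()),
    )
    if not keep.any():
        raise DataError("no SNPs survive the frequency/missing filters")
    return gm.subset_snps(keep)


def _parse_code(token: str, line_no: int, snp_id: str) -> int:
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return MISSING
    if t == "0":
        return 0
    if t == "1":
        return 1
    raise DataError(
        f"unknown genotype symbol {token!r} for SNP {snp_id} (line {line_no})"
    )


def read_genotype_table(
    path, format: str | None = None, apply_filters: bool = True,
    min_freq: float = MIN_GENOTYPE_FREQ, max_missing: float = MAX_MISSING_FRACTION,
) -> GenotypeMatrix:
    """Read genotypes from a delimited table or a VCF, filters applied."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "table"
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "table":
        gm = _read_delimited(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if apply_filters:
        gm = apply_snp_filters(gm, min_freq=min_freq, max_missing=max_missing)
    return gm


def _read_delimited(path: Path) -> GenotypeMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.ParserError as err:
        raise DataError(f"malformed genotype table {path}: {err}") from err
    required = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise DataError(
            f"genotype table must start with columns {required}, got {list(df.columns[:3])}"
        )
    progeny_ids = list(df.columns[3:])
    if not progeny_ids:
        raise DataError("genotype table has no progeny columns")
    try:
        pos = df["pos"].astype(np.int64).to_numpy()
    except ValueError as err:
        bad = df.index[pd.to_numeric(df["pos"], errors="coerce").isna()]
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise DataError(f"non-integer position in {path} at line {line}") from err
    codes = np.empty((len(df), len(progeny_ids)), dtype=np.int8)
    raw = df[progeny_ids].to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for jcol in range(raw.shape[1]):
            val = raw[i, jcol]
            codes[i, jcol] = _parse_code(
                "" if val is None or (isinstance(val, float) and np.isnan(val)) else str(val),
                i + 2, str(df["snp_id"].iloc[i]),
            )
    return GenotypeMatrix(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=pos,
        codes=codes,
        progeny_ids=progeny_ids,
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    progeny_ids = list(vcf.samples)
    snp_ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # keep biallelic SNPs only
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        row = np.full(gt.shape, MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 3] = 1
        rows.append(row)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
    if not rows:
        raise DataError(f"no biallelic SNPs found in {path}")
    return GenotypeMatrix(
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos),
        codes=np.vstack(rows),
        progeny_ids=progeny_ids,
    )


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        {"snp_id": gm.snp_ids, "chrom": gm.chrom, "pos": gm.pos}
    )
    codes = gm.codes.astype(object)
    codes[gm.codes == MISSING] = "NA"
    for k, pid in enumerate(gm.progeny_ids):
        df[pid] = codes[:, k]
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


PHENOTYPE_COLUMNS = ["progeny", "density", "trait", "week", "value"]


def read_phenotype_table(path) -> LongitudinalTraitSet:
    """Long-format phenotypes -> pivoted trait set with per-density grids.

    Replicate rows for a (progeny, density, trait, week) cell are averaged
    (the mapping model works on progeny means).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise DataError(f"phenotype table lacks columns: {sorted(missing_cols)}")
    bad_density = set(df["density"].unique()) - set(DENSITIES)
    if bad_density:
        raise DataError(f"unknown density labels: {sorted(bad_density)}")
    bad_trait = set(df["trait"].unique()) - set(TRAITS)
    if bad_trait:
        raise DataError(f"unknown trait labels: {sorted(bad_trait)}")
    if (df["value"] < 0).any():
        raise DataError("negative trait values are not allowed")
    agg = (
        df.groupby(["progeny", "density", "trait", "week"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    progeny_ids = sorted(agg["progeny"].astype(str).unique())
    pidx = {p: i for i, p in enumerate(progeny_ids)}
    times, values = {}, {}
    for d in DENSITIES:
        sub = agg[agg["density"] == d]
        if sub.empty:
            continue
        weeks = np.sort(sub["week"].unique()).astype(float)
        widx = {w: k for k, w in enumerate(weeks)}
        arr = np.full((len(progeny_ids), len(TRAITS), len(weeks)), np.nan)
        ti = {t: k for k, t in enumerate(TRAITS)}
        for row in sub.itertuples(index=False):
            arr[pidx[str(row.progeny)], ti[row.trait], widx[float(row.week)]] = row.value
        times[d] = weeks
        values[d] = arr
    if not times:
        raise DataError("phenotype table contains no recognized density")
    return LongitudinalTraitSet(progeny_ids=progeny_ids, times=times, values=values)


def write_phenotype_table(traits: LongitudinalTraitSet, path) -> None:
    rows = []
    for d in traits.densities:
        for ti, trait in enumerate(traits.traits):
            for wi, week in enumerate(traits.times[d]):
                col = traits.values[d][:, ti, wi]
                for p, v in zip(traits.progeny_ids, col):
                    if np.isfinite(v):
                        rows.append((p, d, trait, week, v))
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(path, index=False)


SCAN_COLUMNS = [
    "snp_id", "chrom", "pos", "L0", "L1", "LR", "LOD",
    "alpha0_high", "beta0_high", "alpha0_low", "beta0_low",
    "alpha1_high", "beta1_high", "alpha1_low", "beta1_low",
    "phi_high", "phi_low", "sigma2", "significant", "skipped",
]


def write_scan_table(records, path) -> None:
    """Scan records -> TSV, floats at 6 significant digits (bit-stable)."""
    if not records:
        raise ValueError("no scan records to write")

    def fmt(v):
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return "NA"
        return f"{v:.6g}"

    with open(path, "w") as fh:
        fh.write("\t".join(SCAN_COLUMNS) + "\n")
        for r in records:
            mp, sp = r.mean_params, r.sad_params
            row = [
                r.snp_id, r.chrom, str(r.pos),
                fmt(r.logl0), fmt(r.logl1), fmt(r.lr), fmt(r.lod),
            ]
            for j in (0, 1):
                for d in ("high", "low"):
                    if mp is None:
                        row += ["NA", "NA"]
                    else:
                        row += [fmt(mp.alpha[j][d]), fmt(mp.beta[j][d])]
            if sp is None:
                row += ["NA", "NA", "NA"]
            else:
                row += [fmt(sp.phi_high), fmt(sp.phi_low), fmt(sp.sigma2)]
            row.append("NA" if r.significant is None else str(int(r.significant)))
            row.append(str(int(r.skipped)))
            fh.write("\t".join(row) + "\n")


def read_scan_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"scan table lacks columns: {sorted(missing)}")
    return df
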