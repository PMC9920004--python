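"""Result surfaces of a scan: effect curves, PVE, QTL tables, overlap.

For two homozygous genotype classes the additive effect at predictor value
x is half the difference of the class mean curves,
``a_d(x) = (alpha_1d x**beta_1d - alpha_0d x**beta_0d) / 2``; with class
frequencies p + q = 1 the genetic variance contributed by the locus is
``4 p q a**2`` and PVE is that variance as a share of the observed
phenotypic variance of the response, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import TraitPairData
from .scan import ScanRecord


@dataclass
class EffectCurve:
    density: str
    x_grid: np.ndarray
    additive_effect: np.ndarray


def additive_effect_curve(
    record: ScanRecord, x_grid: np.ndarray, density: str
) -> EffectCurve:
    """Additive-effect curve a_d(x) of a fitted SNP over a predictor grid."""
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid <= 0):
        raise ValueError("x_grid must be strictly positive")
    if record.mean_params is None:
        raise ValueError("record has no fitted H1 parameters")
    mp = record.mean_params
    a = 0.5 * (mp.mean_curve(x_grid, 1, density) - mp.mean_curve(x_grid, 0, density))
    return EffectCurve(density=density, x_grid=x_grid, additive_effect=a)


def pve(
    record: ScanRecord,
    genotype_frequencies: tuple[float, float],
    data: TraitPairData,
    mode: str = "mean",
) -> float:
    """Percent phenotypic variance explained by the fitted QTL.

    At each observed week and density the locus contributes genetic
    variance 4 p q a_d(xbar(t))**2, with xbar(t) the progeny-mean predictor;
    the ratio to the observed phenotypic variance of the response at that
    week is averaged over weeks and densities (``mode="mean"``) or maximised
    (``mode="max"``), then expressed in percent.
    """
    p, q = genotype_frequencies
    if not np.isclose(p + q, 1.0):
        raise ValueError("genotype frequencies must sum to 1")
    if record.mean_params is None:
        raise ValueError("record has no fitted H1 parameters")
    ratios = []
    for d in data.densities:
        xbar = np.nanmean(data.x[d], axis=0)
        yvar = np.nanvar(data.y[d], axis=0, ddof=1)
        if np.all(yvar[np.isfinite(yvar)] == 0):
            raise ValueError(f"zero phenotypic variance under density {d!r}")
        eff = additive_effect_curve(record, xbar, d).additive_effect
        gvar = 4.0 * p * q * eff**2
        ok = np.isfinite(yvar) & (yvar > 0)
        ratios.extend((gvar[ok] / yvar[ok]).tolist())
    if not ratios:
        raise ValueError("no week with positive phenotypic variance")
    if mode == "mean":
        return 100.0 * float(np.mean(ratios))
    if mode == "max":
        return 100.0 * float(np.max(ratios))
    raise ValueError(f"unknown mode {mode!r}")


def _chrom_sort_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


def significant_snps(records: list[ScanRecord], lr_threshold: float) -> pd.DataFrame:
    """Records with LR >= threshold, sorted by chrom/pos, flags set in place."""
    rows = []
    for r in records:
        if r.skipped:
            r.significant = False
            continue
        r.significant = bool(r.lr >= lr_threshold)
        if r.significant:
            rows.append(
                {"snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                 "lr": r.lr, "lod": r.lod}
            )
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "lr", "lod"])
    if len(df):
        df = df.sort_values(
            by=["chrom", "pos"], key=lambda col: col.map(_chrom_sort_key)
            if col.name == "chrom" else col
        ).reset_index(drop=True)
    return df


def per_chromosome_counts(table: pd.DataFrame) -> dict[str, int]:
    return {str(c): int(n) for c, n in table.groupby("chrom").size().items()}


def pleiotropy_overlap(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[list[str], dict[str, int]]:
    """SNPs significant in both scans, with per-chromosome counts.

    Loci affecting both the shape (L-A) and position (P-L) relations are
    candidate pleiotropic regulators of the shade-avoidance response.
    """
    shared = sorted(set(table_a["snp_id"]) & set(table_b["snp_id"]))
    sub = table_a[table_a["snp_id"].isin(shared)]
    return shared, per_chromosome_counts(sub)


def manhattan_export(records: list[ScanRecord], lr_threshold: float, path) -> None:
    """Plot-ready per-SNP table: chrom, pos, lod, significant flag."""
    if not records:
        raise ValueError("no scan records to export")
    rows = []
    for r in records:
        if r.skipped:
            continue
        rows.append(
            {"chrom": r.chrom, "pos": r.pos, "lod": r.lod,
             "significant": int(r.lr >= lr_threshold)}
        )
    pd.DataFrame(rows, columns=["chrom", "pos", "lod", "significant"]).to_csv(
        path, sep="\t", index=False
    )
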