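"""Negative-binomial differential testing with BH-FDR.

Counts are normalized by median-of-ratios size factors and tested per gene
with a likelihood-ratio test between nested NB GLMs (log link, library
offsets).  Dispersion is a method-of-moments estimate on normalized
counts, pooled over design cells, then moderated by shrinking each
gene-wise estimate halfway toward the across-gene mean (and floored at
1e-8): with few replicates the raw gene-wise estimate is noisy enough to
make the likelihood-ratio test anti-conservative, and equal-weight
shrinkage toward the common value restores type-I calibration.  The
operating characteristics (calibration under the global null, power
against planted effects) are themselves part of the test suite.

Three contrasts are supported:

* ``rna`` / ``ribo`` — condition effect on one assay's libraries
  (mean ~ samplegroup, reduced: intercept only);
* ``interaction`` — the samplegroup:type coefficient of
  mean ~ samplegroup + type + samplegroup:type, i.e. the change in
  translation between conditions after controlling for the change in
  transcription: the translational-regulation test.

A gene is called differential when |log2FC| is strictly above the
threshold (default 1) and its BH-adjusted p-value is strictly below the
FDR threshold (default 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("metaribo")

CONTRASTS = ("rna", "ribo", "interaction")
_DISPERSION_FLOOR = 1e-8
_DISPERSION_CAP = 10.0


@dataclass
class DifferentialResult:
    feature_id: str
    base_mean: float
    log2fc: float
    p_value: float
    fdr: float = math.nan
    call: str = "ns"
    contrast: str = "rna"


@dataclass
class DesignSpec:
    """Per-column factors: condition (samplegroup), assay type, replicate."""

    samplegroup: list[str]
    assay_type: list[str]  # 'rna' or 'ribo'
    replicate: list[str]

    def __post_init__(self) -> None:
        n = len(self.samplegroup)
        if not (len(self.assay_type) == len(self.replicate) == n):
            raise ValueError("design factor lengths differ")

    @property
    def n_columns(self) -> int:
        return len(self.samplegroup)

    def validate_for(self, contrast: str) -> None:
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}")
        groups = sorted(set(self.samplegroup))
        if len(groups) != 2:
            raise ValueError("exactly two samplegroups are required")
        if contrast == "interaction":
            types = sorted(set(self.assay_type))
            if types != ["ribo", "rna"] and types != ["rna", "ribo"]:
                raise ValueError("interaction contrast needs both rna and ribo columns")
            for g in groups:
                for t in types:
                    n = sum(
                        1
                        for sg, ty in zip(self.samplegroup, self.assay_type)
                        if sg == g and ty == t
                    )
                    if n < 2:
                        raise ValueError(
                            f"interaction contrast needs >=2 replicates per cell; "
                            f"cell ({g}, {t}) has {n}"
                        )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per column.

    The per-gene reference is the geometric mean across columns over genes
    with no zero count; each column's factor is the median ratio of its
    counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every column; filter genes first"
        )
    ref = np.exp(np.log(mat[nonzero]).mean(axis=1))
    ratios = mat[nonzero] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _design_matrices(design: DesignSpec, contrast: str) -> tuple[np.ndarray, np.ndarray, int]:
    """(full, reduced) design matrices and the tested-coefficient index."""
    groups = sorted(set(design.samplegroup))
    g = np.array([groups.index(x) for x in design.samplegroup], dtype=float)
    if contrast in ("rna", "ribo"):
        full = np.column_stack([np.ones_like(g), g])
        reduced = full[:, :1]
        return full, reduced, 1
    t = np.array([1.0 if x == "ribo" else 0.0 for x in design.assay_type])
    full = np.column_stack([np.ones_like(g), g, t, g * t])
    reduced = full[:, :3]
    return full, reduced, 3


def _mom_dispersion(norm_counts: np.ndarray, full: np.ndarray) -> float:
    """Pooled within-cell method-of-moments NB dispersion estimate."""
    cells: dict[tuple, list[float]] = {}
    for j in range(full.shape[0]):
        cells.setdefault(tuple(full[j, 1:]), []).append(norm_counts[j])
    num = 0.0
    den = 0.0
    for vals in cells.values():
        if len(vals) < 2:
            continue
        v = np.asarray(vals)
        m = v.mean()
        if m <= 0:
            continue
        s2 = v.var(ddof=1)
        num += (s2 - m) * (len(vals) - 1)
        den += m * m * (len(vals) - 1)
    if den <= 0:
        return _DISPERSION_FLOOR
    alpha = num / den
    return float(min(max(alpha, _DISPERSION_FLOOR), _DISPERSION_CAP))


def _fit_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    model = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
    )
    return model.fit(maxiter=100, tol=1e-9)


def nb_fit_test(
    counts: pd.DataFrame,
    design: DesignSpec,
    contrast: str,
    sf: Optional[pd.Series] = None,
) -> list[DifferentialResult]:
    """Likelihood-ratio NB test per gene for the requested contrast.

    For the single-assay contrasts only the matching columns are used.
    Genes with all-zero counts in the relevant columns are excluded before
    testing (logged); non-converging fits yield p = NaN and are excluded
    from the FDR denominator downstream.
    """
    design.validate_for(contrast)
    if counts.shape[1] != design.n_columns:
        raise ValueError("counts columns and design length differ")
    if contrast in ("rna", "ribo"):
        keep = [i for i, t in enumerate(design.assay_type) if t == contrast]
        counts = counts.iloc[:, keep]
        design = DesignSpec(
            samplegroup=[design.samplegroup[i] for i in keep],
            assay_type=[design.assay_type[i] for i in keep],
            replicate=[design.replicate[i] for i in keep],
        )
    if sf is None:
        sf = size_factors(counts)
    else:
        sf = sf.loc[counts.columns]
    offset = np.log(sf.to_numpy(dtype=float))
    full, reduced, coef_idx = _design_matrices(design, contrast)
    df_diff = full.shape[1] - reduced.shape[1]

    mat = counts.to_numpy(dtype=float)
    norm = mat / sf.to_numpy(dtype=float)[None, :]
    nonzero = mat.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("excluding %d all-zero genes from %s contrast", n_dropped, contrast)

    gene_alphas = np.array(
        [_mom_dispersion(norm[gi], full) for gi in range(mat.shape[0])]
    )
    mean_alpha = float(gene_alphas[nonzero].mean()) if nonzero.any() else 0.0
    moderated = np.maximum(0.5 * gene_alphas + 0.5 * mean_alpha, _DISPERSION_FLOOR)

    results: list[DifferentialResult] = []
    for gi, gene in enumerate(counts.index):
        base_mean = float(norm[gi].mean())
        if not nonzero[gi]:
            continue
        y = mat[gi]
        alpha = float(moderated[gi])
        try:
            fit_full = _fit_nb(y, full, offset, alpha)
            fit_red = _fit_nb(y, reduced, offset, alpha)
            lr = 2.0 * (fit_full.llf - fit_red.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=df_diff))
            log2fc = float(fit_full.params[coef_idx] / math.log(2.0))
        except Exception:  # non-convergence / separation
            logger.warning("NB fit failed for gene %s; p set to NA", gene)
            p, log2fc = math.nan, math.nan
        results.append(
            DifferentialResult(
                feature_id=str(gene),
                base_mean=base_mean,
                log2fc=log2fc,
                p_value=p,
                contrast=contrast,
            )
        )
    return results


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries propagate."""
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[finite]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[finite] = res
    return out


def call_differential(
    results: Sequence[DifferentialResult],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[DifferentialResult]:
    """Attach BH-FDR and the strict |log2FC| > t and FDR < q call rule."""
    fdr = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        if not math.isnan(q) and q < fdr_threshold:
            if r.log2fc > lfc_threshold:
                r.call = "up"
            elif r.log2fc < -lfc_threshold:
                r.call = "down"
            else:
                r.call = "ns"
        else:
            r.call = "ns"
    return list(results)


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "call": [r.call for r in results],
            "contrast": [r.contrast for r in results],
        }
    )
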