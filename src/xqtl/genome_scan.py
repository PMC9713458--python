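"""Per-window ANOVA contrasting selected vs control haplotype frequencies.

Each window's estimated founder proportions are arcsine-square-root
transformed and laid out as a balanced replicate x haplotype x treatment
array. The test statistic for consistent treatment-driven differentiation is
F = MS(HxT) / MS(RxHxT) by default, i.e. the haplotype-by-treatment
interaction mean square against the three-way interaction error stratum,
with df = ((F-1)(T-1), (R-1)(F-1)(T-1)). A pooled-residual stratum is
available as an alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

ERROR_STRATA = ("three-way", "pooled")

_MAX_NEGLOG10P = 300.0


def asf_transform(p):
    """Arcsine square-root transform arcsin(sqrt(p)) for proportions.

    Values outside [0, 1] by more than 1e-9 raise; tiny excursions are
    clamped. Returns values in [0, pi/2].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))


def _anova_stack(X: np.ndarray, error_stratum: str = "three-way"):
    """Balanced factorial decomposition for a stack of windows.

    ``X`` has shape (W, R, H, T). Returns (fstat, df1, df2, neglog10p) with
    per-window arrays. Degenerate windows (zero interaction and zero error
    variation) get F = 0, p = 1.
    """
    if error_stratum not in ERROR_STRATA:
        raise ValueError(f"error_stratum must be one of {ERROR_STRATA}")
    X = np.asarray(X, dtype=float)
    W, R, H, T = X.shape
    if R < 2:
        raise ValueError("need >= 2 replicates: the error stratum is undefined for R < 2")
    if H < 2 or T < 2:
        raise ValueError("need >= 2 haplotypes and 2 treatments")

    m = X.mean(axis=(1, 2, 3), keepdims=True)
    mr = X.mean(axis=(2, 3), keepdims=True)
    mh = X.mean(axis=(1, 3), keepdims=True)
    mt = X.mean(axis=(1, 2), keepdims=True)
    mrh = X.mean(axis=3, keepdims=True)
    mrt = X.mean(axis=2, keepdims=True)
    mht = X.mean(axis=1, keepdims=True)

    ss_ht = R * ((mht - mh - mt + m) ** 2).sum(axis=(1, 2, 3))
    resid = X - mrh - mrt - mht + mr + mh + mt - m
    ss_rht = (resid**2).sum(axis=(1, 2, 3))

    df1 = (H - 1) * (T - 1)
    if error_stratum == "three-way":
        ss_err, df2 = ss_rht, (R - 1) * (H - 1) * (T - 1)
    else:
        ss_r = H * T * ((mr - m) ** 2).sum(axis=(1, 2, 3))
        ss_rh = T * ((mrh - mr - mh + m) ** 2).sum(axis=(1, 2, 3))
        ss_rt = H * ((mrt - mr - mt + m) ** 2).sum(axis=(1, 2, 3))
        ss_err, df2 = ss_r + ss_rh + ss_rt + ss_rht, (R - 1) * H * T

    # round-off floor: an interaction SS at machine epsilon of the data scale is zero
    floor = 1e-18 * np.maximum((X**2).sum(axis=(1, 2, 3)), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (ss_ht / df1) / (ss_err / df2)
    fstat = np.where(ss_ht <= floor, 0.0, fstat)  # covers 0/0 -> p = 1
    pvals = scipy.stats.f.sf(fstat, df1, df2)
    pvals = np.where(np.isinf(fstat), 0.0, pvals)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pvals)
    neglog = np.minimum(neglog, _MAX_NEGLOG10P)
    return fstat, df1, df2, neglog


def anova_window(asf: np.ndarray, error_stratum: str = "three-way"):
    """F test of the haplotype-by-treatment interaction for one window.

    ``asf`` is the balanced (R, H, T) array of transformed proportions.
    Returns (F, df1, df2, neglog10p).
    """
    asf = np.asarray(asf, dtype=float)
    if asf.ndim != 3:
        raise ValueError("expected a (replicates, haplotypes, treatments) array")
    f, df1, df2, nl = _anova_stack(asf[None], error_stratum)
    return float(f[0]), df1, df2, float(nl[0])


def scan_genome(freqs, error_stratum: str = "three-way") -> pd.DataFrame:
    """Run the window ANOVA along the genome.

    ``freqs`` is a haplotype_inference.WindowFreqs. Each (replicate, sex)
    pair of samples is treated as one independent replicate r; windows
    missing in any sample are skipped. Returns the track as a DataFrame with
    chrom, center_bp, center_cM, fstat, df1, df2, neglog10p_raw.
    """
    meta = freqs.samples
    groups: dict[tuple[int, str], dict[str, int]] = {}
    for j, row in meta.iterrows():
        groups.setdefault((int(row["replicate"]), str(row["sex"])), {})[str(row["treatment"])] = j
    keys = sorted(groups)
    for key in keys:
        if set(groups[key]) != {"control", "selected"}:
            raise ValueError(f"(replicate, sex) cell {key} lacks a control/selected pair")
    ctrl_idx = np.array([groups[k]["control"] for k in keys])
    sel_idx = np.array([groups[k]["selected"] for k in keys])

    complete = ~freqs.missing.any(axis=1)
    if not complete.any():
        raise ValueError("no window has haplotype calls in every sample")

    P = freqs.freqs[complete]  # (Wc, n_samples, F)
    X = np.stack([P[:, ctrl_idx, :], P[:, sel_idx, :]], axis=-1)  # (Wc, R, F, T)
    fstat, df1, df2, neglog = _anova_stack(asf_transform(X), error_stratum)

    g = freqs.grid.table.loc[complete].reset_index(drop=True)
    return pd.DataFrame(
        {
            "chrom": g["chrom"],
            "center_bp": g["center_bp"],
            "center_cM": g["center_cM"],
            "fstat": fstat,
            "df1": df1,
            "df2": df2,
            "neglog10p_raw": neglog,
        }
    )
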