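"""Founder-haplotype frequency estimation in sliding genetic-map windows.

For each pooled sample and each window on the cM axis, the observed per-SNP
REF frequencies are modelled as a mixture of the known founder haplotypes:
``y ~ A p`` with ``A`` the (SNPs x founders) 0/1 founder allele matrix. The
mixing proportions ``p`` are found by weighted least squares constrained to
the probability simplex (p >= 0, sum p = 1).

The solver contract is the constrained optimum itself, not a particular
algorithm; here the equality constraint is enforced through a heavily
weighted augmentation row on top of non-negative least squares, which is
exact to well below the estimation noise floor. Founders with identical
alleles at every retained SNP in a window are indistinguishable: their summed
proportion is identified, and the minimum-norm tie-break splits it equally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .io_formats import FounderPanel, GeneticMap, PooledSample, intersect_snps

log = logging.getLogger(__name__)

DEFAULT_WINDOW_CM = 1.5
DEFAULT_STEP_CM = 0.05
DEFAULT_MIN_SNPS = 10
DEFAULT_CLEAN_TOL = 0.05


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------


@dataclass
class WindowGrid:
    """Sliding windows on the cM axis, one row per window."""

    table: pd.DataFrame  # chrom, start_cM, end_cM, center_cM, center_bp
    window_cm: float
    step_cm: float

    @property
    def n_windows(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


def build_window_grid(
    gmap: GeneticMap, window_cm: float = DEFAULT_WINDOW_CM, step_cm: float = DEFAULT_STEP_CM
) -> WindowGrid:
    """Windows of ``window_cm`` advancing by ``step_cm`` along each chromosome.

    Centers start at the chromosome's first mapped cM plus half a window and
    advance until the window's end would pass the last mapped cM. Chromosomes
    shorter than one window get zero windows (with a warning).
    """
    if not (window_cm > step_cm > 0):
        raise ValueError("require window_cm > step_cm > 0")
    frames = []
    for chrom in gmap.chromosomes:
        lo, hi = gmap.cm_span(chrom)
        span = hi - lo
        if span < window_cm:
            log.warning("chromosome %s spans %.3f cM < one %.2f cM window; skipped", chrom, span, window_cm)
            continue
        n = int(math.floor((span - window_cm) / step_cm + 1e-9)) + 1
        centers = lo + window_cm / 2 + step_cm * np.arange(n)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start_cM": centers - window_cm / 2,
                "end_cM": centers + window_cm / 2,
                "center_cM": centers,
                "center_bp": gmap.interpolate_bp(chrom, centers),
            }
        )
        frames.append(df)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start_cM", "end_cM", "center_cM", "center_bp"])
    )
    return WindowGrid(table, window_cm, step_cm)


# ---------------------------------------------------------------------------
# SNP selection
# ---------------------------------------------------------------------------


def clean_founder_matrix(M: np.ndarray, tol: float = DEFAULT_CLEAN_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Round near-fixed founder frequencies to {0,1}; flag usable SNPs.

    A SNP is kept iff every founder frequency is within ``tol`` of 0 or 1 and
    the rounded alleles are not identical across all founders.
    """
    M = np.asarray(M, float)
    near_fixed = np.minimum(M, 1 - M) <= tol
    rounded = (M >= 0.5).astype(float)
    informative = (rounded.sum(1) > 0) & (rounded.sum(1) < M.shape[1])
    keep = near_fixed.all(axis=1) & informative
    return rounded, keep


def select_window_snps(
    panel: FounderPanel,
    sample: PooledSample,
    window,
    min_depth: int = 1,
    tol: float = DEFAULT_CLEAN_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix A, observations y and weights w for one (window, sample).

    ``window`` is any object with chrom, start_cM and end_cM attributes.
    Requires sample counts row-aligned with the panel (use
    ``io_formats.intersect_snps`` first). Retains SNPs inside the window that
    survive founder cleaning and have depth >= ``min_depth``; y is the
    observed REF frequency and w the read depth.
    """
    tab = panel.table
    if len(sample.counts) != len(tab) or not np.array_equal(
        sample.counts["pos"].to_numpy(), tab["pos"].to_numpy()
    ):
        raise ValueError("sample counts not aligned with panel; run intersect_snps first")
    in_window = (
        (tab["chrom"] == window.chrom)
        & (tab["cM"] >= window.start_cM)
        & (tab["cM"] <= window.end_cM)
    ).to_numpy()
    rounded, keep = clean_founder_matrix(tab[panel.founders].to_numpy(float), tol)
    depth = sample.depth()
    sel = in_window & keep & (depth >= min_depth)
    y = sample.ref_freq()[sel]
    return rounded[sel], y, depth[sel]


# ---------------------------------------------------------------------------
# Constrained solver
# ---------------------------------------------------------------------------


def estimate_haplotype_freqs(
    A: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """argmin_p sum_i w_i (y_i - (A p)_i)^2 over the simplex.

    Returns (p, weighted residual sum of squares). Deterministic for fixed
    input; indistinguishable founder columns share their proportion equally.
    """
    A = np.asarray(A, float)
    y = np.asarray(y, float)
    if A.ndim != 2 or A.shape[0] == 0:
        raise ValueError("design matrix must be non-empty")
    n, F = A.shape
    w = np.ones(n) if w is None else np.asarray(w, float)
    if w.shape != (n,) or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per SNP")

    uniq, inverse = np.unique(A, axis=1, return_inverse=True)
    counts = np.bincount(inverse)

    sw = np.sqrt(w)
    Aw = uniq * sw[:, None]
    yw = y * sw
    kappa = 1e4 * max(1.0, float(np.linalg.norm(yw)))
    A_aug = np.vstack([Aw, np.full(uniq.shape[1], kappa)])
    y_aug = np.append(yw, kappa)
    q, _ = scipy.optimize.nnls(A_aug, y_aug)
    q = np.maximum(q, 0.0)
    total = q.sum()
    if total <= 0:  # pragma: no cover - cannot happen with the penalty row
        q = np.full(uniq.shape[1], 1.0 / uniq.shape[1])
    else:
        q /= total

    p = q[inverse] / counts[inverse]
    resid = yw - Aw @ q
    return p, float(resid @ resid)


# ---------------------------------------------------------------------------
# Whole-genome inference
# ---------------------------------------------------------------------------


@dataclass
class WindowFreqs:
    """Estimated founder proportions for every (window, sample) pair.

    ``freqs`` is (n_windows, n_samples, F) with NaN rows where a window was
    flagged missing (fewer than min_snps usable SNPs)."""

    grid: WindowGrid
    samples: pd.DataFrame  # sample_id, replicate, sex, treatment
    founders: list[str]
    freqs: np.ndarray
    n_snps: np.ndarray  # (n_windows, n_samples)
    rss: np.ndarray

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.freqs[:, :, 0])

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per (window, sample, founder)."""
        g = self.grid.table
        nw, ns, F = self.freqs.shape
        rows = {
            "chrom": np.repeat(g["chrom"].to_numpy(), ns * F),
            "center_cM": np.repeat(g["center_cM"].to_numpy(), ns * F),
            "center_bp": np.repeat(g["center_bp"].to_numpy(), ns * F),
            "sample_id": np.tile(np.repeat(self.samples["sample_id"].to_numpy(), F), nw),
            "founder": np.tile(self.founders, nw * ns),
            "proportion": self.freqs.reshape(-1),
            "n_snps": np.repeat(self.n_snps.reshape(-1), F),
        }
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")

    @classmethod
    def read_tsv(cls, path, samples_meta: pd.DataFrame, window_cm: float = DEFAULT_WINDOW_CM,
                 step_cm: float = DEFAULT_STEP_CM) -> "WindowFreqs":
        """Rebuild from the long TSV plus sample metadata (sheet order kept)."""
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        founders = list(dict.fromkeys(df["founder"]))
        sample_ids = list(samples_meta["sample_id"])
        gtab = df.drop_duplicates(["chrom", "center_cM"])[["chrom", "center_cM", "center_bp"]].reset_index(drop=True)
        gtab["start_cM"] = gtab["center_cM"] - window_cm / 2
        gtab["end_cM"] = gtab["center_cM"] + window_cm / 2
        grid = WindowGrid(gtab[["chrom", "start_cM", "end_cM", "center_cM", "center_bp"]], window_cm, step_cm)
        nw, ns, F = len(gtab), len(sample_ids), len(founders)
        key = pd.MultiIndex.from_frame(df[["chrom", "center_cM"]])
        widx = pd.MultiIndex.from_frame(gtab[["chrom", "center_cM"]]).get_indexer(key)
        sidx = pd.Index(sample_ids).get_indexer(df["sample_id"])
        fidx = pd.Index(founders).get_indexer(df["founder"])
        freqs = np.full((nw, ns, F), np.nan)
        n_snps = np.zeros((nw, ns), dtype=int)
        freqs[widx, sidx, fidx] = df["proportion"].to_numpy(float)
        n_snps[widx, sidx] = df["n_snps"].to_numpy(int)
        return cls(grid, samples_meta.reset_index(drop=True), founders, freqs, n_snps, np.zeros((nw, ns)))


def infer_all_windows(
    panel: FounderPanel,
    samples: list[PooledSample],
    grid: WindowGrid,
    min_snps: int = DEFAULT_MIN_SNPS,
    min_depth: int = 1,
    weights: str = "depth",
    tol: float = DEFAULT_CLEAN_TOL,
) -> WindowFreqs:
    """Run the constrained estimator for every (window, sample) pair.

    ``weights`` is "depth" (per-SNP read depth, the default) or "equal".
    Windows with fewer than ``min_snps`` usable SNPs are flagged missing.
    """
    if weights not in ("depth", "equal"):
        raise ValueError("weights must be 'depth' or 'equal'")
    panel, samples = intersect_snps(panel, samples)
    F = panel.n_founders
    nw, ns = grid.n_windows, len(samples)
    freqs = np.full((nw, ns, F), np.nan)
    n_snps = np.zeros((nw, ns), dtype=int)
    rss = np.full((nw, ns), np.nan)

    rounded_all, keep_all = clean_founder_matrix(panel.table[panel.founders].to_numpy(float), tol)
    gtab = grid.table

    for chrom in grid.chromosomes:
        chrom_mask = (panel.table["chrom"] == chrom).to_numpy()
        widx = np.flatnonzero((gtab["chrom"] == chrom).to_numpy())
        if widx.size == 0:
            continue
        starts = gtab["start_cM"].to_numpy()[widx]
        ends = gtab["end_cM"].to_numpy()[widx]
        base = np.flatnonzero(chrom_mask & keep_all)
        cm_base = panel.table["cM"].to_numpy(float)[base]
        G = rounded_all[base]
        any_done = False
        for j, s in enumerate(samples):
            depth = s.depth()[base]
            ref = s.counts["ref_count"].to_numpy(float)[base]
            ok = depth >= min_depth
            cm_ok = cm_base[ok]
            G_ok = G[ok]
            y_ok = ref[ok] / depth[ok]
            w_ok = depth[ok] if weights == "depth" else np.ones(ok.sum())
            i0 = np.searchsorted(cm_ok, starts, side="left")
            i1 = np.searchsorted(cm_ok, ends, side="right")
            for k, wi in enumerate(widx):
                a, b = i0[k], i1[k]
                n_snps[wi, j] = b - a
                if b - a < min_snps:
                    continue
                p, r = estimate_haplotype_freqs(G_ok[a:b], y_ok[a:b], w_ok[a:b])
                freqs[wi, j] = p
                rss[wi, j] = r
                any_done = True
        if not any_done:
            log.warning("chromosome %s: every window missing for every sample", chrom)
        else:
            log.info("chromosome %s: inferred %d windows x %d samples", chrom, widx.size, ns)

    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "replicate": [s.replicate for s in samples],
            "sex": [s.sex for s in samples],
            "treatment": [s.treatment for s in samples],
        }
    )
    return WindowFreqs(grid, meta, list(panel.founders), freqs, n_snps, rss)
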