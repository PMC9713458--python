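"""Readers and writers for every external file the pipeline touches.

All tabular files are tab-separated with a header row, UTF-8, '.' decimal.
Genomic coordinates are 1-based inclusive everywhere except the BED export,
which follows the BED convention (0-based, half-open).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TREATMENTS = ("control", "selected")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map, one anchor list per chromosome.

    Anchors must be strictly increasing in both bp and cM; interpolation is
    linear between anchors with constant extrapolation beyond the terminal
    anchors.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in self.anchors.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if pos.size < 2:
                raise FormatError(f"genetic map: chromosome {chrom!r} needs >= 2 anchors")
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"genetic map: bp anchors not strictly increasing on {chrom!r}")
            if np.any(np.diff(cm) <= 0):
                raise FormatError(f"genetic map: cM anchors not strictly increasing on {chrom!r}")
            clean[chrom] = (pos, cm)
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def cm_span(self, chrom: str) -> tuple[float, float]:
        _, cm = self._get(chrom)
        return float(cm[0]), float(cm[-1])

    def bp_span(self, chrom: str) -> tuple[float, float]:
        pos, _ = self._get(chrom)
        return float(pos[0]), float(pos[-1])

    def interpolate_cm(self, chrom: str, pos):
        """cM position(s) for bp coordinate(s); constant beyond the anchors."""
        apos, acm = self._get(chrom)
        return np.interp(pos, apos, acm)

    def interpolate_bp(self, chrom: str, cm):
        """Inverse lookup: bp coordinate(s) for cM position(s)."""
        apos, acm = self._get(chrom)
        return np.interp(cm, acm, apos)

    def _get(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.anchors[chrom]
        except KeyError:
            raise FormatError(f"chromosome {chrom!r} absent from genetic map") from None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        _require_columns(df, ["chrom", "pos", "cM"], "genetic map")
        anchors = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            anchors[str(chrom)] = (sub["pos"].to_numpy(float), sub["cM"].to_numpy(float))
        return cls(anchors)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom, (pos, cm) in self.anchors.items():
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(int), "cM": cm}))
        return pd.concat(rows, ignore_index=True)


def load_genetic_map(path) -> GeneticMap:
    return GeneticMap.from_dataframe(_read_tsv(path, "genetic map"))


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------


@dataclass
class FounderPanel:
    """Per-SNP REF-allele frequency of each inbred founder.

    ``table`` holds columns chrom, pos, ref, alt, cM plus one column per
    founder, sorted by (chrom, pos). Founder frequencies are expected to be
    near 0 or 1; cleaning to exact {0,1} happens at window selection time.
    """

    table: pd.DataFrame
    founders: list[str]

    def __post_init__(self) -> None:
        self.table = self.table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if len(set(self.founders)) != len(self.founders):
            raise FormatError("founder names must be unique")
        for f in self.founders:
            col = self.table[f].to_numpy(float)
            if np.any((col < 0) | (col > 1)):
                raise FormatError(f"founder {f!r} has allele frequencies outside [0, 1]")

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def matrix(self, chrom: str | None = None) -> np.ndarray:
        """(L, F) array of founder REF frequencies, optionally one chromosome."""
        tab = self.table if chrom is None else self.table[self.table["chrom"] == chrom]
        return tab[self.founders].to_numpy(float)

    def subset(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def load_founder_panel(path, gmap: GeneticMap) -> FounderPanel:
    """Load a founder allele table and interpolate cM from the genetic map.

    Expected header: ``chrom pos ref alt <founder1> ... <founderF>``.
    """
    df = _read_tsv(path, "founder panel")
    _require_columns(df, ["chrom", "pos", "ref", "alt"], "founder panel")
    founders = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt", "cM")]
    if len(founders) < 2:
        raise FormatError("founder panel needs at least 2 founder columns")
    for chrom in df["chrom"].unique():
        if str(chrom) not in gmap.anchors:
            raise FormatError(f"founder panel chromosome {chrom!r} absent from genetic map")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["cM"] = [
        float(gmap.interpolate_cm(str(c), p)) for c, p in zip(df["chrom"], df["pos"])
    ]
    return FounderPanel(df, founders)


def write_founder_panel(panel: FounderPanel, path) -> None:
    cols = ["chrom", "pos", "ref", "alt"] + panel.founders
    panel.table[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pooled samples
# ---------------------------------------------------------------------------


@dataclass
class PooledSample:
    """REF/ALT read counts at every SNP for one pooled DNA sample."""

    sample_id: str
    replicate: int
    sex: str
    treatment: str
    counts: pd.DataFrame = field(repr=False)  # chrom pos ref_count alt_count

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise FormatError(
                f"sample {self.sample_id!r}: treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        c = self.counts
        _require_columns(c, ["chrom", "pos", "ref_count", "alt_count"], f"counts for {self.sample_id}")
        if (c["ref_count"] < 0).any() or (c["alt_count"] < 0).any():
            raise FormatError(f"sample {self.sample_id!r}: negative read counts")
        self.counts = c.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def depth(self) -> np.ndarray:
        return (self.counts["ref_count"] + self.counts["alt_count"]).to_numpy(float)

    def ref_freq(self) -> np.ndarray:
        """Observed REF frequency per SNP; NaN where depth is zero."""
        d = self.depth()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.counts["ref_count"].to_numpy(float) / d, np.nan)


def load_pooled_counts(sample_sheet_path) -> list[PooledSample]:
    """Load all pools listed in a sample sheet.

    Sheet columns: ``sample_id replicate sex treatment counts_path``; relative
    counts paths are resolved against the sheet's directory. Validates that
    every (replicate, sex) cell has a matched control/selected pair.
    """
    sheet = _read_tsv(sample_sheet_path, "sample sheet")
    _require_columns(sheet, ["sample_id", "replicate", "sex", "treatment", "counts_path"], "sample sheet")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s) in sheet: {dupes}")
    base = os.path.dirname(os.fspath(sample_sheet_path))
    samples = []
    for row in sheet.itertuples(index=False):
        cpath = row.counts_path
        if not os.path.isabs(cpath):
            cpath = os.path.join(base, cpath)
        counts = _read_tsv(cpath, f"counts for {row.sample_id}")
        samples.append(
            PooledSample(str(row.sample_id), int(row.replicate), str(row.sex), str(row.treatment), counts)
        )
    _validate_pairing(samples)
    return samples


def _validate_pairing(samples: list[PooledSample]) -> None:
    cells: dict[tuple[int, str], set[str]] = {}
    for s in samples:
        cells.setdefault((s.replicate, s.sex), set()).add(s.treatment)
    bad = [cell for cell, trts in cells.items() if trts != set(TREATMENTS)]
    if bad:
        raise FormatError(f"unpaired control/selected samples in (replicate, sex) cell(s): {sorted(bad)}")


def write_pooled_counts(samples: list[PooledSample], outdir) -> str:
    """Write one counts TSV per sample plus the sample sheet; returns sheet path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"{s.sample_id}.counts.tsv"
        s.counts.to_csv(os.path.join(outdir, fname), sep="\t", index=False)
        rows.append((s.sample_id, s.replicate, s.sex, s.treatment, fname))
    sheet = pd.DataFrame(rows, columns=["sample_id", "replicate", "sex", "treatment", "counts_path"])
    sheet_path = os.path.join(outdir, "sample_sheet.tsv")
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return sheet_path


def intersect_snps(panel: FounderPanel, samples: list[PooledSample]) -> tuple[FounderPanel, list[PooledSample]]:
    """Restrict panel and all samples to their common (chrom, pos) SNP set.

    The result is independent of input row order: rows are re-sorted by
    (chrom, pos) on the way out.
    """
    keys = pd.MultiIndex.from_frame(panel.table[["chrom", "pos"]])
    common = keys
    for s in samples:
        common = common.intersection(pd.MultiIndex.from_frame(s.counts[["chrom", "pos"]]))
    common = common.sort_values()
    ptab = panel.table.set_index(["chrom", "pos"]).loc[common].reset_index()
    new_panel = FounderPanel(ptab, panel.founders)
    new_samples = []
    for s in samples:
        ctab = s.counts.set_index(["chrom", "pos"]).loc[common].reset_index()
        new_samples.append(PooledSample(s.sample_id, s.replicate, s.sex, s.treatment, ctab))
    return new_panel, new_samples


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------


def export_results(scan: pd.DataFrame, qtls: list, outdir) -> dict[str, str]:
    """Write scan.tsv, qtl.tsv and qtl.bed under ``outdir``.

    ``scan`` must carry chrom, center_bp, center_cM, neglog10p_raw and
    (optionally) neglog10p_smooth; ``qtls`` is a list of peak_calling.QTLCall.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    scan_out = scan.copy()
    if "neglog10p_smooth" not in scan_out.columns:
        scan_out["neglog10p_smooth"] = np.nan
    cols = ["chrom", "center_bp", "center_cM", "neglog10p_raw", "neglog10p_smooth"]
    paths["scan"] = os.path.join(outdir, "scan.tsv")
    scan_out[cols].to_csv(paths["scan"], sep="\t", index=False, float_format="%.6g")

    qrows = []
    brows = []
    for q in qtls:
        qrows.append(
            (q.chrom, int(q.peak_bp), int(q.ci_start_bp), int(q.ci_end_bp), q.width_mb, q.width_cm, q.peak_score)
        )
        brows.append((q.chrom, int(q.ci_start_bp) - 1, int(q.ci_end_bp), f"QTL_{q.chrom}_{int(q.peak_bp)}"))
    qdf = pd.DataFrame(
        qrows, columns=["chrom", "peak_bp", "ci_start_bp", "ci_end_bp", "width_mb", "width_cM", "peak_score"]
    )
    paths["qtl"] = os.path.join(outdir, "qtl.tsv")
    qdf.to_csv(paths["qtl"], sep="\t", index=False, float_format="%.6g")

    paths["bed"] = os.path.join(outdir, "qtl.bed")
    with open(paths["bed"], "w") as fh:
        for chrom, start, end, name in brows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return paths


# ---------------------------------------------------------------------------
# GFF gene counting
# ---------------------------------------------------------------------------


def count_genes_in_interval(
    gff_path, chrom: str, start_bp: int, end_bp: int, feature_type: str = "gene", biotype: str | None = None
) -> tuple[int, list[str]]:
    """Count annotated genes overlapping a 1-based inclusive interval.

    Overlap of >= 1 bp counts. Malformed GFF lines are skipped with a logged
    warning. If ``biotype`` is given, only features whose attribute column
    carries ``biotype=<value>`` (or gene_biotype=) are counted.
    """
    if start_bp > end_bp:
        raise ValueError("interval start exceeds end")
    hits: list[str] = []
    n_bad = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                n_bad += 1
                log.warning("%s:%d: malformed GFF line skipped", gff_path, lineno)
                continue
            seqid, _source, ftype, fstart, fend, *_rest, attrs = parts
            if seqid != chrom or ftype != feature_type:
                continue
            try:
                gstart, gend = int(fstart), int(fend)
            except ValueError:
                n_bad += 1
                log.warning("%s:%d: non-integer coordinates, line skipped", gff_path, lineno)
                continue
            if gend < start_bp or gstart > end_bp:
                continue
            attr_map = _parse_gff_attrs(attrs)
            if biotype is not None:
                bt = attr_map.get("biotype", attr_map.get("gene_biotype"))
                if bt != biotype:
                    continue
            hits.append(attr_map.get("ID", attr_map.get("Name", f"{seqid}:{gstart}-{gend}")))
    if n_bad:
        log.warning("%s: skipped %d malformed line(s)", gff_path, n_bad)
    return len(hits), hits


def _parse_gff_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for piece in attrs.split(";"):
        piece = piece.strip()
        if not piece or "=" not in piece:
            continue
        k, v = piece.split("=", 1)
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _read_tsv(path, what: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise FormatError(f"could not parse {what} at {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")
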