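"""Synthetic multiparent X-QTL experiments with a known truth record.

The generator emulates the design the pipeline targets: a small number of
fixed inbred founder haplotypes, an outbred cohort of recombinant mosaic
genomes, truncation survival whose odds depend on the founder alleles
carried at planted causal sites, and binomial pooled sequencing at modest
coverage. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import FounderPanel, GeneticMap, PooledSample


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    cm_per_mb: float

    @property
    def length_cm(self) -> float:
        return self.length_bp / 1e6 * self.cm_per_mb


@dataclass(frozen=True)
class CausalSpec:
    """One causal site: additive per-founder log-odds effects on survival."""

    chrom: str
    position_bp: int
    founder_effects: tuple[float, ...]
    baseline_logit: float = 0.0

    def __post_init__(self):
        eff = np.asarray(self.founder_effects, float)
        if not np.all(np.isfinite(eff)):
            raise ValueError("founder effects must be finite")
        object.__setattr__(self, "founder_effects", tuple(float(e) for e in eff))

    @property
    def is_null(self) -> bool:
        return all(e == 0.0 for e in self.founder_effects)


@dataclass
class SimConfig:
    """Parameters of one synthetic X-QTL experiment."""

    n_founders: int = 8
    chromosomes: list[ChromSpec] = field(
        default_factory=lambda: [ChromSpec("chr1", 25_000_000, 2.0)]
    )
    snp_density: float = 100.0  # SNPs per Mb
    breakpoint_rate: float = 0.5  # expected breakpoints per cM per transmitted genome
    cohort_size: int = 600  # individuals reared per replicate, pre-selection
    pool_size_selected: int = 200
    pool_size_control: int = 200
    survival_model: CausalSpec | None = None
    coverage: float = 40.0  # mean read depth per SNP
    n_replicates: int = 4  # control/selected pairs
    window_cm: float = 1.5  # truth-record window size
    step_cm: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.chromosomes = [c if isinstance(c, ChromSpec) else ChromSpec(*c) for c in self.chromosomes]
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")
        if self.breakpoint_rate < 0:
            raise ValueError("breakpoint_rate must be >= 0")
        if min(self.cohort_size, self.pool_size_selected, self.pool_size_control, self.n_replicates) <= 0:
            raise ValueError("cohort, pool sizes and n_replicates must be > 0")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for c in self.chromosomes:
            if c.length_bp <= 0 or c.cm_per_mb <= 0:
                raise ValueError(f"chromosome {c.name}: length and cM rate must be > 0")
        if self.survival_model is not None:
            cs = self.survival_model
            if len(cs.founder_effects) != self.n_founders:
                raise ValueError("causal founder_effects length must equal n_founders")
            chroms = {c.name: c for c in self.chromosomes}
            if cs.chrom not in chroms:
                raise ValueError(f"causal chromosome {cs.chrom!r} not simulated")
            if not (1 <= cs.position_bp <= chroms[cs.chrom].length_bp):
                raise ValueError("causal position outside its chromosome")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "chromosomes" in d:
            d["chromosomes"] = [
                ChromSpec(c["name"], int(c["length_bp"]), float(c["cm_per_mb"]))
                if isinstance(c, dict)
                else ChromSpec(*c)
                for c in d["chromosomes"]
            ]
        if d.get("survival_model") is not None and isinstance(d["survival_model"], dict):
            sm = d["survival_model"]
            d["survival_model"] = CausalSpec(
                sm["chrom"], int(sm["position_bp"]), tuple(sm["founder_effects"]),
                float(sm.get("baseline_logit", 0.0)),
            )
        return cls(**d)


@dataclass
class FounderMosaic:
    """One transmitted genome: per chromosome, which founder contributed each
    cM segment. ``segments[chrom] = (starts_cM, founder_idx)`` with
    ``starts_cM[0] == 0`` and consecutive founders distinct; founder indices
    are 0-based."""

    segments: dict[str, tuple[np.ndarray, np.ndarray]]

    def founder_at(self, chrom: str, cm: float) -> int:
        starts, founders = self.segments[chrom]
        i = int(np.searchsorted(starts, cm, side="right")) - 1
        return int(founders[max(i, 0)])

    def n_breakpoints(self, chrom: str) -> int:
        return len(self.segments[chrom][0]) - 1


@dataclass
class TruthRecord:
    """What the generator actually did: causal spec, per-pool true founder
    frequencies in every window of the truth grid, and realized survival."""

    causal: CausalSpec | None
    grid: pd.DataFrame  # chrom, start_cM, end_cM, center_cM, center_bp
    sample_ids: list[str]
    freqs: np.ndarray  # (n_samples, n_windows, F)
    survival_fractions: list[float]  # one per replicate

    def to_json(self, path) -> None:
        payload = {
            "causal": None
            if self.causal is None
            else {
                "chrom": self.causal.chrom,
                "position_bp": self.causal.position_bp,
                "founder_effects": list(self.causal.founder_effects),
                "baseline_logit": self.causal.baseline_logit,
            },
            "survival_fractions": self.survival_fractions,
            "sample_ids": self.sample_ids,
            "windows": self.grid.to_dict(orient="list"),
            "freqs": self.freqs.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------


def genetic_map_for(config: SimConfig) -> GeneticMap:
    """Uniform-rate map: anchors at bp 1 (0 cM) and at the chromosome end."""
    anchors = {}
    for c in config.chromosomes:
        end_cm = (c.length_bp - 1) / 1e6 * c.cm_per_mb
        anchors[c.name] = (np.array([1.0, float(c.length_bp)]), np.array([0.0, end_cm]))
    return GeneticMap(anchors)


def simulate_founder_panel(config: SimConfig, rng: np.random.Generator | None = None) -> FounderPanel:
    """Evenly spaced SNPs; founder alleles iid Bernoulli(0.5), monomorphic
    sites redrawn so every SNP is polymorphic among the founders."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gmap = genetic_map_for(config)
    frames = []
    names = [f"f{i + 1}" for i in range(config.n_founders)]
    for c in config.chromosomes:
        n = int(round(config.snp_density * c.length_bp / 1e6))
        if n < 1:
            raise ValueError(f"snp_density too low: zero SNPs on {c.name}")
        pos = np.unique(np.linspace(1, c.length_bp, n).round().astype(int))
        alleles = rng.integers(0, 2, size=(len(pos), config.n_founders))
        bad = np.flatnonzero((alleles.sum(1) == 0) | (alleles.sum(1) == config.n_founders))
        while bad.size:
            alleles[bad] = rng.integers(0, 2, size=(bad.size, config.n_founders))
            s = alleles[bad].sum(1)
            bad = bad[(s == 0) | (s == config.n_founders)]
        df = pd.DataFrame({"chrom": c.name, "pos": pos, "ref": "A", "alt": "T"})
        df["cM"] = gmap.interpolate_cm(c.name, pos)
        for j, name in enumerate(names):
            df[name] = alleles[:, j].astype(float)
        frames.append(df)
    return FounderPanel(pd.concat(frames, ignore_index=True), names)


# ---------------------------------------------------------------------------
# Recombinant mosaics
# ---------------------------------------------------------------------------


def _batch_chrom_mosaics(n: int, length_cm: float, rate: float, n_founders: int, rng: np.random.Generator):
    """Poisson breakpoints along the cM axis for ``n`` transmitted chromosomes.

    Returns (pos, founders, counts): ``pos`` is (n, K) breakpoint positions
    padded with +inf, ``founders`` is (n, K+1) 0-based founder per segment
    (segment k spans [pos[k-1], pos[k]) with pos[-1] := 0), ``counts`` the
    number of real breakpoints per row. The first founder is uniform, and at
    each breakpoint the next founder is uniform among the other F-1.
    """
    counts = rng.poisson(rate * length_cm, size=n) if rate > 0 else np.zeros(n, dtype=int)
    K = int(counts.max()) if n else 0
    pos = np.full((n, K), np.inf)
    if K:
        raw = rng.uniform(0.0, length_cm, size=(n, K))
        mask = np.arange(K)[None, :] < counts[:, None]
        raw[~mask] = np.inf
        pos = np.sort(raw, axis=1)
    founders = np.empty((n, K + 1), dtype=np.int16)
    founders[:, 0] = rng.integers(0, n_founders, size=n)
    if K:
        jumps = rng.integers(0, n_founders - 1, size=(n, K))
        for k in range(K):
            nxt = jumps[:, k]
            nxt = nxt + (nxt >= founders[:, k])
            founders[:, k + 1] = nxt.astype(np.int16)
    return pos, founders, counts


def _founders_at(pos: np.ndarray, founders: np.ndarray, query_cm: np.ndarray) -> np.ndarray:
    """Founder index for every (row, query) pair; rows loop over searchsorted."""
    n = pos.shape[0]
    out = np.empty((n, len(query_cm)), dtype=np.int16)
    for i in range(n):
        seg = np.searchsorted(pos[i], query_cm, side="right")
        out[i] = founders[i][seg]
    return out


def simulate_mosaic(gmap: GeneticMap, config: SimConfig, rng: np.random.Generator) -> FounderMosaic:
    """One transmitted genome as an explicit segment list."""
    segments = {}
    for c in config.chromosomes:
        lo, hi = gmap.cm_span(c.name)
        length_cm = hi - lo
        pos, founders, counts = _batch_chrom_mosaics(1, length_cm, config.breakpoint_rate, config.n_founders, rng)
        k = int(counts[0])
        starts = np.concatenate([[0.0], pos[0, :k]])
        segments[c.name] = (starts, founders[0, : k + 1].astype(int))
    return FounderMosaic(segments)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def _survival_probs(causal_founders: np.ndarray, causal: CausalSpec | None) -> np.ndarray:
    """Per-individual survival probability from the founders on both homologs.

    ``causal_founders`` is (n, 2); a null spec (or None) gives inverse-logit
    of the baseline alone (0.5 when the baseline is 0)."""
    if causal is None:
        return np.full(causal_founders.shape[0], 0.5)
    eff = np.asarray(causal.founder_effects)
    logit = causal.baseline_logit + eff[causal_founders[:, 0]] + eff[causal_founders[:, 1]]
    return expit(logit)


def apply_selection(
    population: list[tuple[FounderMosaic, FounderMosaic]],
    causal: CausalSpec | None,
    rng: np.random.Generator,
    gmap: GeneticMap | None = None,
    n_control: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Truncation selection on a diploid cohort.

    Returns (selected_ids, control_ids, survival_fraction). Selected ids are
    the survivors; controls are a simple random sample (without replacement)
    of size ``n_control`` from the full pre-selection cohort. Mosaic segment
    coordinates are cM offsets from the chromosome's first mapped cM, so a
    map is needed to locate a bp-specified causal site.
    """
    n = len(population)
    if causal is not None:
        if gmap is None:
            raise ValueError("a genetic map is required to locate the causal site")
        lo, _ = gmap.cm_span(causal.chrom)
        cm = float(gmap.interpolate_cm(causal.chrom, causal.position_bp)) - lo
        cf = np.array(
            [[a.founder_at(causal.chrom, cm), b.founder_at(causal.chrom, cm)] for a, b in population]
        )
    else:
        cf = np.zeros((n, 2), dtype=int)
    probs = _survival_probs(cf, causal)
    survive = rng.random(n) < probs
    selected = np.flatnonzero(survive)
    if selected.size == 0:
        raise RuntimeError(
            "no survivors under the causal model; raise baseline_logit or enlarge the cohort"
        )
    if n_control is None:
        n_control = n // 2
    control = rng.choice(n, size=min(n_control, n), replace=False)
    return selected, np.sort(control), float(survive.mean())


# ---------------------------------------------------------------------------
# Pooled sequencing
# ---------------------------------------------------------------------------


def sequence_pool(
    panel: FounderPanel,
    pool: list[tuple[FounderMosaic, FounderMosaic]],
    coverage: float,
    rng: np.random.Generator,
    sample_id: str = "pool",
    replicate: int = 1,
    sex: str = "F",
    treatment: str = "control",
) -> PooledSample:
    """Binomial read sampling from the pooled true REF frequency.

    Per SNP: q = mean REF allele over all 2n homologs, depth ~ Poisson(mean
    coverage), ref_count ~ Binomial(depth, q).
    """
    if not pool:
        raise ValueError("empty pool")
    frames = []
    for chrom in panel.chromosomes:
        sub = panel.subset(chrom)
        snp_cm = sub["cM"].to_numpy(float)
        snp_cm0 = snp_cm - snp_cm.min()
        M = sub[panel.founders].to_numpy(float)
        total = np.zeros(len(sub))
        for a, b in pool:
            for hom in (a, b):
                starts, founders = hom.segments[chrom]
                seg = np.searchsorted(starts[1:], snp_cm0, side="right")
                total += M[np.arange(len(sub)), founders[seg]]
        q = total / (2 * len(pool))
        depth = rng.poisson(coverage, size=len(sub))
        ref = rng.binomial(depth, q)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sub["pos"].to_numpy(),
                    "ref_count": ref,
                    "alt_count": depth - ref,
                }
            )
        )
    return PooledSample(sample_id, replicate, sex, treatment, pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Whole experiment
# ---------------------------------------------------------------------------


def simulate_experiment(
    config: SimConfig,
) -> tuple[FounderPanel, GeneticMap, list[PooledSample], TruthRecord]:
    """End-to-end synthetic experiment: founders, cohorts, selection, pools.

    Emits ``n_replicates`` control/selected pairs. Pair index r maps to
    experimental replicate (r+1)//2 and alternating sex labels, mirroring the
    2-replicates-by-2-sexes layout; sex has no genetic meaning here.
    """
    rng = np.random.default_rng(config.seed)
    gmap = genetic_map_for(config)
    panel = simulate_founder_panel(config, rng)
    causal = config.survival_model

    # truth grid (same windowing the inference uses)
    from .haplotype_inference import build_window_grid

    grid = build_window_grid(gmap, config.window_cm, config.step_cm)
    gtab = grid.table

    chrom_info = {}
    for c in config.chromosomes:
        sub = panel.subset(c.name)
        lo, hi = gmap.cm_span(c.name)
        chrom_info[c.name] = {
            "snp_cm0": sub["cM"].to_numpy(float) - lo,
            "pos": sub["pos"].to_numpy(),
            "M": sub[panel.founders].to_numpy(float),
            "length_cm": hi - lo,
            "lo_cm": lo,
        }

    samples: list[PooledSample] = []
    truth_freqs = []
    sample_ids = []
    survival_fractions = []

    causal_cm0 = None
    if causal is not None:
        lo = chrom_info[causal.chrom]["lo_cm"]
        causal_cm0 = float(gmap.interpolate_cm(causal.chrom, causal.position_bp)) - lo

    for r in range(1, config.n_replicates + 1):
        rep = (r + 1) // 2
        sex = "F" if r % 2 == 1 else "M"
        n = config.cohort_size
        n_hom = 2 * n

        mosaics = {
            c.name: _batch_chrom_mosaics(
                n_hom, chrom_info[c.name]["length_cm"], config.breakpoint_rate, config.n_founders, rng
            )
            for c in config.chromosomes
        }

        if causal is not None:
            pos_c, fnd_c, _ = mosaics[causal.chrom]
            cf_flat = _founders_at(pos_c, fnd_c, np.array([causal_cm0]))[:, 0]
            cf = cf_flat.reshape(n, 2)
        else:
            cf = np.zeros((n, 2), dtype=int)
        probs = _survival_probs(cf, causal)
        survive = rng.random(n) < probs
        selected_ids = np.flatnonzero(survive)
        if selected_ids.size == 0:
            raise RuntimeError(
                f"replicate {r}: no survivors; raise baseline_logit or cohort_size"
            )
        if selected_ids.size > config.pool_size_selected:
            selected_ids = np.sort(rng.choice(selected_ids, config.pool_size_selected, replace=False))
        if config.pool_size_control > n:
            raise ValueError("pool_size_control exceeds cohort_size")
        control_ids = np.sort(rng.choice(n, config.pool_size_control, replace=False))
        survival_fractions.append(float(survive.mean()))

        for treatment, ids in (("control", control_ids), ("selected", selected_ids)):
            sid = f"rep{rep}{sex}_{treatment}"
            hom_rows = np.empty(2 * ids.size, dtype=int)
            hom_rows[0::2] = 2 * ids
            hom_rows[1::2] = 2 * ids + 1
            frames = []
            wfreq_parts = []
            for c in config.chromosomes:
                info = chrom_info[c.name]
                pos_b, fnd_b, _ = mosaics[c.name]
                fidx = _founders_at(pos_b[hom_rows], fnd_b[hom_rows], info["snp_cm0"])
                occ = np.zeros((len(info["snp_cm0"]), config.n_founders))
                for f in range(config.n_founders):
                    occ[:, f] = (fidx == f).sum(axis=0)
                occ /= fidx.shape[0]
                q = (occ * info["M"]).sum(axis=1)
                depth = rng.poisson(config.coverage, size=len(q))
                ref = rng.binomial(depth, q)
                frames.append(
                    pd.DataFrame(
                        {"chrom": c.name, "pos": info["pos"], "ref_count": ref, "alt_count": depth - ref}
                    )
                )
                # truth founder frequencies per window: mean SNP occupancy
                sub_g = gtab[gtab["chrom"] == c.name]
                if len(sub_g):
                    snp_cm = info["snp_cm0"] + info["lo_cm"]
                    i0 = np.searchsorted(snp_cm, sub_g["start_cM"].to_numpy(), side="left")
                    i1 = np.searchsorted(snp_cm, sub_g["end_cM"].to_numpy(), side="right")
                    cum = np.vstack([np.zeros(config.n_founders), np.cumsum(occ, axis=0)])
                    counts = np.maximum(i1 - i0, 1)
                    wf = (cum[i1] - cum[i0]) / counts[:, None]
                    wfreq_parts.append(wf)
            samples.append(
                PooledSample(sid, r, sex, treatment, pd.concat(frames, ignore_index=True))
            )
            sample_ids.append(sid)
            truth_freqs.append(np.vstack(wfreq_parts) if wfreq_parts else np.zeros((0, config.n_founders)))

    truth = TruthRecord(
        causal=causal,
        grid=gtab.copy(),
        sample_ids=sample_ids,
        freqs=np.stack(truth_freqs),
        survival_fractions=survival_fractions,
    )
    return panel, gmap, samples, truth
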