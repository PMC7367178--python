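"""Synthetic two-condition, multi-factor ChIP-seq / RNA-seq dataset generator.

The generator plants every structure the analysis pipeline is meant to
recover, and writes a machine-readable truth manifest alongside the data:

* enhancer *sites* — short genomic intervals bound by subsets of the
  simulated factors (a YAP-like co-activator, the Oct4/Sox2/Nanog core
  factors, H3K27ac and Med1), with per-site, per-condition strengths;
* *SE clusters* — groups of 4-8 constituent sites within a 20 kb span with
  strongly boosted acetylation, each either common to both conditions,
  unique to the knockout (gained), or unique to the wild type (lost);
* a *knockout effect* — a fraction of YAP sites boosted in the KO
  condition, with correlated gains on the coupled factors (OSN, H3K27ac);
* *expression changes* — genes near gained clusters are up-regulated,
  genes near lost clusters down-regulated, against a stable background.

Fragment counts per bound site are Poisson in the site strength times the
depth parameter; background fragments fall uniformly; fragments have a
fixed length.  Peak statistics mimic a Poisson-tail caller so the peak
files look like narrowPeak output without running a peak caller.

Binding co-occurrence is planted with a latent-Gaussian (Gaussian copula)
scheme: each site draws a correlated standard-normal vector, thresholded
at each factor's marginal, with pairwise correlations solved so the joint
binding probabilities hit the requested site-level enrichment ratios.
Because binding is confined to discrete sites, the site-level ratio rho
and the genome-scale base-pair enrichment score r that the co-localization
module measures differ by the site density: r = rho * L / (S * w).  Use
:func:`site_ratio_for_genome_score` to convert.

Everything is driven by one seed; a fixed seed gives byte-identical output
files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeSpec
from .intervals import IntervalSet

DEFAULT_FACTORS = ("YAP", "Oct4", "Sox2", "Nanog", "H3K27ac", "Med1")
DEFAULT_MARGINALS = {
    "YAP": 0.6,
    "Oct4": 0.5,
    "Sox2": 0.5,
    "Nanog": 0.5,
    "H3K27ac": 0.9,
    "Med1": 0.4,
}
CONDITIONS = ("wt", "ko")


class ConfigError(ValueError):
    """Simulation configuration cannot be realised."""


def default_genome() -> GenomeSpec:
    return GenomeSpec(("chr1", "chr2"), (2_500_000, 2_500_000))


@dataclass
class SimulationConfig:
    """Parameters of the planted dataset; defaults define the reference
    study conditions (5 Mb genome, 600 enhancer sites, 30 SE clusters).

    ``co_occurrence`` maps factor pairs to *site-level* joint enrichment
    ratios (joint binding probability divided by the product of
    marginals); ``None`` means site-level independence.
    """

    seed: int = 0
    genome: GenomeSpec = field(default_factory=default_genome)
    n_genes: int = 200
    n_enhancer_sites: int = 600
    n_se_clusters: int = 30
    se_cluster_size: tuple[int, int] = (4, 8)
    se_cluster_span: int = 20_000
    factors: tuple[str, ...] = DEFAULT_FACTORS
    marginals: dict[str, float] | None = None
    co_occurrence: dict[tuple[str, str], float] | None = None
    ko_boost_fraction: float = 0.2
    ko_boost_multiplier: float = 4.0
    coupling: float = 0.8
    coupled_factors: tuple[str, ...] = ("Oct4", "Sox2", "Nanog", "H3K27ac")
    se_boost: float = 5.0
    premark_level: float = 0.3  # unique clusters in their inactive condition
    ko_unique_fraction: float = 0.2
    wt_unique_fraction: float = 0.1
    depth: float = 100.0
    background_rate: float = 0.01
    fragment_length: int = 200
    site_width: tuple[int, int] = (300, 700)
    strength_log_sd: float = 0.3
    expression_log_mean: float = math.log(8.0)
    expression_log_sd: float = 0.8
    de_fold: float = 4.0
    genes_per_cluster: int = 2
    condition_jitter_log2_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.marginals is None:
            self.marginals = {
                f: DEFAULT_MARGINALS.get(f, 0.5) for f in self.factors
            }
        for name in ("n_genes", "n_enhancer_sites", "n_se_clusters", "depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("ko_boost_fraction", "ko_unique_fraction", "wt_unique_fraction", "coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.se_cluster_size
        if not (1 <= lo <= hi):
            raise ConfigError("invalid se_cluster_size range")
        if self.co_occurrence is not None:
            for (a, b), r in self.co_occurrence.items():
                if r < 0:
                    raise ConfigError(f"negative co_occurrence for ({a}, {b})")


def site_ratio_for_genome_score(
    genome_score: float, n_sites: int, site_width: float, genome_bp: int
) -> float:
    """Site-level joint enrichment ratio that yields a target genome-scale
    base-pair enrichment score for factors confined to ``n_sites``
    non-overlapping sites of ``site_width`` bp on a ``genome_bp`` genome."""
    return genome_score * n_sites * site_width / genome_bp


def _solve_bvn_corr(za: float, zb: float, q: float) -> float:
    """Correlation of a standard bivariate normal with P(X<=za, Y<=zb) = q."""

    def joint(r: float) -> float:
        cov = [[1.0, r], [r, 1.0]]
        return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([za, zb]))

    lo, hi = -0.999, 0.999
    q_lo, q_hi = joint(lo), joint(hi)
    if not (q_lo - 1e-9 <= q <= q_hi + 1e-9):
        raise ConfigError("joint probability outside achievable range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if joint(mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def plant_co_binding(
    n_sites: int,
    marginals: Mapping[str, float],
    co_occurrence: Mapping[tuple[str, str], float] | None,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw per-site factor memberships with planted pairwise co-occurrence.

    ``co_occurrence[(a, b)]`` is the site-level joint enrichment ratio:
    P(a and b bind a site) = ratio * P(a) * P(b).  Missing pairs default
    to 1 (independence).  Raises :class:`ConfigError` naming the violating
    pair if a requested joint probability is outside the Frechet bounds or
    the implied latent correlation matrix is not positive semi-definite.
    """
    factors = list(marginals)
    p = np.array([marginals[f] for f in factors], dtype=np.float64)
    if np.any((p <= 0) | (p >= 1)):
        raise ConfigError("marginal binding probabilities must be in (0, 1)")
    F = len(factors)
    z = stats.norm.ppf(p)
    corr = np.eye(F)
    ratio_of = {}
    if co_occurrence:
        for (a, b), r in co_occurrence.items():
            ratio_of[frozenset((a, b))] = r
    for i in range(F):
        for j in range(i + 1, F):
            r = ratio_of.get(frozenset((factors[i], factors[j])), 1.0)
            q = r * p[i] * p[j]
            lo = max(0.0, p[i] + p[j] - 1.0)
            hi = min(p[i], p[j])
            if not (lo <= q <= hi):
                raise ConfigError(
                    f"infeasible co-occurrence for pair ({factors[i]}, "
                    f"{factors[j]}): joint {q:.4f} outside [{lo:.4f}, {hi:.4f}]"
                )
            if r == 1.0:
                corr[i, j] = corr[j, i] = 0.0
            else:
                corr[i, j] = corr[j, i] = _solve_bvn_corr(z[i], z[j], q)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-8:
        if eigvals[0] < -0.05:
            worst = max(
                ((i, j) for i in range(F) for j in range(i + 1, F)),
                key=lambda ij: abs(corr[ij]),
            )
            raise ConfigError(
                "co-occurrence matrix has no consistent joint distribution; "
                f"most extreme pair ({factors[worst[0]]}, {factors[worst[1]]})"
            )
        # mild violation from pairwise fitting: project to nearest PSD
        vals, vecs = np.linalg.eigh(corr)
        corr = vecs @ np.diag(np.clip(vals, 1e-6, None)) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(F))
    latent = rng.standard_normal((n_sites, F)) @ chol.T
    member = latent <= z
    return {f: member[:, k].copy() for k, f in enumerate(factors)}


def place_slots(
    genome: GenomeSpec, n_slots: int, width: int, rng: np.random.Generator, min_gap: int = 1
) -> list[tuple[str, int, int]]:
    """Place ``n_slots`` non-overlapping intervals of ``width`` bp, at least
    ``min_gap`` bp apart, spread over the genome proportionally to
    chromosome length."""
    total = genome.total_bp
    counts = [int(round(n_slots * l / total)) for l in genome.chrom_lengths]
    while sum(counts) > n_slots:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_slots:
        counts[int(np.argmin(counts))] += 1
    slots = []
    for chrom, length, k in zip(genome.chrom_names, genome.chrom_lengths, counts):
        if k == 0:
            continue
        free = length - k * (width + min_gap)
        if free < 0:
            raise ConfigError("too many slots for chromosome; reduce n or width")
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        starts = offsets + np.arange(k) * (width + min_gap)
        for s in starts.tolist():
            slots.append((chrom, int(s), int(s) + width))
    return slots


def simulate_cobinding_sets(
    genome: GenomeSpec,
    n_sites: int,
    site_width: int,
    marginals: Mapping[str, float],
    genome_ratios: Mapping[tuple[str, str], float],
    rng: np.random.Generator,
) -> dict[str, IntervalSet]:
    """Factor binding-site sets with planted *genome-scale* pairwise
    enrichment ratios, built on shared non-overlapping site slots.

    The requested genome-scale ratios are converted to site-level joint
    ratios via :func:`site_ratio_for_genome_score` and planted with
    :func:`plant_co_binding`; a pairwise enrichment measured at base-pair
    resolution over the whole genome then recovers the requested values up
    to binomial sampling error.
    """
    c = n_sites * site_width / genome.total_bp
    site_ratios = {pair: r * c for pair, r in genome_ratios.items()}
    slots = place_slots(genome, n_sites, site_width, rng)
    members = plant_co_binding(n_sites, marginals, site_ratios, rng)
    out = {}
    for f, mask in members.items():
        chosen = [slots[i] for i in np.flatnonzero(mask)]
        if not chosen:
            raise ConfigError(f"factor {f!r} bound no sites; increase n_sites")
        out[f] = IntervalSet(chosen, genome=genome)
    return out


# ---------------------------------------------------------------------------
# full dataset simulation


@dataclass
class PlantedSite:
    site_id: int
    chrom: str
    start: int
    end: int
    cluster_id: int | None  # None for ordinary enhancer sites
    factors: dict[str, dict[str, float]]  # factor -> {"wt": strength, "ko": strength}


@dataclass
class PlantedCluster:
    cluster_id: int
    chrom: str
    start: int
    end: int
    constituents: list[int]
    status: str  # common | ko_unique | wt_unique
    yap_bound: bool


@dataclass
class TruthManifest:
    """Ground truth for every planted structure, JSON round-trippable."""

    seed: int
    genome: dict
    sites: list[PlantedSite]
    clusters: list[PlantedCluster]
    ko_boosted_yap_sites: list[int]
    de_genes: list[dict]
    library_sizes: dict[str, int]
    parameters: dict

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "genome": self.genome,
            "sites": [
                {
                    "site_id": s.site_id,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "cluster_id": s.cluster_id,
                    "factors": s.factors,
                }
                for s in self.sites
            ],
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "constituents": c.constituents,
                    "status": c.status,
                    "yap_bound": c.yap_bound,
                }
                for c in self.clusters
            ],
            "ko_boosted_yap_sites": self.ko_boosted_yap_sites,
            "de_genes": self.de_genes,
            "library_sizes": self.library_sizes,
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            genome=d["genome"],
            sites=[
                PlantedSite(
                    s["site_id"], s["chrom"], s["start"], s["end"],
                    s["cluster_id"], s["factors"],
                )
                for s in d["sites"]
            ],
            clusters=[
                PlantedCluster(
                    c["cluster_id"], c["chrom"], c["start"], c["end"],
                    c["constituents"], c["status"], c["yap_bound"],
                )
                for c in d["clusters"]
            ],
            ko_boosted_yap_sites=d["ko_boosted_yap_sites"],
            de_genes=d["de_genes"],
            library_sizes=d["library_sizes"],
            parameters=d["parameters"],
        )

    def clusters_active_in(self, condition: str) -> list[PlantedCluster]:
        unique = {"wt": "wt_unique", "ko": "ko_unique"}[condition]
        return [c for c in self.clusters if c.status in ("common", unique)]


@dataclass
class SimulatedDataset:
    """Paths of all emitted files plus the loaded truth manifest."""

    out_dir: Path
    genome: GenomeSpec
    manifest: TruthManifest
    files: dict[str, Path]

    def path(self, key: str) -> Path:
        return self.files[key]


def _clipped_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    draw = np.clip(rng.standard_normal(size), -2.0, 2.0)
    return np.exp(sigma * draw)


def _layout_unit(
    widths: np.ndarray, gaps: np.ndarray
) -> tuple[int, list[tuple[int, int]]]:
    """Relative (start, end) offsets of sites laid left-to-right."""
    offsets = []
    pos = 0
    for k, w in enumerate(widths.tolist()):
        offsets.append((pos, pos + w))
        pos += w
        if k < len(gaps):
            pos += int(gaps[k])
    return pos, offsets


def simulate(config: SimulationConfig, out_dir) -> SimulatedDataset:
    """Generate the full dataset and truth manifest under ``out_dir``.

    Emits, per condition and factor: ``{factor}_{cond}.fragments.bed``,
    ``{factor}_{cond}.bedgraph`` and ``{factor}_{cond}.narrowPeak`` (plus
    input fragment/track files without peaks), together with
    ``genes.bed``, ``segmentation.bed``, ``expression.tsv``,
    ``genome.tsv`` and ``truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    factors = list(config.factors)
    marg = config.marginals

    # -- cluster bookkeeping ------------------------------------------------
    n_cl = config.n_se_clusters
    n_ko_u = int(round(config.ko_unique_fraction * n_cl))
    n_wt_u = int(round(config.wt_unique_fraction * n_cl))
    statuses = (
        ["ko_unique"] * n_ko_u + ["wt_unique"] * n_wt_u
        + ["common"] * (n_cl - n_ko_u - n_wt_u)
    )
    rng.shuffle(statuses)
    cluster_sizes = rng.integers(
        config.se_cluster_size[0], config.se_cluster_size[1] + 1, size=n_cl
    )
    n_constituents = int(cluster_sizes.sum())
    n_ordinary = config.n_enhancer_sites - n_constituents
    if n_ordinary < 0:
        raise ConfigError(
            "n_enhancer_sites smaller than the SE-cluster constituents; "
            "reduce n_se_clusters or the cluster size range"
        )

    # -- spatial units: clusters + small typical-enhancer groups -----------
    te_group_sizes: list[int] = []
    remaining = n_ordinary
    while remaining > 0:
        size = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        size = min(size, remaining)
        te_group_sizes.append(size)
        remaining -= size

    w_lo, w_hi = config.site_width
    units = []  # (kind, cluster_index_or_None, length, site_offsets)
    for ci in range(n_cl):
        widths = rng.integers(w_lo, w_hi + 1, size=int(cluster_sizes[ci]))
        gaps = rng.integers(800, 1701, size=int(cluster_sizes[ci]) - 1)
        length, offs = _layout_unit(widths, gaps)
        if length > config.se_cluster_span:
            # compress gaps to honour the declared maximum span
            scale = (config.se_cluster_span - widths.sum()) / max(1, gaps.sum())
            gaps = np.maximum(1, (gaps * scale).astype(np.int64))
            length, offs = _layout_unit(widths, gaps)
        units.append(("cluster", ci, length, offs))
    for size in te_group_sizes:
        widths = rng.integers(w_lo, w_hi + 1, size=size)
        gaps = rng.integers(1000, 4001, size=size - 1) if size > 1 else np.empty(0, int)
        length, offs = _layout_unit(widths, gaps)
        units.append(("te", None, length, offs))

    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # greedy left-to-right placement with wide margins around clusters so a
    # default-distance stitch never merges a planted cluster with neighbours
    # typical-enhancer groups usually sit beyond stitching range of each
    # other (occasional merges keep the ranked curve continuous); clusters
    # always do, so a default-distance stitch recovers each planted cluster
    # as exactly one region
    cluster_margin = lambda: int(rng.integers(13_000, 15_001))
    te_gap = lambda: (
        int(rng.integers(13_000, 15_001))
        if rng.random() < 0.75
        else int(rng.integers(3_000, 9_001))
    )
    placements: list[tuple[str, int]] = []  # (chrom, unit_start) parallel to units
    chrom_iter = iter(zip(genome.chrom_names, genome.chrom_lengths))
    chrom, chrom_len = next(chrom_iter)
    pos = te_gap()
    prev_was_cluster = False
    for kind, ci, length, offs in units:
        gap = cluster_margin() if (kind == "cluster" or prev_was_cluster) else te_gap()
        while pos + gap + length + 1000 > chrom_len:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ConfigError(
                    "cannot place all enhancer sites and SE clusters at the "
                    "requested density; reduce n_enhancer_sites or n_se_clusters"
                )
            chrom, chrom_len = nxt
            pos = te_gap()
            gap = cluster_margin() if kind == "cluster" else te_gap()
        start = pos + gap
        placements.append((chrom, start))
        pos = start + length
        prev_was_cluster = kind == "cluster"

    # -- materialise sites --------------------------------------------------
    sites: list[PlantedSite] = []
    clusters: list[PlantedCluster] = []
    ordinary_ids: list[int] = []
    group_size_of: dict[int, int] = {}  # ordinary site -> TE-group size
    for (kind, ci, length, offs), (chrom, ustart) in zip(units, placements):
        ids = []
        for rel_s, rel_e in offs:
            sid = len(sites)
            sites.append(
                PlantedSite(sid, chrom, ustart + rel_s, ustart + rel_e, ci, {})
            )
            ids.append(sid)
        if kind == "cluster":
            clusters.append(
                PlantedCluster(
                    ci, chrom, ustart, ustart + length, ids, statuses[ci], False
                )
            )
        else:
            for sid in ids:
                sites[sid].cluster_id = None
                ordinary_ids.append(sid)
                group_size_of[sid] = len(ids)
    clusters.sort(key=lambda c: c.cluster_id)

    # -- factor memberships -------------------------------------------------
    member = {f: np.zeros(len(sites), dtype=bool) for f in factors}
    ord_members = plant_co_binding(len(ordinary_ids), marg, config.co_occurrence, rng)
    for f in factors:
        member[f][np.array(ordinary_ids, dtype=int)] = ord_members[f]
    for cl in clusters:
        yap_p = 0.4 if cl.status == "wt_unique" else 0.85
        cl.yap_bound = bool(rng.random() < yap_p)
        for sid in cl.constituents:
            for f in factors:
                if f == "H3K27ac":
                    member[f][sid] = True  # acetylation defines the cluster
                elif f == "YAP":
                    member[f][sid] = cl.yap_bound and (rng.random() < 0.8)
                else:
                    member[f][sid] = rng.random() < 0.8

    # -- strengths ----------------------------------------------------------
    status_of = {c.cluster_id: c.status for c in clusters}
    strength = {
        f: {"wt": np.zeros(len(sites)), "ko": np.zeros(len(sites))} for f in factors
    }
    base = {
        f: _clipped_lognormal(rng, config.strength_log_sd, len(sites)) for f in factors
    }
    for f in factors:
        bound = member[f]
        for s in np.flatnonzero(bound):
            b = base[f][s]
            cid = sites[s].cluster_id
            st = status_of.get(cid) if cid is not None else None
            wt = b
            ko = b
            if st == "common":
                wt = ko = b * config.se_boost
            elif st == "wt_unique":
                wt = b * config.se_boost
                ko = b * config.premark_level
            elif st == "ko_unique":
                wt = b * config.premark_level
                ko = b * config.se_boost
            strength[f]["wt"][s] = wt
            strength[f]["ko"][s] = ko

    # knockout boost on a fraction of ordinary YAP sites, with coupled
    # gains; boosted sites are drawn from isolated (singleton) enhancers so
    # the coupled acetylation gain creates stronger typical enhancers, not
    # accidental multi-site clusters that would blur the planted SE truth
    ord_yap = [s for s in ordinary_ids if member["YAP"][s]]
    eligible = [s for s in ord_yap if group_size_of.get(s, 1) == 1]
    n_boost = min(
        int(round(config.ko_boost_fraction * len(ord_yap))), len(eligible)
    )
    boosted = sorted(
        int(s) for s in rng.choice(eligible, size=n_boost, replace=False)
    ) if n_boost else []
    for s in boosted:
        strength["YAP"]["ko"][s] *= config.ko_boost_multiplier
        gain = config.ko_boost_multiplier ** config.coupling
        for f in config.coupled_factors:
            if f in strength and member[f][s]:
                strength[f]["ko"][s] *= gain
    # constituents of gained clusters are also KO-boosted YAP sites
    ko_boosted_yap = sorted(
        set(boosted)
        | {
            s
            for cl in clusters
            if cl.status == "ko_unique"
            for s in cl.constituents
            if member["YAP"][s]
        }
    )
    if config.condition_jitter_log2_sd > 0:
        for f in factors:
            jit = 2.0 ** (
                config.condition_jitter_log2_sd * rng.standard_normal(len(sites))
            )
            strength[f]["ko"] *= np.where(member[f], jit, 1.0)

    for s in sites:
        for f in factors:
            if member[f][s.site_id]:
                s.factors[f] = {
                    "wt": round(float(strength[f]["wt"][s.site_id]), 6),
                    "ko": round(float(strength[f]["ko"][s.site_id]), 6),
                }

    # -- fragments, tracks, peaks -------------------------------------------
    files: dict[str, Path] = {}
    library_sizes: dict[str, int] = {}
    site_arr = {
        "chrom": np.array([s.chrom for s in sites]),
        "start": np.array([s.start for s in sites], dtype=np.int64),
        "end": np.array([s.end for s in sites], dtype=np.int64),
    }
    frag_len = config.fragment_length

    def _background():
        chroms, starts = [], []
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            n_bg = rng.poisson(config.background_rate * length)
            st = rng.integers(0, length - frag_len, size=n_bg)
            chroms.append(np.repeat(chrom, n_bg))
            starts.append(st)
        return np.concatenate(chroms), np.concatenate(starts)

    def _emit_track(name: str, site_counts: np.ndarray | None):
        chroms_parts, starts_parts = [], []
        if site_counts is not None:
            for s in np.flatnonzero(site_counts):
                k = int(site_counts[s])
                lo = max(0, site_arr["start"][s] - frag_len // 2)
                hi = min(
                    genome.length_of(str(site_arr["chrom"][s])) - frag_len,
                    site_arr["end"][s] - frag_len // 2,
                )
                st = rng.integers(lo, max(lo + 1, hi), size=k)
                chroms_parts.append(np.repeat(site_arr["chrom"][s], k))
                starts_parts.append(st)
        bg_c, bg_s = _background()
        chroms_parts.append(bg_c)
        starts_parts.append(bg_s)
        chroms = np.concatenate(chroms_parts)
        starts = np.concatenate(starts_parts).astype(np.int64)
        ends = starts + frag_len
        order = np.lexsort((starts, chroms))
        chroms, starts, ends = chroms[order], starts[order], ends[order]
        frag_path = out_dir / f"{name}.fragments.bed"
        with open(frag_path, "w") as fh:
            fh.writelines(
                f"{c}\t{s}\t{e}\n" for c, s, e in zip(chroms, starts, ends)
            )
        files[f"{name}.fragments"] = frag_path
        library_sizes[name] = len(starts)
        # depth track via run-length encoding of per-base coverage
        bg_path = out_dir / f"{name}.bedgraph"
        with open(bg_path, "w") as fh:
            for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
                mask = chroms == chrom
                delta = np.zeros(length + 1, dtype=np.int32)
                np.add.at(delta, starts[mask], 1)
                np.add.at(delta, ends[mask], -1)
                depth = np.cumsum(delta)[:-1]
                change = np.flatnonzero(np.diff(depth)) + 1
                bounds = np.concatenate([[0], change, [length]])
                for lo_b, hi_b in zip(bounds[:-1], bounds[1:]):
                    v = int(depth[lo_b])
                    if v != 0:
                        fh.write(f"{chrom}\t{lo_b}\t{hi_b}\t{v}\n")
        files[f"{name}.bedgraph"] = bg_path
        return chroms, starts, ends

    site_counts_by = {}
    for f in factors:
        for cond in CONDITIONS:
            lam = strength[f][cond] * config.depth
            site_counts_by[(f, cond)] = rng.poisson(lam)
    for f in factors:
        for cond in CONDITIONS:
            _emit_track(f"{f}_{cond}", site_counts_by[(f, cond)])
    for cond in CONDITIONS:
        _emit_track(f"input_{cond}", None)

    # narrowPeak files: Poisson-tail statistics against the local background
    sort_idx = np.lexsort((site_arr["start"], site_arr["chrom"]))
    for f in factors:
        for cond in CONDITIONS:
            counts = site_counts_by[(f, cond)]
            path = out_dir / f"{f}_{cond}.narrowPeak"
            with open(path, "w") as fh:
                k = 0
                for s in sort_idx:
                    if not member[f][s] or counts[s] == 0:
                        continue
                    k += 1
                    width = int(site_arr["end"][s] - site_arr["start"][s])
                    lam_bg = max(1e-3, config.background_rate * width)
                    obs = int(counts[s]) + int(round(lam_bg))
                    fe = obs / lam_bg
                    nlp = -stats.poisson.logsf(obs - 1, lam_bg) / math.log(10)
                    if not np.isfinite(nlp):
                        nlp = 5000.0
                    summit = width // 2
                    fh.write(
                        f"{site_arr['chrom'][s]}\t{site_arr['start'][s]}\t"
                        f"{site_arr['end'][s]}\t{f}_{cond}_peak{k}\t0\t.\t"
                        f"{fe:.5f}\t{nlp:.5f}\t-1\t{summit}\n"
                    )
            files[f"{f}_{cond}.narrowPeak"] = path

    # -- genes and expression ----------------------------------------------
    genes = []  # (gene_id, chrom, start, end, strand, cluster_id or None)
    gid = 0
    for cl in clusters:
        for _ in range(config.genes_per_cluster):
            center = (cl.start + cl.end) // 2
            offset = int(rng.integers(5_000, 40_001)) * (1 if rng.random() < 0.5 else -1)
            tss = int(np.clip(center + offset, 1_000, genome.length_of(cl.chrom) - 25_000))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2_000, 20_001))
            if strand == "+":
                start, end = tss, min(tss + length, genome.length_of(cl.chrom))
            else:
                start, end = max(0, tss + 1 - length), tss + 1
            genes.append((f"gene{gid:04d}", cl.chrom, start, end, strand, cl.cluster_id))
            gid += 1
    unique_spans = [
        (c.chrom, c.start - 55_000, c.end + 55_000)
        for c in clusters
        if c.status in ("ko_unique", "wt_unique")
    ]
    attempts = 0
    while gid < config.n_genes:
        attempts += 1
        if attempts > 100 * config.n_genes:
            raise ConfigError("cannot place background genes; genome too crowded")
        ci = int(rng.integers(0, len(genome.chrom_names)))
        chrom = genome.chrom_names[ci]
        tss = int(rng.integers(1_000, genome.chrom_lengths[ci] - 25_000))
        if any(c == chrom and lo <= tss < hi for c, lo, hi in unique_spans):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(2_000, 20_001))
        if strand == "+":
            start, end = tss, min(tss + length, genome.chrom_lengths[ci])
        else:
            start, end = max(0, tss + 1 - length), tss + 1
        genes.append((f"gene{gid:04d}", chrom, start, end, strand, None))
        gid += 1

    genes_path = out_dir / "genes.bed"
    with open(genes_path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g[1], g[2])):
            fh.write(f"{g[1]}\t{g[2]}\t{g[3]}\t{g[0]}\t0\t{g[4]}\n")
    files["genes"] = genes_path

    de_genes = []
    expr_rows = []
    for gene_id, chrom, start, end, strand, cid in genes:
        st = status_of.get(cid) if cid is not None else None
        if st == "ko_unique":
            base_fpkm = max(2.0, float(rng.lognormal(config.expression_log_mean,
                                                     config.expression_log_sd)))
            fpkm_wt = base_fpkm
            fpkm_ko = base_fpkm * config.de_fold
            q = float(rng.uniform(0.0, 0.005))
            de_genes.append(
                {"gene_id": gene_id, "true_fold": config.de_fold,
                 "direction": "up", "cluster_id": cid}
            )
        elif st == "wt_unique":
            base_fpkm = max(2.0, float(rng.lognormal(config.expression_log_mean,
                                                     config.expression_log_sd)))
            fpkm_wt = base_fpkm
            fpkm_ko = base_fpkm / config.de_fold
            q = float(rng.uniform(0.0, 0.005))
            de_genes.append(
                {"gene_id": gene_id, "true_fold": 1.0 / config.de_fold,
                 "direction": "down", "cluster_id": cid}
            )
        else:
            fpkm_wt = float(rng.lognormal(config.expression_log_mean,
                                          config.expression_log_sd))
            fpkm_ko = fpkm_wt * 2.0 ** float(rng.normal(0.0, 0.15))
            q = float(rng.uniform(0.2, 1.0))
        expr_rows.append((gene_id, fpkm_wt, fpkm_ko, q))

    expr_path = out_dir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\tfpkm_wt\tfpkm_ko\tq_value\n")
        for gene_id, a, b, q in sorted(expr_rows):
            fh.write(f"{gene_id}\t{a:.4f}\t{b:.4f}\t{q:.6g}\n")
    files["expression"] = expr_path

    # -- chromatin-state segmentation ---------------------------------------
    seg_path = out_dir / "segmentation.bed"
    state_codes = {0: "Quies", 1: "Tx", 2: "Tss", 3: "EnhA"}
    with open(seg_path, "w") as fh:
        for ci, (chrom, length) in enumerate(zip(genome.chrom_names, genome.chrom_lengths)):
            paint = np.zeros(length, dtype=np.int8)
            for gene_id, gchrom, start, end, strand, cid in genes:
                if gchrom == chrom:
                    paint[start:end] = 1
            for gene_id, gchrom, start, end, strand, cid in genes:
                if gchrom == chrom:
                    tss = start if strand == "+" else end - 1
                    paint[max(0, tss - 1000): min(length, tss + 1000)] = 2
            for s in sites:
                if s.chrom == chrom:
                    paint[max(0, s.start - 200): min(length, s.end + 200)] = 3
            change = np.flatnonzero(np.diff(paint)) + 1
            bounds = np.concatenate([[0], change, [length]])
            for lo_b, hi_b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{chrom}\t{lo_b}\t{hi_b}\t{state_codes[int(paint[lo_b])]}\n")
    files["segmentation"] = seg_path

    genome_path = out_dir / "genome.tsv"
    genome.to_tsv(genome_path)
    files["genome"] = genome_path

    manifest = TruthManifest(
        seed=config.seed,
        genome={
            "chrom_names": list(genome.chrom_names),
            "chrom_lengths": list(genome.chrom_lengths),
        },
        sites=sites,
        clusters=clusters,
        ko_boosted_yap_sites=[int(x) for x in ko_boosted_yap],
        de_genes=de_genes,
        library_sizes=library_sizes,
        parameters={
            "n_enhancer_sites": config.n_enhancer_sites,
            "n_se_clusters": config.n_se_clusters,
            "se_boost": config.se_boost,
            "ko_boost_fraction": config.ko_boost_fraction,
            "ko_boost_multiplier": config.ko_boost_multiplier,
            "coupling": config.coupling,
            "de_fold": config.de_fold,
            "depth": config.depth,
            "background_rate": config.background_rate,
            "fragment_length": config.fragment_length,
        },
    )
    truth_path = out_dir / "truth.json"
    manifest.to_json(truth_path)
    files["truth"] = truth_path

    return SimulatedDataset(out_dir=out_dir, genome=genome, manifest=manifest, files=files)
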