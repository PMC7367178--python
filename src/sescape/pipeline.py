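"""End-to-end pipeline: simulate -> diffpeaks -> coloc -> SEs -> expression.

One configured, logged, resumable run.  Every stage writes its outputs
under the run directory; a JSON report summarises the counts and — when a
truth manifest is present — recovery of the planted structures.  Reruns
with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coloc as coloc_mod
from . import expression as expr_mod
from . import io as sio
from . import peaks as peaks_mod
from . import superenhancer as se_mod
from .genome import GenomeSpec
from .intervals import IntervalSet
from .synthetic import SimulationConfig, TruthManifest, simulate

logger = logging.getLogger("sescape.pipeline")

STAGES = ("simulate", "diffpeaks", "coloc", "superenhancer", "expression", "report")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; unknown keys in a YAML file are rejected."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    data_dir: str | None = None  # existing dataset when simulate is False
    factors: tuple[str, ...] = ("YAP", "Oct4", "Sox2", "Nanog", "H3K27ac", "Med1")
    diff_factor: str = "YAP"
    se_factor: str = "H3K27ac"
    min_neg_log10_p: float = peaks_mod.DEFAULT_MIN_NEG_LOG10_P
    min_fold_enrichment: float = peaks_mod.DEFAULT_MIN_FOLD_ENRICHMENT
    rpkm_pseudocount: float = peaks_mod.DEFAULT_PSEUDOCOUNT_RPKM
    stitch_distance: int = se_mod.DEFAULT_STITCH_DISTANCE
    tss_exclusion_bp: int | None = None  # ROSE -t off by default
    se_fold_pseudocount: float = 1.0
    gene_window_bp: int = 50_000
    min_fpkm: float = expr_mod.DEFAULT_MIN_FPKM
    min_fold: float = expr_mod.DEFAULT_MIN_FOLD
    max_q: float = expr_mod.DEFAULT_MAX_Q
    fpkm_pseudocount: float = expr_mod.DEFAULT_PSEUDOCOUNT_FPKM
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ConfigError("stitch_distance must be >= 0")
        if self.gene_window_bp < 0:
            raise ConfigError("gene_window_bp must be >= 0")
        for name in ("min_neg_log10_p", "min_fold_enrichment", "rpkm_pseudocount",
                     "se_fold_pseudocount", "min_fpkm", "min_fold", "fpkm_pseudocount"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.max_q <= 0 or self.max_q > 1:
            raise ConfigError("max_q must be in (0, 1]")
        if not self.simulate and self.data_dir is None:
            raise ConfigError("either simulate: true or data_dir must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "factors" in raw:
            raw["factors"] = tuple(raw["factors"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# recovery metrics against a truth manifest


def _overlap_fraction(targets, calls) -> float:
    """Fraction of target intervals overlapped (>=1 bp) by any call."""
    if not targets:
        return float("nan")
    call_set = IntervalSet(calls) if calls else None
    hit = sum(
        1 for t in targets if call_set is not None and call_set.overlaps_any(*t)
    )
    return hit / len(targets)


def se_recovery(se_table, manifest: TruthManifest) -> dict:
    """Recall/precision of called SEs against active planted clusters,
    pooled over both conditions, plus the gained-cluster (KO-unique) recall
    under the fold > 2 rule."""
    recalls, precisions = [], []
    for cond in ("wt", "ko"):
        active = [
            (c.chrom, c.start, c.end) for c in manifest.clusters_active_in(cond)
        ]
        called = [
            (r.chrom, r.start, r.end)
            for r in se_table.itertuples()
            if r.condition == cond
        ]
        recalls.append(_overlap_fraction(active, called))
        truth_set = IntervalSet(active) if active else None
        ok = sum(1 for c in called if truth_set is not None and truth_set.overlaps_any(*c))
        precisions.append(ok / len(called) if called else float("nan"))
    gained = [
        (c.chrom, c.start, c.end)
        for c in manifest.clusters
        if c.status == "ko_unique"
    ]
    called_unique = [
        (r.chrom, r.start, r.end)
        for r in se_table.itertuples()
        if r.condition == "ko" and r.unique_to == "ko"
    ]
    return {
        "se_recall": float(np.nanmean(recalls)),
        "se_precision": float(np.nanmean(precisions)),
        "ko_unique_se_recall": _overlap_fraction(gained, called_unique),
    }


def diffpeak_recovery(diff_peaks, manifest: TruthManifest) -> dict:
    """Recall/precision of up-classified union peaks against planted
    KO-boosted YAP sites."""
    boosted = [
        (s.chrom, s.start, s.end)
        for s in manifest.sites
        if s.site_id in set(manifest.ko_boosted_yap_sites)
    ]
    up = [p.interval for p in diff_peaks if p.klass == "up"]
    truth_set = IntervalSet(boosted) if boosted else None
    precision = (
        sum(1 for u in up if truth_set is not None and truth_set.overlaps_any(*u)) / len(up)
        if up else float("nan")
    )
    return {
        "up_peak_recall": _overlap_fraction(boosted, up),
        "up_peak_precision": precision,
    }


# ---------------------------------------------------------------------------
# stages


def _load_filtered_peaks(data_dir: Path, name: str, genome, cfg) -> list:
    raw = sio.read_peaks(data_dir / f"{name}.narrowPeak", "narrowPeak", genome)
    return peaks_mod.filter_peaks(raw, cfg.min_neg_log10_p, cfg.min_fold_enrichment)


def run_pipeline(
    config: PipelineConfig,
    sim_config: SimulationConfig | None = None,
    from_stage: str = "simulate",
) -> dict:
    """Run all stages from ``from_stage`` on; returns the JSON report dict.

    Earlier stages must have left their outputs in the run directory when
    resuming.  All stage randomness derives from ``config.seed``.
    """
    if from_stage not in STAGES:
        raise ConfigError(f"unknown stage {from_stage!r}; stages: {STAGES}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out_dir / "pipeline.log")
    logger.addHandler(fh)
    start_idx = STAGES.index(from_stage)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    report["config"]["factors"] = list(config.factors)

    try:
        # -- simulate -------------------------------------------------------
        data_dir = Path(config.data_dir) if config.data_dir else out_dir / "data"
        if config.simulate and start_idx <= STAGES.index("simulate"):
            logger.info("stage simulate: seed %d", config.seed)
            sc = sim_config or SimulationConfig(seed=config.seed)
            if sim_config is None:
                sc = SimulationConfig(seed=config.seed)
            simulate(sc, data_dir)
            report["stages"]["simulate"] = {"data_dir": str(data_dir)}
        genome = GenomeSpec.from_tsv(data_dir / "genome.tsv")
        truth_path = data_dir / "truth.json"
        manifest = TruthManifest.from_json(truth_path) if truth_path.exists() else None

        genes = sio.read_gene_table(data_dir / "genes.bed", genome)
        diff_f = config.diff_factor

        # -- differential peaks ---------------------------------------------
        dp_path = out_dir / "diffpeaks.tsv"
        if start_idx <= STAGES.index("diffpeaks"):
            logger.info("stage diffpeaks: factor %s", diff_f)
            p_wt = _load_filtered_peaks(data_dir, f"{diff_f}_wt", genome, config)
            p_ko = _load_filtered_peaks(data_dir, f"{diff_f}_ko", genome, config)
            frags_wt = sio.read_fragments(data_dir / f"{diff_f}_wt.fragments.bed", genome)
            frags_ko = sio.read_fragments(data_dir / f"{diff_f}_ko.fragments.bed", genome)
            union = peaks_mod.union_peaks(p_wt, p_ko)
            diffs = peaks_mod.classify_differential_many(
                union, frags_wt, frags_ko, frags_wt.n_fragments, frags_ko.n_fragments,
                config.rpkm_pseudocount,
            )
            with open(dp_path, "w") as out:
                out.write("chrom\tstart\tend\trpkm_wt\trpkm_ko\tratio\tclass\tcontributors\n")
                for d in diffs:
                    out.write(
                        f"{d.chrom}\t{d.start}\t{d.end}\t{d.rpkm_wt:.4f}\t"
                        f"{d.rpkm_ko:.4f}\t{d.ratio:.4f}\t{d.klass}\t"
                        f"{'+'.join(sorted(d.contributors))}\n"
                    )
            for klass in ("up", "down"):
                with open(out_dir / f"diffpeaks_{klass}.bed", "w") as out:
                    for d in diffs:
                        if d.klass == klass:
                            out.write(f"{d.chrom}\t{d.start}\t{d.end}\t{klass}\n")
            stage = {
                "peaks_retained_wt": len(p_wt),
                "peaks_retained_ko": len(p_ko),
                "union_peaks": len(union),
                "up": sum(d.klass == "up" for d in diffs),
                "down": sum(d.klass == "down" for d in diffs),
                "unchanged": sum(d.klass == "unchanged" for d in diffs),
            }
            if manifest is not None:
                stage.update(diffpeak_recovery(diffs, manifest))
            report["stages"]["diffpeaks"] = stage

        # -- co-localization -------------------------------------------------
        if start_idx <= STAGES.index("coloc"):
            logger.info("stage coloc")
            sets = {}
            for f in config.factors:
                fp = _load_filtered_peaks(data_dir, f"{f}_wt", genome, config)
                sets[f] = IntervalSet([p.interval for p in fp], genome=genome)
            em = coloc_mod.enrichment_matrix(sets, genome.total_bp)
            em.scores.to_csv(out_dir / "coloc_scores.tsv", sep="\t", float_format="%.4f")
            em.p_values.to_csv(out_dir / "coloc_pvalues.tsv", sep="\t", float_format="%.4g")
            seg = sio.read_segmentation(data_dir / "segmentation.bed", genome)
            se_states = coloc_mod.state_enrichment(
                sets[diff_f], seg, genome.total_bp
            )
            with open(out_dir / "state_enrichment.tsv", "w") as out:
                out.write("state\tstate_bp\toverlap_bp\texpected_bp\tscore\n")
                for s in se_states:
                    score = "NA" if s.score is None else f"{s.score:.4f}"
                    out.write(
                        f"{s.state}\t{s.state_bp}\t{s.overlap_bp}\t"
                        f"{s.expected_bp:.2f}\t{score}\n"
                    )
            report["stages"]["coloc"] = {
                "factors": em.factors,
                "dendrogram_order": em.order,
                "max_offdiag_score": float(
                    (em.scores.values - np.diag(np.diag(em.scores.values))).max()
                ),
            }

        # -- super-enhancers -------------------------------------------------
        se_table_path = out_dir / "se_table.tsv"
        if start_idx <= STAGES.index("superenhancer"):
            logger.info("stage superenhancer: factor %s", config.se_factor)
            se_f = config.se_factor
            pk = {
                c: _load_filtered_peaks(data_dir, f"{se_f}_{c}", genome, config)
                for c in ("wt", "ko")
            }
            treat = {
                c: sio.read_fragments(data_dir / f"{se_f}_{c}.fragments.bed", genome)
                for c in ("wt", "ko")
            }
            ctrl = {
                c: sio.read_fragments(data_dir / f"input_{c}.fragments.bed", genome)
                for c in ("wt", "ko")
            }
            factor_sets = {}
            for f in config.factors:
                if f == se_f:
                    continue
                fp = _load_filtered_peaks(data_dir, f"{f}_wt", genome, config)
                fpk = _load_filtered_peaks(data_dir, f"{f}_ko", genome, config)
                factor_sets[f] = IntervalSet(
                    [p.interval for p in fp] + [p.interval for p in fpk], genome=genome
                )
            excl = (
                se_mod.tss_windows(genes, config.tss_exclusion_bp)
                if config.tss_exclusion_bp
                else None
            )
            call = se_mod.call_ses(
                {c: pk[c] for c in ("wt", "ko")},
                treat, ctrl,
                {c: treat[c].n_fragments for c in ("wt", "ko")},
                {c: ctrl[c].n_fragments for c in ("wt", "ko")},
                factor_peaks=factor_sets,
                stitch_distance=config.stitch_distance,
                tss_exclusion=excl,
                fold_pseudocount=config.se_fold_pseudocount,
            )
            call.table.to_csv(se_table_path, sep="\t", index=False, float_format="%.4f")
            for cond in ("wt", "ko"):
                regions = call.per_condition[cond].regions
                with open(out_dir / f"enhancer_ranking_{cond}.tsv", "w") as out:
                    out.write("rank\tchrom\tstart\tend\tsignal\tis_super\n")
                    for r in sorted(regions, key=lambda r: r.rank):
                        out.write(
                            f"{r.rank}\t{r.chrom}\t{r.start}\t{r.end}\t"
                            f"{r.signal:.4f}\t{int(r.is_super)}\n"
                        )
            stage = {
                "regions_wt": len(call.per_condition["wt"].regions),
                "regions_ko": len(call.per_condition["ko"].regions),
                "ses_wt": int((call.table["condition"] == "wt").sum()),
                "ses_ko": int((call.table["condition"] == "ko").sum()),
                "unique_wt": int((call.table["unique_to"] == "wt").sum()),
                "unique_ko": int((call.table["unique_to"] == "ko").sum()),
                "common": int((call.table["unique_to"] == "common").sum()),
                "yap_bound_ses": int(
                    call.table["bound_by"].str.contains(diff_f).sum()
                ),
            }
            if manifest is not None:
                stage.update(se_recovery(call.table, manifest))
            report["stages"]["superenhancer"] = stage
            se_table = call.table
        else:
            import pandas as pd

            se_table = pd.read_csv(se_table_path, sep="\t")

        # -- expression integration ------------------------------------------
        if start_idx <= STAGES.index("expression"):
            logger.info("stage expression")
            records = sio.read_expression(data_dir / "expression.tsv")
            de = expr_mod.call_de(
                records, config.min_fpkm, config.min_fold, config.max_q,
                config.fpkm_pseudocount,
            )
            with open(out_dir / "de_genes.tsv", "w") as out:
                out.write("gene_id\tfpkm_wt\tfpkm_ko\tlog2_fold\tq_value\tclass\n")
                for g in de:
                    out.write(
                        f"{g.gene_id}\t{g.fpkm_wt:.4f}\t{g.fpkm_ko:.4f}\t"
                        f"{g.log2_fold:.4f}\t{g.q_value:.6g}\t{g.klass}\n"
                    )
            # binding stratification from the differential-peak table
            import pandas as pd

            dp = pd.read_csv(dp_path, sep="\t")
            dp_ivals = list(zip(dp["chrom"], dp["start"], dp["end"]))
            _, gene_to_peaks = peaks_mod.assign_peaks_to_genes(
                dp_ivals, genes, config.gene_window_bp
            )
            gene_classes = {
                g: [dp["class"].iloc[i] for i in idxs]
                for g, idxs in gene_to_peaks.items()
            }
            counts, _members = expr_mod.stratify_by_binding(de, gene_classes)
            with open(out_dir / "binding_stratification.tsv", "w") as out:
                out.write("expression_class\tbinding_stratum\tn_genes\n")
                for (ek, bk), n in sorted(counts.items()):
                    out.write(f"{ek}\t{bk}\t{n}\n")
            # expression shift: genes near gained SEs vs background
            gained_spans = [
                (r.chrom, int(r.start), int(r.end))
                for r in se_table.itertuples()
                if r.condition == "ko" and r.unique_to == "ko"
            ]
            lfc = {g.gene_id: g.log2_fold for g in de}
            shift = None
            if gained_spans:
                _, gene_to_se = peaks_mod.assign_peaks_to_genes(
                    gained_spans, genes, config.gene_window_bp
                )
                linked = sorted(gene_to_se)
                background = sorted(set(lfc) - set(linked))
                if len(linked) >= 3 and len(background) >= 3:
                    res = expr_mod.expression_shift_test(
                        [lfc[g] for g in linked], [lfc[g] for g in background]
                    )
                    shift = {
                        "n_linked": len(linked),
                        "n_background": len(background),
                        "p_value": res.p_value,
                        "method": res.method,
                    }
                    with open(out_dir / "shift_ecdf.tsv", "w") as out:
                        out.write("group\tlfc\tcum_fraction\n")
                        for name, (xs, ys) in (
                            ("se_linked", res.ecdf_a), ("background", res.ecdf_b)
                        ):
                            for x, y in zip(xs, ys):
                                out.write(f"{name}\t{x:.4f}\t{y:.4f}\n")
            report["stages"]["expression"] = {
                "de_up": sum(g.klass == "up" for g in de),
                "de_down": sum(g.klass == "down" for g in de),
                "not_de": sum(g.klass == "not_de" for g in de),
                "shift_test": shift,
            }
            if manifest is not None:
                truth_up = {g["gene_id"] for g in manifest.de_genes if g["direction"] == "up"}
                called_up = {g.gene_id for g in de if g.klass == "up"}
                report["stages"]["expression"]["de_up_recall"] = (
                    len(truth_up & called_up) / len(truth_up) if truth_up else float("nan")
                )

        report_path = out_dir / "report.json"
        with open(report_path, "w") as out:
            json.dump(report, out, indent=1, sort_keys=True, default=str)
            out.write("\n")
        logger.info("report written to %s", report_path)
        return report
    finally:
        logger.removeHandler(fh)
        fh.close()
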