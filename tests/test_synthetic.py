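"""Generator validity: planted structure, determinism, calibration."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from sescape import io as sio
from sescape.genome import GenomeSpec
from sescape.synthetic import (
    ConfigError,
    SimulationConfig,
    TruthManifest,
    plant_co_binding,
    simulate,
    simulate_cobinding_sets,
)


class TestPlantCoBinding:
    def test_independent_pair_joint_matches_product(self):
        """ratio 1 at marginals 0.3 gives joint ~ 0.09 (exact binomial CI)."""
        n = 6000
        rng = np.random.default_rng(0)
        m = plant_co_binding(n, {"A": 0.3, "B": 0.3}, {("A", "B"): 1.0}, rng)
        joint = int((m["A"] & m["B"]).sum())
        ci = stats.binomtest(joint, n, 0.09).proportion_ci(0.999)
        assert ci.low <= 0.09 <= ci.high

    def test_enriched_pair_joint(self):
        """ratio 5 at marginals 0.1 gives joint ~ 0.05."""
        n = 6000
        rng = np.random.default_rng(1)
        m = plant_co_binding(n, {"A": 0.1, "B": 0.1}, {("A", "B"): 5.0}, rng)
        joint = int((m["A"] & m["B"]).sum())
        ci = stats.binomtest(joint, n, 0.05).proportion_ci(0.999)
        assert ci.low <= 0.05 <= ci.high

    def test_single_factor_marginal(self):
        rng = np.random.default_rng(2)
        m = plant_co_binding(5000, {"A": 0.4}, None, rng)
        assert abs(m["A"].mean() - 0.4) < 0.03

    def test_infeasible_ratio_names_pair(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ConfigError, match=r"\(A, B\)"):
            # joint would be 0.45 > min marginal 0.5*0.9... > Frechet bound
            plant_co_binding(10, {"A": 0.5, "B": 0.5}, {("A", "B"): 3.0}, rng)


@pytest.fixture(scope="module")
def halfscale(tmp_path_factory):
    cfg = SimulationConfig(seed=21, n_genes=80, n_enhancer_sites=300, n_se_clusters=15)
    return cfg, simulate(cfg, tmp_path_factory.mktemp("halfscale") / "a")


class TestGeneratorValidity:
    def test_records_within_genome_and_peaks_sorted(self, default_dataset):
        ds = default_dataset
        genome = ds.genome
        for f in ("YAP", "H3K27ac"):
            for cond in ("wt", "ko"):
                pk = sio.read_peaks(ds.path(f"{f}_{cond}.narrowPeak"), "narrowPeak", genome)
                keys = [(p.chrom, p.start) for p in pk]
                assert keys == sorted(keys)

    def test_manifest_round_trips_through_json(self, default_dataset):
        back = TruthManifest.from_json(default_dataset.path("truth"))
        assert back.ko_boosted_yap_sites == default_dataset.manifest.ko_boosted_yap_sites
        assert len(back.sites) == len(default_dataset.manifest.sites)
        assert [c.status for c in back.clusters] == [
            c.status for c in default_dataset.manifest.clusters
        ]

    def test_cluster_constituents_within_declared_span(self, default_dataset):
        m = default_dataset.manifest
        sites = {s.site_id: s for s in m.sites}
        for c in m.clusters:
            for sid in c.constituents:
                assert c.start <= sites[sid].start < sites[sid].end <= c.end
            assert c.end - c.start <= 20_000

    def test_de_genes_map_to_unique_clusters(self, default_dataset):
        m = default_dataset.manifest
        statuses = {c.cluster_id: c.status for c in m.clusters}
        for g in m.de_genes:
            assert statuses[g["cluster_id"]] in ("ko_unique", "wt_unique")

    def test_fixed_seed_is_byte_identical(self, halfscale, tmp_path):
        cfg, first = halfscale
        second = simulate(cfg, tmp_path / "b")
        for key, path in first.files.items():
            h1 = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            h2 = hashlib.sha256(Path(second.files[key]).read_bytes()).hexdigest()
            assert h1 == h2, f"{key} differs between identical runs"

    def test_null_ko_effect_leaves_strengths_identical(self, tmp_path):
        cfg = SimulationConfig(
            seed=9, n_genes=60, n_enhancer_sites=200, n_se_clusters=10,
            ko_boost_fraction=0.0, ko_unique_fraction=0.0, wt_unique_fraction=0.0,
        )
        ds = simulate(cfg, tmp_path / "null")
        for s in ds.manifest.sites:
            for v in s.factors.values():
                assert v["wt"] == v["ko"]

    def test_infeasible_density_raises(self, tmp_path):
        cfg = SimulationConfig(
            seed=0, genome=GenomeSpec(("chr1",), (200_000,)),
            n_enhancer_sites=600, n_se_clusters=30,
        )
        with pytest.raises(ConfigError, match="density|reduce"):
            simulate(cfg, tmp_path / "dense")


class TestPlantedSignalStructure:
    def test_cluster_acetylation_depth_ratio(self, default_dataset):
        """Active-cluster H3K27ac depth ~ se_boost x the median typical
        enhancer depth, measured from the emitted track."""
        ds = default_dataset
        m = ds.manifest
        track = sio.read_bedgraph(ds.path("H3K27ac_wt.bedgraph"), ds.genome)
        active = {c.cluster_id for c in m.clusters_active_in("wt")}
        cluster_depths, typical_depths = [], []
        for s in m.sites:
            if "H3K27ac" not in s.factors:
                continue
            depth = track.mean(s.chrom, s.start, s.end)
            if s.cluster_id in active:
                cluster_depths.append(depth)
            elif s.cluster_id is None:
                typical_depths.append(depth)
        ratio = np.mean(cluster_depths) / np.median(typical_depths)
        assert 0.8 * 5.0 <= ratio <= 1.2 * 5.0

    def test_yap_acetylation_coupling(self, default_dataset):
        """Planted KO/WT strength changes of H3K27ac track those of YAP."""
        m = default_dataset.manifest
        y, k = [], []
        for s in m.sites:
            if "YAP" in s.factors and "H3K27ac" in s.factors:
                y.append(np.log2(s.factors["YAP"]["ko"] / s.factors["YAP"]["wt"]))
                k.append(np.log2(s.factors["H3K27ac"]["ko"] / s.factors["H3K27ac"]["wt"]))
        r = np.corrcoef(y, k)[0, 1]
        assert r > 0.5

    def test_independent_cobinding_score_near_unity(self):
        """A pair planted at genome-scale ratio 1 scores in [0.8, 1.25]."""
        genome = GenomeSpec(("chr1", "chr2"), (1_000_000, 1_000_000))
        from sescape.coloc import pairwise_enrichment

        scores = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            sets = simulate_cobinding_sets(
                genome, 5000, 200, {"A": 0.15, "B": 0.15}, {("A", "B"): 1.0}, rng
            )
            scores.append(
                pairwise_enrichment(sets["A"], sets["B"], genome.total_bp).score
            )
        assert 0.8 <= float(np.mean(scores)) <= 1.25
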