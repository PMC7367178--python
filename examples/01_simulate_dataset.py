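"""Generate a synthetic two-condition ChIP-seq/RNA-seq dataset.

The generator plants enhancer sites bound by a YAP-like factor, the
Oct4/Sox2/Nanog core factors, H3K27ac and Med1 on a 5 Mb toy genome,
groups some of them into super-enhancer clusters (common, KO-gained or
WT-lost), boosts a fraction of YAP sites in the knockout with coupled
acetylation gains, and links expression changes to the gained clusters.
Every planted structure is recorded in truth.json.
"""

from collections import Counter

from sescape.synthetic import SimulationConfig, simulate

ds = simulate(SimulationConfig(seed=42), "example_output/dataset")

m = ds.manifest
print(f"wrote {len(ds.files)} files to {ds.out_dir}")
print(f"planted sites:        {len(m.sites)}")
print(f"SE clusters:          {Counter(c.status for c in m.clusters)}")
print(f"KO-boosted YAP sites: {len(m.ko_boosted_yap_sites)}")
print(f"planted DE genes:     {len(m.de_genes)}")
print(f"library sizes (YAP):  wt={m.library_sizes['YAP_wt']}, ko={m.library_sizes['YAP_ko']}")
# The cluster statuses are the recovery targets for the SE caller: 'common'
# clusters should be called in both conditions, 'ko_unique' only in the
# knockout (with >2-fold higher acetylation there), 'wt_unique' vice versa.
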