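"""One-shot pipeline run: every stage, one seeded report.

Writes all stage CSVs plus report.json; identical config + seed give a
byte-identical report.  (Permutation counts reduced here for speed; the
defaults are 999-20,000.)
"""

import json

from haplopop import RunConfig, paper_scale_config, run_all

cfg = RunConfig(
    output_dir="pipeline_out", seed=1,
    simulate=paper_scale_config(seed=1),
    n_perm_linkage=199, n_perm_amova=199, n_perm_fst=99,
    n_perm_mantel=199, n_perm_sasha=200, n_boot_gra=300,
)
report = run_all(cfg)

print(json.dumps({
    "amova_phi": report["stages"]["amova"]["phi"],
    "max_pairwise_fst": report["stages"]["fst"]["max_fst"],
    "dapc_k_opt": report["stages"]["dapc"]["k_opt"],
    "mantel_r": report["stages"]["ibd"]["mantel_r"],
    "sasha": {k: report["stages"]["sasha"][k]
              for k in ("observed_mean_km", "expected_mean_km", "p")},
    "errors": report["errors"],
}, indent=1))
print("full report in pipeline_out/report.json")
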