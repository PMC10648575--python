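"""Simulate the synthetic deep-sequencing cohort the later steps consume.

30 tumor/normal pairs x 500 panel sites at ~2,000x error-corrected depth
with background error 1e-3 and 50 true variants spiked at VAF 2% into
tumor samples.  Full count tables go to scratch/ (they are inputs for
step 02, regenerable from the seed); a compact per-sample summary goes to
results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from umivar.io import write_report
from umivar.model import SiteCountTable
from umivar.simulate import ErrorProfile, SpikeSpec, default_sites, simulate_cohort_counts

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    n_pairs, n_sites, depth = 30, 500, 2000
    sites = default_sites(n_sites)
    rng = np.random.default_rng(SEED)
    chosen = sorted(rng.choice(n_sites, size=50, replace=False))
    spikes = [
        SpikeSpec(site=sites[j], sample_id=f"P{i % n_pairs:02d}-T", true_vaf=0.02)
        for i, j in enumerate(chosen)
    ]
    tumors, normals, truth = simulate_cohort_counts(
        n_pairs, n_sites, depth, ErrorProfile(rate=1e-3), spikes, seed=SEED, sites=sites
    )
    tumors.to_tsv(SCRATCH / "cohort.tumor.tsv")
    normals.to_tsv(SCRATCH / "cohort.normal.tsv")
    write_report(
        [
            {"sample_id": s, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "label": v}
            for (s, k), v in sorted(truth.labels.items())
        ],
        SCRATCH / "cohort.truth.tsv",
    )

    rows = []
    for table, tissue in ((tumors, "tumor"), (normals, "normal")):
        depths = table.df.groupby("sample_id").apply(
            lambda g: (g.ref_count + g.alt_count + g.other_count).median(),
            include_groups=False,
        )
        for sample_id, median_depth in depths.items():
            rows.append({"sample_id": sample_id, "tissue": tissue,
                         "median_depth": int(median_depth)})
    summary = pd.DataFrame(rows)
    write_report(summary, RESULTS / "cohort_depth_summary.tsv")
    print(f"simulated {n_pairs} pairs x {n_sites} sites, {len(spikes)} spiked variants at VAF 2%")
    print(f"median error-corrected depth: tumors "
          f"{summary[summary.tissue == 'tumor'].median_depth.median():.0f}x, "
          f"normals {summary[summary.tissue == 'normal'].median_depth.median():.0f}x")
    print(f"count tables -> {SCRATCH}/cohort.*.tsv; summary -> {RESULTS}/cohort_depth_summary.tsv")


if __name__ == "__main__":
    main()
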