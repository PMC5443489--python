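"""Windowed differential methylation in a synthetic islet WGBS cohort.

Simulates 18 donors (16 non-diabetic, 2 T2D) over a ±5 kb region at 30X,
with T2D donors hypo-methylated by 16 percentage points at every CpG, then
summarizes the window under each stratification scheme.
"""

from glycometh.simulate import WgbsSimConfig, simulate_wgbs_counts
from glycometh.window import extract_window, stratify, summarize_window

config = WgbsSimConfig(seed=5)          # chr17, 10 kb window, delta 0.16
tables, donors, truth = simulate_wgbs_counts(config)
matrix = extract_window(tables, config.chrom, config.start, config.end)
print(f"{matrix.shape[0]} strand-specific CpG sites x "
      f"{matrix.shape[1]} donors\n")

for scheme in ("t2d", "age", "sex", "t2d_sex_matched"):
    controls, cases = stratify(donors, scheme)
    s = summarize_window(matrix, (controls, cases), seed=0, n_boot=200)
    print(f"{scheme:16s} {len(controls):2d} vs {len(cases):2d} donors | "
          f"up {s.increased_dmps:3d} down {s.decreased_dmps:3d} | "
          f"sDMPs {s.sdmp_count:3d} | "
          f"mean change (all sites) {s.mean_change_all:6.2f}% | "
          f"sDMP mean {s.mean_change_sdmp:6.2f}% "
          f"(CI {s.ci_low:.2f} ~ {s.ci_high:.2f})")

print()
print("Change is control mean minus case mean, so +16% under the t2d")
print("scheme recovers the planted hypo-methylation of the two T2D donors;")
print("age and sex splits mix the two T2D donors into both groups, so")
print("their planted contrast largely cancels out.  The sex-matched 6-vs-2")
print("split has only C(8,2)=28 labelings, so the exact Mann-Whitney test")
print("cannot reach p < 0.05 there (minimum two-sided p = 1/14) and the")
print("sDMP count is structurally zero despite the visible shift.")
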