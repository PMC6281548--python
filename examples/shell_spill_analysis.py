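"""Quantify spill-in around the bladder with morphological shell analysis.

The bladder mask is dilated with a Euclidean ball (2, 4, ..., 10 voxels);
ring shells between successive radii collect per-voxel percent differences
between reconstruction and truth, normalised by the bladder's true SUV.
d-bar is the shell mean, LOA the Bland-Altman 95% limits d-bar +/- 1.96 SD.
"""

from spillrecon.experiments import ExperimentConfig, run_shell_study

cfg = ExperimentConfig(seed=1, n_realisations=5)
report = run_shell_study(cfg, bladder_suv=55.5)

print("mean % activity difference d-bar per shell (bladder SUV 55.5,")
print("30 iterations, mean of 5 realisations; filtered value in brackets)\n")
print("shell (voxels)   " + "   ".join(
    f"{tuple(s['range_voxels'])}" for s in
    report["variants"]["OSEM"]["unfiltered"]["shells"]))
for variant, d in report["variants"].items():
    unf = [s["d_bar_percent"] for s in d["unfiltered"]["shells"]]
    fil = [s["d_bar_percent"] for s in d["filtered"]["shells"]]
    cells = "  ".join(f"{u:5.1f} ({f:5.1f})" for u, f in zip(unf, fil))
    print(f"  {variant:12s} {cells}")

s0 = report["variants"]["OSEM"]["unfiltered"]["shells"][0]
print(f"\nOSEM inner shell: d-bar {s0['d_bar_percent']:.1f}%, "
      f"SD {s0['sd_percent']:.1f}%, LOA [{s0['loa_percent'][0]:.1f}, "
      f"{s0['loa_percent'][1]:.1f}]%")
print("Spill-in decays with distance, the post-filter aggravates it, and")
print("background correction suppresses it in the innermost shells.")
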