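"""End-to-end synthetic study at desk scale.

Simulates a reduced two-group cohort (8 + 8 subjects, 3 ROIs), runs the
full pipeline (windowed GC edges, tract tensor metrics with free-water
masking, group tests with Bonferroni/FDR flags, covariate-adjusted
FA-memory associations) and prints the corrected group differences.
"""

import tempfile
from pathlib import Path

import pandas as pd

from stgc import RunConfig, run_pipeline

config = RunConfig(
    seed=11,
    n_hc=12,
    n_patient=12,
    roi_subset=["L-Thalamus", "L-IPL", "PCC"],
    voxels_per_roi=2,
)
out = Path(tempfile.mkdtemp()) / "run"
paths = run_pipeline(config, out)

tests = pd.read_csv(paths["group_tests"], sep="\t")
print("group tests surviving Bonferroni correction:")
for _, row in tests[tests["bonferroni_significant"]].iterrows():
    print(f"  {row['test']:<40} t={row['statistic']:7.2f}  p={row['p']:.2e}")

gc_row = tests[tests["test"] == "gc:L-Thalamus->L-IPL"].iloc[0]
print(f"\nplanted effective-connectivity edge: t={gc_row['statistic']:.2f} "
      f"p={gc_row['p']:.4f} (HC > patients)")

assoc = pd.read_csv(paths["associations"], sep="\t")
print("\nFA-memory associations (gender/age/motion adjusted):")
for _, row in assoc.iterrows():
    print(f"  {row['group']:>4}: t({row['df']:.0f}) = {row['t']:.2f}, p = {row['p']:.3f}")
print(f"\nall tables and the manifest are under {out}")
# Patients show lower tract FA and raised diffusivities at the corrected
# threshold, reduced GC on the planted edge, and an FA-memory association
# absent in controls - the study's qualitative dissociation.
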