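"""Generate the synthetic tissue cohort and write it to disk.

Emits matched 5modC / 5hmC beta matrices (40 samples, 5 tissues, 4000
probes), the sample sheet, a minimal probe manifest, and the ground-truth
sidecar used by the downstream scripts' recovery summaries.
"""

import numpy as np

from common import get_cohort, outdir
from methylcode.io import write_beta_matrix, write_manifest, write_sample_sheet
from methylcode.simulate import manifest_for_probes

out = outdir("01_cohort")
modc, hmc, sheet, gt = get_cohort()

write_beta_matrix(modc, out / "betas_5modC.tsv")
write_beta_matrix(hmc, out / "betas_5hmC.tsv")
write_sample_sheet(sheet, out / "samples.csv")
write_manifest(manifest_for_probes(list(modc.probe_ids)), out / "manifest.tsv")
gt.to_json(out / "ground_truth.json")

n_na = int(np.isnan(modc.to_numpy()).sum())
print(f"cohort: {modc.shape[0]} probes x {modc.shape[1]} samples "
      f"({sheet.table['tissue'].nunique()} tissues, {n_na} NA cells in 5modC)")
print(f"planted: {sum(len(df) for df in gt.marker_ids.values())} tissue markers, "
      f"{len(gt.age_cpgs)} age-CpGs, "
      f"{len(gt.sex_cpgs['male_hyper']) + len(gt.sex_cpgs['male_hypo'])} sex-CpGs")
print(f"written to {out}")
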