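"""One-vs-rest tissue marker discovery plus the methylation-level screens.

Finds the planted markers at AUC >= 0.8 and |delta beta| >= 0.2 with high
precision/recall, and reports the constitutive and intermediate screens.
"""

from common import get_cohort, outdir
from methylcode.io import BetaMatrix, write_probe_set
from methylcode.markers import (
    MarkerThresholds,
    constitutive_screen,
    intermediate_screen,
    one_vs_rest_all_contrasts,
)

out = outdir("03_markers")
modc, _, sheet, gt = get_cohort()
groups = sheet.groups("tissue")

markers = one_vs_rest_all_contrasts(
    modc, groups, MarkerThresholds(min_auc=0.8, min_delta=0.2)
)
markers.to_csv(out / "markers.tsv", sep="\t", index=False)

truth = {(ct, p) for ct, df in gt.marker_ids.items() for p in df["probe_id"]}
found = set(zip(markers["contrast"], markers["probe_id"]))
tp = len(found & truth)
print(f"markers: {len(markers)} selected across {markers['contrast'].nunique()} contrasts")
print(f"precision {tp / len(found):.3f}, recall {tp / len(truth):.3f} "
      f"against {len(truth)} planted markers")

unmod, mod = constitutive_screen(modc)
write_probe_set(unmod, out / "constitutively_unmodified.txt")
write_probe_set(mod, out / "constitutively_modified.txt")
inter = intermediate_screen(modc, min_frac_samples=0.8)
write_probe_set(inter, out / "intermediate.txt")
print(f"screens: {len(unmod)} consistently unmodified (beta<0.2), "
      f"{len(mod)} consistently modified (beta>0.8), "
      f"{len(inter)} intermediate (0.3-0.7 in >=80% of samples)")
imprinted = set(gt.imprinted_cpgs)
inter_set = set(inter)
print(f"intermediate screen vs planted imprinted-like loci: "
      f"recall {len(inter_set & imprinted) / len(imprinted):.3f}, "
      f"precision {len(inter_set & imprinted) / max(len(inter_set), 1):.3f} "
      f"({len(imprinted)} planted)")
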