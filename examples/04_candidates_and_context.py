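"""Candidate ranking and genomic-context statistics.

On the stock genome: rank genes by fractional methylation loss at d21
(the gDMD-like discovery step), show the top loss bin, and test the
feature/repeat composition of hypomethylated versus stable tiles.
"""

from remethyl.annotation import composition_chi2
from remethyl.reporting import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=12))

print("Top of the candidate ranking (mean % loss of tile methylation per gene):")
print(res.candidates.head(12).to_string(index=False))
top = res.candidates[res.candidates["bin"] == "[85,100]"]
n_imp = int(top["imprinted_flag"].sum())
print(
    f"\nTop bin [85,100]% loss: {len(top)} genes, {n_imp} imprinted, "
    f"{len(top) - n_imp} gDMD-like —\nknown imprints rank alongside novel "
    "heritable candidates, which is the discovery readout."
)

ann = res.annotations
hypo = res.diff_d21["status"] == "hypo"
re_class = ann["repeat_overlap"].fillna("no_RE")
hypo_re = re_class[hypo].value_counts().to_dict()
stable_re = re_class[~hypo].value_counts().to_dict()
chi2, dof, p = composition_chi2(hypo_re, stable_re)
print(
    f"\nRepeat-class composition, hypo vs stable tiles: chi2={chi2:.1f} "
    f"(df={dof}), p={p:.2e}"
)
print("hypo tiles by repeat class:", hypo_re)
print(
    "\nA significant chi-square says tiles that fail to recover methylation "
    "sit in a different\nrepeat landscape than stable tiles (LINE-enriched "
    "in the experiment this emulates)."
)
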