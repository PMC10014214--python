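"""Classification metrics on a ten-drug mock ranking.

Ten candidate drugs ranked for one indication; four are known treatments.
Calling the top five positive gives the confusion counts, from which every
threshold metric follows.  The ROC and PR areas summarize the whole
ranking across all cutoffs.
"""

import repurbench as rb

# rank:    1  2  3  4  5  6  7  8  9 10   (1 = known treatment)
rel = rb.RelevanceVector((1, 0, 1, 1, 0, 0, 1, 0, 0, 0))
c = rb.confusion_at_cutoff(rel, 5)

print(f"cutoff 5 -> TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}")
print(f"sensitivity {rb.sensitivity(c):.3f}   specificity {rb.specificity(c):.3f}")
print(f"precision   {rb.precision(c):.3f}   FDR         {rb.fdr(c):.3f}")
print(f"accuracy    {rb.accuracy(c):.3f}   F1          {rb.f1(c):.3f}")
print(f"MCC         {rb.mcc(c):.3f}")
print(f"AUROC (trapezoid) {rb.auroc_trapezoid(rel):.3f}")
print(f"AUPRC (step)      {rb.auprc(rel):.3f}  (= average precision)")
print("\nThree of the five positive calls are real treatments; the two false")
print("positives are exactly the repurposing candidates such a tool would")
print("put forward for validation.")
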