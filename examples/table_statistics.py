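"""Cohort-table statistics and confusion-matrix reconstruction.

Recomputes the kind of statistics a case-control demographics table reports
(Pearson chi-square on 2x2 counts, pooled t from summary statistics) and
inverts printed sensitivity/specificity percentages back to integer
confusion counts, from which all the other diagnostic metrics follow.
"""

from morphosvm import (
    ContingencyTable2x2,
    chi_square_2x2,
    diagnostic_metrics,
    reconstruct_confusion,
    two_sample_t,
)
from morphosvm.crossval import round_pct

# antipsychotic use: 10/23 cases vs 15/19 comparison subjects
chi2 = chi_square_2x2(ContingencyTable2x2(10, 13, 15, 4))
print(f"antipsychotics: chi2 = {chi2.statistic:.2f}, df = {chi2.df}, "
      f"p = {chi2.p_value:.3f}")

# age: mean 27.09 (SD 8.87, n 23) vs 29.05 (SD 8.34, n 19)
t = two_sample_t(27.09, 8.87, 23, 29.05, 8.34, 19)
print(f"age: t = {t.statistic:.3f}, df = {t.df}, p = {t.p_value:.3f}")

# printed sensitivity 39.1% of 23 and specificity 84.8% of 33 pin down a
# unique integer contingency table ...
cm = reconstruct_confusion(23, 33, printed_sens_pct=39.1, printed_spec_pct=84.8)
print(f"reconstructed counts: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")

# ... from which the remaining diagnostic metrics follow exactly
rep = diagnostic_metrics(cm)
print(f"accuracy {round_pct(rep.accuracy)}%, PPV {round_pct(rep.ppv)}%, "
      f"NPV {round_pct(rep.npv)}%")
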