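"""Univariate seasonal and sexual difference tests on the presence quadrats.

Continuous factors are dispatched to one-way ANOVA when each group passes
a normality check and the groups pass a median-centred Levene test,
otherwise to the Mann-Whitney U test (normal approximation with tie
correction); categorical factors use a chi-square test on the
level x category table.
"""

import warnings

from microniche import compare_groups, generate_survey

warnings.simplefilter("ignore")

ds, _ = generate_survey(seed=1)

for grouping in ("sex", "season"):
    print(f"\n=== {grouping} comparison ===")
    for res in compare_groups(ds, grouping):
        stat_name = {"mann_whitney": "Z", "anova": "F", "chi_square": "chi2"}[res.test]
        print(f"  {res.variable:<20} {res.test:<13} {stat_name} = "
              f"{res.statistic:7.3f}  p = {res.p_value:.3f}")
print("\np < 0.05 flags a factor whose use differs between the two levels")
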