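"""Validate the derived score with ROC analysis on every draw.

The operating cutoff is chosen on each derivation cohort by minimal
Euclidean distance to the ideal ROC point (0, 1) and applied unchanged to
the held-out validation third; the table mirrors a screening-performance
report (sensitivity, specificity, PPV, NPV per draw).
"""

from mrdash import (
    CohortSpec, ScoreBuilderConfig, assign_points, evaluate_draws,
    generate_cohort, phenotype_cohort, run_draws,
)

phenotyped, _ = phenotype_cohort(generate_cohort(CohortSpec(n_subjects=3014, seed=1)))
cfg = ScoreBuilderConfig(seed=1)
draws = run_draws(phenotyped, cfg)
score = assign_points(draws, cfg)
report = evaluate_draws(phenotyped, draws, score)

print(f"score points: {score.points}\n")
print("  draw  cohort       AUC (95% CI)        cutoff  sens%  spec%   PPV%   NPV%")
for e in report.draws:
    for name, roc, m in (("derivation", e.derivation_roc, e.derivation_metrics),
                         ("validation", e.validation_roc, e.validation_metrics)):
        print(f"  {e.draw_index + 1:>4}  {name:<11} "
              f"{roc.auc:.3f} ({roc.auc_ci_low:.3f}-{roc.auc_ci_high:.3f})  "
              f"{m.cutoff:>5.1f} {100 * m.sensitivity:6.1f} "
              f"{100 * m.specificity:6.1f} {100 * m.ppv:6.1f} {100 * m.npv:6.1f}")

print(f"\nmean derivation AUC: {report.mean_derivation_auc:.3f}  "
      f"(range {report.derivation_auc_range[0]:.3f}-"
      f"{report.derivation_auc_range[1]:.3f})")
print(f"mean validation AUC: {report.mean_validation_auc:.3f}  "
      f"(range {report.validation_auc_range[0]:.3f}-"
      f"{report.validation_auc_range[1]:.3f})")
print("\nA score above the cutoff screens positive; the high NPV means a")
print("low score reliably rules out silent AF, the scale's intended use.")
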