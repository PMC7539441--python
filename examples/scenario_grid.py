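"""LR-method cross-validation of combined-line training sets.

Runs three training-set scenarios for one target line on a small simulated
study: the within-line control (scenario 1), adding the other line's late
generations (scenario 3), and the reduced-target-line design (scenario 5).
Accuracy is the correlation between partial-data and whole-data GEBV of the
validation animals; the slope of GEBVw on GEBVp measures bias (1 = none).
"""

import pandas as pd

from ssgblup import SimConfig, simulate_study, true_variance_components, evaluate_scenarios

cfg = SimConfig(n_snps=1000, n_qtl=150, n_generations=6,
                n_g0_candidates=48, n_candidates_per_gen=48,
                n_dams_per_line=16, n_f0_sires=16, n_f0_dams=16, seed=5)
study, bundle = simulate_study(cfg)

varcomps = true_variance_components(cfg)
res = evaluate_scenarios(bundle, varcomps, traits=("ADG", "RFI"),
                         scenario_ids=(1, 3, 5), lines=("HRFI",))

cols = ["trait", "scenario", "n_train", "n_val", "r", "se", "slope",
        "williams_p", "rel_target_mean", "rel_other_mean"]
pd.set_option("display.width", 160)
print(res[cols].round(3).to_string(index=False))

# r: LR accuracy of each scenario's partial evaluation relative to the
#    whole-data run of the target line (higher = less information lost);
# slope: regression of whole-data on partial GEBV, 1 means unbiased;
# williams_p: does the scenario's accuracy differ from the control?
# rel_*_mean: mean H-relationship between validation animals and the
#    training animals of the target / other line.
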