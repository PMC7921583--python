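"""Generate a synthetic 16-season study and run the full analysis pipeline.

The generator builds capture records, rainfall, cone scores and isotope
samples with known parameter values; the report then re-estimates those
parameters from the data alone.  Compare the printed slopes with the truth
the generator used: arrival -5.8 d per cone-score point, sex-ratio dip
-7.5, fledgling rise -7.3, brood-patch midpoint -3.5.
"""

from mastphen import SimulationConfig, run_all, simulate_study

study = simulate_study(SimulationConfig(), seed=42)
print(f"captures: {len(study.captures)} birds over "
      f"{study.captures['session_date'].nunique()} sessions")

rain = study.rainfall.set_index("date")["rain_mm"]
scores = study.cone_scores.rename(
    columns={"autumn_year": "cone_year", "score": "cone_score"}
)
bundle = run_all(study.captures, rain, scores, study.isotopes, study.cone_samples)

print("\nestimated cone-score effects (days per score point):")
print(f"  arrival:            {bundle.regressions['arrival_vs_cone'].slope:6.2f}  (truth -5.8)")
print(f"  sex-ratio shift:    {-bundle.regressions['sex_ratio_shift'].slope:6.2f}  (truth -7.5)")
print(f"  fledgling shift:    {-bundle.regressions['fledgling_shift'].slope:6.2f}  (truth -7.3)")
print(f"  brood-patch midpoint:{bundle.regressions['brood_patch_vs_cone'].slope:5.2f}  (truth -3.5)")

print("\nrainfall: positive catch correlation in "
      f"{bundle.statistics['n_seasons_positive_rain_correlation']} of "
      f"{bundle.statistics['n_seasons_with_rain_correlation']} seasons "
      f"(sign test p = {bundle.statistics['rain_sign_test_p']:.4f})")
print("a positive slope in most seasons means catches spike after wet spells,"
      " when closed cones push the birds to other food")
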