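"""A small Monte Carlo comparison of binary vs ordinal growth-model bias.

Runs 50 replicates of the shift-pattern / small-slope / N = 200 cell for 2
and 3 categories and prints difficulty rates and relative bias of the slope
parameters.  (The full 54-condition study runs via `catlgm run`.)
"""

from catlgm import Condition, report_tables, run_condition

reports = []
for categories in (2, 3):
    cond = Condition("shift", "small", categories, 200, base_seed=7)
    rep = run_condition(cond, reps=50)
    reports.append(rep)
    print(f"{cond.label}: difficulties {rep.difficulty_rate:.1f}% "
          f"(converged {rep.converged}/{rep.attempted})")
    print(f"   RB(alpha10) = {rep.rb['alpha10']:+.3f} +- {rep.mc_se['alpha10']:.3f} (MC SE)")
    print(f"   RB(psi11)   = {rep.rb['psi11']:+.3f} +- {rep.mc_se['psi11']:.3f}")

# binary estimation fails much more often and its slope-variance bias is an
# order of magnitude larger; the ordinal model stays near zero bias.
print("\ndifficulties table (percent, NaN = condition not run):")
print(report_tables(reports)["difficulties"].dropna(how="all"))
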