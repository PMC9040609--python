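"""Absolute proteorhodopsin quantification to copies per cell.

Regenerates the reference scenario's PR standard-peptide MS1 areas and
growth curves, fits the OD-to-cell-density calibration, converts peak-area
ratios to pmol and copies/cell, and summarizes the stationary-phase C/N
fold change and the C-limited expression maximum.
"""

from iptlpipe import default_scenario
from iptlpipe.expression_tables import assign_phase
from iptlpipe.pr_absolute import (CellCalibration, condition_fold_change,
                                  max_copies_per_cell, quantify_samples,
                                  trajectory)
from iptlpipe.synthetic_data import (simulate_calibration,
                                     simulate_growth_all,
                                     simulate_pr_standard_areas)

scenario = default_scenario()
seed = 1
areas = simulate_pr_standard_areas(scenario, seed)
growth = simulate_growth_all(scenario, seed)
cal = simulate_calibration(scenario, seed)
calibration = CellCalibration.fit(cal.od, cal.cells_per_ml)

amounts = quantify_samples(areas, growth, calibration,
                           volume_ml=scenario.sample_volume_ml)
phase_map = assign_phase(sorted(scenario.timepoints_h))
fc, fc_err = condition_fold_change(amounts, phase_map)

print("C-limited PR trajectory (mean over replicates and light conditions):")
print(f"{'t (h)':>6} {'pmol':>8} {'copies/cell':>12}")
for row in trajectory(amounts, "C_limited").itertuples():
    print(f"{row.timepoint_h:>6g} {row.pr_pmol:>8.2f} "
          f"{row.copies_per_cell:>12.0f}")
print(f"\nstationary-phase fold change C/N : {fc:.2f} +/- {fc_err:.2f}")
print(f"maximum PR expression (C-limited): "
      f"{max_copies_per_cell(amounts):.0f} copies/cell")
print(f"scenario truths                  : "
      f"{scenario.pr_stationary_fold_change_true():.1f}-fold, "
      f"{max(scenario.pr_copies_per_cell['C_limited']):.0f} copies/cell")
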