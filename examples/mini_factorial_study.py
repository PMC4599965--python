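"""A scaled-down factorial Monte Carlo study with the full analysis stack.

Runs a reduced factor grid (2 item starts x 2 weight starts x 2 sample
sizes x both true distributions x 2 criteria, 5 replications), then prints
the Earth Mover's Distance summary table, the eta-squared ANOVA of ICC
bias, and the Welch/Cohen comparison of latent recovery between normal and
skewed truth.  The full design (all levels, 100 replications) uses the
same code with the default StudyConfig.
"""

import pandas as pd

from ehirt.study import (
    FACTORS_EH,
    StudyConfig,
    aggregate_cells,
    eta_squared_table,
    run_study,
    summarize_tables,
    welch_cohen,
)

cfg = StudyConfig(
    iip_levels=("default", "const"),
    ild_levels=("default", "uniform"),
    n_levels=(250, 1000),
    criteria=(1e-2, 1e-4),
    methods=("eh",),
    n_reps=5,
    master_seed=42,
)
records = run_study(cfg, progress=True)

pd.set_option("display.width", 120)
tables = summarize_tables(records)
print("\nMean EMD by (true distribution, criterion) x initial weights:")
print(tables["emd"].round(3))

cells = aggregate_cells(records, "eh")
tab = eta_squared_table(cells[cells.criterion == 1e-2], "icc_bias", FACTORS_EH)
print("\nEta-squared for ICC bias at criterion 1e-2 (rows sum to 1):")
print(tab.table.round(4))

eh = records[records.method == "eh"]
t, df, p, d = welch_cohen(
    eh[eh.tld == "normal"].emd, eh[eh.tld == "skew_normal"].emd
)
print(f"\nEMD normal vs skewed truth: t({df:.1f}) = {t:.2f}, p = {p:.3g}, d = {d:.2f}")
print("Positive t: the latent distribution is recovered less accurately "
      "under normal truth than under skewed truth.")
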