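"""Full privacy-utility trade-off experiment with figures.

Runs the whole grid (3 schemes x 6 amplitudes x 6 studies x 2 attack
scenarios), prints the trade-off table for the largest amplitude and
exports the minimisation-vs-pseudonymisation scatter, a weekly epidemic
series overlay and the birth-scheme uniqueness heatmap.
"""

from pathlib import Path

from dateshift import (
    ExperimentPlan,
    SchemeParams,
    SyntheticConfig,
    apply_scheme,
    birth_param_sweep,
    generate_full_dataset,
    generate_population,
    run_experiment,
    study_epidemic,
)
from dateshift.plots import (
    plot_minimisation_scatter,
    plot_uniqueness_heatmap,
    plot_weekly_series,
)

out = Path("results/figures")
out.mkdir(parents=True, exist_ok=True)

plan = ExperimentPlan(
    config=SyntheticConfig(n_patients=2000, seed=5), target_sample=200, master_seed=9
)
dataset = generate_full_dataset(plan.config)
report = run_experiment(plan, dataset=dataset)
report.to_csv(out.parent / "tradeoff.csv", index=False)

show = report[(report["delta_t"] == 1000) & (report["scenario"] == "random_target")]
cols = ["study", "scheme", "p_access", "uniqueness", "p_success", "unreliability"]
print(show[cols].round(4).to_string(index=False))

fig = plot_minimisation_scatter(report[report["scenario"] == "random_target"])
fig.savefig(out / "success_vs_cohort_size.png", dpi=150)

series = {"original": study_epidemic(dataset, "J21").series}
for dt in (7, 100):
    pseudo = apply_scheme(dataset, SchemeParams("base", dt), seed=9)
    series[f"base Δt={dt}"] = study_epidemic(
        pseudo, "J21", week_origin=dataset.study_window[0]
    ).series
fig = plot_weekly_series(series, title="Bronchiolitis weekly admissions")
fig.savefig(out / "bronchiolitis_series.png", dpi=150)

matrix = birth_param_sweep(
    generate_population(SyntheticConfig(n_patients=1500, seed=5)),
    (0, 7, 30, 100, 1000),
    (0, 7, 30, 100, 1000),
    seed=9,
    target_sample=250,
)
fig = plot_uniqueness_heatmap(matrix, title="Birth scheme uniqueness")
fig.savefig(out / "birth_sweep_heatmap.png", dpi=150)
print(f"\nfigures written to {out}/")
# Cohort size (minimisation) moves P(success) by orders of magnitude;
# pseudonymisation moves it far less — but is what protects utility-
# preserving cohorts once an attacker is certain the target is inside.
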