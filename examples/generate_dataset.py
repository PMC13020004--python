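"""Generate a synthetic hospitalisation dataset and inspect its marginals.

Draws a 38-hospital background population plus the standard study
cohorts (bronchiolitis and flu waves, incident pancreatic cancer,
bariatric surgery), prints the marginal summary, and writes the
patients/stays CSV pair.
"""

from dateshift import SyntheticConfig, generate_full_dataset, summarise_dataset, write_dataset

config = SyntheticConfig(n_patients=5000, seed=1)
dataset = generate_full_dataset(config)
summary = summarise_dataset(dataset)

print(f"patients: {summary['n_patients']}, stays: {summary['n_stays']}")
print(f"male fraction:  {summary['male_fraction']:.3f}   (target 0.46)")
print(f"death fraction: {summary['death_fraction']:.3f}   (target 0.10)")
print(
    f"age at first stay: median {summary['median_age_first_stay']:.1f} y, "
    f"IQR [{summary['age_iqr'][0]:.1f}, {summary['age_iqr'][1]:.1f}]"
)
print(f"length of stay quantiles (days): {summary['los_quantiles']}")
print(f"stays per patient quantiles: {summary['stays_per_patient_quantiles']}")

write_dataset(dataset, "results/example_dataset")
print("wrote results/example_dataset/{patients,stays}.csv (ISO-8601 dates)")
# The summary shows the heavy-tailed utilisation structure the attack
# exploits: most patients have one short stay, a few have many.
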