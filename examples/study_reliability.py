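"""Measure how pseudonymisation distorts six archetypal studies.

Runs each study on the original data and on three pseudonymised copies,
then prints the unreliability indicator: the mean relative deviation of
the study's key statistics (KL divergence of the weekly series for the
epidemic studies). 0 means the study is unaffected.
"""

import pandas as pd

from dateshift import (
    SchemeParams,
    SyntheticConfig,
    apply_scheme,
    generate_full_dataset,
    study_bariatric,
    study_care_pathways,
    study_epidemic,
    study_hosp_characterisation,
    study_survival,
    unreliability,
)

dataset = generate_full_dataset(SyntheticConfig(n_patients=3000, seed=4))

STUDIES = {
    "characterisation": study_hosp_characterisation,
    "bronchiolitis": lambda d: study_epidemic(d, "J21", week_origin=d.study_window[0]),
    "flu": lambda d: study_epidemic(d, "J10", week_origin=d.study_window[0]),
    "bariatric": study_bariatric,
    "survival": study_survival,
    "pathways": study_care_pathways,
}
originals = {name: fn(dataset) for name, fn in STUDIES.items()}

rows = []
for scheme, dt in (("base", 1000), ("birth", 1000), ("stay", 1000), ("base", 7)):
    params = SchemeParams(scheme, dt, dt if scheme == "birth" else 0)
    pseudo = apply_scheme(dataset, params, seed=8)
    row = {"scheme": scheme, "delta_t": dt}
    for name, fn in STUDIES.items():
        row[name] = round(unreliability(originals[name], fn(pseudo)).value, 4)
    rows.append(row)

print(pd.DataFrame(rows).to_string(index=False))
# base leaves every interval-based study untouched at any amplitude (the
# epidemic series and window-filtered survival are the exceptions, since
# they depend on absolute dates); stay shifting destroys readmission and
# pathway statistics.
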