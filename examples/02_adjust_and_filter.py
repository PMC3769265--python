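"""From raw weighings to adjusted, filtered records.

A handful of raw records (birth, weaning and yearling-plus weighings) are
adjusted to the standard ages 120/240/365/450 d, grouped into herd-year-
season contemporary groups, and passed through the consistency filters.
The filter report shows how many records and trait values survive each
stage.
"""

import pandas as pd

from willham.preprocess import preprocess_records, screen_fixed_effects

raw = pd.DataFrame([
    # animal sire dam herd birth_date sex dam_age bw  ww  wean_age aw  last_age
    ("c1", "s1", "d1", "1", "1995-02-10", "M", 5, 30, 186, 240, 258, 490),
    ("c2", "s1", "d2", "1", "1995-03-01", "F", 4, 28, 170, 230, 240, 500),
    ("c3", "s1", "d3", "1", "1995-01-20", "M", 6, 32, 180, 250, 265, 480),
    ("c4", "s2", "d4", "1", "1995-02-25", "F", 7, 29, 175, 245, 250, 470),
    ("c5", "s2", "d5", "1", "1995-03-15", "M", 5, 31, 190, 235, 270, 510),
    ("c6", "s2", "d6", "1", "1995-01-05", "F", 4, 27, 165, 240, 235, 495),
    ("c7", "s3", "d7", "1", "1995-02-18", "M", 6, 30, 260, 240, 300, 500),  # outlier WW
], columns=["animal", "sire", "dam", "herd", "birth_date", "sex", "dam_age",
            "bw", "ww", "weaning_age", "aw", "last_age"])

adjusted, report = preprocess_records(raw)
print("filter report (records and non-missing trait values per stage):")
print(report.to_frame().to_string(index=False))
print("\nadjusted records:")
print(adjusted.round(1).to_string(index=False))

print("\npartial F-tests of the fixed effects on W240:")
print(screen_fixed_effects(raw.assign(w240=raw.bw + 240 * (raw.ww - raw.bw) / raw.weaning_age),
                           "w240", effects=("sex", "dam_age")).to_string(index=False))
print("\n(effects with p below the chosen level are kept in the animal model)")
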