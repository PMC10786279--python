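"""Growth and segmentation analysis of two morphologically distinct digits.

Generates the synthetic digit III vs digit IV element-length series (five
vs four phalanges, digit IV initiating at 0.8x the digit III lengths, equal
whole-digit growth during the segmentation window), and runs the full
analysis: per-element OLS growth fits, initiation detection, and the
between-digit comparison table. Writes results/growth_fits.csv and
results/digit_comparison.csv.

Finding: whole-digit growth rates over 144-184 h are statistically
indistinguishable, while per-element initial lengths in digit IV are ~0.8x
their digit III counterparts — the extra element comes from a shorter
segmentation wavelength, not faster overall growth.
"""

from pathlib import Path

import pandas as pd

from digitpattern.growth import compare_digits, fit_growth
from digitpattern.synth import digit_pair_preset

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

digit3, digit4, truth = digit_pair_preset(seed=1)

fits = []
for digit, elements in (("III", digit3), ("IV", digit4)):
    for name, series in elements.items():
        fit = fit_growth(series)
        fits.append({
            "digit": digit, "element": name,
            "slope_um_per_h": fit.slope, "slope_se": fit.slope_se,
            "n": fit.n, "r_squared": fit.r_squared,
        })
pd.DataFrame(fits).to_csv(OUT / "growth_fits.csv", index=False)

table = compare_digits(digit3, digit4)
table.to_csv(OUT / "digit_comparison.csv", index=False)

whole = table[table.element == "digit"].set_index("digit")
print("whole-digit growth rates (144-184 h):")
for digit in ("III", "IV"):
    print(f"  digit {digit}: {whole.loc[digit, 'growth_rate_um_per_h']:.2f} "
          f"+- {whole.loc[digit, 'growth_rate_se']:.2f} um/h")
pairs = table[table.element != "digit"].pivot(
    index="element", columns="digit", values="initial_length_um"
).dropna()
print("initial element lengths (um):")
for element, row in pairs.iterrows():
    print(f"  {element}: III {row['III']:.0f}, IV {row['IV']:.0f} "
          f"(ratio {row['IV']/row['III']:.2f})")
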