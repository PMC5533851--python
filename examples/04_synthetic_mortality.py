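"""The synthetic Swedish-like mortality table.

Generates the default Gompertz–Makeham age-banded mortality table (the
stand-in for unavailable regional life tables), checks its remaining life
expectancy at the three scenario starting ages, and writes it as CSV in the
dialect the cohort model reads back.
"""

from diabcea import MortalityGeneratorParams, generate_mortality_table, life_expectancy

table = generate_mortality_table(MortalityGeneratorParams.default())
for age in (30, 50, 70):
    print(f"remaining life expectancy at {age}: {life_expectancy(table, age):5.1f} years")

print("\nage band        all-cause   T2D-specific")
for lo, hi, q_all, q_t2d in table.bands:
    if 30 <= lo < 90:
        print(f"[{lo:5.0f}, {hi:5.0f})   {q_all:9.5f}   {q_t2d:10.6f}")

table.to_csv("synthetic_mortality.csv")
print("\nwrote synthetic_mortality.csv")
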