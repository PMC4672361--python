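"""BaPeq conversion and standard screening for one water sample.

A surface-water sample with a few detected carcinogens is collapsed to
its BaP-equivalent concentration and screened against the Chinese, US
and Egyptian drinking-water standards.
"""

from pahrisk import (CHINA_STANDARD, EGYPT_STANDARD, US_STANDARD, PEFTable,
                     WaterSample, bapeq_concentration, screen_sample, total_pahs)

sample = WaterSample(
    village_id="R01", group="risk", water_type="SW", season="summer",
    conc={"Nap": 2054.0, "Phe": 730.5, "BaA": 9.4, "Chy": 31.3, "BaP": 11.7,
          "BbF": 2.9, "BkF": 43.9, "IcdP": 9.9},
    nondetect={"DahA": True},
)

pefs = PEFTable()
bapeq = bapeq_concentration(sample, pefs)
print(f"total PAHs : {total_pahs(sample):.1f} ng/L")
print(f"BaPeq      : {bapeq:.2f} ng/L   (BaP alone: {sample.conc['BaP']} ng/L)")
for standard in (CHINA_STANDARD, US_STANDARD, EGYPT_STANDARD):
    print(f"{standard.name:6s} flags: {screen_sample(sample, standard, pefs)}")

# The PEF weighting adds the other carcinogens' BaP-equivalents on top of
# BaP itself, so the sample exceeds the 10 ng/L Chinese BaP/BaPeq limit
# while remaining far below the 200/700 ng/L US/Egyptian BaP limits.
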