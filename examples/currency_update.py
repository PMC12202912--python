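"""Updating a foreign, older cost estimate to Dutch 2023 euros.

Demonstrates the medical basket approach: inflate within the source
economy with its CPI, then convert with hospital-services PPP factors.
The index values below are a small synthetic fixture — real analyses
supply CPI/PPP tables (e.g. from OECD / World Bank) as CSV files.
"""

from ocudelay import PriceIndexTables, update_cost

tables = PriceIndexTables(
    cpi={
        ("USA", 2018): 251.1, ("USA", 2023): 304.7,
        ("NLD", 2018): 103.0, ("NLD", 2023): 124.6,
    },
    ppp_hospital={
        ("USA", 2023): 1.00,  # reference economy
        ("NLD", 2023): 0.88,
        ("USA", 2018): 1.00,
        ("NLD", 2018): 0.91,
    },
)

amount = 236.0  # a 2018 US-dollar cost estimate from the literature
updated = update_cost(amount, "USA", 2018, tables, "NLD", 2023)
print(f"USD {amount:.2f} (USA, 2018) -> EUR {updated:.2f} (NLD, 2023)")

alt = update_cost(amount, "USA", 2018, tables, "NLD", 2023, order="convert_first")
print(f"convert-first convention instead:   EUR {alt:.2f}")
print()
print(
    "The first line inflates 2018->2023 inside the US (CPI ratio 304.7/251.1)\n"
    "and then crosses to the Netherlands with the 2023 hospital-basket PPP\n"
    "ratio (0.88/1.00).  The alternative order converts first and inflates\n"
    "with Dutch CPI; the two differ whenever PPP factors move over time."
)
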