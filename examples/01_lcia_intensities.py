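"""From life-cycle inventory flows to endpoint damage intensities.

Builds a three-flow inventory for two foods, converts it to midpoint
impacts (global warming, water use) with characterization factors, and
then to human-health (DALY/kg) and ecosystem (species/kg) endpoint
intensities.  The endpoint numbers are the per-kg damage the rest of the
pipeline multiplies by national supply.
"""
import pandas as pd

import foodcost as fc

inventory = pd.DataFrame(
    [
        ("beef", "co2", 30.0),      # kg CO2e emitted per kg of beef
        ("beef", "water", 15_000.0),  # litres of irrigation water per kg
        ("beans", "co2", 2.0),
        ("beans", "water", 4_000.0),
    ],
    columns=["item", "flow", "amount"],
)
midpoint_cf = pd.DataFrame(
    [("co2", "global-warming", 1.0), ("water", "water-use", 0.001)],
    columns=["flow", "midpoint", "factor"],
)
endpoint_cf = pd.DataFrame(
    [
        ("global-warming", "HH", 9.3e-7),   # DALY per kg CO2e
        ("global-warming", "ECO", 2.8e-9),  # species-yr per kg CO2e
        ("water-use", "ECO", 6.0e-8),
    ],
    columns=["midpoint", "endpoint", "factor"],
)

midpoints, endpoints = fc.intensities_from_inventory(inventory, midpoint_cf, endpoint_cf)
print("Midpoint intensities (impact per kg of food):")
print(midpoints.to_string(index=False))
print("\nEndpoint intensities (damage per kg of food):")
print(endpoints.to_string(index=False))
print(
    "\nBeef carries ~{:.0f}x the human-health damage of beans per kg; the "
    "water-use midpoint contributes only to the ecosystem endpoint.".format(
        endpoints.query("item=='beef' and endpoint=='HH'")["value"].iloc[0]
        / endpoints.query("item=='beans' and endpoint=='HH'")["value"].iloc[0]
    )
)
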