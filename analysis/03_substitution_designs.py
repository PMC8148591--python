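#!/usr/bin/env python
"""Dilution (substitution) designs: is one substance a dilution of another?

Concentration addition assumes mixture components are dilutions of each
other, so an equitoxic portion of one hyperactive substance should be
replaceable by another without changing the mixture's behaviour per toxic
unit.  This driver derives the two substituted ternary designs - half of
chlorpyrifos' toxic units handed to hexaconazole (from the
chlorpyrifos-oxon pair) or to chlorpyrifos-oxon (from the hexaconazole
pair) at fixed molar share - and reports their molar fractions and CA
predictions.  It also demonstrates the toxic-unit-conserving variant, under
which the CA-predicted EC50 expressed in parent-mixture-equivalent units is
exactly invariant.
"""

import pandas as pd

from stcmix import ca_ecx, equitoxic_design, reference_substances, substitution_design

subs = reference_substances()

pair_a = equitoxic_design(
    [(n, subs[n].crc()) for n in ("chlorpyrifos", "chlorpyrifos-oxon")],
    label="hyper A (chlorpyrifos + oxon)",
)
pair_b = equitoxic_design(
    [(n, subs[n].crc()) for n in ("hexaconazole", "chlorpyrifos")],
    label="hyper B (hexaconazole + chlorpyrifos)",
)

rows = []
for parent, replaced, newcomer in (
    (pair_a, "chlorpyrifos", "hexaconazole"),
    (pair_b, "chlorpyrifos", "chlorpyrifos-oxon"),
):
    share = substitution_design(
        parent, replaced, (newcomer, subs[newcomer].crc()), portion=0.5
    )
    tu = substitution_design(
        parent, replaced, (newcomer, subs[newcomer].crc()), portion=0.5,
        conserve="toxic_units",
    )
    rows.append(
        {
            "parent": parent.label,
            "substituted_fractions": "; ".join(
                f"{c.name}={c.fraction:.3f}" for c in share.components
            ),
            "parent_ca_ec50_um": round(ca_ecx(50.0, parent), 3),
            "substituted_ca_ec50_um": round(ca_ecx(50.0, share), 3),
            "tu_mode_ca_ec50_parent_units": round(
                ca_ecx(50.0, tu) / tu.parent_scale, 9
            ),
        }
    )

table = pd.DataFrame(rows)
print(table.to_string(index=False))
print(
    "\nAt fixed molar share the substituted mixture carries a different toxic-unit "
    "density per mole, so its molar CA EC50 shifts by ~20-30% (up when the "
    "newcomer is less potent per mole, down when more potent) - the same order "
    "as the shifts observed experimentally (factors 1.4 and 1.3).  Conserving toxic "
    "units instead leaves the CA EC50 per parent-equivalent mole exactly "
    "unchanged, which is the dilution identity the substitution experiment tests."
)
table.to_csv("results/substitution.csv", index=False)
print("wrote results/substitution.csv")
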