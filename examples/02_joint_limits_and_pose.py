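"""Joint coordinate systems, posing and the packaged joint-limit table.

Poses the synthetic hindlimb chain in z-y-x Euler order and prints the
packaged limb joint limits (per-DOF minima/maxima and totals, with the
anatomical meaning of each sign).
"""

import numpy as np

from paleolimb import synthetic
from paleolimb.config import gracilisuchus_rom_table
from paleolimb.joints import pose

chain = synthetic.make_toy_chain()
flexed = pose(chain, {"hip": (0.0, 0.0, np.deg2rad(-45)),
                      "knee": (0.0, 0.0, np.deg2rad(-60))})
toe = flexed["toe"][:3, 3]
print(f"toe position with hip flexed 45 deg, knee flexed 60 deg: {toe.round(4)}")
print("(reference pose is the parasagittally straight, all-zeros pose)\n")

print("packaged joint-limit table (degrees):")
print(gracilisuchus_rom_table().to_string(index=False))
print("\nTotals: hip flexion/extension 130, hip long-axis rotation 120, "
      "knee 130 (extension capped at 0), ankle 100, MTP3 165, MCP3 160 -- "
      "wide 3D mobility consistent with neither a fully sprawling nor a "
      "fully erect hindlimb.")
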