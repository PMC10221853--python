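"""Rank the implicit-wall types by their effective interaction strength.

The 9-3 wall eps-W-zc is a two-parameter family; the single scalar
I = int_0^zc exp(-W(z)) dz (a Boltzmann-weighted interaction volume per unit
area) orders walls from barely attractive (I < 1) to strongly attractive.
"""

from hpbrush import effective_wall_strength
from hpbrush.config import parse_wall_name

WALLS = ["1W1", "3W1", "1W1.5", "1W2", "1W2.5", "3W1.5", "3W2", "3W2.5"]

print(f"{'wall':>7}  {'eps':>4}  {'zc':>4}  {'I':>7}")
for name in WALLS:
    spec = parse_wall_name(name)
    i = effective_wall_strength(spec.epsilon, spec.zc)
    print(f"{name:>7}  {spec.epsilon:>4.0f}  {spec.zc:>4.1f}  {i:>7.3f}")

print(
    "\nI < 1 means the attractive well adds less phase-space weight than a "
    "unit slab of free volume: such walls do not adsorb proteins; the "
    "strongest wall (3W2.5) is ~24x more attractive than the weakest (1W1)."
)
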