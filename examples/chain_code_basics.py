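"""Encode ERP-like curves as slope chain codes and compare their shapes.

Builds a P300-like bump and a flat curve, encodes both at S=16 segments,
and prints the chains, their l1 distance, and tortuosities — the three
primitives every later stage builds on. Small distances mean similar
waveshape; tortuosity 0 means a flat (purely horizontal) curve.
"""

import numpy as np

from p300shape import Curve, chain_distance, encode_chain, format_chain, tortuosity

fs = 256.0
t = np.arange(204) / fs
bump = 10.0 * np.exp(-0.5 * ((t - 0.35) / 0.08) ** 2)  # microvolts
wiggly = bump + 3.0 * np.sin(2 * np.pi * 6 * t)

for name, y in [("P300 bump", bump), ("bump + 6 Hz wiggle", wiggly), ("flat", 0 * t)]:
    chain = encode_chain(Curve(np.arange(1, 205), y), 16)
    print(f"{name:>18s}: ({format_chain(chain)})  tortuosity={tortuosity(chain):.2f}")

a = encode_chain(Curve(np.arange(1, 205), bump), 16)
b = encode_chain(Curve(np.arange(1, 205), wiggly), 16)
print(f"\nl1 distance bump vs wiggly: {chain_distance(a, b):.2f}")
print("(0 would mean identical waveshape; each symbol differs by at most 2.)")
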