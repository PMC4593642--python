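"""Motor-clutch regimes of one filopodium against soft vs rigid anchors.

A single filopodium grows toward one collagen fiber, binds it through a
stochastic focal complex and contracts by myosin activity.  Against a rigid
fiber the tip tension ramps within seconds to a sustained ~2 nN; against a
softly tethered fiber the anchor yields, tension builds slowly to a much
weaker level and the filopodium repeatedly fails and regrows
(load-and-fail cycling).
"""

import numpy as np

from filosim.engine import run_single_filopodium
from filosim.filopodium import FiloState

for label, k_anchor in (("rigid anchor", None), ("soft anchor (50 pN/um)", 50.0)):
    out = run_single_filopodium(k_anchor, total_time=600.0, seed=21)
    states = out["state"]
    dwell = {s.name: float((states == int(s)).mean()) for s in FiloState
             if (states == int(s)).any()}
    print(f"--- {label} ---")
    print("fraction of time per phase:",
          {k: round(v, 2) for k, v in dwell.items()})
    print(f"peak tension: {out['tension'].max():.0f} pN, "
          f"peak bonds: {out['bonds'].max()}")
    contractile = states == int(FiloState.CONTRACTILE)
    if contractile.any():
        print(f"mean contractile tension: "
              f"{out['tension'][contractile].mean():.0f} pN")
    print()
print("Rigid anchors load within seconds and sustain nN-scale tension; "
      "soft anchors yield, carry far less tension and cycle through "
      "repeated load-and-fail events.")
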