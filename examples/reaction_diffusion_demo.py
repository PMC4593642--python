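"""Proteolysis biochemistry around a secreting filopodium root.

Solves the seven-species reaction–diffusion network in a small box with
MT1-MMP and TIMP-2 secretion at one grid cell, and reports how active MMP-2
accumulates and erodes the local ECM concentration.
"""

import numpy as np

from filosim.config import RDConfig
from filosim.rd import make_fields, rd_step, secretion_sources

cfg = RDConfig()
fields = make_fields((10, 6, 6), cfg)
root = np.array([2.5, 3.0, 3.0])
sources = secretion_sources([root], fields)
print("secretion cell:", sources)

t = 0.0
for t_end in (60.0, 300.0, 600.0):
    while t < t_end - 1e-9:
        rd_step(fields, cfg, sources, 0.5)   # operator-split 0.5 s steps
        t += 0.5
    i = fields.cell_index(root)
    print(f"t={t_end:5.0f} s: MMP-2 at root = {fields.data['mmp2'][i]:.3e} M, "
          f"ECM integrity at root = {fields.data['ecm'][i] / 10e-6:.3f}")
print("MMP-2 produced via the MT1-MMP/TIMP-2 ternary-complex pathway "
      "degrades the ECM field; crosslink detachment follows this integrity.")
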