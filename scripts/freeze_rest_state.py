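"""Recompute the frozen quiescent rest state of the 41-variable model.

Usage: python scripts/freeze_rest_state.py
Prints the RESTING_STATE block to paste into cell_models/bondarenko.py.
"""

import numpy as np

from micromyo.cell_models.bondarenko import STATE_NAMES, settle

s = settle(2000.0)
print("RESTING_STATE = np.array([")
for name, v in zip(STATE_NAMES, s):
    print(f"    {v!r},  # {name}")
print("])")
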