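"""Disconnectivity graph of a two-funnel landscape.

Minima are grouped into superbasins at descending thresholds (spacing
DELTA, in k_B T); the tree's first split shows which minima only
interconvert over the highest barrier.
"""

import tempfile
from pathlib import Path

import numpy as np

import dridscape as ds

pl = ds.make_landscape(6, "two-funnel", seed=1)
net = pl.to_network()

first = max(net.barriers.values()) + 0.25
cfg = ds.DisconnectivityConfig(delta=0.5, first=first,
                               levels=int(np.ceil(first / 0.5)) + 1)
tree = ds.build_tree(net, cfg)

print(f"thresholds from {tree.thresholds[0]:.2f} down to "
      f"{tree.thresholds[-1]:.2f} k_B T in steps of {cfg.delta}")
for level, nodes in zip(tree.thresholds, tree.levels):
    if len(nodes) > 1:
        print(f"first split at E = {level:.2f} k_B T into "
              f"{[sorted(n.members) for n in nodes]}")
        break

layout = ds.layout_tree(tree)
with tempfile.TemporaryDirectory() as tmp:
    out = ds.render(tree, layout, coloring=net.free_energy, label_lowest=2,
                    path=Path(tmp) / "tree.svg")
    print(f"rendered {out.name} ({out.stat().st_size} bytes)")
print("The two top-level branches are the two planted funnels: every "
      "barrier inside a branch lies below the threshold at which the "
      "branches merge.")
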