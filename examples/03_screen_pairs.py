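"""Screen a small gene panel for differential co-expression.

Stacks two independently simulated gene pairs (one carrying a real
co-expression change, one null) into a 4-gene panel, screens all 6
pairs, and prints the BH-corrected top table.
"""

import numpy as np
import pandas as pd

from zicoex import droplet_preset, screen, simulate, top_table

signal = simulate(droplet_preset(n_patients=5, cells_per_patient=120,
                                 tau0=0.0, tau1=0.45), seed=1)
null = simulate(droplet_preset(n_patients=5, cells_per_patient=120,
                               tau0=0.0, tau1=0.0), seed=2)

cells = [f"c{i:04d}" for i in range(signal.counts.shape[0])]
counts = pd.DataFrame(
    np.vstack([signal.counts.T, null.counts.T]),
    index=["TNF", "SRGN", "ACTB", "GAPDH"], columns=cells)
metadata = pd.DataFrame({"cell_id": cells, "patient": signal.patient,
                         "group": signal.group, "depth": signal.depth})

table = screen(counts, metadata)
print(top_table(table, 6).round(4).to_string(index=False))
print("\nOnly TNF-SRGN was generated with differential co-expression "
      "(tau1=0.45); it should carry the smallest BH-adjusted p-value by a "
      "wide margin. The other pairs are null, but with only 5 patients and "
      "patient-level co-expression variability their estimates scatter "
      "around zero, so an occasional null pair can brush nominal "
      "significance -- rank and effect size matter, not p alone.")
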