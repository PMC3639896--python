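"""Fold-change conventions: per-million abundance, the n.d. rule, DE calling.

A transcript absent from the control library has no finite fold change and is
flagged "n.d." (treated as up-regulated); calling requires no less than a
twofold change and p <= 0.05, with down-regulation at the reciprocal 0.5.
"""

import pandas as pd

from mirtarget import annotate_expression

table = pd.DataFrame(
    {
        "id": ["TBT-like", "GGPPS-like", "cwf22-like", "stable"],
        "count_nonelicited": [0, 120, 500, 380],
        "count_elicited": [35, 370, 210, 385],
        "adjusted_p": [0.001, 0.004, 0.02, 0.6],
    }
)
annotated = annotate_expression(table)
cols = ["id", "abundance_nonelicited", "abundance_elicited", "fold",
        "fold_status", "direction"]
print(annotated[cols].round(2).to_string(index=False))
# "TBT-like" is zero in the control culture: its fold is not determined (nd)
# and it counts as up-regulated; "stable" fails both the fold and p criteria.
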