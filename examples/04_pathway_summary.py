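"""Pathway-level direction summary at the fourfold threshold.

Members count toward a pathway's up/down tallies only when they are
differentially expressed AND change at least fourfold; a pathway is
increased/decreased when all such members move one way, mixed otherwise.
"""

import pandas as pd

from mirtarget import annotate_expression, summarize_pathways

expression = pd.DataFrame(
    {
        "id": ["a", "b", "c", "d", "e", "f"],
        "count_nonelicited": [10, 10, 80, 40, 10, 150],
        "count_elicited": [55, 62, 8, 10, 30, 135],
        "adjusted_p": [0.01] * 6,
    }
)
pathways = pd.DataFrame(
    [
        ("diterpenoid_like", "a"), ("diterpenoid_like", "b"),
        ("cell_cycle_like", "c"), ("cell_cycle_like", "d"),
        ("mixed_pathway", "b"), ("mixed_pathway", "c"),
        ("subthreshold", "e"), ("subthreshold", "f"),
    ],
    columns=["pathway_id", "member_id"],
)
annotated = annotate_expression(expression)
summary = summarize_pathways(annotated, pathways, pathway_fold_threshold=4.0)
print(summary.to_string(index=False))
# "e" is up-regulated (3x) but below the fourfold bar, so "subthreshold"
# classifies as none; pathways with >=4x members in both directions are mixed.
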