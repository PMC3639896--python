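"""Score one miRNA:mRNA duplex and apply the four acceptance rules.

Builds a candidate site from a miRNA's reverse complement, perturbs it with
two mismatches and one G:U wobble, and shows the weighted score and verdict.
"""

from mirtarget import MiRNA, build_site, evaluate_rules, render_duplex, score_duplex

mirna = MiRNA("mir-demo", "UGUGGUAGUAGGUUGUAUAGU")

# two mismatches (miRNA positions 13, 16) and one wobble (position 2)
site = build_site(mirna, mismatch_positions={13, 16}, gu_positions={2})
duplex = score_duplex(mirna, site)
verdict = evaluate_rules(duplex)

print(render_duplex(duplex))
print(f"score = {duplex.score}  (mismatches x 1.0 + wobbles x 0.5)")
print(
    f"total<=4: {verdict.pass_total}  run<=2: {verdict.pass_contiguous}  "
    f"seed<=1: {verdict.pass_seed}  central==0: {verdict.pass_central}"
)
print(f"accepted as a target site: {verdict.passed}")
# Score 2.5 stays under the 4.0 cap and no positional rule is violated, so
# this site would be reported by the scanner.
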