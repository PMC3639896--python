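# mirtarget

Plant miRNA target prediction and two-condition expression integration for
elicitation transcriptomes, built around the workflow used to study methyl
jasmonate (MeJA)-elicited *Taxus* cell cultures: scan assembled transcript
contigs ("unique sequences") for miRNA target sites under strict
complementarity rules, apply the study's fold-change and differential-
expression conventions, summarize regulation at the pathway level, and pair
predicted targets with miRNA expression directions to find complementary
expression patterns — the signature expected of miRNA-mediated repression.

A synthetic-data module generates every input the pipeline needs (transcripts
with planted target sites, decoy sites violating exactly one rule, and
negative-binomial count tables with planted fold tiers), with a ground-truth
ledger, so the whole pipeline is testable end to end without any downloads.

## The duplex model

Plant miRNAs pair with their targets nearly perfectly, so a candidate site is
judged on the ungapped, antiparallel duplex between the miRNA (positions
1..L from the 5′ end) and a transcript window. Each position is a
Watson–Crick match, a G:U wobble, or a mismatch, and the duplex score is

    S = n_mismatch × 1.0 + n_G:U × 0.5

A window is accepted as a target site iff all four rules hold (defaults):

1. total weighted score S ≤ 4.0;
2. no more than 2 contiguous mismatches;
3. at most 1 mismatch in the seed region (miRNA positions 1–9);
4. no mismatch at the central positions 10–11 (the cleavage-spanning sites).

By default wobbles are penalized in S but not counted as mismatches by the
positional rules 2–4 (`RuleConfig(gu_counts_in_positional_rules=True)` gives
the stricter reading).

Expression conventions: abundances are transcripts per million; fold change is
elicited/nonelicited, with a transcript absent from the control library
flagged **n.d.** (not determined, treated as up-regulated); differential
expression requires **no less than** a twofold change (reciprocal 0.5 for
down-regulation, both boundaries inclusive) and p ≤ 0.05; pathway summaries
use a stricter fourfold bar and classify each pathway as
increased / decreased / mixed / none.

## Worked example

```python
from mirtarget import MiRNA, build_site, evaluate_rules, render_duplex, score_duplex

mirna = MiRNA("mir-demo", "UGUGGUAGUAGGUUGUAUAGU")
site = build_site(mirna, mismatch_positions={13, 16}, gu_positions={2})
duplex = score_duplex(mirna, site)
print(render_duplex(duplex))
print(duplex.score, evaluate_rules(duplex).passed)
```

prints

```
5' ACUAUCCACCCUACUACCAUA 3'  target
   ||||| || ||||||||||o|
3' UGAUAUGUUGGAUGAUGGUGU 5'  mir-demo
2.5 True
```

Two mismatches and one wobble give S = 2×1.0 + 1×0.5 = 2.5 ≤ 4.0, with no
positional rule violated, so the site is accepted. The `examples/` directory
holds one short script per capability (duplex rules, transcriptome scanning,
fold-change/DE conventions, pathway summaries, and the full synthetic study);
each prints the numbers it computes and what they mean.

## Command line

The same stages are available as a thin CLI:

```
mirtarget simulate  --seed 11 --outdir demo/        # synthetic study + ledger
mirtarget scan      --mirnas demo/mirnas.fasta --transcripts demo/transcripts.fasta --out demo/hits.tsv
mirtarget de        --expression demo/expression.tsv --out demo/flagged.tsv
mirtarget pathways  --flagged demo/flagged.tsv --pathways demo/pathways.tsv --out demo/pw.tsv
mirtarget integrate --hits demo/hits.tsv --directions demo/mirna_directions.tsv \
                    --expression demo/flagged.tsv --out demo/integration.tsv
mirtarget report    --hits demo/hits.tsv --flagged demo/flagged.tsv \
                    --pathway-summary demo/pw.tsv --integration demo/integration.tsv --out demo/report.txt
```

Outputs are tab-separated with stable column orders, written atomically, and
byte-identical across reruns on identical inputs.

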