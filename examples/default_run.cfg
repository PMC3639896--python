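# Default run configuration (flat key: value; parse with mirtarget.read_config).
#
# Duplex rules — a site is accepted iff all four hold:
# weighted score cap (mismatch = 1.0, G:U wobble = gu_score)
max_total_score: 4.0
# longest tolerated run of consecutive mismatches
max_contiguous_mismatch: 2
# seed region (miRNA positions from the 5' end) and its mismatch allowance:
# 5' mismatches are the most disruptive to plant target recognition
seed_region: 1-9
max_seed_mismatch: 1
# central, cleavage-site-spanning positions: no mismatch tolerated
central_region: 10-11
# wobble penalty: tolerated pairing, half the weight of a mismatch
gu_score: 0.5
# by default wobbles are penalized in the score only, not counted as
# mismatches by the run/seed/central rules; set true for the stricter reading
gu_counts_in_positional_rules: false
#
# Expression conventions:
# differential expression: fold >= 2 (or n.d.) / fold <= 0.5, inclusive
fold_threshold: 2.0
# significance cutoff applied to the supplied p column
p_threshold: 0.05
# stricter bar for the pathway-level direction summary
pathway_fold_threshold: 4.0
# expression input is raw counts (converted to per-million) vs abundances
input_is_counts: true
seed: 0
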