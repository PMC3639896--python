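"""Brute-force rule checker, coded independently of the package's verdict engine.

Works on a symbol string ('M' match, 'G' wobble, 'X' mismatch) and returns the
four pass flags as a tuple, using string operations only.
"""

from mirtarget import PairState

_SYM = {PairState.MATCH: "M", PairState.GU: "G", PairState.MISMATCH: "X"}


def states_to_symbols(states) -> str:
    return "".join(_SYM[s] for s in states)


def brute_force_flags(states, config):
    sym = states_to_symbols(states)
    score = sym.count("X") * 1.0 + sym.count("G") * config.gu_score
    bad = "XG" if config.gu_counts_in_positional_rules else "X"
    marked = "".join("1" if c in bad else "0" for c in sym)
    longest = max((len(chunk) for chunk in marked.split("0")), default=0)
    s_lo, s_hi = config.seed_region
    c_lo, c_hi = config.central_region
    seed_ct = marked[s_lo - 1 : s_hi].count("1")
    central_ct = marked[c_lo - 1 : c_hi].count("1")
    return (
        score <= config.max_total_score,
        longest <= config.max_contiguous_mismatch,
        seed_ct <= config.max_seed_mismatch,
        central_ct == 0,
    )
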