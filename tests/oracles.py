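"""Independent reference implementations used only as test oracles.

These deliberately re-derive the model's rules from first principles with a
different implementation style (log-space step-by-step traces, explicit
counting) so agreement with the package is a meaningful cross-check.
"""

import math

LOG_TIE = 1e-9  # two log-scores within this absolute gap count as tied


def trace_decode(symbols, p_an0, p_na0, e_a, e_n, shift=True):
    """Step-by-step most-likely-path trace over the two hidden states.

    Maintains log path scores for both states, with transition probabilities
    damped by the contiguous-run counters derived from the symbols seen so
    far.  Ties prefer staying in the current state, and the non-adaptive
    state at the end of the sequence.
    """
    assert symbols, "empty sequence"
    c_p = c_notp = 0
    log_scores = {}
    parents = []
    for k, symbol in enumerate(symbols):
        p_an = p_an0 * math.exp(-min(c_p, 50))
        p_na = p_na0 * math.exp(-min(c_notp, 50))
        move = {
            ("N", "N"): 1.0 - p_na,
            ("N", "A"): p_na,
            ("A", "A"): 1.0 - p_an,
            ("A", "N"): p_an,
        }
        emit = {"A": e_a[symbol], "N": e_n[symbol]}
        if k == 0:
            log_scores = {
                s: math.log(move[("N", s)]) + math.log(emit[s]) for s in "NA"
            }
            parents.append({"N": "N", "A": "N"})
        else:
            new_scores, parent = {}, {}
            for s in "NA":
                o = "A" if s == "N" else "N"
                stay = log_scores[s] + math.log(move[(s, s)]) + math.log(emit[s])
                switch = log_scores[o] + math.log(move[(o, s)]) + math.log(emit[s])
                if switch > stay + LOG_TIE:
                    new_scores[s], parent[s] = switch, o
                else:
                    new_scores[s], parent[s] = stay, s
            log_scores = new_scores
            parents.append(parent)
        if symbol == "P":
            c_p, c_notp = c_p + 1, 0
        else:
            c_p, c_notp = 0, c_notp + 1

    state = "A" if log_scores["A"] > log_scores["N"] + LOG_TIE else "N"
    path = [state]
    for parent in reversed(parents[1:]):
        path.append(parent[path[-1]])
    path.reverse()
    if shift and len(path) > 1:
        path = path[1:] + [path[-1]]
    return tuple(path)


def random_emissions(rng, max_length=50):
    length = int(rng.integers(1, max_length + 1))
    return tuple(rng.choice(["P", "N", "Z"], size=length))
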