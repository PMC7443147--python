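"""Straight-line brute-force reference pipeline, independent of the package.

Pure-Python loops over plain dicts: counts -> RPM -> log2 -> guide LFCs ->
median correction -> gene calls.  Used to cross-check the vectorized
implementation on small inputs.
"""

import math


def brute_force_hits(counts, guide_to_gene, treated, control, tau, min_concordant):
    """counts: {sample: {guide: int}}; returns (guide_lfc, gene_calls).

    gene_calls: {gene: (score, n_up, n_down, hit, direction)}.
    """
    samples = list(counts)
    # RPM then log2(x+1), one sample at a time
    logvals = {}
    for s in samples:
        total = 0
        for g in counts[s]:
            total += counts[s][g]
        logvals[s] = {}
        for g in counts[s]:
            rpm = counts[s][g] / total * 1_000_000
            logvals[s][g] = math.log2(rpm + 1.0)

    guides = list(guide_to_gene)
    raw = {}
    for g in guides:
        t_mean = sum(logvals[s][g] for s in treated) / len(treated)
        c_mean = sum(logvals[s][g] for s in control) / len(control)
        raw[g] = t_mean - c_mean

    ordered = sorted(raw.values())
    n = len(ordered)
    if n % 2 == 1:
        med = ordered[n // 2]
    else:
        med = (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0
    corrected = {g: raw[g] - med for g in guides}

    genes = {}
    for g in guides:
        genes.setdefault(guide_to_gene[g], []).append(corrected[g])
    calls = {}
    for gene, vals in genes.items():
        n_up = sum(1 for v in vals if v > tau)
        n_down = sum(1 for v in vals if v < -tau)
        score = sum(vals) / len(vals)
        if len(vals) < min_concordant:
            hit, direction = False, "none"
        elif n_up >= min_concordant and n_down >= min_concordant:
            if n_up > n_down:
                hit, direction = True, "up"
            elif n_down > n_up:
                hit, direction = True, "down"
            else:
                hit, direction = False, "none"
        elif n_up >= min_concordant:
            hit, direction = True, "up"
        elif n_down >= min_concordant:
            hit, direction = True, "down"
        else:
            hit, direction = False, "none"
        calls[gene] = (score, n_up, n_down, hit, direction)
    return corrected, calls
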