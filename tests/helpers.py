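"""Independent brute-force oracles used by several test modules.

These deliberately avoid the package's vectorised scanning code: scoring is
done by per-character comparison over explicit loops so that agreement with
``rponseq.motifs.scan`` is a genuine cross-check.
"""

from rponseq.motifs import IUPAC_SETS, MotifModel, revcomp


def brute_force_best_placements(sequence: str, model: MotifModel):
    """Best (strand, fwd_span_start, spacer, score) placement per element-1
    start, by per-character comparison over explicit loops.

    Mirrors the scanner's contract: at a given element-1 start the
    best-scoring spacer is kept, ties to the shorter spacer; reverse-strand
    placements are reported at their forward-strand span start.
    """
    placements = []
    L = len(sequence)
    e1, w1 = model.upstream.consensus, model.upstream.weights
    e2, w2 = model.downstream.consensus, model.downstream.weights
    for strand, oriented in (("+", sequence), ("-", revcomp(sequence))):
        for p in range(L):
            best = None
            for s in range(model.spacer_range[0], model.spacer_range[1] + 1):
                span = len(e1) + s + len(e2)
                if p + span > L:
                    continue
                score = 0.0
                for j in range(len(e1)):
                    if oriented[p + j] not in IUPAC_SETS[e1[j]]:
                        score += w1[j]
                for j in range(len(e2)):
                    if oriented[p + len(e1) + s + j] not in IUPAC_SETS[e2[j]]:
                        score += w2[j]
                if best is None or score < best[1]:
                    best = (s, score)
            if best is not None:
                span = len(e1) + best[0] + len(e2)
                start = p if strand == "+" else L - p - span
                placements.append((strand, start, best[0], best[1]))
    return placements


def brute_force_scan(sequence: str, model: MotifModel, threshold: float,
                     placements=None):
    """Hits with score ≤ threshold, sorted (independent brute-force oracle)."""
    if placements is None:
        placements = brute_force_best_placements(sequence, model)
    return sorted(h for h in placements if h[3] <= threshold)


def scan_signature(sites):
    """The comparable signature of scanner output."""
    return sorted((s.strand, s.start, s.spacer, s.mismatches) for s in sites)


def anova_f_by_sums_of_squares(groups):
    """One-way ANOVA F from explicit sums of squares (independent oracle)."""
    flat = [x for g in groups for x in g]
    grand = sum(flat) / len(flat)
    ss_between = sum(
        len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups
    )
    ss_within = sum(
        (x - sum(g) / len(g)) ** 2 for g in groups for x in g
    )
    df_between = len(groups) - 1
    df_within = len(flat) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)
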