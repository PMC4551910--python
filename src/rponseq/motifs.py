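"""Bipartite promoter motif models and genome scanning.

The σ54 RNA polymerase holoenzyme recognises a bipartite promoter with
conserved elements centred near −24 (GG core) and −12 (GC core) relative to
the transcription start site.  The C of the −12 GC element is the key
repressive consensus position: promoters that transcribe without an AAA+
activator ("bypass" promoters) tend to carry a non-consensus base there,
while σ54 sites that repress an overlapping σ70 promoter retain the C.
σ70 promoters use the classical −35 TTGACA / −10 TATAAT pair with a
16–18 bp spacer.

Scanning is exhaustive: every placement of the two elements with an allowed
spacer length is scored by weighted mismatches against an IUPAC consensus
(degenerate letters match their base set at zero cost, ``N`` in the subject
sequence never matches).  For a given element-1 start only the best-scoring
spacer is reported (ties broken toward the shorter spacer).  Reverse-strand
sites are reported in forward-strand coordinates with ``strand='-'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("rponseq.motifs")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


#: IUPAC degenerate letter -> set of plain bases it covers.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(b): c for c, b in IUPAC_SETS.items()}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# byte-level encode/decode tables for fast sequence handling
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N to uint8 indices 0..4; reject other letters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = _ENCODE[raw]
    bad = (idx == 4) & (raw != ord("N"))
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return idx


def decode_sequence(idx: np.ndarray) -> str:
    return _DECODE[idx].tobytes().decode("ascii")


@dataclass(frozen=True)
class MotifElement:
    """One conserved element of a bipartite promoter motif."""

    name: str
    consensus: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.consensus) == 0:
            raise ValueError("empty element consensus")
        if len(self.weights) != len(self.consensus):
            raise ValueError("weights and consensus lengths differ")
        if any(w <= 0 for w in self.weights):
            raise ValueError("element weights must be positive")
        bad = set(self.consensus) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifModel:
    """A two-element promoter model with an allowed spacer range.

    Parameters
    ----------
    upstream, downstream
        The 5' and 3' elements on the motif strand (−24/−12 for σ54,
        −35/−10 for σ70).
    spacer_range
        Inclusive (min, max) gap in nt between the elements.
    score_threshold
        Maximum total weighted mismatches for a reported site.
    tss_anchor, tss_offset
        The inferred transcription start lies ``tss_offset`` nt downstream
        of position ``tss_anchor`` within the downstream element.
    minus12_index
        Index of the −12 C consensus position within the downstream element
        (σ54 only; ``None`` for σ70).
    """

    motif_id: str
    upstream: MotifElement
    downstream: MotifElement
    spacer_range: tuple[int, int]
    score_threshold: float
    tss_anchor: int
    tss_offset: int
    minus12_index: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.spacer_range
        if lo < 0 or hi < lo:
            raise ValueError("spacer_range must be non-empty and non-negative")

    @property
    def total_weight(self) -> float:
        return float(sum(self.upstream.weights) + sum(self.downstream.weights))

    @property
    def max_span(self) -> int:
        return len(self.upstream) + self.spacer_range[1] + len(self.downstream)


#: Default σ54 −24/−12 model.  The invariant GG of the −24 element and GC of
#: the −12 element carry weight 2, all other positions weight 1; the −12 C
#: consensus position is the C of TTGC (index 3 of the downstream element).
SIGMA54 = MotifModel(
    motif_id="sigma54",
    upstream=MotifElement("minus24", "TGGCACG", (1, 2, 2, 1, 1, 1, 1)),
    downstream=MotifElement("minus12", "TTGCW", (1, 1, 2, 2, 1)),
    spacer_range=(4, 5),
    score_threshold=2.0,
    tss_anchor=3,
    tss_offset=12,
    minus12_index=3,
)

#: Default σ70 −35/−10 model, uniform weights.
SIGMA70 = MotifModel(
    motif_id="sigma70",
    upstream=MotifElement("minus35", "TTGACA", (1,) * 6),
    downstream=MotifElement("minus10", "TATAAT", (1,) * 6),
    spacer_range=(16, 18),
    score_threshold=3.0,
    tss_anchor=0,
    tss_offset=7,
)

MODELS = {"sigma54": SIGMA54, "sigma70": SIGMA70}


@dataclass(frozen=True)
class PromoterSite:
    """A located promoter motif occurrence, in forward-strand coordinates.

    ``elements`` lists (name, start, end) 0-based half-open intervals in
    forward coordinates, ordered 5'→3' on the motif strand; ``matched``
    holds the corresponding motif-strand sequences.  ``mismatches`` is the
    total weighted mismatch count and ``score = total_weight − mismatches``
    (a perfect consensus match scores the maximum).  ``tss`` is the inferred
    transcription start (forward coordinate), ``minus12_base`` the base at
    the −12 C consensus position on the motif strand (σ54 only).
    """

    motif_id: str
    strand: str
    start: int
    end: int
    elements: tuple[tuple[str, int, int], ...]
    matched: tuple[tuple[str, str], ...]
    spacer: int
    mismatches: float
    score: float
    tss: int
    minus12_base: str | None = None
    seq_id: str = "genome"

    def element(self, name: str) -> tuple[int, int]:
        for nm, s, e in self.elements:
            if nm == name:
                return s, e
        raise KeyError(name)

    def matched_seq(self, name: str) -> str:
        for nm, s in self.matched:
            if nm == name:
                return s
        raise KeyError(name)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def _element_cost(idx: np.ndarray, element: MotifElement) -> np.ndarray:
    """Weighted mismatch cost of *element* at every start position."""
    m = len(element)
    n = len(idx) - m + 1
    if n <= 0:
        return np.empty(0)
    cost = np.zeros(n)
    for j, (letter, w) in enumerate(zip(element.consensus, element.weights)):
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC_SETS[letter]:
            allowed[_BASE_INDEX[b]] = True
        cost += w * (~allowed[idx[j : j + n]])
    return cost


def scan(
    sequence: str,
    model: MotifModel,
    both_strands: bool = True,
    threshold: float | None = None,
    seq_id: str = "genome",
) -> list[PromoterSite]:
    """All motif occurrences with weighted mismatches ≤ threshold.

    Returns sites sorted by forward span start (forward strand first at
    equal starts).  At a given element-1 start the single best-scoring
    spacer is reported; ties go to the shorter spacer.
    """
    if threshold is None:
        threshold = model.score_threshold
    L = len(sequence)
    min_span = len(model.upstream) + model.spacer_range[0] + len(model.downstream)
    if L < min_span:
        raise ValueError(
            f"sequence ({L} nt) shorter than minimum motif span ({min_span} nt)"
        )
    sequence = sequence.upper()
    hits: list[PromoterSite] = []
    orientations = [("+", sequence)]
    if both_strands:
        orientations.append(("-", revcomp(sequence)))
    m1, m2 = len(model.upstream), len(model.downstream)
    smin, smax = model.spacer_range
    for strand, oriented in orientations:
        idx = encode_sequence(oriented)
        c1 = _element_cost(idx, model.upstream)
        c2 = _element_cost(idx, model.downstream)
        n_max = L - min_span + 1
        totals = np.full((smax - smin + 1, n_max), np.inf)
        for k, s in enumerate(range(smin, smax + 1)):
            span = m1 + s + m2
            n = L - span + 1
            if n <= 0:
                continue
            totals[k, :n] = c1[:n] + c2[m1 + s : m1 + s + n]
        best_k = totals.argmin(axis=0)  # first minimum -> shortest spacer
        best = totals[best_k, np.arange(n_max)]
        for p in np.nonzero(best <= threshold)[0]:
            s = smin + int(best_k[p])
            hits.append(
                _make_site(model, oriented, strand, int(p), s,
                           float(best[p]), L, seq_id)
            )
    hits.sort(key=lambda h: (h.start, h.strand, h.spacer))
    return hits


def _make_site(
    model: MotifModel,
    oriented: str,
    strand: str,
    p: int,
    spacer: int,
    mismatches: float,
    L: int,
    seq_id: str,
) -> PromoterSite:
    m1, m2 = len(model.upstream), len(model.downstream)
    e1 = (p, p + m1)
    e2 = (p + m1 + spacer, p + m1 + spacer + m2)
    span = (p, e2[1])

    def fwd(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return iv
        return L - iv[1], L - iv[0]

    tss_oriented = e2[0] + model.tss_anchor + model.tss_offset
    tss = tss_oriented if strand == "+" else L - 1 - tss_oriented
    minus12_base = None
    if model.minus12_index is not None:
        minus12_base = oriented[e2[0] + model.minus12_index]
    f_span = fwd(span)
    return PromoterSite(
        motif_id=model.motif_id,
        strand=strand,
        start=f_span[0],
        end=f_span[1],
        elements=(
            (model.upstream.name,) + fwd(e1),
            (model.downstream.name,) + fwd(e2),
        ),
        matched=(
            (model.upstream.name, oriented[e1[0] : e1[1]]),
            (model.downstream.name, oriented[e2[0] : e2[1]]),
        ),
        spacer=spacer,
        mismatches=mismatches,
        score=model.total_weight - mismatches,
        tss=tss,
        minus12_base=minus12_base,
        seq_id=seq_id,
    )


def minus12_conservation(sites: list[PromoterSite]) -> float:
    """Fraction of σ54 sites whose −12 consensus position carries a C.

    The C of the −12 GC element is conserved in ~96% of bacterial σ54
    promoters but is typically lost at bypass-capable promoters; this
    statistic summarises a hit set.  Undefined (raises) for an empty list.
    """
    if not sites:
        raise ValueError("−12 conservation is undefined for an empty site list")
    bases = []
    for s in sites:
        if s.minus12_base is None:
            raise ValueError(f"site at {s.start} has no −12 position (not a σ54 site)")
        bases.append(s.minus12_base)
    return sum(b == "C" for b in bases) / len(bases)


def build_consensus(sites: list[PromoterSite]) -> tuple[pd.DataFrame, str]:
    """Per-position base frequencies and IUPAC consensus of a hit set.

    Sites are aligned by concatenating their element sequences (spacers
    removed) so all rows have equal width.  Each consensus letter is the
    majority base if a single base reaches frequency ≥ 0.75, otherwise the
    IUPAC code covering all bases with frequency ≥ 0.25.
    """
    if not sites:
        raise ValueError("cannot build a consensus from an empty site list")
    rows = ["".join(seq for _, seq in s.matched) for s in sites]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"mixed aligned widths {sorted(widths)}; sites must share a motif model")
    width = widths.pop()
    counts = np.zeros((4, width))
    for r in rows:
        for j, b in enumerate(r):
            counts[_BASE_INDEX[b], j] += 1
    freq = counts / len(rows)
    letters = []
    bases = "ACGT"
    for j in range(width):
        col = freq[:, j]
        if col.max() >= 0.75:
            letters.append(bases[int(col.argmax())])
        else:
            present = frozenset(bases[i] for i in range(4) if col[i] >= 0.25)
            letters.append(_SET_TO_IUPAC[present])
    freq_df = pd.DataFrame(freq, index=list(bases))
    return freq_df, "".join(letters)


def assign_sites_to_genes(
    sites: list[PromoterSite],
    genes,
    window_upstream: int = 300,
    window_downstream: int = 100,
) -> list[str | None]:
    """Map each site to a gene by promoter-window proximity.

    A site is assigned to a gene when its inferred tss lies within
    ``[gene 5' − window_upstream, gene 5' + window_downstream)`` measured
    along the gene's orientation (the gene 5' end is ``start`` on the
    forward strand and ``end − 1`` on the reverse strand).  When several
    genes qualify the nearest wins; exact distance ties go to the gene with
    the smaller start coordinate.  Returns one gene_id (or None) per site.
    """
    if window_upstream < 0 or window_downstream < 0:
        raise ValueError("windows must be non-negative")
    assignments: list[str | None] = []
    for site in sites:
        best: tuple[int, int, str] | None = None
        for g in genes:
            five_p = g.start if g.strand == "+" else g.end - 1
            offset = site.tss - five_p if g.strand == "+" else five_p - site.tss
            if -window_upstream <= offset < window_downstream:
                key = (abs(offset), g.start, g.gene_id)
                if best is None or key < best:
                    best = key
        assignments.append(best[2] if best else None)
    return assignments
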