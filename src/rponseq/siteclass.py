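"""Positional classification of σ54 sites at σ54-repressed genes.

At genes whose expression rises when σ54 is absent, the location of the
σ54 −24/−12 site relative to the active σ70 promoter suggests the
repression mechanism.  Sites are grouped into four classes by overlap with
the likely σ70 RNA polymerase footprint and by strand:

* class I  — σ54 site overlaps the σ70 footprint on the same strand
  (direct binding competition);
* class II — overlaps the footprint on the opposite strand;
* class III — no overlap but within ``distal_cutoff`` bp of the footprint;
* class IV — distal, e.g. a convergent site far downstream of the σ70 tss,
  where interference between converging polymerases rather than simple
  promoter occlusion is the plausible mechanism.

The footprint is the interval from ``pad_upstream`` bp before the −35
element to ``pad_downstream`` bp past the tss, on the σ70 strand.  Class
boundaries are configurable and recorded in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .contrast import GeneCall
from .motifs import PromoterSite, assign_sites_to_genes, build_consensus

logger = logging.getLogger("rponseq.siteclass")

DEFAULT_PAD_UPSTREAM = 5
DEFAULT_PAD_DOWNSTREAM = 20
DEFAULT_DISTAL_CUTOFF = 100


def sigma70_footprint(
    site: PromoterSite,
    pad_upstream: int = DEFAULT_PAD_UPSTREAM,
    pad_downstream: int = DEFAULT_PAD_DOWNSTREAM,
) -> tuple[int, int]:
    """Likely σ70 holoenzyme footprint, as a forward-strand interval.

    On the σ70 strand the footprint runs from ``pad_upstream`` bp before
    the −35 element start to ``pad_downstream`` bp past the tss.
    """
    if site.motif_id != "sigma70":
        raise ValueError(f"footprint requires a σ70 site, got {site.motif_id}")
    e35 = site.element("minus35")
    if site.strand == "+":
        return e35[0] - pad_upstream, site.tss + pad_downstream
    return site.tss - pad_downstream + 1, e35[1] + pad_upstream


@dataclass(frozen=True)
class SiteClassCall:
    """One classified (gene, σ54 site, σ70 site) configuration.

    ``offset_bp`` is the signed distance from the σ54 −12 element midpoint
    to the σ70 tss, positive downstream in the σ70 promoter's orientation;
    ``overlap_bp`` is the overlap of the σ54 element span with the σ70
    footprint (class IV implies zero); ``distance_bp`` the gap between
    them when disjoint.
    """

    gene_id: str
    site_class: str
    offset_bp: int
    overlap_bp: int
    distance_bp: int
    sigma54_site: PromoterSite
    sigma70_site: PromoterSite


def classify_site(
    s54: PromoterSite,
    s70: PromoterSite,
    footprint: tuple[int, int] | None = None,
    distal_cutoff: int = DEFAULT_DISTAL_CUTOFF,
    pad_upstream: int = DEFAULT_PAD_UPSTREAM,
    pad_downstream: int = DEFAULT_PAD_DOWNSTREAM,
    gene_id: str = "",
) -> SiteClassCall:
    """Assign one σ54/σ70 site pair to positional class I–IV."""
    if s54.seq_id != s70.seq_id:
        raise ValueError(
            f"sites on different sequences ({s54.seq_id!r} vs {s70.seq_id!r})"
        )
    if footprint is None:
        footprint = sigma70_footprint(s70, pad_upstream, pad_downstream)
    span = s54.span
    overlap = max(0, min(span[1], footprint[1]) - max(span[0], footprint[0]))
    if overlap > 0:
        site_class = "I" if s54.strand == s70.strand else "II"
        distance = 0
    else:
        distance = max(footprint[0] - span[1], span[0] - footprint[1])
        site_class = "III" if distance <= distal_cutoff else "IV"
    e12 = s54.element("minus12")
    mid12 = (e12[0] + e12[1]) // 2
    offset = mid12 - s70.tss if s70.strand == "+" else s70.tss - mid12
    return SiteClassCall(
        gene_id=gene_id,
        site_class=site_class,
        offset_bp=int(offset),
        overlap_bp=int(overlap),
        distance_bp=int(distance),
        sigma54_site=s54,
        sigma70_site=s70,
    )


@dataclass
class RepressedClassification:
    """Classified σ54-repressed genes plus per-class summaries."""

    calls: list[SiteClassCall]
    counts: dict[str, int]
    consensus: dict[str, str] = field(default_factory=dict)
    unclassifiable: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": c.gene_id,
                "site_class": c.site_class,
                "offset_bp": c.offset_bp,
                "overlap_bp": c.overlap_bp,
                "distance_bp": c.distance_bp,
                "sigma54_start": c.sigma54_site.start,
                "sigma54_end": c.sigma54_site.end,
                "sigma54_strand": c.sigma54_site.strand,
                "sigma54_score": c.sigma54_site.score,
                "minus12_base": c.sigma54_site.minus12_base,
                "sigma70_start": c.sigma70_site.start,
                "sigma70_end": c.sigma70_site.end,
                "sigma70_strand": c.sigma70_site.strand,
                "sigma70_tss": c.sigma70_site.tss,
            }
            for c in self.calls
        ]
        columns = [
            "gene_id", "site_class", "offset_bp", "overlap_bp", "distance_bp",
            "sigma54_start", "sigma54_end", "sigma54_strand", "sigma54_score",
            "minus12_base", "sigma70_start", "sigma70_end", "sigma70_strand",
            "sigma70_tss",
        ]
        return pd.DataFrame(rows, columns=columns)


def _best_site(sites: list[PromoterSite]) -> PromoterSite:
    # highest similarity score wins; ties to the leftmost site
    return sorted(sites, key=lambda s: (-s.score, s.start))[0]


def classify_repressed_set(
    calls,
    sigma54_sites: list[PromoterSite],
    sigma70_sites: list[PromoterSite],
    genes,
    window_upstream: int = 300,
    window_downstream: int = 100,
    pad_upstream: int = DEFAULT_PAD_UPSTREAM,
    pad_downstream: int = DEFAULT_PAD_DOWNSTREAM,
    distal_cutoff: int = DEFAULT_DISTAL_CUTOFF,
) -> RepressedClassification:
    """Classify every σ54-repressed gene with assigned σ54 and σ70 sites.

    ``calls`` is the per-gene call table from :func:`rponseq.contrast.
    call_genome` (or a list of :class:`GeneCall`).  Sites are attached to
    genes by promoter-window proximity; at genes with several candidate
    σ54 (or σ70) sites the best-scoring one is used and the choice logged.
    Genes missing either site type are reported as unclassifiable.
    A per-class σ54 consensus is built for classes with ≥ 2 members.
    """
    if isinstance(calls, pd.DataFrame):
        repressed_ids = list(calls.index[calls["category"] == "sigma54_repressed"])
    else:
        repressed_ids = [c.gene_id for c in calls if c.category == "sigma54_repressed"]

    gene_map = {g.gene_id: g for g in genes}
    by_gene_54: dict[str, list[PromoterSite]] = {}
    by_gene_70: dict[str, list[PromoterSite]] = {}
    for sites, bucket in ((sigma54_sites, by_gene_54), (sigma70_sites, by_gene_70)):
        for site, gid in zip(
            sites,
            assign_sites_to_genes(sites, genes, window_upstream, window_downstream),
        ):
            if gid is not None:
                bucket.setdefault(gid, []).append(site)

    out_calls: list[SiteClassCall] = []
    unclassifiable: list[tuple[str, str]] = []
    for gid in repressed_ids:
        if gid not in gene_map:
            unclassifiable.append((gid, "unknown gene"))
            continue
        cands54 = by_gene_54.get(gid, [])
        cands70 = by_gene_70.get(gid, [])
        if not cands54 or not cands70:
            missing = "sigma54" if not cands54 else "sigma70"
            unclassifiable.append((gid, f"no {missing} site assigned"))
            continue
        s54 = _best_site(cands54)
        s70 = _best_site(cands70)
        if len(cands54) > 1:
            logger.info(
                "%s: %d σ54 sites assigned, using best-scoring at %d (score %.1f)",
                gid, len(cands54), s54.start, s54.score,
            )
        out_calls.append(
            classify_site(
                s54, s70,
                distal_cutoff=distal_cutoff,
                pad_upstream=pad_upstream,
                pad_downstream=pad_downstream,
                gene_id=gid,
            )
        )

    counts = {cls: 0 for cls in ("I", "II", "III", "IV")}
    for c in out_calls:
        counts[c.site_class] += 1
    consensus: dict[str, str] = {}
    for cls in counts:
        members = [c.sigma54_site for c in out_calls if c.site_class == cls]
        if len(members) >= 2:
            _, consensus[cls] = build_consensus(members)
    return RepressedClassification(out_calls, counts, consensus, unclassifiable)
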